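"""Tabular IO, configuration and the end-to-end pipeline driver.

Canonical on-disk format is TSV with a header (CSV accepted by extension).
IGP tables need columns ``protein_id``, ``glycosite``, ``peptide``,
``glycan_code`` and one intensity column per TMT channel; ``composition``,
``oacetyl``, ``psm_id`` and ``sequon`` are optional.  Rows whose structure
code fails to parse are quarantined, not fatal; duplicate IGP keys are
treated as PSM replicates.  All positions are 1-based.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .factors import decompose_table
from .features import MotifTable, featurize_table
from .glycan import (GlycanParseError, GlycanStructureError,
                     convert_structure_code, parse_composition,
                     parse_structure, serialize_canonical)
from .integration import pair_glyco_phospho
from .mining import (IGP_KEY_COLUMNS, altered_fraction_per_feature,
                     detect_site_shifts, feature_summary,
                     glycosites_per_protein, motif_split, pair_oacetyl,
                     top_n_glycans, unique_igps)
from .quant import (SampleDesign, Thresholds, derive_scaling_factors,
                    differential_table, normalize_by_protein,
                    normalize_channels, quadrant_classify)

__all__ = [
    "ConfigError", "DataError", "PipelineConfig",
    "read_igp_table", "write_igp_table", "read_design", "write_design",
    "read_quant_table", "run_pipeline",
]

REQUIRED_IGP_COLUMNS = ("protein_id", "glycosite", "peptide", "glycan_code")


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Unreadable or structurally invalid input data (CLI exit code 3)."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype={"glycan_code": str})


def read_igp_table(
    path: str | Path,
    channels: list[str] | None = None,
    dialect: str | None = None,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate an IGP table.

    Returns (records, quarantined).  Structure codes are run through the
    optional dialect converter, parsed (strict by default) and replaced by
    their canonical serialization; a ``composition`` column, when present,
    is checked against the structure's own composition.  Unparseable rows
    land in the quarantine frame with a ``quarantine_reason`` column.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_IGP_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"IGP table {path} lacks required column(s) {missing}")
    if channels:
        missing_ch = [c for c in channels if c not in df.columns]
        if missing_ch:
            raise DataError(
                f"IGP table {path} lacks channel column(s) {missing_ch}")
    if "oacetyl" not in df.columns:
        df["oacetyl"] = False
    df["oacetyl"] = df["oacetyl"].astype(bool)
    reasons = {}
    canon = {}
    for code in df["glycan_code"].unique():
        try:
            native = convert_structure_code(str(code), dialect)
            canon[code] = serialize_canonical(
                parse_structure(native, relaxed=not strict))
        except (GlycanParseError, GlycanStructureError) as exc:
            reasons[code] = str(exc)
    bad = df["glycan_code"].isin(reasons)
    quarantined = df[bad].copy()
    if len(quarantined):
        quarantined["quarantine_reason"] = quarantined["glycan_code"].map(
            reasons)
    records = df[~bad].copy()
    records["canonical_code"] = records["glycan_code"].map(canon)
    if "composition" in records.columns:
        mismatch = []
        for code, comp in zip(records["glycan_code"],
                              records["composition"]):
            if isinstance(comp, str) and comp:
                try:
                    declared = parse_composition(comp, relaxed=True)
                except GlycanParseError:
                    mismatch.append(True)
                    continue
                native = convert_structure_code(str(code), dialect)
                actual = parse_structure(native, relaxed=True).composition()
                mismatch.append(declared != actual)
            else:
                mismatch.append(False)
        records["flag_composition_mismatch"] = mismatch
    return records, quarantined


def write_igp_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an IGP (or any result) table as TSV/CSV by extension.

    Floats carry 6 significant digits; counts stay integers.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, (frozenset, set, tuple))).any():
            out[col] = out[col].map(
                lambda v: ";".join(sorted(map(str, v)))
                if isinstance(v, (frozenset, set, tuple)) else v)
    out.to_csv(path, sep=sep, index=False, float_format="%.6g")


def read_design(path: str | Path) -> SampleDesign:
    """Design TSV/CSV with columns channel, group, sex (sex optional)."""
    df = _read_table(path)
    for col in ("channel", "group"):
        if col not in df.columns:
            raise DataError(f"design file {path} lacks column {col!r}")
    df["channel"] = df["channel"].astype(str)
    groups = dict(zip(df["channel"], df["group"]))
    sexes = dict(zip(df["channel"], df["sex"])) if "sex" in df.columns else {}
    order = list(dict.fromkeys(df["group"]))
    if len(order) != 2:
        raise DataError(
            f"design must define exactly 2 groups, got {order}")
    try:
        return SampleDesign(groups=groups, sexes=sexes,
                            group_a=order[0], group_b=order[1])
    except ValueError as exc:
        raise DataError(str(exc)) from exc


def write_design(design: SampleDesign, path: str | Path) -> None:
    rows = [(c, design.groups[c], design.sexes.get(c, ""))
            for c in design.channels]
    pd.DataFrame(rows, columns=["channel", "group", "sex"]).to_csv(
        path, sep="\t", index=False)


def read_quant_table(path: str | Path, index_col: str) -> pd.DataFrame:
    """Protein / phospho quantification table indexed by its id column."""
    df = _read_table(path)
    if index_col not in df.columns:
        raise DataError(f"table {path} lacks column {index_col!r}")
    return df


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable).

    Unknown keys are rejected so silent typos cannot change an analysis.
    """

    igp_table: str = ""
    design: str = ""
    protein_table: str | None = None
    phospho_table: str | None = None
    motif_table: str | None = None      # YAML: {label: branch code}
    out_dir: str = "results"
    fc: float = 1.5
    p: float = 0.05
    use_fdr: bool = False
    welch: bool = False
    strict_parsing: bool = True
    dialect: str | None = None
    exclude_oligomannose_in_proportions: bool = False
    anova_method: str = "centered"
    r_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc <= 1 or not (0 < self.p < 1):
            raise ConfigError("thresholds: fc must be >1 and p in (0,1)")
        if self.anova_method not in ("centered", "stratified"):
            raise ConfigError(f"unknown anova_method {self.anova_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def thresholds(self) -> Thresholds:
        return Thresholds(fc=self.fc, p=self.p, use_fdr=self.use_fdr,
                          welch=self.welch)


def _aggregate(igp: pd.DataFrame, channels: list[str]) -> pd.DataFrame:
    """PSM rows -> per-IGP channel medians, indexed by the IGP key."""
    keyed = igp.set_index([c for c in IGP_KEY_COLUMNS if c in igp.columns])
    return keyed.groupby(level=list(range(keyed.index.nlevels)))[
        channels].median()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full mining pipeline and write results under out_dir.

    Stages: read/validate -> featurize -> normalize -> PSM aggregation ->
    differential testing -> protein normalization and quadrants (skipped
    with a flag when no protein table is given) -> feature mining ->
    age/sex decomposition (needs sex labels) -> glyco-phospho integration
    (needs a phospho table).  Returns the manifest dict; outputs are
    deterministic given inputs + config.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "glycomine_version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "stages": {},
        "skipped": [],
    }
    design = read_design(config.design)
    channels = design.channels
    records, quarantined = read_igp_table(
        config.igp_table, channels=channels, dialect=config.dialect,
        strict=config.strict_parsing)
    manifest["stages"]["read"] = {
        "rows": int(len(records)), "quarantined": int(len(quarantined))}
    if len(quarantined):
        write_igp_table(quarantined, out_dir / "quarantined_rows.tsv")

    motif_table = None
    if config.motif_table:
        extra = yaml.safe_load(Path(config.motif_table).read_text()) or {}
        motif_table = MotifTable(extra)
    records = featurize_table(records, table=motif_table)
    manifest["stages"]["featurize"] = {
        "unique_igps": int(len(unique_igps(records))),
        "unique_structures": int(records["canonical_code"].nunique())}

    protein_quant = None
    factors = "self"
    if config.protein_table:
        protein_quant = read_quant_table(
            config.protein_table, "protein_id").set_index("protein_id")
        factors = derive_scaling_factors(protein_quant[channels])
    records[channels] = normalize_channels(records[channels], factors)

    aggregated = _aggregate(records, channels)
    manifest["stages"]["aggregate"] = {"igps": int(len(aggregated))}

    thresholds = config.thresholds()
    diff = differential_table(aggregated, design, thresholds)
    manifest["stages"]["differential"] = {
        "up": int((diff["call"] == "up").sum()),
        "down": int((diff["call"] == "down").sum()),
        "ns": int((diff["call"] == "ns").sum())}

    igps = unique_igps(records).set_index(
        [c for c in IGP_KEY_COLUMNS if c in records.columns])
    igps = igps.join(diff, how="left").reset_index()

    if protein_quant is not None:
        prot_norm = normalize_channels(protein_quant[channels], factors)
        prot_diff = differential_table(prot_norm, design, thresholds)
        pfc = igps["protein_id"].map(prot_diff["fc"])
        ppv = igps["protein_id"].map(prot_diff["p"])
        keyed = igps.set_index(
            [c for c in IGP_KEY_COLUMNS if c in igps.columns])
        keyed = normalize_by_protein(keyed, pfc.values, ppv.values)
        keyed["quadrant"] = quadrant_classify(keyed, thresholds)
        igps = keyed.reset_index()
        prot_diff.to_csv(out_dir / "protein_differential.tsv", sep="\t",
                         float_format="%.6g")
        manifest["stages"]["quadrant"] = dict(
            igps["quadrant"].value_counts().astype(int))
    else:
        manifest["skipped"].append("protein-normalization/quadrant")

    write_igp_table(igps, out_dir / "igp_differential.tsv")

    summaries = pd.concat(
        [feature_summary(igps, axis,
                         config.exclude_oligomannose_in_proportions)
         for axis in ("core", "subtype", "branch", "fucosylation",
                      "sialylation", "antenna")],
        ignore_index=True)
    write_igp_table(summaries, out_dir / "feature_summaries.tsv")
    write_igp_table(altered_fraction_per_feature(igps),
                    out_dir / "altered_fractions.tsv")
    write_igp_table(top_n_glycans(igps, 10, "glycosite_count"),
                    out_dir / "top_glycans_overall.tsv")
    write_igp_table(
        top_n_glycans(igps, 10, "direction", exclude_oligomannose=True),
        out_dir / "top_glycans_differential.tsv")

    shifts = detect_site_shifts(igps)
    shift_df = pd.DataFrame(
        [(s.protein_id, s.glycosite, len(s.up_igps), len(s.down_igps),
          json.dumps(s.contrasts, sort_keys=True))
         for s in shifts],
        columns=["protein_id", "glycosite", "n_up", "n_down", "contrasts"])
    write_igp_table(shift_df, out_dir / "shift_sites.tsv")
    manifest["stages"]["shift_sites"] = {"n": int(len(shift_df))}

    oac = pair_oacetyl(igps)
    manifest["stages"]["oacetyl"] = {
        "n_pairs": int(oac["n_pairs"]),
        "spearman_r": None if np.isnan(oac["spearman_r"])
        else float(oac["spearman_r"])}

    glycosites_per_protein(igps).rename_axis("n_glycosites").reset_index() \
        .to_csv(out_dir / "glycosites_per_protein.tsv", sep="\t", index=False)
    motif_split(igps).rename_axis("class").reset_index(name="value") \
        .to_csv(out_dir / "sequon_motifs.tsv", sep="\t",
                index=False, float_format="%.6g")

    if design.sexes:
        fac = decompose_table(aggregated, design,
                              method=config.anova_method)
        fac.reset_index().to_csv(out_dir / "factor_decomposition.tsv",
                                 sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["factors"] = dict(
            fac["assignment"].value_counts().astype(int))
    else:
        manifest["skipped"].append("factor-decomposition")

    if config.phospho_table:
        phospho = read_quant_table(config.phospho_table, "protein_id")
        glyco_sites = igps.groupby(["protein_id", "glycosite"])[
            channels].mean().reset_index()
        pairs = pair_glyco_phospho(
            glyco_sites, phospho, protein_quant, channels,
            r_threshold=config.r_threshold, p_threshold=config.p)
        write_igp_table(pairs, out_dir / "glyco_phospho_pairs.tsv")
        manifest["stages"]["glyco_phospho"] = dict(
            pairs["classification"].value_counts().astype(int))
    else:
        manifest["skipped"].append("glyco-phospho-correlation")

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
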