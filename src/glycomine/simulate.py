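"""Synthetic glyco-/proteo-/phospho-dataset generator with known ground truth.

The generator emulates the study design the quantitative layer is built for:
a 10-channel TMT experiment with two groups of five pooled samples (3 female
and 2 male channels per group), log-normal reporter noise around per-IGP
group means, PSM-level replication, feature-selected planted fold-change
shifts at the glycosylation level, protein-level confounding that propagates
into the raw IGP intensities, designated glycan-shift glycosites, O-acetyl
twin glycopeptides and glyco-phospho coupled site pairs.  Every planted
quantity is recorded in truth tables so each pipeline stage can be scored
against ground truth without any external data.

Structures in the glycan library are assembled from exemplar branch motifs
on the four core classes, so the generator's truth labels are fixed by
construction and never derived from the feature classifiers they are used
to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import EMPTY_BRANCH
from .glycan import MAN_TOPOLOGIES, parse_structure, serialize_canonical
from .quant import SampleDesign

__all__ = [
    "LibrarySpecError",
    "PlantedEffect",
    "GeneratorSpec",
    "SyntheticDataset",
    "motif_exemplars",
    "generate_glycan_library",
    "generate_igp_dataset",
]


class LibrarySpecError(ValueError):
    """Impossible glycan class combination requested."""


#: Exemplar branch subtree per HexNAc-initiated motif label.  The sLewis and
#: sialyl-LacdiNAc exemplars use Neu5Ac; Neu5Gc enters via its own LacNAc
#: motif, keeping planted sialylation classes unambiguous.
N_MOTIF_EXEMPLARS: dict[str, str] = {
    "sole GlcNAc": "N",
    "LacNAc": "N(H)",
    "sialyl-LacNAc-Neu5Ac": "N(H(A))",
    "sialyl-LacNAc-Neu5Gc": "N(H(G))",
    "Lewis x/a": "N(F)(H)",
    "Lewis y/b": "N(F)(H(F))",
    "sLewis x/a": "N(F)(H(A))",
    "LacdiNAc": "N(N)",
    "sialyl-LacdiNAc": "N(N(A))",
    "fucosylated LacdiNAc": "N(F)(N)",
    "polyLacNAc": "N(H(N(H)))",
}

#: Motifs whose exemplar carries an antenna fucose.
_ANTENNA_FUC = {"Lewis x/a", "Lewis y/b", "sLewis x/a", "fucosylated LacdiNAc"}
#: Motif -> sialic acids contributed by the exemplar.
_SIALIC = {
    "sialyl-LacNAc-Neu5Ac": "A",
    "sLewis x/a": "A",
    "sialyl-LacdiNAc": "A",
    "sialyl-LacNAc-Neu5Gc": "G",
}

_CORE_FLAGS = {
    "Core-I": (False, False),
    "Core-II": (True, False),
    "Core-III": (False, True),
    "Core-IV": (True, True),
}

#: Branch multiset and antenna count of the fixed Man-k topologies.
_MAN_BRANCHES = {
    3: (EMPTY_BRANCH, EMPTY_BRANCH),
    4: ("Hex", EMPTY_BRANCH),
    5: ("Hex", "Hex", EMPTY_BRANCH),
    6: ("Hex", "Hex", "Hex"),
    7: ("Hex", "Hex", "Hex"),
    8: ("Hex", "Hex", "Hex"),
    9: ("Hex", "Hex", "Hex"),
}


def motif_exemplars() -> dict[str, str]:
    """One full-glycan structure code per built-in motif label (13 motifs).

    Each HexNAc-initiated motif sits alone on one arm of a plain core; the
    mannose-extension motif ("Hex") is represented by Man5.
    """
    out = {label: _assemble("Core-I", [code, None])
           for label, code in N_MOTIF_EXEMPLARS.items()}
    out["Hex"] = MAN_TOPOLOGIES[5]
    return out


def _assemble(core: str, branch_codes: list[str | None]) -> str:
    """Build a structure code from a core class and per-branch subtree codes.

    ``branch_codes`` entries are subtree codes, ``"H-ext"`` for a mannose
    extension, or None for a bare arm; the first half (rounded up) goes on
    one arm, the rest on the other.
    """
    fuc, bis = _CORE_FLAGS[core]
    real = [c for c in branch_codes if c is not None]
    n_arm1 = (len(real) + 1) // 2 if real else 0
    arm1, arm2 = real[:n_arm1], real[n_arm1:]

    def arm(codes: list[str]) -> str:
        return "H" + "".join(
            "(H)" if c == "H-ext" else f"({c})" for c in codes)

    bman = "H" + f"({arm(arm1)})({arm(arm2)})" + ("(N)" if bis else "")
    return "N" + ("(F)" if fuc else "") + f"(N({bman}))"


@dataclass(frozen=True)
class PlantedEffect:
    """One planted fold-change shift.

    ``level="glycosylation"`` shifts the aged-group means of IGPs selected
    by a feature axis/label (axis in core/subtype/branch/sialylation/
    fucosylation/bisecting; None selects a random fraction of IGPs);
    ``level="protein"`` shifts whole proteins, propagating into all their
    IGPs' raw intensities.
    """

    log2fc: float
    level: str = "glycosylation"
    axis: str | None = None
    label: object = None
    fraction: float = 1.0


DEFAULT_EFFECTS: tuple[PlantedEffect, ...] = (
    # elevated sialoglycans (glycosylation level)
    PlantedEffect(1.3, "glycosylation", "branch", "sialyl-LacNAc-Neu5Gc"),
    PlantedEffect(1.3, "glycosylation", "branch", "sialyl-LacNAc-Neu5Ac",
                  fraction=0.8),
    # depressed bisecting glycans carrying a sole GlcNAc branch
    PlantedEffect(-1.3, "glycosylation", "bisecting+soleGlcNAc", None),
    # protein-expression confounding on a subset of proteins
    PlantedEffect(1.0, "protein", None, None, fraction=0.10),
)


@dataclass
class GeneratorSpec:
    """Study conditions of the synthetic experiment.

    Defaults mirror the emulated study: 5 vs 5 pooled samples (3F/2M per
    group) in one TMT 10-plex, log2-scale reporter noise sd 0.25, 1-4 PSMs
    per IGP, planted |log2fc| 1.3 feature shifts, a 10% protein-level
    confounding fraction and 6 designated glycan-shift glycosites.
    """

    seed: int = 0
    n_proteins: int = 120
    #: P(k sites) for k = 1..6; mode 1 site per glycoprotein
    sites_per_protein_p: tuple[float, ...] = (
        0.735, 0.15, 0.06, 0.03, 0.015, 0.01)
    #: P(k IGPs) for k = 1..4 glycans per site
    igps_per_site_p: tuple[float, ...] = (0.45, 0.30, 0.15, 0.10)
    #: P(k PSMs) for k = 1..4
    psm_per_igp_p: tuple[float, ...] = (0.40, 0.30, 0.20, 0.10)
    noise_sd: float = 0.25          # log2-scale reporter noise
    protein_noise_sd: float = 0.15  # log2-scale protein-table noise
    design: SampleDesign = field(default_factory=SampleDesign.default_tmt10)
    effects: tuple[PlantedEffect, ...] = DEFAULT_EFFECTS
    n_shift_sites: int = 6
    shift_log2fc: float = 1.5
    oacetyl_fraction: float = 0.15  # of sialylated IGPs get an O-Ac twin
    n_phospho_proteins: int = 30
    phosphosites_per_protein: int = 2
    coupled_pair_fraction: float = 0.3
    oligomannose_fraction: float = 0.34  # share of oligo-mannose IGP draws


def _subrng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) * 1_000_003 + salt) % (2**31))


# ---------------------------------------------------------------------------
# glycan library


def generate_glycan_library(
    cores: tuple[str, ...] = ("Core-I", "Core-II", "Core-III", "Core-IV"),
    motifs: tuple[str, ...] = tuple(N_MOTIF_EXEMPLARS),
    oligomannose: tuple[int, ...] = tuple(MAN_TOPOLOGIES),
    include_single_antenna: bool = True,
    include_hybrid: bool = True,
    include_triantennary: bool = True,
    oligomannose_motifs: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Structure library with construction-time truth labels.

    Instantiates, per core class: biantennary complex structures for every
    unordered motif pair, single-antenna complex and hybrid (motif + mannose
    extension) structures per motif, and two triantennary combinations per
    motif; plus the fixed Man3-9 oligomannose series on Core-I.  Returns a
    DataFrame of canonical codes with truth columns (duplicate topologies
    collapsed).

    Requesting HexNAc-initiated motifs on oligomannose glycans is
    contradictory and raises :class:`LibrarySpecError`.
    """
    if oligomannose_motifs:
        raise LibrarySpecError(
            "oligo-mannose glycans cannot carry HexNAc-initiated branches "
            f"(requested {list(oligomannose_motifs)})")
    bad = [m for m in motifs if m not in N_MOTIF_EXEMPLARS]
    if bad:
        raise LibrarySpecError(f"unknown motif label(s) {bad}")
    rows: list[dict] = []

    def add(core: str, branch_labels: list[str | None]) -> None:
        codes = [None if b is None
                 else ("H-ext" if b == "Hex" else N_MOTIF_EXEMPLARS[b])
                 for b in branch_labels]
        code = _assemble(core, codes)
        real = [b for b in branch_labels if b is not None]
        n_empty_arms = 1 if len(real) <= 1 else 0
        branches = tuple(sorted(real + [EMPTY_BRANCH] * n_empty_arms))
        has_hex = "Hex" in real
        has_n = any(b != "Hex" for b in real)
        subtype = ("oligo-mannose" if not has_n
                   else ("hybrid" if has_hex else "complex"))
        fuc_core, bis = _CORE_FLAGS[core]
        fuc_ant = any(b in _ANTENNA_FUC for b in real)
        sial = {_SIALIC[b] for b in real if b in _SIALIC}
        rows.append({
            "structure_code": code,
            "core_class": core,
            "subtype": subtype,
            "branches": branches,
            "antenna_count": len(real),
            "fucosylation": ("both" if fuc_core and fuc_ant else
                             "core" if fuc_core else
                             "antenna" if fuc_ant else "none"),
            "sialylation": ("both" if sial == {"A", "G"} else
                            "Neu5Ac" if sial == {"A"} else
                            "Neu5Gc" if sial == {"G"} else "none"),
            "bisecting": bis,
        })

    motifs = tuple(motifs)
    for core in cores:
        for i, m1 in enumerate(motifs):
            for m2 in motifs[i:]:
                add(core, [m1, m2])
            if include_single_antenna:
                add(core, [m1, None])
            if include_hybrid:
                add(core, [m1, "Hex"])
            if include_triantennary:
                add(core, [m1, "LacNAc", "LacNAc"])
                add(core, [m1, "LacNAc", "sole GlcNAc"])
                add(core, [m1, "sole GlcNAc", "sole GlcNAc"])
                add(core, [m1, "LacNAc", "LacNAc", "LacNAc"])
    for k in oligomannose:
        branches = _MAN_BRANCHES[k]
        rows.append({
            "structure_code": MAN_TOPOLOGIES[k],
            "core_class": "Core-I",
            "subtype": "oligo-mannose",
            "branches": tuple(sorted(branches)),
            "antenna_count": sum(1 for b in branches if b != EMPTY_BRANCH),
            "fucosylation": "none",
            "sialylation": "none",
            "bisecting": False,
        })
    lib = pd.DataFrame(rows)
    lib["canonical_code"] = [
        serialize_canonical(parse_structure(c)) for c in lib["structure_code"]]
    lib = lib.drop_duplicates("canonical_code").reset_index(drop=True)
    return lib


# ---------------------------------------------------------------------------
# dataset


@dataclass
class SyntheticDataset:
    igp: pd.DataFrame          # PSM-level rows, one per (IGP, PSM)
    protein: pd.DataFrame      # protein x channel abundances
    phospho: pd.DataFrame      # phosphosite x channel abundances
    design: SampleDesign
    library: pd.DataFrame
    truth_igp: pd.DataFrame    # per unique IGP: planted effects and calls
    truth_shift_sites: pd.DataFrame
    truth_coupled_pairs: pd.DataFrame


_AA = np.array(list("ACDEFGHIKLMQRVWY"))  # no N/P/S/T to keep sequons planted


def _peptide(rng: np.random.Generator, sequon_third: str) -> tuple[str, str]:
    length = int(rng.integers(8, 15))
    aas = rng.choice(_AA, size=length)
    pos = int(rng.integers(1, length - 3))
    x = str(rng.choice(_AA))
    seq = "".join(aas[:pos]) + "N" + x + sequon_third + "".join(aas[pos:])
    return seq, "N" + x + sequon_third


def _igp_effect(row: dict, effects, rng: np.random.Generator,
                protein_effects: dict[str, float]) -> tuple[float, str]:
    """(planted glyco-level log2fc, matched selector) for one IGP."""
    if row["protein_id"] in protein_effects:
        return 0.0, ""   # protein-level proteins stay clean at glyco level
    for eff in effects:
        if eff.level != "glycosylation":
            continue
        if eff.axis == "branch":
            hit = eff.label in row["branches"]
        elif eff.axis == "bisecting+soleGlcNAc":
            hit = row["bisecting"] and "sole GlcNAc" in row["branches"]
        elif eff.axis in ("core", "subtype", "sialylation", "fucosylation"):
            key = {"core": "core_class"}.get(eff.axis, eff.axis)
            hit = row[key] == eff.label
        elif eff.axis == "bisecting":
            hit = bool(row["bisecting"]) == bool(eff.label)
        elif eff.axis is None:
            hit = True
        else:
            raise ValueError(f"unknown effect axis {eff.axis!r}")
        if hit and (eff.fraction >= 1.0 or rng.random() < eff.fraction):
            return eff.log2fc, eff.axis or "any"
    return 0.0, ""


def generate_igp_dataset(spec: GeneratorSpec | None = None) -> SyntheticDataset:
    """Full synthetic experiment; byte-identical under a fixed seed."""
    spec = spec or GeneratorSpec()
    rng = _subrng(spec.seed, 1)
    design = spec.design
    channels = design.channels
    aged = set(design.channels_of(design.group_b))
    library = generate_glycan_library()
    lib_oligo = library[library["subtype"] == "oligo-mannose"]
    lib_other = library[library["subtype"] != "oligo-mannose"]

    protein_ids = [f"P{i:05d}" for i in range(1, spec.n_proteins + 1)]
    protein_effects: dict[str, float] = {}
    for eff in spec.effects:
        if eff.level != "protein":
            continue
        n_aff = int(round(eff.fraction * spec.n_proteins))
        chosen = rng.choice(spec.n_proteins, size=n_aff, replace=False)
        for i in sorted(chosen):
            protein_effects.setdefault(protein_ids[i], eff.log2fc)

    # --- lay out sites and IGPs -------------------------------------------
    igp_rows: list[dict] = []
    site_registry: list[tuple[str, int]] = []
    for protein in protein_ids:
        n_sites = 1 + int(rng.choice(len(spec.sites_per_protein_p),
                                     p=spec.sites_per_protein_p))
        positions = sorted(rng.choice(np.arange(20, 800), size=n_sites,
                                      replace=False))
        for sitepos in positions:
            site_registry.append((protein, int(sitepos)))
            peptide, sequon = _peptide(rng, "S" if rng.random() < 0.5 else "T")
            n_igps = 1 + int(rng.choice(len(spec.igps_per_site_p),
                                        p=spec.igps_per_site_p))
            pool = lib_oligo if rng.random() < spec.oligomannose_fraction \
                else lib_other
            picks = rng.choice(len(pool), size=min(n_igps, len(pool)),
                               replace=False)
            for j in picks:
                entry = pool.iloc[int(j)]
                igp_rows.append({
                    "protein_id": protein,
                    "glycosite": int(sitepos),
                    "peptide": peptide,
                    "sequon": sequon,
                    "glycan_code": entry["structure_code"],
                    "canonical_code": entry["canonical_code"],
                    "core_class": entry["core_class"],
                    "subtype": entry["subtype"],
                    "branches": frozenset(entry["branches"]),
                    "bisecting": entry["bisecting"],
                    "sialylation": entry["sialylation"],
                    "fucosylation": entry["fucosylation"],
                    "oacetyl": False,
                })

    # planted glycosylation-level effects
    for row in igp_rows:
        log2fc, selector = _igp_effect(row, spec.effects, rng,
                                       protein_effects)
        row["planted_log2fc"] = log2fc
        row["planted_selector"] = selector

    # enforce one planted direction per regular site (shift sites are the
    # only sites allowed to mix up- and down-planted IGPs)
    by_site: dict[tuple[str, int], list[dict]] = {}
    for row in igp_rows:
        by_site.setdefault((row["protein_id"], row["glycosite"]),
                           []).append(row)
    for rows_at_site in by_site.values():
        signs = {np.sign(r["planted_log2fc"]) for r in rows_at_site
                 if r["planted_log2fc"] != 0}
        if len(signs) > 1:
            keep = sorted(signs)[-1]
            for r in rows_at_site:
                if r["planted_log2fc"] != 0 and \
                        np.sign(r["planted_log2fc"]) != keep:
                    r["planted_log2fc"] = 0.0
                    r["planted_selector"] = ""

    # --- designated shift sites -------------------------------------------
    shift_up_code = _assemble("Core-I", ["N(H(A))", "N(H)"])
    shift_down_code = _assemble("Core-III", ["N", "N"])
    up_canon = serialize_canonical(parse_structure(shift_up_code))
    down_canon = serialize_canonical(parse_structure(shift_down_code))
    up_entry = library[library["canonical_code"] == up_canon].iloc[0]
    down_entry = library[library["canonical_code"] == down_canon].iloc[0]
    shift_sites = []
    clean_proteins = [p for p in protein_ids if p not in protein_effects]
    shift_hosts = rng.choice(len(clean_proteins),
                             size=spec.n_shift_sites, replace=False)
    for i in sorted(shift_hosts):
        protein = clean_proteins[int(i)]
        sitepos = int(900 + i)  # outside the regular 20-800 range: unique
        peptide, sequon = _peptide(rng, "T")
        shift_sites.append((protein, sitepos))
        for entry, sign in ((up_entry, +1), (down_entry, -1)):
            igp_rows.append({
                "protein_id": protein, "glycosite": sitepos,
                "peptide": peptide, "sequon": sequon,
                "glycan_code": entry["structure_code"],
                "canonical_code": entry["canonical_code"],
                "core_class": entry["core_class"],
                "subtype": entry["subtype"],
                "branches": frozenset(entry["branches"]),
                "bisecting": entry["bisecting"],
                "sialylation": entry["sialylation"],
                "fucosylation": entry["fucosylation"],
                "oacetyl": False,
                "planted_log2fc": sign * spec.shift_log2fc,
                "planted_selector": "shift-site",
            })

    # --- O-acetyl twins ----------------------------------------------------
    twins = []
    for row in igp_rows:
        if row["sialylation"] != "none" and \
                rng.random() < spec.oacetyl_fraction:
            twin = dict(row)
            twin["oacetyl"] = True
            twins.append(twin)
    igp_rows.extend(twins)

    # --- intensities -------------------------------------------------------
    noise = _subrng(spec.seed, 2)
    psm_rows = []
    truth_rows = []
    for idx, row in enumerate(igp_rows):
        base = noise.uniform(18.0, 24.0)
        prot_fx = protein_effects.get(row["protein_id"], 0.0)
        n_psm = 1 + int(noise.choice(len(spec.psm_per_igp_p),
                                     p=spec.psm_per_igp_p))
        for psm in range(n_psm):
            rec = {
                "protein_id": row["protein_id"],
                "glycosite": row["glycosite"],
                "peptide": row["peptide"],
                "sequon": row["sequon"],
                "glycan_code": row["glycan_code"],
                "oacetyl": row["oacetyl"],
                "psm_id": f"PSM{idx:05d}.{psm}",
            }
            for ch in channels:
                mu = base + (row["planted_log2fc"] + prot_fx
                             if ch in aged else 0.0)
                rec[ch] = float(2.0 ** (mu + noise.normal(0.0, spec.noise_sd)))
            psm_rows.append(rec)
        truth_rows.append({
            "peptide": row["peptide"],
            "glycosite": row["glycosite"],
            "canonical_code": row["canonical_code"],
            "oacetyl": row["oacetyl"],
            "protein_id": row["protein_id"],
            "planted_log2fc": row["planted_log2fc"],
            "planted_protein_log2fc": prot_fx,
            "planted_selector": row["planted_selector"],
            "planted_call": ("up" if row["planted_log2fc"] > 0 else
                             "down" if row["planted_log2fc"] < 0 else "none"),
        })

    igp = pd.DataFrame(psm_rows)
    truth_igp = pd.DataFrame(truth_rows).drop_duplicates(
        ["peptide", "glycosite", "canonical_code", "oacetyl"])

    # --- protein table -----------------------------------------------------
    prng = _subrng(spec.seed, 3)
    prot_rows = []
    for protein in protein_ids:
        base = prng.uniform(20.0, 26.0)
        fx = protein_effects.get(protein, 0.0)
        rec = {"protein_id": protein}
        for ch in channels:
            mu = base + (fx if ch in aged else 0.0)
            rec[ch] = float(2.0 ** (mu + prng.normal(0.0,
                                                     spec.protein_noise_sd)))
        prot_rows.append(rec)
    protein = pd.DataFrame(prot_rows).set_index("protein_id")
    protein.index.name = "protein_id"

    # --- phospho table with coupled pairs ---------------------------------
    qrng = _subrng(spec.seed, 4)
    glyco_by_protein: dict[str, list[int]] = {}
    site_sizes: dict[tuple[str, int], int] = {}
    for i, row in enumerate(igp_rows):
        glyco_by_protein.setdefault(row["protein_id"], []).append(i)
        site_sizes[(row["protein_id"], row["glycosite"])] = \
            site_sizes.get((row["protein_id"], row["glycosite"]), 0) + 1
    # coupling partners: unplanted IGPs alone at their glycosite on proteins
    # without a protein-level effect, so the injected shared signal cannot
    # disturb planted-effect recovery or shift-site detection
    phospho_hosts = [p for p in protein_ids if p not in protein_effects][
        : spec.n_phospho_proteins]
    ph_rows, coupled = [], []
    for protein_id in phospho_hosts:
        ctrl = np.log2(protein.loc[protein_id, channels]
                       .to_numpy(dtype=float))
        candidates = [
            i for i in glyco_by_protein.get(protein_id, [])
            if igp_rows[i]["planted_log2fc"] == 0.0
            and not igp_rows[i]["oacetyl"]
            and site_sizes[(protein_id, igp_rows[i]["glycosite"])] == 1]
        for s in range(spec.phosphosites_per_protein):
            sitepos = int(qrng.integers(5, 900))
            couple = (qrng.random() < spec.coupled_pair_fraction
                      and candidates)
            if couple:
                partner = igp_rows[candidates.pop(0)]
                shared = qrng.normal(0.0, 0.8, size=len(channels))
                mu = ctrl + shared
                coupled.append((protein_id, partner["glycosite"],
                                sitepos, True))
                # write the same shared signal into the partner IGP's PSMs
                key = (partner["peptide"], partner["glycosite"],
                       partner["glycan_code"], partner["oacetyl"])
                mask = ((igp["peptide"] == key[0])
                        & (igp["glycosite"] == key[1])
                        & (igp["glycan_code"] == key[2])
                        & (igp["oacetyl"] == key[3]))
                for ci, ch in enumerate(channels):
                    igp.loc[mask, ch] = igp.loc[mask, ch] * 2.0 ** shared[ci]
            else:
                mu = ctrl + qrng.normal(0.0, 0.5, size=len(channels))
            rec = {"protein_id": protein_id, "phosphosite": sitepos}
            for ci, ch in enumerate(channels):
                rec[ch] = float(2.0 ** (mu[ci]
                                        + qrng.normal(0.0, 0.1)))
            ph_rows.append(rec)
    phospho = pd.DataFrame(ph_rows)

    return SyntheticDataset(
        igp=igp,
        protein=protein,
        phospho=phospho,
        design=design,
        library=library,
        truth_igp=truth_igp,
        truth_shift_sites=pd.DataFrame(
            shift_sites, columns=["protein_id", "glycosite"]),
        truth_coupled_pairs=pd.DataFrame(
            coupled, columns=["protein_id", "glycosite", "phosphosite",
                              "coupled"]),
    )
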