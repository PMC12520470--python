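"""Mining of overall and altered glycan features from featurized IGP tables.

All proportions are computed on the basis of **unique IGPs** (distinct
(peptide, glycosite, canonical structure, O-acetyl) keys), not PSMs.  For
partition axes (core class, subtype, antenna count, fucosylation,
sialylation) proportions over a subset sum to 1; for the branch axis an IGP
counts once per motif label it carries (presence, not multiplicity), so
branch proportions may sum to more than 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import EMPTY_BRANCH, MOTIF_LABELS

__all__ = [
    "IGP_KEY_COLUMNS",
    "unique_igps",
    "top_n_glycans",
    "feature_proportions",
    "feature_summary",
    "altered_fraction_per_feature",
    "fc_range_enrichment",
    "co_occurrence",
    "has_branch",
    "ShiftPair",
    "detect_site_shifts",
    "pair_oacetyl",
    "glycosites_per_protein",
    "motif_split",
]

IGP_KEY_COLUMNS = ["peptide", "glycosite", "canonical_code", "oacetyl"]

PARTITION_AXES = {
    "core": "core_class",
    "subtype": "subtype",
    "antenna": "antenna_count",
    "fucosylation": "fucosylation",
    "sialylation": "sialylation",
}


def unique_igps(df: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate IGP keys (PSM replicates), keeping the first row."""
    keys = [c for c in IGP_KEY_COLUMNS if c in df.columns]
    return df.drop_duplicates(subset=keys) if keys else df


def _axis_values(df: pd.DataFrame, axis: str) -> pd.Series:
    try:
        return df[PARTITION_AXES[axis]]
    except KeyError:
        raise ValueError(
            f"unknown feature axis {axis!r}; "
            f"choose from {sorted(PARTITION_AXES) + ['branch']}") from None


def _branch_labels(df: pd.DataFrame) -> list[str]:
    observed = set().union(*df["branches"]) if len(df) else set()
    ordered = [m for m in MOTIF_LABELS if m in observed]
    ordered += sorted(observed - set(MOTIF_LABELS))
    return ordered


def top_n_glycans(
    df: pd.DataFrame,
    n: int = 10,
    rank_by: str = "glycosite_count",
    exclude_oligomannose: bool = False,
) -> pd.DataFrame:
    """Rank glycan structures by modified-glycosite count or by up/down calls.

    ``rank_by="glycosite_count"`` counts distinct (protein, glycosite) pairs
    per canonical structure; ``rank_by="direction"`` counts unique IGPs in
    the up and down sets separately (requires a ``call`` column).  Ties break
    by canonical code.  ``n`` larger than available returns all.
    """
    data = unique_igps(df)
    if exclude_oligomannose:
        data = data[data["subtype"] != "oligo-mannose"]
    if rank_by == "glycosite_count":
        counts = (
            data.drop_duplicates(["canonical_code", "protein_id", "glycosite"])
            .groupby("canonical_code").size()
        )
        out = counts.rename("n_glycosites").reset_index()
        out = out.sort_values(
            ["n_glycosites", "canonical_code"],
            ascending=[False, True], kind="mergesort").head(n)
        return out.reset_index(drop=True)
    if rank_by == "direction":
        frames = []
        for direction in ("up", "down"):
            sub = data[data["call"] == direction]
            counts = sub.groupby("canonical_code").size().rename("n_igps")
            top = counts.reset_index().sort_values(
                ["n_igps", "canonical_code"],
                ascending=[False, True], kind="mergesort").head(n)
            top.insert(0, "direction", direction)
            frames.append(top)
        return pd.concat(frames, ignore_index=True)
    raise ValueError(f"unknown rank_by {rank_by!r}")


def feature_proportions(
    subset: pd.DataFrame,
    axis: str,
    include_empty_branch: bool = False,
    multiplicity: bool = False,
) -> pd.DataFrame:
    """Per-feature counts and proportions within one IGP subset.

    Returns columns (axis, label, n, prop).  Partition axes divide by the
    number of unique IGPs and sum to 1; the branch axis counts an IGP once
    per carried motif label (``multiplicity=True`` instead counts branch
    positions and divides by total positions).  An empty subset returns an
    empty frame with an ``empty_subset`` attribute flag.
    """
    data = unique_igps(subset)
    if len(data) == 0:
        out = pd.DataFrame(columns=["axis", "label", "n", "prop"])
        out.attrs["empty_subset"] = True
        return out
    if axis == "branch":
        labels = _branch_labels(data)
        if not include_empty_branch:
            labels = [m for m in labels if m != EMPTY_BRANCH]
        if multiplicity:
            lists = data["branch_list"]
            totals = {m: int(sum(branches.count(m) for branches in lists))
                      for m in labels}
            denom = int(sum(len(branches) for branches in lists))
        else:
            totals = {m: int(data["branches"].map(lambda s: m in s).sum())
                      for m in labels}
            denom = len(data)
        rows = [(axis, m, totals[m], totals[m] / denom) for m in labels]
    else:
        counts = _axis_values(data, axis).value_counts().sort_index()
        denom = len(data)
        rows = [(axis, label, int(c), c / denom)
                for label, c in counts.items()]
    out = pd.DataFrame(rows, columns=["axis", "label", "n", "prop"])
    out.attrs["empty_subset"] = False
    return out


def feature_summary(
    df: pd.DataFrame,
    axis: str,
    exclude_oligomannose: bool = False,
) -> pd.DataFrame:
    """FeatureSummary table: per-label totals, up/down shares and ratios.

    ``prop_up`` (``prop_down``) is the share of up- (down-) regulated unique
    IGPs carrying the label; ``up_down_ratio`` their quotient (NaN-flagged
    when the down share is 0); ``altered_fraction`` is the differential
    fraction of all IGPs carrying the label.  Requires a ``call`` column.
    """
    data = unique_igps(df)
    if exclude_oligomannose:
        data = data[data["subtype"] != "oligo-mannose"]
    total = feature_proportions(data, axis).set_index("label")
    up = feature_proportions(data[data["call"] == "up"], axis)
    down = feature_proportions(data[data["call"] == "down"], axis)
    up = up.set_index("label") if len(up) else up.set_index(
        pd.Index([], name="label"))
    down = down.set_index("label") if len(down) else down.set_index(
        pd.Index([], name="label"))
    rows = []
    for label in total.index:
        n_total = int(total.loc[label, "n"])
        n_up = int(up["n"].get(label, 0))
        n_down = int(down["n"].get(label, 0))
        prop_up = float(up["prop"].get(label, 0.0))
        prop_down = float(down["prop"].get(label, 0.0))
        ratio = prop_up / prop_down if prop_down > 0 else np.nan
        rows.append((axis, label, n_total, n_up, n_down, prop_up, prop_down,
                     ratio, (n_up + n_down) / n_total if n_total else np.nan))
    return pd.DataFrame(rows, columns=[
        "axis", "label", "n_total", "n_up", "n_down", "prop_up", "prop_down",
        "up_down_ratio", "altered_fraction"])


def altered_fraction_per_feature(
    df: pd.DataFrame, axes: Sequence[str] = ("core", "subtype", "branch"),
) -> pd.DataFrame:
    """(n_up + n_down) / n_total per feature label across the given axes."""
    frames = [feature_summary(df, axis)[
        ["axis", "label", "n_total", "n_up", "n_down", "altered_fraction"]]
        for axis in axes]
    return pd.concat(frames, ignore_index=True)


def fc_range_enrichment(
    df: pd.DataFrame,
    bin_edges: Sequence[float],
    axis: str = "branch",
) -> pd.DataFrame:
    """Feature composition per |log2fc| bin.

    Bins are right-open ``[e_i, e_{i+1})`` except the last, which is closed.
    Empty bins are kept and flagged with NaN proportions rather than dropped.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing, >=2 values")
    data = unique_igps(df).dropna(subset=["log2fc"])
    mag = data["log2fc"].abs()
    frames = []
    for lo, hi in zip(edges, edges[1:]):
        last = hi == edges[-1]
        sub = data[(mag >= lo) & ((mag <= hi) if last else (mag < hi))]
        props = feature_proportions(sub, axis)
        if props.attrs.get("empty_subset"):
            props = pd.DataFrame(
                [(axis, np.nan, 0, np.nan)],
                columns=["axis", "label", "n", "prop"])
            props["empty_bin"] = True
        else:
            props["empty_bin"] = False
        props.insert(0, "bin", f"[{lo:g},{hi:g}{']' if last else ')'}")
        props["n_igps_in_bin"] = len(sub)
        frames.append(props)
    return pd.concat(frames, ignore_index=True)


FeaturePredicate = Callable[[pd.DataFrame], pd.Series]


def has_branch(label: str | Iterable[str]) -> FeaturePredicate:
    """Predicate: IGP carries at least one of the given branch motif labels."""
    labels = {label} if isinstance(label, str) else set(label)
    return lambda df: df["branches"].map(lambda s: bool(labels & s))


def _as_mask(df: pd.DataFrame, feature) -> pd.Series:
    if callable(feature):
        return feature(df).astype(bool)
    if isinstance(feature, tuple) and len(feature) == 2:
        column, value = feature
        return df[column] == value
    raise TypeError("feature must be a predicate or a (column, value) pair")


def co_occurrence(
    df: pd.DataFrame,
    feature_a,
    feature_b,
    subset: pd.Series | None = None,
) -> tuple[float, int, int]:
    """Fraction of (subset) IGPs with feature_a that also carry feature_b.

    Features are predicates (e.g. :func:`has_branch`) or (column, value)
    pairs.  Returns (fraction, numerator, denominator); the fraction is NaN
    when the denominator is empty.
    """
    data = unique_igps(df)
    if subset is not None:
        data = data[subset.reindex(data.index, fill_value=False)]
    a = _as_mask(data, feature_a)
    b = _as_mask(data, feature_b)
    den = int(a.sum())
    num = int((a & b).sum())
    return (num / den if den else np.nan), num, den


@dataclass
class ShiftPair:
    """One glycosite carrying both up- and down-regulated IGPs."""

    protein_id: str
    glycosite: int
    up_igps: tuple
    down_igps: tuple
    #: per-axis contrast: label -> prop(up members) - prop(down members)
    contrasts: dict[str, dict[str, float]]


def detect_site_shifts(
    df: pd.DataFrame,
    axes: Sequence[str] = ("core", "subtype", "branch"),
) -> list[ShiftPair]:
    """Glycosites with >=1 up AND >=1 down IGP, with feature contrasts.

    The contrast statistic per feature label is the difference in per-label
    proportions between the site's up members and its down members.
    """
    data = unique_igps(df)
    out: list[ShiftPair] = []
    for (protein, site), grp in sorted(
            data.groupby(["protein_id", "glycosite"], sort=False),
            key=lambda kv: (str(kv[0][0]), kv[0][1])):
        ups = grp[grp["call"] == "up"]
        downs = grp[grp["call"] == "down"]
        if len(ups) == 0 or len(downs) == 0:
            continue
        contrasts: dict[str, dict[str, float]] = {}
        for axis in axes:
            pu = feature_proportions(ups, axis).set_index("label")["prop"]
            pdn = feature_proportions(downs, axis).set_index("label")["prop"]
            labels = sorted(set(pu.index) | set(pdn.index), key=str)
            contrasts[axis] = {
                lab: float(pu.get(lab, 0.0) - pdn.get(lab, 0.0))
                for lab in labels}
        key = lambda sub: tuple(
            sub[[c for c in IGP_KEY_COLUMNS if c in sub.columns]]
            .itertuples(index=False, name=None))
        out.append(ShiftPair(str(protein), int(site), key(ups), key(downs),
                             contrasts))
    return out


def pair_oacetyl(df: pd.DataFrame) -> dict:
    """Match O-acetylated sialoglycopeptides to their non-acetylated forms.

    Pairs share (peptide, glycosite, canonical structure); the fold-change
    agreement across pairs is summarized by a Spearman correlation of log2fc.
    Unmatched O-AcSGPs are listed and excluded from the correlation.
    """
    data = unique_igps(df)
    oac = data[data["oacetyl"].astype(bool)]
    non = data[~data["oacetyl"].astype(bool)]
    merged = oac.merge(
        non, on=["peptide", "glycosite", "canonical_code"],
        suffixes=("_oac", "_non"))
    matched_keys = set(zip(merged["peptide"], merged["glycosite"],
                           merged["canonical_code"]))
    unmatched = [
        (r.peptide, r.glycosite, r.canonical_code)
        for r in oac.itertuples()
        if (r.peptide, r.glycosite, r.canonical_code) not in matched_keys]
    pairs = merged[["peptide", "glycosite", "canonical_code",
                    "log2fc_oac", "log2fc_non"]].dropna()
    if len(pairs) >= 3:
        r, p = stats.spearmanr(pairs["log2fc_oac"], pairs["log2fc_non"])
        r, p = float(r), float(p)
    else:
        r = p = np.nan
    return {"pairs": pairs, "spearman_r": r, "spearman_p": p,
            "n_pairs": len(pairs), "unmatched": unmatched,
            "correlation_defined": len(pairs) >= 3}


def glycosites_per_protein(df: pd.DataFrame) -> pd.Series:
    """Histogram: number of distinct glycosites -> number of glycoproteins."""
    sites = unique_igps(df).drop_duplicates(["protein_id", "glycosite"])
    per_protein = sites.groupby("protein_id").size()
    return per_protein.value_counts().sort_index().rename("n_proteins")


def motif_split(df: pd.DataFrame, context_column: str = "sequon") -> pd.Series:
    """N-X-S vs N-X-T sequon proportions over distinct glycosites.

    The context is the 3-residue window starting at the glycosylated Asn.
    Sequons with X = Pro, a non-Asn first residue or a third residue other
    than S/T are counted as ``invalid``; missing context as ``NA``.
    """
    sites = unique_igps(df).drop_duplicates(["protein_id", "glycosite"])

    def classify(ctx) -> str:
        if not isinstance(ctx, str) or len(ctx) < 3:
            return "NA"
        n, x, st = ctx[0].upper(), ctx[1].upper(), ctx[2].upper()
        if n != "N" or x == "P" or st not in "ST":
            return "invalid"
        return f"N-X-{st}"

    classes = sites[context_column].map(classify) \
        if context_column in sites.columns \
        else pd.Series("NA", index=sites.index)
    counts = classes.value_counts()
    valid = counts.reindex(["N-X-S", "N-X-T"], fill_value=0)
    total = valid.sum()
    props = valid / total if total else valid.astype(float) * np.nan
    props["invalid"] = int(counts.get("invalid", 0))
    props["NA"] = int(counts.get("NA", 0))
    return props
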