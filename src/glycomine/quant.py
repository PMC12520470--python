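"""TMT-channel quantification of intact glycopeptides (IGPs).

The quantitative path mirrors a multiplexed reporter-ion workflow:

1. per-channel normalization (global scaling factors from the proteome run,
   or self-derived from channel totals),
2. PSM aggregation to one per-channel vector per IGP (median across PSMs),
3. two-sided unpaired t-tests on log2 intensities with a fold-change (FC)
   call at FC > 1.5 / FC < 1/1.5 and p < 0.05,
4. protein-expression normalization of the IGP fold change, and
5. four-quadrant (Type I / Type II) classification separating changes
   explained by protein expression from genuine glycosylation-level changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleDesign",
    "Thresholds",
    "DifferentialResult",
    "normalize_channels",
    "derive_scaling_factors",
    "aggregate_psms",
    "impute_zeros",
    "differential_test",
    "differential_table",
    "normalize_by_protein",
    "quadrant_classify",
]


@dataclass(frozen=True)
class SampleDesign:
    """Channel -> (group, sex) assignment of a two-group TMT experiment."""

    groups: dict[str, str]            # channel -> group label
    sexes: dict[str, str] = field(default_factory=dict)  # channel -> F/M
    group_a: str = "young"            # reference (denominator) group
    group_b: str = "aged"             # comparison (numerator) group

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate channels in design")
        for g in (self.group_a, self.group_b):
            n = sum(1 for v in self.groups.values() if v == g)
            if n < 2:
                raise ValueError(f"group {g!r} needs >=2 channels, has {n}")

    @property
    def channels(self) -> list[str]:
        return list(self.groups)

    def channels_of(self, group: str) -> list[str]:
        return [c for c, g in self.groups.items() if g == group]

    @classmethod
    def default_tmt10(cls) -> "SampleDesign":
        """The study design: 10-plex, 5 young vs 5 aged, 3F/2M per group."""
        young = ["126", "127N", "127C", "128N", "128C"]
        aged = ["129N", "129C", "130N", "130C", "131"]
        groups = {c: "young" for c in young} | {c: "aged" for c in aged}
        sexes = dict(zip(young, "FFFMM")) | dict(zip(aged, "FFFMM"))
        return cls(groups=groups, sexes=sexes)


@dataclass(frozen=True)
class Thresholds:
    """Differential-call thresholds; the FC>2 preset is ``Thresholds(fc=2)``."""

    fc: float = 1.5
    p: float = 0.05
    use_fdr: bool = False    # apply Benjamini-Hochberg to the p column
    welch: bool = False      # Welch variance instead of pooled

    def __post_init__(self) -> None:
        if self.fc <= 1 or not (0 < self.p < 1):
            raise ValueError("fc must be >1 and p in (0,1)")


@dataclass
class DifferentialResult:
    """Per-IGP differential outcome (fold changes on the linear scale)."""

    igp_key: tuple
    fc: float
    log2fc: float
    p: float
    call: str                 # up / down / ns
    norm_fc: float = math.nan
    protein_fc: float = math.nan
    protein_p: float = math.nan
    quadrant: str = "unchanged"
    flags: tuple[str, ...] = ()


def normalize_channels(
    table: pd.DataFrame,
    factors: dict[str, float] | pd.Series | str = "self",
) -> pd.DataFrame:
    """Divide each channel column by its scaling factor.

    ``factors="self"`` derives factors from the table itself as channel totals
    scaled to their mean, so that after normalization every channel total
    equals the original mean total.  Explicit factors (e.g. derived from a
    global-proteome table with :func:`derive_scaling_factors`) must be
    strictly positive and cover every column.
    """
    if isinstance(factors, str):
        if factors != "self":
            raise ValueError(f"unknown factors mode {factors!r}")
        factors = derive_scaling_factors(table)
    factors = pd.Series(factors, dtype=float)
    missing = [c for c in table.columns if c not in factors.index]
    if missing:
        raise ValueError(f"missing scaling factor for channel(s) {missing}")
    if (factors.loc[list(table.columns)] <= 0).any():
        raise ValueError("scaling factors must be strictly positive")
    return table / factors.loc[list(table.columns)]


def derive_scaling_factors(table: pd.DataFrame) -> pd.Series:
    """Per-channel totals scaled to their mean (factor 1 = average loading)."""
    totals = table.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"channel(s) {bad} have nonpositive total intensity")
    return totals / totals.mean()


def aggregate_psms(psm_rows: pd.DataFrame) -> pd.Series:
    """Per-channel median across the PSMs of one IGP.

    An even PSM count uses the mean of the central pair (numpy convention).
    """
    if len(psm_rows) == 0:
        raise ValueError("aggregate_psms needs >=1 PSM row")
    return psm_rows.median(axis=0)


def impute_zeros(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Replace zeros by half the smallest nonzero value in that channel.

    Returns the imputed table and a boolean row mask of imputed rows.  A
    channel that is entirely zero stays zero (callers flag it downstream).
    """
    out = table.copy()
    flagged = pd.Series(False, index=table.index)
    for col in table.columns:
        vals = out[col]
        zero = vals == 0
        if zero.any():
            nonzero = vals[vals > 0]
            if len(nonzero):
                out.loc[zero, col] = nonzero.min() / 2.0
                flagged |= zero
    return out, flagged


def _t_test_log2(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    res = stats.ttest_ind(np.log2(b), np.log2(a), equal_var=not welch)
    return float(res.pvalue)


def differential_test(
    intensities: pd.Series,
    design: SampleDesign,
    thresholds: Thresholds | None = None,
    igp_key: tuple = (),
) -> DifferentialResult:
    """Two-group comparison of one aggregated IGP.

    fc = mean(group_b) / mean(group_a) on the normalized linear intensities;
    p from a two-sided unpaired t-test on log2 intensities.  Calls follow the
    FC/p thresholds.  All-zero groups yield an ``ns`` call with a flag.
    """
    thresholds = thresholds or Thresholds()
    a = intensities[design.channels_of(design.group_a)].to_numpy(dtype=float)
    b = intensities[design.channels_of(design.group_b)].to_numpy(dtype=float)
    flags: list[str] = []
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative intensity")
    if a.sum() == 0 or b.sum() == 0:
        return DifferentialResult(igp_key, math.nan, math.nan, math.nan,
                                  "ns", flags=("all-zero-group",))
    if np.any(a == 0) or np.any(b == 0):
        # per-vector fallback of the table-level channel imputation
        nz = np.concatenate([a[a > 0], b[b > 0]]).min() / 2.0
        a = np.where(a == 0, nz, a)
        b = np.where(b == 0, nz, b)
        flags.append("zero-imputed")
    fc = float(b.mean() / a.mean())
    p = _t_test_log2(a, b, thresholds.welch)
    call = _call(fc, p, thresholds)
    return DifferentialResult(igp_key, fc, math.log2(fc), p, call,
                              flags=tuple(flags))


def _call(fc: float, p: float, thresholds: Thresholds) -> str:
    if p < thresholds.p and fc > thresholds.fc:
        return "up"
    if p < thresholds.p and fc < 1.0 / thresholds.fc:
        return "down"
    return "ns"


def differential_table(
    table: pd.DataFrame,
    design: SampleDesign,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Vectorized :func:`differential_test` over an aggregated IGP table.

    ``table`` is indexed by IGP key with one column per channel.  Returns a
    DataFrame with fc, log2fc, p, call columns aligned to the input index.
    Optionally applies BH-FDR to the p column before calling.
    """
    thresholds = thresholds or Thresholds()
    imputed, flagged = impute_zeros(table)
    a = imputed[design.channels_of(design.group_a)].to_numpy(dtype=float)
    b = imputed[design.channels_of(design.group_b)].to_numpy(dtype=float)
    zero_group = (a.sum(axis=1) == 0) | (b.sum(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = b.mean(axis=1) / a.mean(axis=1)
        res = stats.ttest_ind(np.log2(np.where(b > 0, b, np.nan)),
                              np.log2(np.where(a > 0, a, np.nan)),
                              axis=1, equal_var=not thresholds.welch,
                              nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    p_adj = _bh_fdr(p) if thresholds.use_fdr else p
    call = np.where(
        (p_adj < thresholds.p) & (fc > thresholds.fc), "up",
        np.where((p_adj < thresholds.p) & (fc < 1.0 / thresholds.fc),
                 "down", "ns"))
    out = pd.DataFrame({
        "fc": fc,
        "log2fc": np.log2(fc),
        "p": p,
        "call": call,
    }, index=table.index)
    if thresholds.use_fdr:
        out["p_adj"] = p_adj
    out.loc[zero_group, ["fc", "log2fc", "p"]] = np.nan
    out.loc[zero_group, "call"] = "ns"
    out["flag_zero_imputed"] = flagged.to_numpy()
    out["flag_all_zero_group"] = zero_group
    return out


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _align_to(values, index: pd.Index) -> pd.Series:
    """Series aligned by index; plain arrays align positionally."""
    if values is None:
        return pd.Series(np.nan, index=index)
    if isinstance(values, pd.Series):
        return values.reindex(index)
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        return pd.Series(float(arr), index=index)
    if len(arr) != len(index):
        raise ValueError("positional values do not match table length")
    return pd.Series(arr, index=index)


def normalize_by_protein(
    result: DifferentialResult | pd.DataFrame,
    protein_fc: float | pd.Series | None,
    protein_p: float | pd.Series | None = None,
) -> DifferentialResult | pd.DataFrame:
    """Deduct protein-expression change: ``norm_fc = fc / protein_fc``.

    IGPs without a protein match keep ``norm_fc = fc`` and get a
    ``no-protein`` flag (they are excluded from quadrant statistics).
    """
    if isinstance(result, DifferentialResult):
        if protein_fc is None or (isinstance(protein_fc, float)
                                  and math.isnan(protein_fc)):
            return replace(result, norm_fc=result.fc,
                           flags=result.flags + ("no-protein",))
        if protein_fc <= 0:
            raise ValueError("protein fold change must be positive")
        return replace(result, norm_fc=result.fc / protein_fc,
                       protein_fc=float(protein_fc),
                       protein_p=float(protein_p)
                       if protein_p is not None else math.nan)
    out = result.copy()
    pfc = _align_to(protein_fc, out.index)
    if (pfc.dropna() <= 0).any():
        raise ValueError("protein fold change must be positive")
    out["protein_fc"] = pfc
    out["protein_p"] = _align_to(protein_p, out.index)
    out["flag_no_protein"] = pfc.isna()
    out["norm_fc"] = np.where(pfc.isna(), out["fc"], out["fc"] / pfc)
    return out


def quadrant_classify(
    result: DifferentialResult | pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> str | pd.Series:
    """Type I / Type II / both / unchanged quadrant call.

    Type I: significant protein change (|log2 protein_fc| > log2 fc-threshold
    and protein p < threshold) without a significant glycosylation-level
    change.  Type II: significant protein-normalized fold change (with the
    IGP's own p-value) without a protein change.  Direction suffix follows the
    significant axis.
    """
    thresholds = thresholds or Thresholds()
    log_thr = math.log2(thresholds.fc)

    def _one(fc_n, p_igp, fc_p, p_p) -> str:
        prot_sig = (not math.isnan(fc_p) and not math.isnan(p_p)
                    and abs(math.log2(fc_p)) > log_thr and p_p < thresholds.p)
        glyc_sig = (not math.isnan(fc_n) and not math.isnan(p_igp)
                    and abs(math.log2(fc_n)) > log_thr
                    and p_igp < thresholds.p)
        if prot_sig and glyc_sig:
            return "both"
        if prot_sig:
            return "TypeI-up" if fc_p > 1 else "TypeI-down"
        if glyc_sig:
            return "TypeII-up" if fc_n > 1 else "TypeII-down"
        return "unchanged"

    if isinstance(result, DifferentialResult):
        q = _one(result.norm_fc, result.p, result.protein_fc,
                 result.protein_p)
        result.quadrant = q
        return q
    out = [
        _one(row.norm_fc, row.p, row.protein_fc, row.protein_p)
        for row in result.itertuples()
    ]
    return pd.Series(out, index=result.index, name="quadrant")
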