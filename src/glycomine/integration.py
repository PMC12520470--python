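"""Multi-omic correlation and network utilities.

Links altered site-specific glycans to their candidate regulators:
pairwise Spearman correlations between entity groups (e.g. sialoglycan IGPs,
sialyltransferases, sialic-acid-binding proteins), partial Spearman
correlations between glycosylation and phosphorylation sites on the same
protein controlling for total protein abundance, cross-tabulation against
user-supplied annotation tables, and hub ranking over interaction networks.

Partial Spearman is implemented as Pearson correlation of rank residuals:
x, y and the control are rank-transformed, the ranks of x and y are
residualized on the ranks of the control by least squares, and the residuals
are correlated.  The p-value uses the t approximation with n - 3 degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .mining import feature_proportions

__all__ = [
    "CorrelationRecord",
    "spearman_matrix",
    "partial_spearman",
    "pair_glyco_phospho",
    "rank_hubs",
    "annotate_categories",
]


@dataclass(frozen=True)
class CorrelationRecord:
    entity_a: str
    entity_b: str
    r: float
    p: float
    n: int
    category_a: str = ""
    category_b: str = ""
    controlled_for: str | None = None
    defined: bool = True


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan, False
    r, p = stats.spearmanr(x, y)
    return float(r), float(p), True


def spearman_matrix(
    groups: dict[str, pd.DataFrame],
    within: bool = True,
) -> list[CorrelationRecord]:
    """All pairwise Spearman correlations across grouped abundance vectors.

    ``groups`` maps a category name to a DataFrame of entities (rows) by
    aligned sample columns.  ``within=False`` restricts to cross-category
    pairs.  Constant vectors yield undefined (flagged) records.
    """
    names = list(groups)
    cols = None
    for name in names:
        c = list(groups[name].columns)
        if cols is None:
            cols = c
        elif c != cols:
            raise ValueError(
                f"sample columns of group {name!r} do not match; "
                "align columns before correlating")
    entities = [(name, idx, groups[name].loc[idx].to_numpy(dtype=float))
                for name in names for idx in groups[name].index]
    out: list[CorrelationRecord] = []
    for i, (cat_a, ent_a, va) in enumerate(entities):
        for cat_b, ent_b, vb in entities[i + 1:]:
            if not within and cat_a == cat_b:
                continue
            r, p, defined = _spearman(va, vb)
            out.append(CorrelationRecord(
                str(ent_a), str(ent_b), r, p, len(va),
                category_a=cat_a, category_b=cat_b, defined=defined))
    return out


def _rank_residuals(v: np.ndarray, control_ranks: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(v)
    design = np.column_stack([np.ones_like(control_ranks), control_ranks])
    beta, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ beta


def partial_spearman(
    x, y, control, entity_a: str = "x", entity_b: str = "y",
    control_name: str = "control",
) -> CorrelationRecord:
    """Partial Spearman correlation of x and y given a control vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    control = np.asarray(control, dtype=float)
    n = len(x)
    if len(y) != n or len(control) != n:
        raise ValueError("x, y and control must be aligned")
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    if (np.all(x == x[0]) or np.all(y == y[0])
            or np.all(control == control[0])):
        return CorrelationRecord(entity_a, entity_b, math.nan, math.nan, n,
                                 controlled_for=control_name, defined=False)
    cr = stats.rankdata(control)
    rx = _rank_residuals(x, cr)
    ry = _rank_residuals(y, cr)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return CorrelationRecord(entity_a, entity_b, math.nan, math.nan, n,
                                 controlled_for=control_name, defined=False)
    r = float(rx @ ry) / denom
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationRecord(entity_a, entity_b, r, p, n,
                             controlled_for=control_name, defined=True)


def pair_glyco_phospho(
    glyco: pd.DataFrame,
    phospho: pd.DataFrame,
    protein_abundance: pd.DataFrame | None,
    sample_columns: list[str],
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Same-protein (glycosite, phosphosite) pairs with partial correlations.

    ``glyco`` and ``phospho`` need ``protein_id`` and a site column
    (``glycosite`` / ``phosphosite``) plus the aligned sample columns;
    ``protein_abundance`` is indexed by protein_id.  Each pair is scored by
    partial Spearman controlling for the protein's abundance; proteins
    without abundance fall back to a raw Spearman with a flag.  Pairs are
    classified positive / negative / ns by the configurable r and p
    thresholds (the r threshold appears in the source study both as 0.5 and
    as 0.05; default 0.5).
    """
    shared = sorted(set(glyco["protein_id"]) & set(phospho["protein_id"]))
    rows = []
    for protein in shared:
        control = None
        if protein_abundance is not None and protein in protein_abundance.index:
            control = protein_abundance.loc[protein, sample_columns] \
                .to_numpy(dtype=float)
        for _, g in glyco[glyco["protein_id"] == protein].iterrows():
            gv = g[sample_columns].to_numpy(dtype=float)
            for _, ph in phospho[phospho["protein_id"] == protein].iterrows():
                pv = ph[sample_columns].to_numpy(dtype=float)
                if control is not None:
                    rec = partial_spearman(gv, pv, control)
                    flag = ""
                else:
                    r, p, defined = _spearman(gv, pv)
                    rec = CorrelationRecord("x", "y", r, p, len(gv),
                                            defined=defined)
                    flag = "no-protein-abundance"
                if not rec.defined or math.isnan(rec.r):
                    cls = "undefined"
                elif rec.p < p_threshold and rec.r > r_threshold:
                    cls = "positive"
                elif rec.p < p_threshold and rec.r < -r_threshold:
                    cls = "negative"
                else:
                    cls = "ns"
                rows.append((protein, g["glycosite"], ph["phosphosite"],
                             rec.r, rec.p, rec.n, cls, flag))
    return pd.DataFrame(rows, columns=[
        "protein_id", "glycosite", "phosphosite", "r", "p", "n",
        "classification", "flag"])


def _eigenvector_centrality(g: nx.Graph) -> dict:
    try:
        return nx.eigenvector_centrality_numpy(g)
    except (TypeError, nx.NetworkXException):
        # scipy's sparse eigensolver rejects graphs with < 3 nodes
        return nx.eigenvector_centrality(g, max_iter=5000)


_CENTRALITY_FUNCS = {
    "degree": nx.degree_centrality,
    "betweenness": nx.betweenness_centrality,
    "closeness": nx.closeness_centrality,
    "eigenvector": _eigenvector_centrality,
}


def rank_hubs(
    edges: pd.DataFrame | list[tuple],
    methods: tuple[str, ...] = ("degree", "betweenness", "closeness",
                                "eigenvector"),
    k: int = 10,
    score_threshold: float = 0.4,
) -> pd.DataFrame:
    """Top-k hub nodes by mean rank across centrality measures.

    Edges below the combined-score threshold (default 0.4) are dropped before
    building the undirected graph.  Per-method ranks are dense descending
    ranks of the centrality (ties share a rank); the aggregate is the mean of
    per-method ranks, ties broken by node id.  An empty graph returns an
    empty frame.
    """
    if isinstance(edges, pd.DataFrame):
        triples = edges[["node_a", "node_b", "score"]].itertuples(
            index=False, name=None)
    else:
        triples = ((a, b, s) for a, b, s in edges)
    g = nx.Graph()
    for a, b, score in triples:
        if score >= score_threshold:
            g.add_edge(a, b, score=score)
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node", "mean_rank",
                                     *[f"rank_{m}" for m in methods]])
    nodes = sorted(g.nodes, key=str)
    ranks = {}
    for method in methods:
        try:
            cent = _CENTRALITY_FUNCS[method](g)
        except KeyError:
            raise ValueError(f"unknown centrality {method!r}") from None
        scores = np.array([cent[n] for n in nodes])
        # descending average ranks: highest centrality -> rank 1
        ranks[method] = stats.rankdata(-scores, method="average")
    mean_rank = np.mean([ranks[m] for m in methods], axis=0)
    out = pd.DataFrame({
        "node": [str(n) for n in nodes],
        "mean_rank": mean_rank,
        **{f"rank_{m}": ranks[m] for m in methods},
    })
    out = out.sort_values(["mean_rank", "node"], kind="mergesort").head(k)
    return out.reset_index(drop=True)


def annotate_categories(
    igps: pd.DataFrame,
    annotation: pd.DataFrame,
    axis: str = "branch",
) -> pd.DataFrame:
    """Feature proportions per protein category from an annotation table.

    ``annotation`` maps protein_id -> category (multi-label proteins appear
    on several rows and are counted once per category).  IGPs whose protein
    has no annotation fall under ``"unannotated"``.
    """
    ann = annotation[["protein_id", "category"]].drop_duplicates()
    merged = igps.merge(ann, on="protein_id", how="left")
    merged["category"] = merged["category"].fillna("unannotated")
    frames = []
    for category, sub in merged.groupby("category", sort=True):
        props = feature_proportions(sub, axis)
        props.insert(0, "category", category)
        props["n_igps_in_category"] = len(
            sub.drop_duplicates([c for c in (
                "peptide", "glycosite", "canonical_code", "oacetyl")
                if c in sub.columns]))
        frames.append(props)
    return pd.concat(frames, ignore_index=True)
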