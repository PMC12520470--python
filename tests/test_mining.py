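"""Feature mining: proportions, rankings, co-occurrence, shifts, pairing.

The proportion routines are checked against a brute-force set-counting
oracle that walks Python sets row by row.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycomine.mining import (
    EMPTY_BRANCH, altered_fraction_per_feature, co_occurrence,
    detect_site_shifts, fc_range_enrichment, feature_proportions,
    feature_summary, glycosites_per_protein, has_branch, motif_split,
    pair_oacetyl, top_n_glycans, unique_igps,
)

from conftest import make_igp_frame


def brute_force_proportions(df, axis):
    """Independent set-counting oracle over unique IGP keys."""
    seen, rows = set(), []
    for _, r in df.iterrows():
        key = (r["peptide"], r["glycosite"], r["canonical_code"],
               r["oacetyl"])
        if key not in seen:
            seen.add(key)
            rows.append(r)
    n = len(rows)
    out = {}
    if axis == "branch":
        labels = set().union(*(r["branches"] for r in rows))
        for lab in labels - {EMPTY_BRANCH}:
            out[lab] = sum(1 for r in rows if lab in r["branches"]) / n
    else:
        col = {"core": "core_class", "subtype": "subtype",
               "antenna": "antenna_count", "fucosylation": "fucosylation",
               "sialylation": "sialylation"}[axis]
        for lab in {r[col] for r in rows}:
            out[lab] = sum(1 for r in rows if r[col] == lab) / n
    return out


@pytest.mark.parametrize("axis", ["core", "subtype", "branch", "antenna",
                                  "fucosylation", "sialylation"])
def test_proportions_match_brute_force(small_igps, axis):
    got = feature_proportions(small_igps, axis)
    expected = brute_force_proportions(small_igps, axis)
    got_map = dict(zip(got["label"], got["prop"]))
    assert set(got_map) == set(expected)
    for lab, prop in expected.items():
        assert got_map[lab] == pytest.approx(prop, abs=1e-12)


def test_partition_axis_proportions_sum_to_one(small_igps):
    for axis in ("core", "subtype", "antenna", "fucosylation",
                 "sialylation"):
        assert feature_proportions(small_igps, axis)["prop"].sum() == \
            pytest.approx(1.0, abs=1e-9)


def test_psm_duplicates_do_not_change_proportions(small_igps):
    doubled = pd.concat([small_igps, small_igps], ignore_index=True)
    a = feature_proportions(small_igps, "core")
    b = feature_proportions(doubled, "core")
    pd.testing.assert_frame_equal(a, b)


def test_empty_subset_flagged(small_igps):
    out = feature_proportions(small_igps.iloc[0:0], "core")
    assert out.attrs["empty_subset"] and len(out) == 0


def test_feature_summary_ratio_and_altered_fraction(small_igps):
    fs = feature_summary(small_igps, "subtype").set_index("label")
    up_n = (unique_igps(small_igps)["call"] == "up").sum()
    down_n = (unique_igps(small_igps)["call"] == "down").sum()
    # hand-count: complex carries 3 up of 4 ups and 2 down of 2 downs
    row = fs.loc["complex"]
    assert row["prop_up"] == pytest.approx(row["n_up"] / up_n)
    assert row["prop_down"] == pytest.approx(row["n_down"] / down_n)
    assert row["up_down_ratio"] == pytest.approx(
        row["prop_up"] / row["prop_down"])
    assert row["altered_fraction"] == pytest.approx(
        (row["n_up"] + row["n_down"]) / row["n_total"])
    # a label absent from the down set has an undefined (NaN) ratio
    oligo = fs.loc["oligo-mannose"]
    assert oligo["n_down"] == 0 and np.isnan(oligo["up_down_ratio"])


def test_altered_fraction_partition_consistency(small_igps):
    out = altered_fraction_per_feature(small_igps, axes=("core",))
    assert out["n_total"].sum() == len(unique_igps(small_igps))


class TestTopN:
    def test_rank_by_glycosite_count_and_ties(self):
        man5 = "N(N(H(H)(H(H)(H))))"
        lac = "N(N(H(H(N(H)))(H(N(H)))))"
        rows = [
            ("P1", 1, "AANTT", man5, False, "ns", 0.0),
            ("P1", 9, "BBNTT", man5, False, "ns", 0.0),
            ("P2", 5, "CCNTT", man5, False, "ns", 0.0),
            ("P1", 1, "AANTT", lac, False, "ns", 0.0),
            ("P3", 7, "DDNTT", lac, False, "ns", 0.0),
        ]
        df = make_igp_frame(rows)
        out = top_n_glycans(df, n=10)
        assert out["n_glycosites"].tolist() == [3, 2]
        # tie case: same counts -> lexicographic canonical order
        df2 = make_igp_frame(rows[:1] + rows[3:4])
        tie = top_n_glycans(df2, n=10)
        assert tie["n_glycosites"].tolist() == [1, 1]
        assert tie["canonical_code"].tolist() == \
            sorted(tie["canonical_code"])

    def test_exclude_oligomannose_and_direction_mode(self, small_igps):
        out = top_n_glycans(small_igps, n=10, exclude_oligomannose=True)
        man5_canon = small_igps.loc[
            small_igps["subtype"] == "oligo-mannose",
            "canonical_code"].iloc[0]
        assert man5_canon not in set(out["canonical_code"])
        d = top_n_glycans(small_igps, n=10, rank_by="direction")
        assert set(d["direction"]) == {"up", "down"}
        up = d[d["direction"] == "up"]
        assert (up["n_igps"].diff().dropna() <= 0).all()


class TestFcRangeEnrichment:
    def test_planted_high_fc_feature_rises_with_bin(self):
        lac = "N(N(H(H(N(H)))(H(N(H)))))"
        ldn = "N(N(H(H(N(N)))(H(N(H)))))"
        rows = []
        # LacdiNAc only at |log2fc| >= 2; LacNAc spread low
        for i in range(20):
            rows.append((f"P{i}", 1, f"AAN{i}TT", lac, False, "up", 0.5))
        for i in range(20, 30):
            rows.append((f"P{i}", 1, f"AAN{i}TT", ldn, False, "up", 2.5))
        df = make_igp_frame(rows)
        out = fc_range_enrichment(df, [0, 1, 2, 3], axis="branch")
        ldn_by_bin = out[out["label"] == "LacdiNAc"].set_index("bin")["prop"]
        assert ldn_by_bin.get("[0,1)", 0.0) == 0.0
        assert ldn_by_bin["[2,3]"] == pytest.approx(1.0)

    def test_empty_bin_flagged_not_dropped(self, small_igps):
        out = fc_range_enrichment(small_igps, [0, 10, 20], axis="core")
        empty = out[out["bin"] == "[10,20]"]
        assert len(empty) == 1 and bool(empty["empty_bin"].iloc[0])

    def test_rejects_bad_edges(self, small_igps):
        with pytest.raises(ValueError):
            fc_range_enrichment(small_igps, [1, 1])


class TestCoOccurrence:
    def test_conditional_fraction(self, small_igps):
        down = small_igps["call"] == "down"
        frac, num, den = co_occurrence(
            small_igps, ("bisecting", True), has_branch("sole GlcNAc"),
            subset=down)
        assert den == 2 and num == 2 and frac == 1.0

    def test_absent_feature_undefined(self, small_igps):
        frac, num, den = co_occurrence(
            small_igps, has_branch("no-such-motif"), ("bisecting", True))
        assert den == 0 and np.isnan(frac)

    def test_bayes_identity(self, small_igps):
        a, b = ("bisecting", True), has_branch("LacNAc")
        p_b_given_a, _, n_a = co_occurrence(small_igps, a, b)
        p_a_given_b, _, n_b = co_occurrence(small_igps, b, a)
        n = len(unique_igps(small_igps))
        assert p_b_given_a * (n_a / n) == pytest.approx(
            p_a_given_b * (n_b / n), abs=1e-12)


class TestSiteShifts:
    def test_detects_only_mixed_sites(self, small_igps):
        shifts = detect_site_shifts(small_igps)
        assert [(s.protein_id, s.glycosite) for s in shifts] == [("P1", 107)]
        s = shifts[0]
        assert len(s.up_igps) == 1 and len(s.down_igps) == 1
        # up member is Core-I, down member Core-III: contrast +1/-1
        assert s.contrasts["core"]["Core-I"] == pytest.approx(1.0)
        assert s.contrasts["core"]["Core-III"] == pytest.approx(-1.0)
        assert s.contrasts["branch"]["sole GlcNAc"] == pytest.approx(-1.0)

    def test_site_with_single_direction_excluded(self, small_igps):
        only_up = small_igps[small_igps["call"] != "down"]
        assert detect_site_shifts(only_up) == []


class TestOacetylPairing:
    def test_matching_and_rank_oracle(self):
        sial = "N(N(H(H(N(H(A))))(H(N(H)))))"
        rng = np.random.default_rng(11)
        rows = []
        fcs = rng.normal(0.5, 1.0, 12)
        for i, f in enumerate(fcs):
            rows.append((f"P{i}", 1, f"AAN{i}TT", sial, False, "ns", f))
            rows.append((f"P{i}", 1, f"AAN{i}TT", sial, True, "ns",
                         f + rng.normal(0, 0.2)))
        # one unmatched O-AcSGP
        rows.append(("PX", 2, "ZZNTT", sial, True, "ns", 0.3))
        df = make_igp_frame(rows)
        out = pair_oacetyl(df)
        assert out["n_pairs"] == 12 and len(out["unmatched"]) == 1
        oracle_r, _ = stats.spearmanr(
            stats.rankdata(out["pairs"]["log2fc_oac"]),
            stats.rankdata(out["pairs"]["log2fc_non"]))
        assert out["spearman_r"] == pytest.approx(oracle_r, abs=1e-12)
        assert out["spearman_r"] > 0.7

    def test_no_pairs_flagged(self, small_igps):
        non_oac = small_igps[~small_igps["oacetyl"]]
        out = pair_oacetyl(non_oac)
        assert not out["correlation_defined"] and np.isnan(out["spearman_r"])


def test_glycosites_per_protein(small_igps):
    hist = glycosites_per_protein(small_igps)
    # P1: 2 sites, P2: 2 sites, P3: 2 sites
    assert hist.to_dict() == {2: 3}
    assert hist.sum() == small_igps["protein_id"].nunique()


def test_motif_split(small_igps):
    out = motif_split(small_igps)
    # sequons: NKS,NRT,NVS,NWT,NGS,NHT over 6 distinct sites
    assert out["N-X-S"] == pytest.approx(3 / 6)
    assert out["N-X-T"] == pytest.approx(3 / 6)
    assert out["invalid"] == 0


def test_motif_split_rejects_proline_and_missing():
    man5 = "N(N(H(H)(H(H)(H))))"
    rows = [("P1", 1, "AANPT", man5, False, "ns", 0.0),
            ("P2", 2, "BBNGT", man5, False, "ns", 0.0)]
    df = make_igp_frame(rows)
    df["sequon"] = ["NPT", "NGT"]
    out = motif_split(df)
    assert out["invalid"] == 1
    assert out["N-X-T"] == pytest.approx(1.0)
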