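"""Channel normalization, PSM aggregation, differential and quadrant calls."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycomine.quant import (
    SampleDesign, Thresholds, aggregate_psms, derive_scaling_factors,
    differential_table, differential_test, impute_zeros,
    normalize_by_protein, normalize_channels, quadrant_classify,
)


def _series(design, young, aged):
    vals = dict(zip(design.channels_of("young"), young))
    vals.update(zip(design.channels_of("aged"), aged))
    return pd.Series(vals, dtype=float)


def oracle_t_p(a, b):
    """Pooled-variance two-sided t-test on log2 values, from the formula."""
    x, y = np.log2(np.asarray(a, float)), np.log2(np.asarray(b, float))
    na, nb = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) \
        / (na + nb - 2)
    t = (y.mean() - x.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


class TestNormalization:
    def test_unit_factors_are_identity(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = normalize_channels(table, {"a": 1.0, "b": 1.0})
        pd.testing.assert_frame_equal(out, table)

    def test_self_mode_equalizes_channel_totals(self):
        table = pd.DataFrame({"a": [4.0, 4.0], "b": [1.0, 3.0],
                              "c": [2.0, 2.0]})
        out = normalize_channels(table, "self")
        totals = out.sum(axis=0)
        assert np.allclose(totals, totals.iloc[0])
        # channel with double the total is scaled down twice as hard
        shrink_a = out.loc[0, "a"] / table.loc[0, "a"]
        shrink_b = out.loc[0, "b"] / table.loc[0, "b"]
        assert np.isclose(shrink_a / shrink_b, 0.5)

    def test_rejects_bad_factors(self):
        table = pd.DataFrame({"a": [1.0], "b": [1.0]})
        with pytest.raises(ValueError):
            normalize_channels(table, {"a": 0.0, "b": 1.0})
        with pytest.raises(ValueError):
            normalize_channels(table, {"a": 1.0})    # missing channel

    def test_derive_factors_mean_one(self):
        table = pd.DataFrame({"a": [2.0, 2.0], "b": [1.0, 1.0]})
        f = derive_scaling_factors(table)
        assert np.isclose(f.mean(), 1.0)
        assert np.isclose(f["a"] / f["b"], 2.0)


class TestAggregation:
    def test_single_psm_is_itself(self):
        row = pd.DataFrame({"a": [5.0], "b": [7.0]})
        pd.testing.assert_series_equal(aggregate_psms(row), row.iloc[0],
                                       check_names=False)

    def test_median_odd_and_even(self):
        odd = pd.DataFrame({"a": [1.0, 2.0, 9.0]})
        assert aggregate_psms(odd)["a"] == 2.0
        even = pd.DataFrame({"a": [1.0, 2.0, 3.0, 9.0]})
        assert aggregate_psms(even)["a"] == 2.5     # mean of central pair

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_psms(pd.DataFrame({"a": []}))


class TestDifferential:
    def test_twofold_up_with_oracle_p(self, design):
        young = [1, 1, 1.1, 0.9, 1]
        aged = [2, 2, 2.2, 1.8, 2]
        res = differential_test(_series(design, young, aged), design)
        assert res.fc == pytest.approx(2.0, rel=0.01)
        assert res.p == pytest.approx(oracle_t_p(young, aged), abs=1e-12)
        assert res.call == "up"

    def test_identical_groups_ns(self, design):
        vals = [1.0, 1.2, 0.9, 1.1, 1.0]
        res = differential_test(_series(design, vals, vals), design)
        assert res.fc == pytest.approx(1.0)
        assert res.call == "ns"

    def test_fc_below_threshold_is_ns_despite_tiny_p(self, design):
        young = [1.0, 1.0, 1.0, 1.0, 1.0]
        aged = [1.4, 1.4, 1.4, 1.4, 1.4]
        res = differential_test(_series(design, young, aged), design)
        assert res.fc == pytest.approx(1.4)
        assert res.call == "ns"

    def test_all_zero_group_flagged_ns(self, design):
        res = differential_test(
            _series(design, [0, 0, 0, 0, 0], [1, 1, 1, 1, 1]), design)
        assert res.call == "ns" and "all-zero-group" in res.flags

    def test_scale_invariance_under_self_normalization(self, design):
        """Scaling one channel's raw data leaves FC and p unchanged."""
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.uniform(1e5, 1e6, (40, 10)),
                             columns=design.channels)
        scaled = table.copy()
        scaled["127N"] *= 7.5
        d1 = differential_table(normalize_channels(table, "self"), design)
        d2 = differential_table(normalize_channels(scaled, "self"), design)
        assert np.allclose(d1["fc"], d2["fc"])
        assert np.allclose(d1["p"], d2["p"])

    def test_group_swap_symmetry(self, design):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.uniform(1e5, 1e6, (30, 10)),
                             columns=design.channels)
        table.iloc[:10] *= np.where(
            [c in design.channels_of("aged") for c in design.channels],
            3.0, 1.0)
        flipped = SampleDesign(groups=design.groups, sexes=design.sexes,
                               group_a="aged", group_b="young")
        d1 = differential_table(table, design)
        d2 = differential_table(table, flipped)
        assert np.allclose(d1["fc"], 1.0 / d2["fc"])
        assert np.allclose(d1["p"], d2["p"])
        assert ((d1["call"] == "up") == (d2["call"] == "down")).all()

    def test_table_matches_rowwise_oracle(self, design):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.uniform(1e5, 1e6, (25, 10)),
                             columns=design.channels)
        d = differential_table(table, design)
        for i in range(len(table)):
            young = table.iloc[i][design.channels_of("young")]
            aged = table.iloc[i][design.channels_of("aged")]
            assert d["fc"].iloc[i] == pytest.approx(
                aged.mean() / young.mean(), abs=1e-12)
            assert d["p"].iloc[i] == pytest.approx(
                oracle_t_p(young, aged), abs=1e-12)

    def test_welch_toggle_changes_p_under_unequal_variance(self, design):
        young = [1.0, 1.01, 0.99, 1.0, 1.0]
        aged = [2.0, 3.5, 1.2, 4.0, 0.8]
        s = _series(design, young, aged)
        p_pooled = differential_test(s, design).p
        p_welch = differential_test(s, design, Thresholds(welch=True)).p
        assert p_pooled != pytest.approx(p_welch)

    def test_bh_fdr_option_is_more_conservative(self, design):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.uniform(1e5, 1e6, (50, 10)),
                             columns=design.channels)
        table.iloc[:5] *= np.where(
            [c in design.channels_of("aged") for c in design.channels],
            2.5, 1.0)
        raw = differential_table(table, design)
        adj = differential_table(table, design, Thresholds(use_fdr=True))
        assert (adj["call"] != "ns").sum() <= (raw["call"] != "ns").sum()
        assert (adj["p_adj"] >= adj["p"] - 1e-15).all()


class TestZeroImputation:
    def test_zero_replaced_by_half_min_nonzero(self):
        table = pd.DataFrame({"a": [0.0, 4.0, 8.0], "b": [1.0, 1.0, 1.0]})
        out, flagged = impute_zeros(table)
        assert out.loc[0, "a"] == 2.0
        assert flagged.tolist() == [True, False, False]


class TestProteinNormalization:
    def test_arithmetic(self, design):
        res = differential_test(
            _series(design, [1] * 5, [3.0] * 5), design)
        out = normalize_by_protein(res, 2.0, 0.01)
        assert out.norm_fc == pytest.approx(1.5)
        out2 = normalize_by_protein(res, res.fc, 0.01)
        assert out2.norm_fc == pytest.approx(1.0)

    def test_unmatched_protein_keeps_fc_with_flag(self, design):
        res = differential_test(
            _series(design, [1] * 5, [2.0] * 5), design)
        out = normalize_by_protein(res, None)
        assert out.norm_fc == pytest.approx(out.fc)
        assert "no-protein" in out.flags

    def test_nonpositive_protein_fc_rejected(self, design):
        res = differential_test(
            _series(design, [1] * 5, [2.0] * 5), design)
        with pytest.raises(ValueError):
            normalize_by_protein(res, -1.0)


class TestQuadrant:
    def _df(self, fc, p, norm_fc, pfc, pp):
        return pd.DataFrame({"fc": [fc], "p": [p], "norm_fc": [norm_fc],
                             "protein_fc": [pfc], "protein_p": [pp]})

    def test_protein_driven_is_type_one(self):
        q = quadrant_classify(self._df(2.0, 0.001, 1.05, 2.0, 0.001))
        assert q.iloc[0] == "TypeI-up"

    def test_glycosylation_driven_is_type_two(self):
        q = quadrant_classify(self._df(2.1, 0.001, 2.1, 1.05, 0.8))
        assert q.iloc[0] == "TypeII-up"
        q = quadrant_classify(self._df(0.4, 0.001, 0.4, 1.0, 0.9))
        assert q.iloc[0] == "TypeII-down"

    def test_both_and_unchanged(self):
        q = quadrant_classify(self._df(4.0, 0.001, 2.0, 2.0, 0.001))
        assert q.iloc[0] == "both"
        q = quadrant_classify(self._df(1.1, 0.5, 1.1, 1.0, 0.9))
        assert q.iloc[0] == "unchanged"
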