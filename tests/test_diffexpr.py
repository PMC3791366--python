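"""Normalization, dispersion, the NB likelihood-ratio test and BH selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfscreen import SimConfig, simulate
from tfscreen.diffexpr import (
    CountMatrix,
    DEConfig,
    SampleDesign,
    bh_adjust,
    call_de,
    estimate_dispersion,
    nb_lrt_test,
    nb_lrt_vectorized,
    size_factors,
)

from oracles import bh_suffix


def _df(arr, samples):
    return pd.DataFrame(np.asarray(arr), columns=samples)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        f = size_factors(_df([[5, 5], [9, 9]], ["a", "b"]))
        assert np.allclose(f, [1.0, 1.0])

    def test_exact_doubling_splits_geometrically(self):
        # B = 2A: per-gene geomean is c*sqrt(2), ratios 1/sqrt(2) and sqrt(2)
        f = size_factors(_df([[10, 20], [3, 6], [7, 14]], ["A", "B"]))
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scaling_one_sample_scales_factors_predictably(self):
        base = np.array([[10, 11], [3, 4], [7, 6]])
        f0 = size_factors(_df(base, ["A", "B"]))
        scaled = base.copy()
        scaled[:, 1] *= 10
        f1 = size_factors(_df(scaled, ["A", "B"]))
        # the scaled sample's factor gains 10, both lose 10^(1/n) via the geomean
        assert np.allclose(f1["B"] / f0["B"], 10 / np.sqrt(10))
        assert np.allclose(f1["A"] / f0["A"], 1 / np.sqrt(10))

    def test_no_common_positive_gene_errors_with_advice(self):
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(_df([[0, 5], [4, 0]], ["a", "b"]))
        f = size_factors(_df([[0, 5], [4, 0]], ["a", "b"]), pseudo_reference=True)
        assert (f > 0).all()


class TestDispersion:
    def test_constant_gene_floors(self):
        counts = _df([[7, 7, 7, 7]], ["a", "b", "c", "d"])
        cond = ["x", "x", "y", "y"]
        f = pd.Series([1.0] * 4, index=counts.columns)
        assert estimate_dispersion(counts, cond, f).iloc[0] == 1e-8

    def test_poisson_gene_stays_near_floor_and_nb_gene_is_recovered(self):
        rng = np.random.default_rng(5)
        n = 4000
        pois = rng.poisson(100, size=(1, n))
        r = 1 / 0.1
        nb = rng.negative_binomial(r, r / (r + 100.0), size=(1, n))
        counts = _df(np.vstack([pois, nb]), [f"s{i}" for i in range(n)])
        cond = ["x"] * n
        f = pd.Series(np.ones(n), index=counts.columns)
        d = estimate_dispersion(counts, cond, f)
        assert d.iloc[0] < 0.01  # Poisson: variance ~ mean
        assert abs(d.iloc[1] - 0.1) < 0.02  # NB alpha recovered

    def test_all_zero_gene_gets_floor(self):
        counts = _df([[0, 0, 0, 0]], ["a", "b", "c", "d"])
        f = pd.Series([1.0] * 4, index=counts.columns)
        assert estimate_dispersion(counts, ["x", "x", "y", "y"], f).iloc[0] == 1e-8


class TestNbLrt:
    def test_identical_conditions_give_p_one(self):
        p, lfc = nb_lrt_test([10, 10, 10, 10], [1, 1, 1, 1], ["u", "u", "s", "s"], 0.1)
        assert p == pytest.approx(1.0)
        assert lfc == pytest.approx(0.0)

    def test_all_zero_gene_is_untestable(self):
        p, lfc = nb_lrt_test([0, 0, 0, 0], [1, 1, 1, 1], ["u", "u", "s", "s"], 0.1)
        assert (p, lfc) == (1.0, 0.0)

    def test_relabelling_within_condition_is_irrelevant(self):
        k = [12, 30, 15, 40]
        p1, _ = nb_lrt_test(k, [1, 1, 1, 1], ["u", "s", "u", "s"], 0.1)
        p2, _ = nb_lrt_test([15, 40, 12, 30], [1, 1, 1, 1], ["u", "s", "u", "s"], 0.1)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_scaling_all_size_factors_changes_nothing(self):
        k = [12, 30, 15, 40]
        p1, l1 = nb_lrt_test(k, [1.0, 1.1, 0.9, 1.0], ["u", "s", "u", "s"], 0.1)
        p2, l2 = nb_lrt_test(k, [3.0, 3.3, 2.7, 3.0], ["u", "s", "u", "s"], 0.1)
        assert p1 == pytest.approx(p2, rel=1e-6)
        assert l1 == pytest.approx(l2, rel=1e-6)

    def test_zero_condition_uses_half_count_pseudo_rate(self):
        _, lfc = nb_lrt_test([0, 0, 8, 8], [1, 1, 1, 1], ["u", "u", "s", "s"], 0.1)
        assert lfc == pytest.approx(np.log2(8 / 0.25))

    def test_poisson_limit_rate_is_weighted_mean(self):
        # with alpha at the floor, the fitted rate must equal sum(k)/sum(s)
        k = np.array([[10, 20, 12, 25]])
        s = np.array([0.8, 1.2, 1.0, 1.0])
        from tfscreen.diffexpr import _fit_rate

        q = _fit_rate(k.astype(float), s, np.array([[1e8]]))
        assert q[0] == pytest.approx(k.sum() / s.sum(), rel=1e-6)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.011, 0.02, 0.04), (0.02, 0.022, 4 * 0.02 / 3, 0.04)),
            ((0.3, 0.3, 0.3), (0.3, 0.3, 0.3)),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_min_over_suffix_definition_and_monotone(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_suffix(p))
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(300)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestCallDe:
    def _matrix(self, seed=0, **kw):
        return simulate(SimConfig(seed=seed, **kw)).counts

    def test_missing_condition_errors(self):
        cm = self._matrix()
        half = [s for s in cm.design if s.treatment == "untreated"]
        broken = CountMatrix(cm.counts[[s.sample_id for s in half]], half)
        with pytest.raises(ValueError, match="missing treatment"):
            call_de(broken, "wt")

    def test_flipping_treatment_labels_negates_log2fc(self):
        cm = self._matrix(seed=4)
        de = call_de(cm, "wt")
        flipped_design = [
            SampleDesign(s.sample_id, s.genotype,
                         "stimulated" if s.treatment == "untreated" else "untreated")
            for s in cm.design
        ]
        de_f = call_de(CountMatrix(cm.counts, flipped_design), "wt")
        assert np.allclose(de["log2fc"], -de_f["log2fc"], atol=1e-8)
        assert np.allclose(de["pvalue"], de_f["pvalue"], atol=1e-10)

    def test_planted_wt_effects_do_not_appear_in_knockout(self):
        data = simulate(SimConfig(seed=6))
        de_null = call_de(data.counts, "null")
        up = set(de_null.loc[de_null["call"] == "up", "gene_id"])
        wt_only = up & (data.truth.induced_wt - data.truth.induced_null)
        assert len(wt_only) <= 3  # FDR-level leakage only

    def test_calls_respect_padj_and_sign_invariants(self, default_sim):
        de = call_de(default_sim.counts, "wt")
        tested = de[de["tested"]]
        assert (tested["padj"] >= tested["pvalue"] - 1e-12).all()
        up = de[de["call"] == "up"]
        down = de[de["call"] == "down"]
        assert (up["padj"] < 0.05).all() and (up["log2fc"] > 0).all()
        assert (down["padj"] < 0.05).all() and (down["log2fc"] < 0).all()

    def test_independent_filter_excludes_low_count_genes_from_bh(self, default_sim):
        cm = default_sim.counts
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        de = call_de(CountMatrix(counts, cm.design), "wt", DEConfig(min_total_count=1))
        assert not de.iloc[0]["tested"]
        assert np.isnan(de.iloc[0]["padj"]) and de.iloc[0]["call"] == "ns"
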