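"""Normalisation, dispersion, exact test, BH, selection, heatmap, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom, nbinom

from famseg import (
    CountMatrix,
    CountSimConfig,
    GeneSetCollection,
    bh_adjust,
    cpm,
    de_filter,
    enrich,
    estimate_common_dispersion,
    exact_test,
    expression_universe,
    fpkm,
    heatmap_matrix,
    read_gmt,
    simulate_counts,
    top_n_by_direction,
)
from famseg.errors import ValidationError
from famseg.rnaseq import conditional_two_sided_p


def _cm(counts, lengths=None, n_patients=1):
    counts = np.atleast_2d(np.asarray(counts))
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    group = {s: ("patient" if j < n_patients else "control")
             for j, s in enumerate(samples)}
    lengths = lengths if lengths is not None else [1000] * n_genes
    return CountMatrix(genes, lengths, samples, group, counts)


class TestNormalisation:
    def test_cpm_single_sample(self):
        c = cpm(_cm([[5], [10], [85]]))
        np.testing.assert_allclose(c.to_numpy().ravel(), [50000, 100000, 850000])

    def test_cpm_zero_gene(self):
        c = cpm(_cm([[0, 0], [10, 20]]))
        np.testing.assert_array_equal(c.iloc[0].to_numpy(), [0.0, 0.0])

    def test_cpm_column_conservation(self, rng):
        counts = rng.integers(0, 500, (50, 4))
        counts[0] += 1  # guard against an all-zero library
        c = cpm(_cm(counts))
        np.testing.assert_allclose(c.sum(axis=0).to_numpy(), 1e6, rtol=1e-12)

    def test_fpkm_unit_definition(self):
        m = _cm([[10], [999_990]], lengths=[1000, 1000])
        assert fpkm(m).iloc[0, 0] == pytest.approx(10.0, abs=1e-12)

    def test_fpkm_length_scaling(self):
        a = fpkm(_cm([[10], [90]], lengths=[1000, 1000]))
        b = fpkm(_cm([[10], [90]], lengths=[2000, 1000]))
        assert b.iloc[0, 0] == pytest.approx(a.iloc[0, 0] / 2)

    def test_fpkm_equals_cpm_over_length_kb(self, rng):
        counts = rng.integers(1, 300, (20, 3))
        lengths = rng.integers(200, 5000, 20)
        m = _cm(counts, lengths=lengths)
        np.testing.assert_allclose(
            fpkm(m).to_numpy(),
            cpm(m).to_numpy() / (lengths[:, None] / 1e3),
            rtol=1e-12,
        )


class TestDispersion:
    def test_poisson_truth_near_zero(self):
        cm, _ = simulate_counts(CountSimConfig(
            n_genes=2000, dispersion=0.0, de_fraction=0.0, seed=5))
        assert estimate_common_dispersion(cm) <= 0.05

    def test_nb_truth_recovered(self):
        cm, _ = simulate_counts(CountSimConfig(
            n_genes=2000, dispersion=0.2, de_fraction=0.0, seed=5))
        assert 0.1 <= estimate_common_dispersion(cm) <= 0.3

    def test_single_sample_per_group_falls_back(self):
        cm = _cm([[5, 7], [1, 2]], n_patients=1)
        with pytest.warns(UserWarning, match="fallback"):
            assert estimate_common_dispersion(cm) == 0.1


class TestExactTest:
    def test_symmetric_split_is_one(self):
        cm = _cm([[50, 50]], n_patients=1)
        assert exact_test(cm, 0.0)[0] == pytest.approx(1.0, abs=1e-9)

    def test_extreme_split_doubled_binomial_tail(self):
        # total 10 all in one of two equal samples, Poisson limit
        p = conditional_two_sided_p(np.array([10]), np.array([0]), 1, 1, 0.0)
        assert p[0] == pytest.approx(2 / 1024, rel=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_oracle_equivalence_small_totals(self, phi):
        """Conditional p equals exhaustive NB-product enumeration."""
        n_a, n_b, mu = 2, 4, 3.3
        for t in (1, 7, 23, 60):
            ks = np.arange(t + 1)
            if phi == 0:
                pmf = binom.pmf(ks, t, n_a / (n_a + n_b))
            else:
                r_a, r_b = n_a / phi, n_b / phi
                w = (nbinom.pmf(ks, r_a, r_a / (r_a + n_a * mu))
                     * nbinom.pmf(t - ks, r_b, r_b / (r_b + n_b * mu)))
                pmf = w / w.sum()
            for a in (0, t // 3, t // 2, t):
                expected = min(1.0, 2 * min(pmf[:a + 1].sum(), pmf[a:].sum()))
                got = conditional_two_sided_p(
                    np.array([a]), np.array([t - a]), n_a, n_b, phi)[0]
                assert got == pytest.approx(expected, abs=1e-10)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValidationError):
            conditional_two_sided_p(np.array([1]), np.array([1]), 2, 4, -0.1)


class TestBH:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_dominates_p(self, ps):
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= np.asarray(ps) - 1e-15) & (q <= 1.0)).all()


def _res_table(rows):
    return pd.DataFrame(rows).set_index("gene_id")


class TestDeFilterAndTopN:
    def test_threshold_edges(self):
        res = _res_table([
            {"gene_id": "a", "log2fc": 0.9, "fdr": 0.04},
            {"gene_id": "b", "log2fc": -1.2, "fdr": 0.04},
            {"gene_id": "c", "log2fc": 2.0, "fdr": 0.06},
        ])
        up, down = de_filter(res)
        assert up == [] and down == ["b"]

    def test_top_n_truncation_and_ties(self):
        res = _res_table([
            {"gene_id": "a", "log2fc": 2.0, "fdr": 0.02},
            {"gene_id": "b", "log2fc": 2.0, "fdr": 0.01},
            {"gene_id": "c", "log2fc": 3.0, "fdr": 0.03},
            {"gene_id": "d", "log2fc": -2.0, "fdr": 0.01},
        ])
        up, down = top_n_by_direction(res, n=100)
        assert up == ["c", "b", "a"]  # tie between a/b broken by fdr
        assert down == ["d"]
        up2, _ = top_n_by_direction(res, n=2)
        assert up2 == ["c", "b"]


class TestHeatmap:
    def test_row_mean_normalisation(self):
        df = pd.DataFrame([[2, 4, 6]], index=["g"], columns=list("abc"))
        out = heatmap_matrix(df, ["g"])
        np.testing.assert_allclose(out.to_numpy().ravel(), [0.5, 1.0, 1.5])

    def test_constant_row_all_ones(self):
        df = pd.DataFrame([[3, 3, 3]], index=["g"], columns=list("abc"))
        np.testing.assert_allclose(heatmap_matrix(df, ["g"]).to_numpy(), 1.0)

    def test_output_row_means_one_and_zero_rows_flagged(self, rng):
        df = pd.DataFrame(rng.random((5, 4)) + 0.1,
                          index=[f"g{i}" for i in range(5)])
        df.iloc[2] = 0.0
        out = heatmap_matrix(df, df.index)
        means = out.mean(axis=1)
        assert out.attrs["zero_mean_rows"] == ["g2"]
        np.testing.assert_allclose(means.drop("g2").to_numpy(), 1.0, rtol=1e-12)
        assert (out.loc["g2"] == 0).all()


class TestEnrich:
    def _gsc(self):
        universe = {f"g{i}" for i in range(20)}
        return GeneSetCollection(
            sets={"S1": ("set one", {f"g{i}" for i in range(5)}),
                  "ALL": ("everything", set(universe))},
            universe=universe,
        )

    def test_exact_hypergeometric_value(self):
        gsc = self._gsc()
        res = enrich(["g0", "g1", "g2", "g3"], gsc).set_index("set_id")
        expected = 5 / 4845  # C(5,4)*C(15,0)/C(20,4)
        assert res.loc["S1", "p"] == pytest.approx(expected, abs=1e-12)
        assert res.loc["S1", "enrichment_ratio"] == pytest.approx(4 / 5)

    def test_zero_overlap(self):
        gsc = self._gsc()
        res = enrich(["g10", "g11"], gsc).set_index("set_id")
        assert res.loc["S1", "p"] == pytest.approx(1.0)
        assert res.loc["S1", "enrichment_ratio"] == 0.0

    def test_set_equal_universe(self):
        gsc = self._gsc()
        res = enrich(["g0", "g1", "g2", "g3"], gsc).set_index("set_id")
        assert res.loc["ALL", "p"] == pytest.approx(1.0)
        assert res.loc["ALL", "enrichment_ratio"] == pytest.approx(4 / 20)

    def test_de_gene_outside_universe_dropped(self):
        gsc = self._gsc()
        with pytest.warns(UserWarning, match="dropped"):
            res = enrich(["g0", "g1", "g2", "g3", "nope"], gsc).set_index("set_id")
        assert res.loc["S1", "n"] == 4

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tfirst set\tg1\tg2\tg3\nS2\tsecond\tg2\tg4\n")
        gsc = read_gmt(p)
        assert gsc.sets["S1"][1] == {"g1", "g2", "g3"}
        assert gsc.universe == {"g1", "g2", "g3", "g4"}


def test_expression_universe_filter():
    counts = np.array([[100, 100, 100, 100],   # expressed everywhere
                       [0, 0, 0, 0],           # silent
                       [5000, 0, 0, 0]])       # expressed in one sample only
    cm = _cm(counts, n_patients=2)
    assert expression_universe(cm, min_cpm=1.0, min_samples=2) == ["g0"]
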