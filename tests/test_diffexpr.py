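import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

from osintegrate.diffexpr import (
    CountMatrix,
    DispersionEstimate,
    bh_adjust,
    call_de,
    estimate_dispersion,
    exact_nb_pvalue,
    exact_test,
    normalize_libsizes,
    transcriptome_correlation,
)
from osintegrate.simulate import SimConfig, simulate_counts


def oracle_split_pvalue(z1, z2, n1, n2, phi):
    """Independent enumeration oracle via scipy nbinom/binom pmf products.

    The group sums are NB with sizes n1/phi and n2/phi sharing any success
    probability (it cancels on conditioning); enumerate every split of the
    total and sum the probabilities no larger than the observed one.
    """
    z = z1 + z2
    k = np.arange(z + 1)
    if phi == 0:
        pmf = binom.pmf(k, z, n1 / (n1 + n2))
    else:
        r = 1.0 / phi
        pmf = nbinom.pmf(k, n1 * r, 0.4) * nbinom.pmf(z - k, n2 * r, 0.4)
        pmf = pmf / pmf.sum()
    return min(1.0, pmf[pmf <= pmf[z1] * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# normalization


class TestNormalizeLibsizes:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 10, 20], "s2": [5, 10, 20], "s3": [5, 10, 20]},
                              index=["a", "b", "c"])
        groups = pd.Series({"s1": "aggressive", "s2": "curable", "s3": "curable"})
        eff = normalize_libsizes(CountMatrix(counts, groups))
        assert np.allclose(eff.values, eff.values[0])

    def test_doubled_column_factor_two(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 200, size=100)
        counts = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
        groups = pd.Series({"s1": "aggressive", "s2": "curable", "s3": "curable"})
        eff = normalize_libsizes(CountMatrix(counts, groups))
        assert eff["s3"] / eff["s1"] == pytest.approx(2.0, rel=1e-6)

    def test_single_sample(self):
        counts = pd.DataFrame({"s1": [5, 10]})
        eff = normalize_libsizes(CountMatrix(counts, pd.Series({"s1": "aggressive"})))
        assert eff["s1"] == 15

    def test_all_zero_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [0, 0]})
        groups = pd.Series({"s1": "aggressive", "s2": "curable"})
        with pytest.raises(ValueError, match="all-zero"):
            normalize_libsizes(CountMatrix(counts, groups))


# ---------------------------------------------------------------------------
# dispersion


class TestEstimateDispersion:
    def test_recovers_phi(self):
        cfg = SimConfig(seed=3, n_genes=2000, dispersion=0.2, de_fraction=0.0)
        m, _ = simulate_counts(cfg)
        d = estimate_dispersion(m)
        assert 0.15 <= d.common <= 0.25

    def test_poisson_data_near_zero(self):
        cfg = SimConfig(seed=4, n_genes=2000, dispersion=0.0, de_fraction=0.0)
        m, _ = simulate_counts(cfg)
        d = estimate_dispersion(m)
        assert d.common < 0.02

    def test_infinite_shrinkage_collapses_to_common(self):
        cfg = SimConfig(seed=5, n_genes=300, dispersion=0.3)
        m, _ = simulate_counts(cfg)
        d = estimate_dispersion(m, shrinkage_weight=np.inf)
        assert np.allclose(d.tagwise.values, d.common)

    def test_large_shrinkage_near_common(self):
        cfg = SimConfig(seed=5, n_genes=300, dispersion=0.3)
        m, _ = simulate_counts(cfg)
        d = estimate_dispersion(m, shrinkage_weight=1e9)
        # grid-valued tagwise: every gene lands on the grid point nearest common
        assert np.allclose(d.tagwise.values, d.common, rtol=0.1)

    def test_no_replicates_raises(self):
        counts = pd.DataFrame({"s1": [5, 10], "s2": [6, 9]})
        groups = pd.Series({"s1": "aggressive", "s2": "curable"})
        with pytest.raises(ValueError, match="fixed dispersion"):
            estimate_dispersion(CountMatrix(counts, groups))

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            DispersionEstimate(common=-0.1, tagwise=pd.Series([0.1]), shrinkage_weight=1)


# ---------------------------------------------------------------------------
# exact test


class TestExactTest:
    def test_zero_vs_ten_poisson(self):
        # oracle: Bin(10, 1/2); p = P(0) + P(10) = 2 * (1/2)**10
        assert exact_nb_pvalue(0, 10, 1, 1, 0.0) == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_balanced_split_p_one(self):
        assert exact_nb_pvalue(25, 25, 3, 3, 0.1) == pytest.approx(1.0)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (5, 5)])
    def test_matches_enumeration_oracle(self, phi, n1, n2):
        for z in [1, 7, 23, 50]:
            for z1 in range(z + 1):
                p = exact_nb_pvalue(z1, z - z1, n1, n2, phi)
                o = oracle_split_pvalue(z1, z - z1, n1, n2, phi)
                assert p == pytest.approx(o, rel=1e-8, abs=1e-12)

    def test_zero_total_gene(self, toy_counts):
        res = exact_test(toy_counts, 0.1)
        assert res.loc["g5", "p"] == 1.0
        assert res.loc["g5", "log2_fold_change"] == 0.0

    def test_full_matrix_agrees_with_oracle(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(0, 8, size=(20, 6)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(6)])
        # equal library sizes so pseudo-counts stay un-rescaled
        counts.iloc[0] = 5
        groups = pd.Series({f"s{i}": ("aggressive" if i < 3 else "curable")
                            for i in range(6)})
        m = CountMatrix(counts, groups)
        eff = normalize_libsizes(m)
        res = exact_test(m, 0.2)
        # recompute expected from the (rounded) pseudo counts the test used
        target = np.exp(np.mean(np.log(eff.values)))
        pseudo = np.rint(counts.values * (target / eff.values)[None, :])
        for i, gene in enumerate(counts.index):
            z1 = int(pseudo[i, :3].sum())
            z2 = int(pseudo[i, 3:].sum())
            assert res.loc[gene, "p"] == pytest.approx(
                oracle_split_pvalue(z1, z2, 3, 3, 0.2), rel=1e-8)

    def test_bad_which_rejected(self, toy_counts):
        d = estimate_dispersion(toy_counts)
        with pytest.raises(ValueError, match="which"):
            exact_test(toy_counts, d, "neither")


# ---------------------------------------------------------------------------
# calling + BH


class TestCallDE:
    @staticmethod
    def _frame(ps, genes=None):
        genes = genes or [f"g{i}" for i in range(len(ps))]
        return pd.DataFrame({"p": ps, "log2_fold_change": [1.0] * len(ps)},
                            index=genes)

    def test_bh_by_definition_two_genes(self):
        rc = self._frame([0.001, 0.5])
        rt = self._frame([0.002, 0.5])
        res = call_de(rc, rt)
        assert res.table["fdr_common"].tolist() == pytest.approx([0.002, 0.5])
        assert res.table["fdr_tagwise"].tolist() == pytest.approx([0.004, 0.5])
        assert res.mode_used == "dual_fdr"
        assert res.significant_genes == {"g0"}

    def test_tied_p_all_significant(self):
        rc = self._frame([0.04] * 100)
        res = call_de(rc, rc)
        assert res.mode_used == "dual_fdr"
        assert np.allclose(res.table["fdr_common"], 0.04)
        assert res.table["significant"].all()

    def test_fallback_engages(self):
        # 20 genes at p=0.04 plus 80 at 0.9: BH fdr = 0.04*100/20 = 0.2 >= alpha
        ps = [0.04] * 20 + [0.9] * 80
        res = call_de(self._frame(ps), self._frame(ps))
        assert res.mode_used == "unadjusted_fallback"
        assert len(res.significant_genes) == 20

    def test_fallback_requires_both_p_below_alpha(self):
        rc = self._frame([0.04, 0.9, 0.04])
        rt = self._frame([0.04, 0.04, 0.9])
        res = call_de(rc, rt)
        assert res.mode_used == "unadjusted_fallback"
        assert res.significant_genes == {"g0"}

    def test_mismatched_genes_rejected(self):
        with pytest.raises(ValueError, match="different gene sets"):
            call_de(self._frame([0.1]), self._frame([0.1], genes=["other"]))

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(size=50)
        res = call_de(self._frame(ps), self._frame(ps))
        assert (res.table["fdr_common"].values >= res.table["p_common"].values - 1e-12).all()


class TestBHAdjust:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_matches_closed_form(self, ps):
        # NOTE: BH is *not* idempotent as a map on p-vectors
        # (p = (0.25, 1) -> (0.5, 1) -> (1, 1)); the correct invariant is the
        # step-up closed form: adj_(i) = min_{j >= i} min(1, p_(j) * n / j).
        adj = bh_adjust(ps)
        assert ((adj >= np.asarray(ps) - 1e-12) & (adj <= 1 + 1e-12)).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
        n = len(ps)
        srt = np.sort(ps)
        expected = np.minimum.accumulate(
            np.minimum(1.0, srt * n / np.arange(1, n + 1))[::-1]
        )[::-1]
        assert np.allclose(adj[order], expected)

    def test_rejections_stable_under_readjustment_at_small_alpha(self):
        # the decision-level stability BH does provide: re-adjusting the
        # adjusted values never creates new rejections
        rng = np.random.default_rng(1)
        ps = rng.uniform(size=40)
        once = bh_adjust(ps)
        twice = bh_adjust(once)
        assert set(np.flatnonzero(twice < 0.05)) <= set(np.flatnonzero(once < 0.05))

    def test_empty(self):
        assert bh_adjust([]).size == 0


# ---------------------------------------------------------------------------
# correlation


class TestTranscriptomeCorrelation:
    def test_identical_vectors(self):
        a = np.array([10.0, 100.0, 5.0, 60.0, 3.0])
        assert transcriptome_correlation(a, a) == pytest.approx(1.0)

    def test_anticorrelated_after_transform(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = -a + 10.0
        assert transcriptome_correlation(a, b, transform=False) == pytest.approx(-1.0)

    def test_matches_hand_formula(self):
        a = np.array([10.0, 100.0, 5.0, 60.0, 3.0])
        b = np.array([12.0, 80.0, 9.0, 70.0, 2.0])
        la = np.log2(a / a.sum() * 1e6 + 1)
        lb = np.log2(b / b.sum() * 1e6 + 1)
        expected = np.cov(la, lb, bias=True)[0, 1] / (la.std() * lb.std())
        assert transcriptome_correlation(a, b) == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            transcriptome_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                                      transform=False)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            transcriptome_correlation([1.0, 2.0], [1.0, 2.0, 3.0])
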