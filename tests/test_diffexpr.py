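"""NB Wald engine: normalization, dispersion, test calibration, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nanovax as nv
from nanovax.diffexpr import ALPHA_MIN, bh_adjust, estimate_dispersion


def _frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def _groups(n1, n2, columns):
    return pd.Series(["Control"] * n1 + ["PostVaccination"] * n2, index=columns)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = _frame(np.tile([[10], [20], [30]], (1, 2)))
        np.testing.assert_allclose(nv.estimate_size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_scales_proportionally(self):
        base = np.array([[10], [25], [40], [100]])
        counts = _frame(np.hstack([base, 2 * base]))
        factors = nv.estimate_size_factors(counts).to_numpy()
        np.testing.assert_allclose(factors[1] / factors[0], 2.0)
        np.testing.assert_allclose(np.exp(np.mean(np.log(factors))), 1.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(42)
        counts = _frame(rng.poisson(50, size=(50, 6)))
        # independent brute-force oracle
        x = counts.to_numpy(float)
        keep = (x > 0).all(axis=1)
        geo = np.exp(np.mean(np.log(x[keep]), axis=1))
        ratios = x[keep] / geo[:, None]
        oracle = np.median(ratios, axis=0)
        oracle = oracle / np.exp(np.mean(np.log(oracle)))
        np.testing.assert_allclose(nv.estimate_size_factors(counts), oracle, rtol=1e-12)

    def test_matches_pydeseq2_on_small_matrix(self):
        """Cross-check against an established DE package's size factors."""
        pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
        rng = np.random.default_rng(7)
        # odd gene count: the ratio-space and log-space medians coincide
        counts = _frame(rng.poisson(40, size=(61, 6)))
        groups = _groups(3, 3, counts.columns)
        meta = pd.DataFrame({"condition": groups})
        dds = pydeseq2_dds.DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        theirs = np.asarray(dds.obs["size_factors"], dtype=float)
        ours = nv.estimate_size_factors(counts).to_numpy()
        # ours is rescaled to geometric mean 1; compare up to that scaling
        theirs = theirs / np.exp(np.mean(np.log(theirs)))
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)

    def test_all_zero_row_fallback_warns(self):
        counts = _frame([[0, 5], [3, 0]])
        with pytest.warns(UserWarning, match="total-count"):
            factors = nv.estimate_size_factors(counts)
        assert (factors > 0).all()


class TestDispersion:
    def test_worked_example(self):
        """mu=100, pooled within-group variance 300 -> alpha = 0.02."""
        # two groups of 3 values each, constructed to hit mu=100, s2=300
        a = 100 + np.sqrt(300) * np.array([-1.0, 0.0, 1.0])
        counts = _frame(np.vstack([np.concatenate([a, a])]))
        groups = _groups(3, 3, counts.columns)
        disp = estimate_dispersion(counts, groups)
        np.testing.assert_allclose(disp["dispersion"], (300 - 100) / 100**2, rtol=1e-12)

    def test_poisson_like_gene_floors_at_alpha_min(self):
        # sub-Poisson spread: variance < mean -> floored
        counts = _frame([[100, 100, 101, 99, 100, 100]])
        disp = estimate_dispersion(counts, _groups(3, 3, counts.columns))
        assert disp["dispersion"].iloc[0] == ALPHA_MIN

    def test_zero_mean_gene_flagged(self):
        counts = _frame([[0, 0, 0, 0], [5, 6, 7, 8]])
        disp = estimate_dispersion(counts, _groups(2, 2, counts.columns))
        assert disp.loc["g0", "zero_mean"]
        assert disp.loc["g0", "dispersion"] == ALPHA_MIN

    def test_never_negative_on_random_input(self):
        rng = np.random.default_rng(0)
        counts = _frame(rng.poisson(20, size=(200, 8)))
        disp = estimate_dispersion(counts, _groups(4, 4, counts.columns))
        assert (disp["dispersion"] >= ALPHA_MIN).all()


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100))
    def test_matches_brute_force_oracle(self, pvals):
        """BH equals the explicit min-over-j>=i step-up on random vectors."""
        p = np.array(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        oracle = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            oracle[order[rank - 1]] = min(running, 1.0)
        np.testing.assert_allclose(bh_adjust(p), oracle, rtol=1e-12, atol=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-10, atol=1e-12)

    def test_order_preserving(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        padj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-15).all()


class TestWald:
    def test_identical_groups_null(self):
        counts = _frame(np.tile([[40], [80], [120]], (1, 6)))
        de = nv.wald_test(counts, _groups(3, 3, counts.columns))
        np.testing.assert_allclose(de["log2FoldChange"], 0.0, atol=1e-12)
        assert (de["pvalue"] > 0.99).all()

    def test_full_recovery_on_default_design(self, default_matrix, default_de):
        """Every designed-up/down gene is significant with the right sign
        at FDR < 0.05 on the default synthetic study."""
        truth = default_matrix.truth
        up = truth.index[truth["gene_class"] == "designed_up"]
        down = truth.index[truth["gene_class"] == "designed_down"]
        assert up.isin(nv.significant_up(default_de, 0.05)).all()
        assert down.isin(nv.significant_down(default_de, 0.05)).all()

    def test_marker_genes_all_upregulated(self, default_matrix, default_de):
        markers = default_matrix.truth.index[default_matrix.truth["gene_class"] == "marker"]
        assert markers.isin(nv.significant_up(default_de, 0.05)).all()

    def test_swapping_labels_flips_fold_changes(self, default_matrix):
        de_fwd = nv.wald_test(default_matrix.counts, default_matrix.groups, reference="Control")
        de_rev = nv.wald_test(
            default_matrix.counts, default_matrix.groups, reference="PostVaccination"
        )
        np.testing.assert_allclose(
            de_fwd["log2FoldChange"], -de_rev["log2FoldChange"], rtol=1e-9, atol=1e-12
        )
        np.testing.assert_allclose(de_fwd["pvalue"], de_rev["pvalue"], rtol=1e-9, atol=1e-15)

    def test_sign_convention_follows_group_means(self, default_matrix, default_de):
        norm = nv.normalize_counts(default_matrix.counts)
        diff = (
            norm.loc[:, default_matrix.groups == "PostVaccination"].mean(axis=1)
            - norm.loc[:, default_matrix.groups == "Control"].mean(axis=1)
        )
        nonzero = diff.abs() > 1e-9
        assert (np.sign(default_de.loc[nonzero, "log2FoldChange"]) == np.sign(diff[nonzero])).all()

    def test_all_zero_group_rejected(self):
        counts = _frame([[0, 0, 5, 6], [0, 0, 7, 8]])
        with pytest.raises(ValueError, match="all-zero"):
            nv.wald_test(counts, _groups(2, 2, counts.columns))

    def test_type_i_error_on_nb_null_genes(self):
        """Empirical size at nominal 0.05 stays within [0.03, 0.08] for
        2000 NB null genes (mu=100, dispersion 0.02, n=5 per group)."""
        rng = np.random.default_rng(0)
        mu, alpha = 100.0, 0.02
        r, pr = 1 / alpha, (1 / alpha) / (1 / alpha + mu)
        counts = _frame(rng.negative_binomial(r, pr, size=(2000, 10)))
        de = nv.wald_test(counts, _groups(5, 5, counts.columns))
        size = (de["pvalue"] < 0.05).mean()
        assert 0.03 <= size <= 0.08

    def test_matches_score_test_in_poisson_regime(self):
        """On Poisson data the Wald p-values rank-agree with a two-sample
        score (normal-approximation) test computed independently."""
        from scipy import stats

        rng = np.random.default_rng(3)
        mu = rng.uniform(20, 200, size=200)
        counts = _frame(rng.poisson(mu[:, None], size=(200, 10)))
        groups = _groups(5, 5, counts.columns)
        de = nv.wald_test(counts, groups)
        x = counts.to_numpy(float)
        m1, m2 = x[:, :5].mean(axis=1), x[:, 5:].mean(axis=1)
        pooled = x.mean(axis=1)
        z = (m2 - m1) / np.sqrt(pooled * (1 / 5 + 1 / 5))
        p_score = 2 * stats.norm.sf(np.abs(z))
        rho = stats.spearmanr(de["pvalue"], p_score).statistic
        assert rho > 0.95
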