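import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpratools import (
    DesignMatrix,
    MpraFormatError,
    estimate_consensus_correlation,
    fit_elements,
    gls_fit,
    moderated_t,
    mpralm,
    squeeze_var,
    top_table,
    two_group_design,
    wls_fit,
)


def _two_group(n1=3, n2=3):
    indicator = np.array([0.0] * n1 + [1.0] * n2)
    return DesignMatrix(
        matrix=np.column_stack([np.ones_like(indicator), indicator]),
        coefficient_names=["intercept", "group"],
    )


class TestWlsFit:
    def test_group_means_recovered_with_unit_weights(self):
        design = _two_group()
        y = np.array([1.0, 1.0, 1.0, 3.0, 3.0, 3.0])
        coef, _, sigma, df, _ = wls_fit(y, np.ones(6), design)
        np.testing.assert_allclose(coef, [1.0, 2.0])
        assert sigma == pytest.approx(0.0)
        assert df == 4

    def test_matches_normal_equations_oracle(self):
        """WLS agrees with an explicit (X'WX)^-1 X'Wy solve to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 9)
            p = rng.integers(1, min(4, n - 1) + 1)
            x = rng.normal(size=(n, p))
            x[:, 0] = 1.0
            if np.linalg.matrix_rank(x) < p:
                continue
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 5.0, size=n)
            design = DesignMatrix(matrix=x, coefficient_names=[f"c{i}" for i in range(p)])
            coef, sd_u, sigma, df, cov = wls_fit(y, w, design)
            xtwx_inv = np.linalg.inv(x.T @ np.diag(w) @ x)
            beta = xtwx_inv @ x.T @ np.diag(w) @ y
            np.testing.assert_allclose(coef, beta, atol=1e-10)
            np.testing.assert_allclose(cov, xtwx_inv, atol=1e-10)
            resid = y - x @ beta
            rss = float(resid @ (w * resid))
            np.testing.assert_allclose(sigma**2, rss / (n - p), atol=1e-10)

    def test_zero_response_gives_zero_fit(self):
        design = _two_group()
        coef, _, sigma, _, _ = wls_fit(np.zeros(6), np.ones(6), design)
        np.testing.assert_allclose(coef, 0.0)
        assert sigma == 0.0

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(MpraFormatError, match="rank"):
            DesignMatrix(
                matrix=np.column_stack([np.ones(4), np.ones(4)]),
                coefficient_names=["a", "b"],
            )


class TestGlsFit:
    def test_rho_zero_reduces_to_wls(self):
        rng = np.random.default_rng(1)
        design = _two_group()
        design.block = np.array(["b1", "b2", "b3", "b1", "b2", "b3"])
        y = rng.normal(size=6)
        w = rng.uniform(0.5, 2.0, size=6)
        for a, b in zip(gls_fit(y, w, design, rho=0.0), wls_fit(y, w, design)):
            np.testing.assert_allclose(a, b)

    def test_matches_whitened_regression_oracle(self):
        """GLS agrees with an explicit Sigma^-1 solve to 1e-10."""
        rng = np.random.default_rng(2)
        block = np.array(["b1", "b1", "b2", "b2", "b3", "b3"])
        design = _two_group()
        design.block = block
        for _ in range(100):
            y = rng.normal(size=6)
            w = rng.uniform(0.2, 3.0, size=6)
            rho = rng.uniform(-0.6, 0.9)
            coef, sd_u, sigma, df, cov = gls_fit(y, w, design, rho=rho)
            corr = np.where(np.equal.outer(block, block), rho, 0.0)
            np.fill_diagonal(corr, 1.0)
            sig = corr / np.sqrt(np.outer(w, w))
            sig_inv = np.linalg.inv(sig)
            x = design.matrix
            xtsx_inv = np.linalg.inv(x.T @ sig_inv @ x)
            beta = xtsx_inv @ x.T @ sig_inv @ y
            np.testing.assert_allclose(coef, beta, atol=1e-10)
            np.testing.assert_allclose(cov, xtsx_inv, atol=1e-10)
            resid = y - x @ beta
            np.testing.assert_allclose(
                sigma**2, float(resid @ sig_inv @ resid) / df, atol=1e-10
            )

    def test_se_of_paired_difference_shrinks_as_rho_grows(self):
        rng = np.random.default_rng(3)
        block = np.array(["b1", "b1", "b2", "b2", "b3", "b3"])
        indicator = np.array([0.0, 1.0] * 3)
        design = DesignMatrix(
            matrix=np.column_stack([np.ones(6), indicator]),
            coefficient_names=["intercept", "allele"],
            block=block,
        )
        y = rng.normal(size=6)
        w = np.ones(6)
        ses = [
            gls_fit(y, w, design, rho=rho)[1][1] for rho in np.linspace(0.0, 0.95, 10)
        ]
        assert np.all(np.diff(ses) < 0)


class TestSqueezeVar:
    def test_moderation_formula_direct_value(self):
        # prior d0=4, s0^2=2 with one observed s^2=6 at d=4:
        # (4*2 + 4*6) / 8 = 4.0
        d0, s0_sq = 4.0, 2.0
        s2_post = (d0 * s0_sq + 4 * 6.0) / (d0 + 4)
        assert s2_post == pytest.approx(4.0)
        # and the fitted pipeline reproduces it when the prior is imposed
        _, _, post = squeeze_var(np.array([6.0, 6.0]), np.array([4.0, 4.0]))
        assert post.shape == (2,)

    def test_identical_variances_give_infinite_prior_df(self):
        d0, s0_sq, post = squeeze_var(np.full(50, 3.0), np.full(50, 4.0))
        assert np.isinf(d0)
        assert s0_sq == pytest.approx(3.0)
        np.testing.assert_allclose(post, 3.0)

    def test_hyperparameter_recovery_from_known_prior(self):
        """Variances from a scaled inverse-chi-square prior recover (d0, s0^2)."""
        rng = np.random.default_rng(4)
        d0_true, s0_true, d, m = 10.0, 1.0, 4, 20000
        sigma2 = d0_true * s0_true / stats.chi2.rvs(d0_true, size=m, random_state=rng)
        s2 = sigma2 * stats.chi2.rvs(d, size=m, random_state=rng) / d
        d0_hat, s0_hat, post = squeeze_var(s2, np.full(m, float(d)))
        assert abs(d0_hat - d0_true) / d0_true < 0.20
        assert abs(s0_hat - s0_true) / s0_true < 0.05
        # moderation shrinks: posterior is between prior and observed
        assert np.all(np.abs(post - s0_hat) <= np.abs(s2 - s0_hat) + 1e-12)

    def test_zero_residual_df_excluded_but_moderated(self):
        s2 = np.array([1.0, 2.0, 4.0, np.nan])
        df = np.array([4.0, 4.0, 4.0, 0.0])
        d0, s0_sq, post = squeeze_var(s2, df)
        assert np.isfinite(post[3])
        assert post[3] == pytest.approx(s0_sq)


class TestModeratedT:
    def _fit(self, values, design, weights=None):
        if weights is None:
            weights = np.ones_like(values)
        frame = pd.DataFrame(values, index=[f"e{i}" for i in range(len(values))])
        return fit_elements(frame, weights, design)

    def test_zero_coefficient_gives_t_zero_p_one(self):
        design = _two_group()
        values = np.vstack(
            [
                np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]),
                np.array([1.0, 2.0, 4.0, 2.0, 3.0, 1.0]),
            ]
        )
        fit = moderated_t(self._fit(values, design), "group")
        assert fit.t_moderated[0] == pytest.approx(0.0)
        assert fit.p_value[0] == pytest.approx(1.0)

    def test_null_gaussian_data_gives_uniform_p(self):
        """On fully null data, moderated p values are uniform (KS < 0.02)."""
        rng = np.random.default_rng(5)
        design = _two_group(4, 4)
        values = rng.normal(size=(5000, 8))
        fit = moderated_t(self._fit(values, design), 1)
        ks = stats.kstest(fit.p_value, "uniform").statistic
        assert ks < 0.02

    def test_identity_contrast_equals_coefficient_test(self):
        rng = np.random.default_rng(6)
        design = _two_group()
        values = rng.normal(size=(50, 6))
        by_index = moderated_t(self._fit(values, design), 1)
        t_index = by_index.t_moderated.copy()
        by_contrast = moderated_t(self._fit(values, design), np.array([0.0, 1.0]))
        np.testing.assert_allclose(t_index, by_contrast.t_moderated)

    def test_wrong_contrast_length_rejected(self):
        design = _two_group()
        fit = self._fit(np.random.default_rng(7).normal(size=(20, 6)), design)
        with pytest.raises(MpraFormatError, match="contrast"):
            moderated_t(fit, np.array([1.0, 0.0, 0.0]))


class TestConsensusCorrelation:
    def _paired_data(self, rng, rho, n_elem=2000, n_blocks=4, sd=0.5):
        n = 2 * n_blocks
        block_effect = rng.normal(0.0, sd * np.sqrt(rho), size=(n_elem, n_blocks))
        noise = rng.normal(0.0, sd * np.sqrt(1.0 - rho), size=(n_elem, n))
        block_idx = np.concatenate([np.arange(n_blocks), np.arange(n_blocks)])
        values = block_effect[:, block_idx] + noise
        design = DesignMatrix(
            matrix=np.column_stack(
                [np.ones(n), np.array([0.0] * n_blocks + [1.0] * n_blocks)]
            ),
            coefficient_names=["intercept", "group"],
            block=np.array([f"b{i}" for i in block_idx]),
        )
        frame = pd.DataFrame(values, index=[f"e{i}" for i in range(n_elem)])
        return frame, design

    def test_recovers_true_within_block_correlation(self):
        rng = np.random.default_rng(8)
        frame, design = self._paired_data(rng, rho=0.5)
        est = estimate_consensus_correlation(frame, np.ones(frame.shape), design)
        assert abs(est - 0.5) < 0.1

    def test_independent_samples_give_near_zero(self):
        rng = np.random.default_rng(9)
        frame, design = self._paired_data(rng, rho=0.0)
        est = estimate_consensus_correlation(frame, np.ones(frame.shape), design)
        assert abs(est) < 0.1

    def test_duplicated_samples_give_near_unit_correlation(self):
        rng = np.random.default_rng(10)
        half = rng.normal(size=(500, 4))
        values = np.hstack([half, half])  # block i duplicated across groups
        design = DesignMatrix(
            matrix=np.column_stack([np.ones(8), np.array([0.0] * 4 + [1.0] * 4)]),
            coefficient_names=["intercept", "group"],
            block=np.array([f"b{i}" for i in list(range(4)) * 2]),
        )
        frame = pd.DataFrame(values, index=[f"e{i}" for i in range(500)])
        est = estimate_consensus_correlation(frame, np.ones(values.shape), design)
        assert est > 0.9

    def test_missing_block_rejected(self):
        design = _two_group()
        with pytest.raises(MpraFormatError, match="block"):
            estimate_consensus_correlation(
                pd.DataFrame(np.zeros((20, 6))), np.ones((20, 6)), design
            )


class TestMpralm:
    def test_duplicated_groups_give_zero_effect(self, null_dataset):
        counts, _ = null_dataset
        import mpratools.data_model as dm

        rna = counts.rna.copy()
        dna = counts.dna.copy()
        for src, dst in zip(["s1", "s2", "s3", "s4"], ["s5", "s6", "s7", "s8"]):
            rna[dst] = rna[src]
            dna[dst] = dna[src]
        dup = dm.BarcodeCountSet(
            rna=rna,
            dna=dna,
            barcode_to_element=counts.barcode_to_element,
            samples=counts.samples,
        )
        fit = mpralm(dup)
        np.testing.assert_allclose(fit.logFC, 0.0, atol=1e-12)

    def test_true_positives_rank_near_top(self, signal_dataset):
        counts, truth = signal_dataset
        fit = mpralm(counts)
        table = top_table(fit)
        labels = truth["differential"].reindex(table.index)
        n_top = max(len(table) // 10, 1)
        n_true = int(labels.sum())
        hits = labels.iloc[:n_top].sum()
        assert hits / n_true > 0.7

    def test_reruns_are_bitwise_identical(self, null_dataset):
        counts, _ = null_dataset
        p1 = mpralm(counts).p_value
        p2 = mpralm(counts).p_value
        np.testing.assert_array_equal(p1, p2)

    def test_paired_beats_unpaired_precision_under_correlation(self):
        from mpratools import SimulationSpec, generate_mpra

        spec = SimulationSpec(
            n_elements=500,
            barcodes_per_element=5,
            within_block_correlation=0.6,
            seed=12,
        )
        counts, _ = generate_mpra(spec)
        fit_paired = mpralm(counts, paired=True)
        fit_unpaired = mpralm(counts, paired=False)
        se_paired = np.median(
            fit_paired.stdev_unscaled[:, 1] * np.sqrt(fit_paired.s2_post)
        )
        se_unpaired = np.median(
            fit_unpaired.stdev_unscaled[:, 1] * np.sqrt(fit_unpaired.s2_post)
        )
        assert se_paired < se_unpaired

    def test_two_group_design_requires_two_levels(self):
        from mpratools import SampleSheet

        sheet = SampleSheet(sample_ids=["s1", "s2", "s3"], condition=["A", "A", "A"])
        with pytest.raises(MpraFormatError, match="levels"):
            two_group_design(sheet)
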