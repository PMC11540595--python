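"""Thresholded-Gaussian cortex model: shrink/threshold calibration, gamma
fitting, sampling laws, connectivity construction, low-rank approximations,
alignment metrics and the alpha fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from olfbilat import (
    CortexResponses,
    ModelConfig,
    build_hebbian_matrix,
    build_random_matrix,
    calibrate_threshold,
    compute_alignment_metrics,
    fit_alpha,
    fit_gamma,
    generate_contralateral,
    lowrank_struct_pca,
    lowrank_struct_svd,
    rescale_and_mix,
    sample_ipsilateral_cortex,
    shrink,
    simulate_bilateral_cortices,
)


class TestShrink:
    @pytest.mark.parametrize("h, phi, expected",
                             [(2.0, 0.5, 1.5), (-0.3, 0.5, 0.0), (-2.0, 0.5, -1.5),
                              (0.5, 0.5, 0.0), (0.0, 0.0, 0.0)])
    def test_values(self, h, phi, expected):
        assert shrink(h, phi) == pytest.approx(expected)

    @given(h=st.floats(-100, 100), phi=st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_odd_symmetry(self, h, phi):
        assert shrink(-h, phi) == pytest.approx(-shrink(h, phi))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrink(1.0, -0.1)


class TestThresholdCalibration:
    def test_median_threshold(self):
        # S = 0.5 puts the threshold at the standard-normal upper quartile
        assert calibrate_threshold(0.5) == pytest.approx(0.67449, abs=1e-4)

    @pytest.mark.parametrize("S", [0.05, 0.224, 0.5, 0.9])
    def test_round_trip(self, S):
        ratio = calibrate_threshold(S)
        assert erfc(ratio / np.sqrt(2)) == pytest.approx(S, abs=1e-9)

    def test_dense_limit(self):
        assert calibrate_threshold(0.999999) < 1e-2

    @pytest.mark.parametrize("S", [0.0, 1.0, -0.1, 1.5])
    def test_domain(self, S):
        with pytest.raises(ValueError):
            calibrate_threshold(S)


class TestFitGamma:
    def test_half_normal_closed_form(self):
        # ratio 0: the MLE is the half-normal scale, gamma^2 = mean(m^2)
        rng = np.random.default_rng(0)
        m = np.abs(rng.normal(0, 2.0, size=5000))
        gamma = fit_gamma(m, 0.0)
        assert gamma == pytest.approx(np.sqrt(np.mean(m**2)), rel=1e-6)

    def test_parameter_recovery(self):
        # simulate from the model's own law at gamma = 1
        rng = np.random.default_rng(1)
        ratio = calibrate_threshold(0.224)
        z = rng.normal(size=200_000)
        m = (np.abs(z) - ratio)[np.abs(z) > ratio]
        gamma = fit_gamma(m[:10_000], ratio)
        assert 0.95 <= gamma <= 1.05

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        m = np.abs(rng.normal(0, 1, size=2000)) + 0.1
        g1 = fit_gamma(m, 0.7)
        g2 = fit_gamma(3.0 * m, 0.7)
        assert g2 == pytest.approx(3.0 * g1, rel=1e-5)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_gamma(np.array([1.0, 0.0]), 0.5)


class TestIpsilateralSampling:
    def test_sparseness_law_on_grid(self, panel):
        """Realized active fraction matches erfc(phi/(gamma sqrt 2)) on a
        (phi, gamma) grid, within 3 binomial SE."""
        rng_seed = 3
        n = 20_000
        for gamma in (0.5, 1.0, 2.0):
            for ratio in (0.5, 1.2, 2.5):
                S = float(erfc(ratio / np.sqrt(2)))
                cfg = ModelConfig(n_neurons=n, gamma=gamma, sparseness_ipsi=S,
                                  seed=rng_seed)
                resp = sample_ipsilateral_cortex(panel, cfg)
                n_pairs = n * panel.n_odors
                se = np.sqrt(S * (1 - S) / n_pairs)
                assert abs(resp.sparseness - S) < 3 * se + 1e-4

    def test_identity_similarity_gives_uncorrelated_inputs(self):
        from olfbilat.synthdata import GlomerularPanel

        eye_panel = GlomerularPanel(np.eye(15))
        cfg = ModelConfig(n_neurons=50_000, seed=4)
        resp = sample_ipsilateral_cortex(eye_panel, cfg)
        corr = np.corrcoef(resp.h.T)
        off = corr[~np.eye(15, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_covariance_fidelity_improves_with_n(self, panel):
        """Frobenius error of the sample covariance halves when the neuron
        count quadruples (1/sqrt(n) convergence)."""
        target = panel.cos_theta
        errs = []
        for n in (2000, 8000, 32_000):
            cfg = ModelConfig(n_neurons=n, gamma=1.0, seed=5)
            resp = sample_ipsilateral_cortex(panel, cfg)
            sample_cov = resp.h.T @ resp.h / n
            errs.append(np.linalg.norm(sample_cov - target))
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.5)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.5)

    def test_huge_threshold_silences(self, panel):
        cfg = ModelConfig(n_neurons=100, gamma=1.0, sparseness_ipsi=1e-12, seed=6)
        resp = sample_ipsilateral_cortex(panel, cfg)
        assert np.all(resp.y == 0)


class TestConnectivityComponents:
    def test_random_matrix_density_and_variance(self):
        g = build_random_matrix(400, 0.1, seed=7)
        nnz = np.mean(g != 0)
        se = np.sqrt(0.1 * 0.9 / g.size)
        assert abs(nnz - 0.1) < 3 * se
        assert np.var(g[g != 0]) == pytest.approx(1.0, rel=0.05)
        dense = build_random_matrix(300, 1.0, seed=8)
        assert np.all(dense != 0)
        assert np.array_equal(dense, build_random_matrix(300, 1.0, seed=8))

    def test_hebbian_hand_oracle(self):
        # 3 neurons, 2 odors, hand-listed responses
        yi = np.array([[1.0, 3.0], [0.0, 2.0], [-1.0, 1.0]])
        yo = np.array([[2.0, 0.0], [1.0, -1.0], [0.0, 4.0]])
        ipsi = CortexResponses(h=yi, y=yi, phi=0.0)
        opp = CortexResponses(h=yo, y=yo, phi=0.0)
        # centered: ai = yi - rowmean, ao = yo - rowmean; G = ai @ ao.T
        ai = yi - yi.mean(axis=1, keepdims=True)
        ao = yo - yo.mean(axis=1, keepdims=True)
        expected = (np.outer(ai[:, 0], ao[:, 0]) + np.outer(ai[:, 1], ao[:, 1]))
        assert np.allclose(build_hebbian_matrix(ipsi, opp), expected)

    def test_single_odor_vanishes(self):
        y = np.array([[2.0], [1.0]])
        c = CortexResponses(h=y, y=y, phi=0.0)
        assert np.allclose(build_hebbian_matrix(c, c), 0.0)

    def test_rank_at_most_p_minus_one(self, panel, small_model_config):
        rng = np.random.default_rng(9)
        a = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        b = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        G = build_hebbian_matrix(a, b)
        assert np.linalg.matrix_rank(G, tol=1e-8 * np.abs(G).max()) <= 14

    def test_chi_equalizes_output_norms(self, panel, small_model_config):
        rng = np.random.default_rng(10)
        a = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        b = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        G_s = build_hebbian_matrix(a, b)
        G_r = build_random_matrix(small_model_config.n_neurons, 0.5, rng=rng)
        conn = rescale_and_mix(G_s, G_r, b, alpha=0.5)
        num = np.linalg.norm(conn.G_rand @ b.y, axis=0).sum()
        den = np.linalg.norm(conn.G_struct @ b.y, axis=0).sum()
        assert num / den == pytest.approx(1.0, rel=1e-6)

    def test_alpha_zero_is_pure_random(self, panel, small_model_config):
        rng = np.random.default_rng(11)
        a = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        b = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        G_s = build_hebbian_matrix(a, b)
        G_r = build_random_matrix(small_model_config.n_neurons, 0.5, rng=rng)
        conn = rescale_and_mix(G_s, G_r, b, alpha=0.0)
        assert np.array_equal(conn.G, G_r)
        conn1 = rescale_and_mix(G_s, G_r, b, alpha=1.0)
        assert np.allclose(conn1.G, conn1.chi * G_s)

    def test_balanced_mix_contributions(self, panel, small_model_config):
        rng = np.random.default_rng(12)
        a = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        b = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        conn = rescale_and_mix(build_hebbian_matrix(a, b),
                               build_random_matrix(small_model_config.n_neurons,
                                                   0.5, rng=rng), b, alpha=0.5)
        s_part = np.linalg.norm(0.5 * conn.G_struct @ b.y, axis=0).sum()
        r_part = np.linalg.norm(0.5 * conn.G_rand @ b.y, axis=0).sum()
        assert 0.5 < s_part / r_part < 2.0


class TestContralateral:
    def test_target_sparseness_reached(self, panel, small_model_config):
        ipsi, contra = simulate_bilateral_cortices(panel, small_model_config,
                                                   alpha=0.42, seed=13)
        assert abs(contra.sparseness - 0.252) <= 0.005

    def test_scale_monotone_in_target(self, panel, small_model_config):
        rng = np.random.default_rng(14)
        b = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        G = build_random_matrix(small_model_config.n_neurons, 0.5, rng=rng)
        scales = [generate_contralateral(b, G, small_model_config.phi, t).scale
                  for t in (0.1, 0.25, 0.5)]
        assert scales[0] < scales[1] < scales[2]

    def test_unreachable_target_reports_range(self, small_model_config, panel):
        rng = np.random.default_rng(15)
        b = sample_ipsilateral_cortex(panel, small_model_config, rng=rng)
        zero_G = np.zeros((b.n_neurons, b.n_neurons))
        with pytest.raises(ValueError, match="unreachable"):
            generate_contralateral(b, zero_G, small_model_config.phi, 0.25)

    def test_hebbian_same_realization_strong_correlation(self, panel):
        """alpha=1 with the Hebbian matrix built from the mapped realization
        itself reproduces that realization's structure (pooled r > 0.5)."""
        cfg = ModelConfig(n_neurons=1500, sparseness_ipsi=0.4,
                          sparseness_contra=0.4, seed=16)
        rng = np.random.default_rng(16)
        b = sample_ipsilateral_cortex(panel, cfg, rng=rng)
        G_s = build_hebbian_matrix(b, b)
        contra = generate_contralateral(b, G_s, cfg.phi, 0.4)
        r = np.corrcoef(b.y.ravel(), contra.y.ravel())[0, 1]
        assert r > 0.5


class TestZeroCorrelationTheorem:
    def test_random_connectivity_produces_zero_correlation(self, panel):
        """Purely random cross-cortical projections give pooled r ~ 0 even
        though both cortices share the glomerular correlation structure."""
        cfg = ModelConfig(n_neurons=1200, seed=17)
        for s in range(20):
            ipsi, contra = simulate_bilateral_cortices(panel, cfg, alpha=0.0,
                                                       seed=1000 + s)
            n_pairs = cfg.n_neurons * cfg.n_odors
            r = np.corrcoef(ipsi.y.ravel(), contra.y.ravel())[0, 1]
            assert abs(r) < 3.0 / np.sqrt(n_pairs)


class TestLowRank:
    @pytest.fixture(scope="class")
    def hebbian_pair(self, panel):
        cfg = ModelConfig(n_neurons=800, seed=18)
        rng = np.random.default_rng(18)
        a = sample_ipsilateral_cortex(panel, cfg, rng=rng)
        b = sample_ipsilateral_cortex(panel, cfg, rng=rng)
        return a, b, build_hebbian_matrix(a, b)

    def test_full_rank_svd_reconstructs(self, hebbian_pair):
        _, _, G = hebbian_pair
        approx = lowrank_struct_svd(G, 14)
        assert np.linalg.norm(approx - G) < 1e-8 * np.linalg.norm(G)

    def test_frobenius_error_nonincreasing(self, hebbian_pair):
        _, _, G = hebbian_pair
        factors = np.linalg.svd(G, full_matrices=False)
        errs = [np.linalg.norm(lowrank_struct_svd(G, q, factors=factors) - G)
                for q in range(1, 15)]
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_q_out_of_range(self, hebbian_pair):
        _, _, G = hebbian_pair
        with pytest.raises(ValueError):
            lowrank_struct_svd(G, 0)

    def test_pca_full_q_spans_hebbian(self, hebbian_pair):
        a, b, G = hebbian_pair
        approx = lowrank_struct_pca(a, b, 15)
        assert np.linalg.norm(approx - G) < 1e-6 * np.linalg.norm(G)

    def test_pca_variance_explained_nondecreasing(self, hebbian_pair):
        a, b, _ = hebbian_pair
        vexp = [lowrank_struct_pca(a, b, q, return_info=True)[1]["variance_explained"]
                for q in range(1, 16)]
        assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(vexp, vexp[1:]))
        assert vexp[-1] == pytest.approx(1.0)

    def test_alignment_saturates_by_q_seven(self, panel):
        """Rank-7 approximations capture most of the cross-side alignment.

        Qualitative sweep: the odor-matching gain from Q=7 to full rank is
        smaller than the gain from Q=1 to Q=7, and Q=7 already reaches at
        least 70% of the full-Hebbian accuracy, for both the SVD and the
        PCA-subspace construction.
        """
        def acc_at(scheme, Q):
            cfg_q = ModelConfig(n_neurons=1500, seed=19, Q=Q)
            ipsi, contra = simulate_bilateral_cortices(panel, cfg_q, alpha=1.0,
                                                       seed=19, lowrank=scheme)
            return compute_alignment_metrics(ipsi, contra, n_sample=385,
                                             n_reps=20, seed=20).odor_match_accuracy

        for scheme in ("svd", "pca"):
            a1, a7, a14 = (acc_at(scheme, q) for q in (1, 7, 14))
            assert a14 - a7 < a7 - a1
            assert a7 >= 0.7 * a14


class TestAlignmentAndAlphaFit:
    def test_identical_cortices_saturate_metrics(self, panel):
        cfg = ModelConfig(n_neurons=600, seed=21)
        resp = sample_ipsilateral_cortex(panel, cfg)
        m = compute_alignment_metrics(resp, resp, n_sample=385, n_reps=10, seed=22)
        assert m.pooled_r == pytest.approx(1.0)
        assert m.odor_match_accuracy == pytest.approx(1.0)
        # silent neurons (no active odor at ~22% sparseness) have degenerate
        # regressions and count as non-BCN even for identical cortices
        assert m.bcn_fraction > 0.9

    def test_metrics_monotone_in_alpha(self, panel, small_model_config):
        rs, bcns, odors = [], [], []
        for a in (0.0, 0.25, 0.5, 0.75, 1.0):
            ipsi, contra = simulate_bilateral_cortices(panel, small_model_config,
                                                       alpha=a, seed=23)
            m = compute_alignment_metrics(ipsi, contra, n_sample=385, n_reps=30,
                                          seed=24)
            rs.append(m.pooled_r)
            bcns.append(m.bcn_fraction)
            odors.append(m.odor_match_accuracy)
        for series in (rs, bcns, odors):
            assert all(b >= a - 0.03 for a, b in zip(series, series[1:]))
            assert series[-1] > series[0]

    def test_hebbian_sufficiency_at_alpha_one(self, panel, small_model_config):
        ipsi, contra = simulate_bilateral_cortices(panel, small_model_config,
                                                   alpha=1.0, seed=25)
        m = compute_alignment_metrics(ipsi, contra, n_sample=385, n_reps=20, seed=26)
        assert m.odor_match_accuracy >= 0.9

    def test_alpha_recovery(self, panel):
        """Mean |fitted - true| <= 0.1 over alpha_true in {0.2, 0.42, 0.8}."""
        cfg = ModelConfig(n_neurons=2000, seed=27)
        grid = np.round(np.arange(0, 1.0001, 0.05), 3)
        errs = []
        for k, true_a in enumerate((0.2, 0.42, 0.8)):
            ipsi, contra = simulate_bilateral_cortices(panel, cfg, alpha=true_a,
                                                       seed=300 + k)
            data = compute_alignment_metrics(ipsi, contra, n_sample=385,
                                             n_reps=30, seed=301 + k)
            fit = fit_alpha(data.as_array(), panel, cfg, alpha_grid=grid,
                            seed=400 + k, n_reps=30)
            errs.append(abs(fit.alpha_star - true_a))
        assert np.mean(errs) <= 0.1

    def test_alpha_fit_stable_under_halved_population(self, panel):
        """The fitted alpha does not depend on the modeled cortex size."""
        grid = np.round(np.arange(0, 1.0001, 0.1), 3)
        fits = []
        for n in (2000, 1000):
            cfg = ModelConfig(n_neurons=n, seed=28)
            ipsi, contra = simulate_bilateral_cortices(panel, cfg, alpha=0.42,
                                                       seed=500)
            data = compute_alignment_metrics(ipsi, contra, n_sample=385,
                                             n_reps=30, seed=501)
            fit = fit_alpha(data.as_array(), panel, cfg, alpha_grid=grid,
                            seed=502, n_reps=30)
            fits.append(fit.alpha_star)
        assert abs(fits[0] - fits[1]) <= 0.1

    def test_sample_larger_than_population_rejected(self, panel):
        cfg = ModelConfig(n_neurons=100, seed=29)
        resp = sample_ipsilateral_cortex(panel, cfg)
        with pytest.raises(ValueError):
            compute_alignment_metrics(resp, resp, n_sample=385, n_reps=2, seed=30)
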