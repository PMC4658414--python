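import numpy as np
import pytest

from motordcm.generative import ROITimeSeries, simulate_bold
from motordcm.inversion import (
    FitDiagnostics,
    PriorDensity,
    dct_basis,
    default_priors,
    invert,
    log_joint,
    qc_filter,
    variance_explained,
)
from motordcm.network import motor_network_preset
from motordcm.paradigm import BlockSchedule, inputs_at_microtime

from conftest import two_region_params, two_region_spec


def small_design(dt=0.25, total=120.0):
    sched = BlockSchedule(
        blocks=(("simple-slow", 6.0, 20.0), ("rest-slow", 30.0, 20.0),
                ("simple-fast", 54.0, 20.0), ("complex-slow", 78.0, 20.0)),
        lead_in=6.0, instruction_gap=4.0,
    )
    return inputs_at_microtime(sched, dt=dt, total_scan=total)


class TestDctBasis:
    def test_orthonormal(self):
        X = dct_basis(221, 3.0, 152.0)
        assert np.allclose(X.T @ X, np.eye(X.shape[1]), atol=1e-10)

    def test_column_count_at_default_cutoff(self):
        # floor(2 * 221 * 3 / 152) + 1 = 9 drift regressors incl. constant
        assert dct_basis(221, 3.0, 152.0).shape == (221, 9)

    def test_constant_column_first(self):
        X = dct_basis(50, 2.0)
        assert np.allclose(X[:, 0], X[0, 0])


class TestVarianceExplained:
    def test_perfect_prediction(self):
        y = ROITimeSeries(np.random.default_rng(0).normal(size=(30, 2)), 3.0, ("a", "b"))
        assert variance_explained(y, y) == 1.0

    def test_column_means_give_zero(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(40, 3))
        obs = ROITimeSeries(data, 3.0, ("a", "b", "c"))
        pred = ROITimeSeries(np.tile(data.mean(axis=0), (40, 1)), 3.0, ("a", "b", "c"))
        assert variance_explained(obs, pred) == pytest.approx(0.0, abs=1e-12)

    def test_known_snr(self):
        """signal + noise at known SNR: VE -> s2/(s2+n2) in expectation."""
        rng = np.random.default_rng(2)
        n, snr = 20_000, 2.0
        signal = rng.normal(size=(n, 1))
        noise = rng.normal(scale=1 / snr, size=(n, 1))
        obs = ROITimeSeries(signal + noise, 1.0, ("a",))
        pred = ROITimeSeries(signal, 1.0, ("a",))
        expected = (1 / snr**2) / (1 + 1 / snr**2)  # residual fraction
        assert variance_explained(obs, pred) == pytest.approx(1 - expected, abs=0.02)

    def test_zero_variance_raises(self):
        flat = ROITimeSeries(np.ones((10, 1)), 3.0, ("a",))
        with pytest.raises(ValueError, match="zero variance"):
            variance_explained(flat, flat)


class TestQcFilter:
    def test_all_pass(self):
        fits = [FitDiagnostics(0.5, True) for _ in range(4)]
        kept, excluded = qc_filter(fits)
        assert kept == [0, 1, 2, 3] and excluded == []

    def test_threshold_boundary(self):
        fits = [FitDiagnostics(0.05, False), FitDiagnostics(0.15, True)]
        kept, excluded = qc_filter(fits, 0.10)
        assert kept == [1] and excluded == [0]

    def test_partition_exhaustive(self):
        rng = np.random.default_rng(3)
        fits = [FitDiagnostics(float(v), v >= 0.1) for v in rng.random(25)]
        kept, excluded = qc_filter(fits, 0.1)
        assert sorted(kept + excluded) == list(range(25))

    def test_unconverged_excluded(self):
        fits = [FitDiagnostics(0.9, False, converged=False)]
        assert qc_filter(fits) == ([], [0])

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            qc_filter([], threshold=1.01)


class TestDefaultPriors:
    def test_free_parameter_count_full_preset(self, full_net):
        priors = default_priors(full_net)
        # 30 intrinsic + 7 self + 17 modulatory + 2 driving + 7 transit
        assert priors.packing.n_params == 63

    def test_masked_out_entry_has_zero_variance(self, full_net):
        priors = default_priors(full_net)
        assert priors.variance("A:pSMA<-lM1") == 0.0
        assert priors.variance("B:speed:lPMd<-lSPC") == 0.0

    def test_self_connection_prior_mean(self, full_net):
        """Prior mean 0 on the log scale corresponds to -0.5 Hz."""
        priors = default_priors(full_net)
        pack = priors.packing
        A, _, _, _ = pack.unpack_batch(priors.mean, __import__("motordcm").HemoParams())
        assert np.allclose(np.diag(A[0]), -0.5)

    def test_packing_is_bijection_onto_masks(self, full_net):
        pack = default_priors(full_net).packing
        labels = pack.labels
        assert len(set(labels)) == len(labels)
        a_count = sum(1 for e in pack.entries if e[0] == "A")
        b_count = sum(1 for e in pack.entries if e[0] == "B")
        assert (a_count, b_count) == (30, 17)

    def test_pack_unpack_round_trip(self, toy_spec):
        priors = default_priors(toy_spec)
        p = two_region_params(a_yx=0.27, c=0.11)
        theta = priors.packing.pack_params(p)
        A, B, C, tau = priors.packing.unpack_batch(theta, p.hemo)
        assert np.allclose(A[0], p.A)
        assert np.allclose(C[0], p.C)
        assert np.allclose(tau[0], 2.0)


class TestInvert:
    def test_self_consistency_near_noiseless(self, toy_spec):
        """Data from known parameters, no noise: VE ~ 1 and truth inside
        the 95% posterior intervals."""
        design = small_design()
        truth = two_region_params(a_yx=0.3, c=0.15)
        ts, _ = simulate_bold(truth, design, n_volumes=40,
                              labels=toy_spec.regions, return_states=False)
        priors = default_priors(toy_spec)
        post, diag = invert(ts, design, toy_spec, priors, max_iter=64)
        assert diag.variance_explained >= 0.99
        theta_true = priors.packing.pack_params(truth)
        sd = np.sqrt(np.diag(post.cov))
        assert np.all(np.abs(post.mean - theta_true) <= 1.96 * sd + 1e-3)

    def test_free_energy_monotone(self, toy_spec):
        design = small_design()
        truth = two_region_params(a_yx=0.3, c=0.15, noise_sd=0.002)
        ts, _ = simulate_bold(truth, design, n_volumes=40, seed=4,
                              labels=toy_spec.regions, return_states=False)
        post, _ = invert(ts, design, toy_spec, max_iter=64)
        hist = post.f_history
        assert len(hist) > 1
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_deterministic_bitwise(self, toy_spec):
        design = small_design()
        truth = two_region_params(noise_sd=0.002)
        ts, _ = simulate_bold(truth, design, n_volumes=40, seed=4,
                              labels=toy_spec.regions, return_states=False)
        p1, d1 = invert(ts, design, toy_spec)
        p2, d2 = invert(ts, design, toy_spec)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.array_equal(p1.cov, p2.cov)
        assert p1.free_energy == p2.free_energy

    def test_constant_data_stays_at_prior_mean(self, toy_spec):
        design = small_design()
        rng = np.random.default_rng(0)
        data = np.zeros((40, 2)) + 1e-12 * rng.standard_normal((40, 2))
        ts = ROITimeSeries(data, 3.0, toy_spec.regions)
        priors = default_priors(toy_spec)
        post, diag = invert(ts, design, toy_spec, priors, max_iter=16)
        assert np.all(np.abs(post.mean - priors.mean) < 1e-2)

    def test_posterior_covariance_spd(self, toy_spec):
        design = small_design()
        truth = two_region_params(noise_sd=0.002)
        ts, _ = simulate_bold(truth, design, n_volumes=40, seed=9,
                              labels=toy_spec.regions, return_states=False)
        post, _ = invert(ts, design, toy_spec)
        np.linalg.cholesky(post.cov)  # raises if not SPD
        assert np.allclose(post.cov, post.cov.T)

    def test_label_mismatch_raises(self, toy_spec):
        design = small_design()
        ts = ROITimeSeries(np.random.default_rng(0).normal(size=(40, 2)), 3.0,
                           ("wrong", "names"))
        with pytest.raises(ValueError, match="labels"):
            invert(ts, design, toy_spec)

    def test_mode_matches_grid_search(self, toy_spec):
        """With one effectively free parameter, the posterior mode agrees
        with a dense grid search over the conditional objective."""
        design = small_design()
        truth = two_region_params(a_yx=0.35, c=0.15, noise_sd=0.001)
        ts, _ = simulate_bold(truth, design, n_volumes=40, seed=2,
                              labels=toy_spec.regions, return_states=False)
        base = default_priors(toy_spec)
        # pin everything except the X -> Y coupling
        k_free = base.packing.labels.index("A:Y<-X")
        cov = np.full(base.packing.n_params, 1e-10)
        cov[k_free] = 1 / 16
        mean = base.packing.pack_params(two_region_params(a_yx=0.0, c=0.15))
        priors = PriorDensity(mean=mean, cov=np.diag(cov), packing=base.packing)
        post, _ = invert(ts, design, toy_spec, priors, max_iter=64, tol=1e-4)
        grid = np.linspace(0.2, 0.5, 121)  # resolution 0.0025
        scores = []
        for val in grid:
            theta = post.mean.copy()
            theta[k_free] = val
            scores.append(log_joint(ts, design, priors, theta, post.noise_precision))
        best = grid[int(np.argmax(scores))]
        assert abs(post.mean[k_free] - best) <= (grid[1] - grid[0])
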