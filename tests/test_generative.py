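import numpy as np
import pytest
from scipy.integrate import solve_ivp

from motordcm.generative import (
    DCMParameters,
    HemoParams,
    is_stable,
    simulate_bold,
    steady_state,
)
from motordcm.inversion import default_priors
from motordcm.paradigm import BlockSchedule, build_paradigm, inputs_at_microtime

from conftest import two_region_params, two_region_spec


def one_region_params(a=-1.0, c=1.0):
    return DCMParameters(
        A=np.array([[a]]),
        B={"complexity": np.zeros((1, 1)), "speed": np.zeros((1, 1))},
        C=np.array([[c, 0.0, 0.0]]),
    )


class TestSteadyState:
    def test_one_region(self):
        z = steady_state(one_region_params(), np.array([1.0, 0.0, 0.0]))
        assert z == pytest.approx([1.0])

    def test_two_region_cascade(self):
        p = DCMParameters(
            A=np.array([[-1.0, 0.0], [0.5, -1.0]]),
            B={}, C=np.array([[1.0], [0.0]]),
        )
        z = steady_state(p, np.array([1.0]), input_names=["task"])
        assert z == pytest.approx([1.0, 0.5], abs=1e-12)

    def test_zero_input(self, toy_params):
        z = steady_state(toy_params, np.zeros(3))
        assert np.allclose(z, 0.0)

    def test_singular_coupling_raises(self):
        p = DCMParameters(A=np.array([[-1.0]]), B={"speed": np.array([[1.0]])},
                          C=np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="singular"):
            steady_state(p, np.array([0.0, 1.0]), input_names=["task", "speed"])


class TestStability:
    def test_negative_identity_stable(self):
        p = one_region_params(a=-1.0)
        assert is_stable(p, np.ones(3))

    def test_positive_self_unstable(self):
        p = DCMParameters(A=np.array([[-0.5]]), B={}, C=np.zeros((1, 1)))
        p2 = DCMParameters(A=np.array([[0.1]]), B={}, C=np.zeros((1, 1)))
        assert is_stable(p)
        assert not is_stable(p2)

    def test_prior_draws_mostly_stable(self, full_net):
        """Random draws from the shrinkage priors give stable systems."""
        priors = default_priors(full_net)
        pack = priors.packing
        rng = np.random.default_rng(123)
        sd = np.sqrt(np.diag(priors.cov))
        n_stable = 0
        for _ in range(1000):
            theta = priors.mean + sd * rng.standard_normal(pack.n_params)
            A, B, C, tau = pack.unpack_batch(theta, HemoParams())
            assert np.all(np.diag(A[0]) < 0)
            if np.all(np.linalg.eigvals(A[0]).real < 0):
                n_stable += 1
        assert n_stable >= 990


class TestSimulateBold:
    def test_zero_input_baseline(self, toy_params):
        sched = BlockSchedule(blocks=(("rest-slow", 0.0, 20.0),), lead_in=0.0)
        design = inputs_at_microtime(sched, dt=0.1875, total_scan=675.0)
        ts, traj = simulate_bold(toy_params, design, n_volumes=225)
        assert np.allclose(ts.data, ts.data[0], atol=1e-12)
        # baseline conserved exactly for >= 675 s: no drift in any state
        assert np.allclose(traj.z, 0.0) and np.allclose(traj.s, 0.0)
        assert np.allclose(traj.f, 1.0) and np.allclose(traj.v, 1.0)
        assert np.allclose(traj.q, 1.0)

    def test_zero_drive_matches_rest(self, default_design, toy_params):
        p0 = DCMParameters(A=toy_params.A, B=toy_params.B, C=np.zeros((2, 3)))
        ts, _ = simulate_bold(p0, default_design, n_volumes=221, return_states=False)
        assert np.allclose(ts.data, ts.data[0], atol=1e-12)

    def test_matches_independent_integrator(self, toy_params):
        """Sampled output agrees with scipy's adaptive integrator to 1e-4."""
        sched = BlockSchedule(blocks=(("simple-slow", 10.0, 20.0),), lead_in=0.0)
        design = inputs_at_microtime(sched, dt=0.1875, total_scan=60.0)
        ts, _ = simulate_bold(toy_params, design, n_volumes=20)

        h = toy_params.hemo
        A, C = toy_params.A, toy_params.C[:, 0]

        i0 = int(round(10.0 / design.dt))
        i1 = int(round(30.0 / design.dt))

        def u_of(t):
            # piecewise-constant per microtime bin, as the kernel holds it
            return 1.0 if i0 <= int(np.floor(t / design.dt + 1e-12)) < i1 else 0.0

        def rhs(t, x):
            z, s, f, v, q = x.reshape(5, 2)
            u = u_of(t)
            dz = A @ z + C * u
            ds = z - h.kappa * s - h.gamma * (f - 1)
            df = s
            dv = (f - v ** (1 / h.alpha)) / 2.0
            E = 1 - (1 - h.E0) ** (1 / f)
            dq = (f * E / h.E0 - v ** (1 / h.alpha) * q / v) / 2.0
            return np.concatenate([dz, ds, df, dv, dq])

        x0 = np.concatenate([np.zeros(4), np.ones(6)])
        t_eval = np.arange(20) * 3.0
        sol = solve_ivp(rhs, (0, 60.0), x0, t_eval=t_eval, rtol=1e-10, atol=1e-12,
                        max_step=design.dt)
        v = sol.y[6:8].T
        q = sol.y[8:10].T
        k1, k2, k3 = 7 * h.E0, 2.0, 2 * h.E0 - 0.2
        y_ref = h.V0 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))
        scale = np.abs(y_ref).max()
        assert np.allclose(ts.data, y_ref, atol=1e-4 * scale)

    def test_grid_convergence(self, toy_params):
        # dt pair chosen commensurate with the block edges so halving the
        # step changes only the integration error, not the input boxcars
        sched = BlockSchedule(blocks=(("simple-fast", 5.0, 20.0),), lead_in=0.0)
        ys = []
        for dt in (0.2, 0.1):
            design = inputs_at_microtime(sched, dt=dt, total_scan=60.0)
            ts, _ = simulate_bold(toy_params, design, n_volumes=20, return_states=False)
            ys.append(ts.data)
        scale = np.abs(ys[1]).max()
        assert np.max(np.abs(ys[0] - ys[1])) < 1e-3 * scale

    def test_linearity_in_drive(self):
        """With B = 0 the neural ODE is linear: doubling C doubles z."""
        sched = BlockSchedule(blocks=(("simple-slow", 5.0, 20.0),), lead_in=0.0)
        design = inputs_at_microtime(sched, dt=0.1875, total_scan=60.0)
        _, t1 = simulate_bold(one_region_params(c=0.05), design, n_volumes=20)
        _, t2 = simulate_bold(one_region_params(c=0.10), design, n_volumes=20)
        assert np.abs(t2.z).max() == pytest.approx(2 * np.abs(t1.z).max(), rel=1e-2)

    def test_decay_after_offset(self):
        sched = BlockSchedule(blocks=(("simple-slow", 0.0, 10.0),), lead_in=0.0)
        design = inputs_at_microtime(sched, dt=0.125, total_scan=100.0)
        _, traj = simulate_bold(one_region_params(a=-0.5, c=0.2), design, n_volumes=30)
        peak = np.abs(traj.z).max()
        # slowest eigenvalue -0.5: within ~14 time constants after offset
        tail = traj.z[traj.t > 10.0 + 14 / 0.5]
        assert np.abs(tail).max() < 1e-6 * peak

    def test_unstable_params_raise_naming_eigenvalue(self, default_design):
        p = DCMParameters(A=np.array([[-0.5, 1.0], [1.0, -0.5]]),
                          B={"complexity": np.zeros((2, 2)), "speed": np.zeros((2, 2))},
                          C=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_bold(p, default_design)

    def test_noise_seeded_and_optional(self, toy_params, default_design):
        noisy = two_region_params(noise_sd=0.01)
        ts1, _ = simulate_bold(noisy, default_design, seed=5, return_states=False)
        ts2, _ = simulate_bold(noisy, default_design, seed=5, return_states=False)
        ts3, _ = simulate_bold(noisy, default_design, seed=6, return_states=False)
        assert np.array_equal(ts1.data, ts2.data)
        assert not np.array_equal(ts1.data, ts3.data)

    def test_coupling_direction_convention(self):
        """A[i, j] couples from region j to region i: only Y responds to X."""
        sched = BlockSchedule(blocks=(("simple-slow", 5.0, 20.0),), lead_in=0.0)
        design = inputs_at_microtime(sched, dt=0.1875, total_scan=60.0)
        _, traj = simulate_bold(two_region_params(a_yx=0.4), design, n_volumes=20)
        assert np.abs(traj.z[:, 1]).max() > 0.01  # Y driven via X
        # reverse: drive enters X only; with A[0,1]=0, X is unaffected by Y
        p_rev = DCMParameters(
            A=np.array([[-0.5, 0.0], [0.0, -0.5]]),
            B={"complexity": np.zeros((2, 2)), "speed": np.zeros((2, 2))},
            C=np.array([[0.15, 0, 0], [0, 0, 0]]),
        )
        _, traj0 = simulate_bold(p_rev, design, n_volumes=20)
        assert np.abs(traj0.z[:, 1]).max() < 1e-12


def test_validate_masks(toy_spec):
    p = two_region_params()
    p.validate(toy_spec)
    bad = DCMParameters(A=np.array([[-0.5, 0.2], [0.3, -0.5]]),
                        B=p.B, C=p.C)
    with pytest.raises(ValueError, match="outside"):
        bad.validate(toy_spec)
    with pytest.raises(ValueError, match="negative"):
        DCMParameters(A=np.array([[0.5]]), B={}, C=np.zeros((1, 1))).validate()
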