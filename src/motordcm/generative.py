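"""Bilinear neural model with Balloon-Windkessel hemodynamics.

Neural dynamics (bilinear, one state per region):

    dz/dt = (A + sum_j u_j B_j) z + C u

A couples regions task-independently (Hz; negative diagonal = self-decay),
the B matrices let the modulatory inputs change couplings, and C routes the
driving input into regions.  Each region's neural state feeds a standard
Balloon-Windkessel cascade

    ds/dt = z - kappa s - gamma (f - 1)
    df/dt = s
    tau dv/dt = f - v^(1/alpha)
    tau dq/dt = f E(f, E0)/E0 - v^(1/alpha) q / v,   E(f, E0) = 1-(1-E0)^(1/f)

observed as y = V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v)).  Integration is
fixed-step RK4 on the design's microtime grid with inputs held constant per
bin; the defaults (kappa 0.64/s, gamma 0.32/s, tau 2 s, alpha 0.32, E0 0.4,
V0 0.04) are the canonical deterministic values for this forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _integrate
from .network import NetworkSpec, MODULATORY_INPUTS
from .paradigm import StimulusDesign, TR_DEFAULT, N_VOLUMES_DEFAULT

KAPPA_DEFAULT = 0.64
GAMMA_DEFAULT = 0.32
TAU_DEFAULT = 2.0
ALPHA_DEFAULT = 0.32
E0_DEFAULT = 0.4
V0_DEFAULT = 0.04
SELF_DECAY_DEFAULT = -0.5


@dataclass(frozen=True)
class HemoParams:
    """Per-region hemodynamic constants (tau may vary by region)."""

    kappa: float = KAPPA_DEFAULT  # signal decay, 1/s
    gamma: float = GAMMA_DEFAULT  # flow-dependent elimination, 1/s
    tau: np.ndarray | float = TAU_DEFAULT  # mean transit time, s
    alpha: float = ALPHA_DEFAULT  # vessel stiffness exponent
    E0: float = E0_DEFAULT  # resting oxygen extraction fraction
    V0: float = V0_DEFAULT  # resting venous volume fraction

    def tau_vector(self, n_regions: int) -> np.ndarray:
        tau = np.broadcast_to(np.asarray(self.tau, dtype=float), (n_regions,))
        return np.ascontiguousarray(tau)

    def validate(self) -> None:
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if np.any(tau <= 0):
            raise ValueError("tau must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.E0 < 1):
            raise ValueError("E0 must lie in (0, 1)")


@dataclass(frozen=True)
class DCMParameters:
    """Numeric coupling matrices plus hemodynamics for one subject."""

    A: np.ndarray = field(repr=False)  # (R, R), Hz
    B: dict[str, np.ndarray] = field(repr=False)  # input label -> (R, R), Hz
    C: np.ndarray = field(repr=False)  # (R, n_inputs), Hz per unit input
    hemo: HemoParams = field(default_factory=HemoParams)
    noise_sd: float = 0.0

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    def validate(self, spec: NetworkSpec | None = None) -> None:
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A must be strictly negative")
        self.hemo.validate()
        if spec is not None:
            if np.any(self.A[~spec.A_mask] != 0):
                raise ValueError("A has entries outside the permitted mask")
            for name, Bm in self.B.items():
                if np.any(Bm[~spec.B_masks[name]] != 0):
                    raise ValueError(f"B[{name}] has entries outside the mask")
            if np.any(self.C[~spec.C_mask] != 0):
                raise ValueError("C has entries outside the mask")

    def with_noise(self, noise_sd: float) -> "DCMParameters":
        return replace(self, noise_sd=noise_sd)


@dataclass(frozen=True)
class ROITimeSeries:
    """Region-of-interest BOLD matrix sampled at the repetition time."""

    data: np.ndarray  # (T, R)
    tr: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("data must be a non-empty T x R matrix")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("label count does not match data columns")


@dataclass(frozen=True)
class StateTrajectory:
    """Neural and hemodynamic states on the microtime grid."""

    t: np.ndarray
    z: np.ndarray  # (n_bins+1, R)
    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray


def _input_order(params: DCMParameters, design: StimulusDesign) -> list[str]:
    names = list(design.input_names)
    for b in params.B:
        if b not in names:
            raise ValueError(f"modulatory input {b!r} absent from the design")
    return names


def _stacked(params: DCMParameters, input_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """B matrices and C re-ordered to match the design input columns."""
    R = params.n_regions
    J = len(input_names)
    B = np.zeros((J, R, R))
    for j, name in enumerate(input_names):
        if name in params.B:
            B[j] = params.B[name]
    if params.C.shape[1] != J:
        raise ValueError("C column count does not match design inputs")
    return B, np.asarray(params.C, dtype=float)


def effective_coupling(params: DCMParameters, u_const: np.ndarray, input_names=None) -> np.ndarray:
    """A + sum_j u_j B_j for a constant input vector."""
    u = np.asarray(u_const, dtype=float)
    names = input_names or list(dict.fromkeys(["task", *MODULATORY_INPUTS]))[: u.size]
    M = np.array(params.A, dtype=float)
    for j, name in enumerate(names):
        if name in params.B:
            M = M + u[j] * params.B[name]
    return M


def is_stable(
    params: DCMParameters,
    u_const: np.ndarray | None = None,
    input_names=None,
    margin: float = 0.0,
) -> bool:
    """True iff every eigenvalue of the effective coupling has Re < -margin.

    ``margin > 0`` additionally rejects weakly damped systems whose neural
    steady states would be implausibly large (the slowest mode amplifies
    the drive by 1/|Re lambda|).
    """
    if u_const is None:
        u_const = np.zeros(params.C.shape[1])
    M = effective_coupling(params, u_const, input_names)
    return bool(np.all(np.linalg.eigvals(M).real < -margin))


def steady_state(params: DCMParameters, u_const: np.ndarray, input_names=None) -> np.ndarray:
    """Neural fixed point z* solving (A + sum u_j B_j) z* + C u = 0."""
    u = np.asarray(u_const, dtype=float)
    M = effective_coupling(params, u, input_names)
    rhs = -params.C @ u
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as err:
        raise ValueError("effective coupling matrix is singular") from err


def _check_stability(params: DCMParameters, design: StimulusDesign) -> None:
    names = list(design.input_names)
    patterns = np.unique(design.u, axis=0)
    for u in patterns:
        M = effective_coupling(params, u, names)
        eig = np.linalg.eigvals(M)
        worst = eig[np.argmax(eig.real)]
        if worst.real >= 0:
            raise ValueError(
                f"unstable coupling under input pattern {u.tolist()}: "
                f"eigenvalue {worst:.4f} has non-negative real part"
            )


def simulate_bold(
    params: DCMParameters,
    design: StimulusDesign,
    tr: float = TR_DEFAULT,
    n_volumes: int = N_VOLUMES_DEFAULT,
    seed: int | None = None,
    *,
    return_states: bool = True,
    labels: tuple[str, ...] | None = None,
) -> tuple[ROITimeSeries, StateTrajectory | None]:
    """Simulate noisy BOLD for one subject.

    Integrates the neural and hemodynamic states on the design's microtime
    grid, samples the observation every ``tr`` seconds, and adds iid
    Gaussian observation noise of sd ``params.noise_sd`` (none when 0).
    """
    _check_stability(params, design)
    names = _input_order(params, design)
    B, C = _stacked(params, names)
    R = params.n_regions
    hemo = params.hemo
    tau = hemo.tau_vector(R)
    A = np.ascontiguousarray(params.A, dtype=float)
    U = np.ascontiguousarray(design.u, dtype=float)
    dt = design.dt
    sample_idx = np.round(np.arange(n_volumes) * tr / dt).astype(np.int64)
    if sample_idx[-1] > U.shape[0]:
        raise ValueError("design does not cover the requested scan duration")
    if return_states:
        X, status = _integrate.rk4_states(
            A[None], B[None], C[None], U, dt, hemo.kappa, hemo.gamma,
            tau[None], hemo.alpha, hemo.E0,
        )
        if status:
            raise FloatingPointError(
                f"hemodynamic state became non-positive at step {status} "
                f"(dt={dt}); reduce the step size"
            )
        y_grid = _integrate.bold_from_states(X[0], hemo.E0, hemo.V0)
        y = y_grid[sample_idx]
        traj = StateTrajectory(
            t=np.arange(U.shape[0] + 1) * dt,
            z=X[0, :, 0, :], s=X[0, :, 1, :], f=X[0, :, 2, :],
            v=X[0, :, 3, :], q=X[0, :, 4, :],
        )
    else:
        y_batch, status = _integrate.rk4_bold(
            A[None], B[None], C[None], U, dt, hemo.kappa, hemo.gamma,
            tau[None], hemo.alpha, hemo.E0, hemo.V0, sample_idx,
        )
        if status:
            raise FloatingPointError(
                f"hemodynamic state became non-positive at step {status} "
                f"(dt={dt}); reduce the step size"
            )
        y = y_batch[0]
        traj = None
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sd, size=y.shape)
    if labels is None:
        labels = tuple(f"R{i}" for i in range(R))
    return ROITimeSeries(data=y, tr=tr, labels=labels), traj


def simulate_bold_batch(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    design: StimulusDesign,
    hemo: HemoParams,
    tau: np.ndarray,
    tr: float = TR_DEFAULT,
    n_volumes: int = N_VOLUMES_DEFAULT,
) -> np.ndarray:
    """Noise-free sampled BOLD for a batch of parameter sets.

    A (nb, R, R); B (nb, J, R, R) ordered as the design inputs; C (nb, R, J);
    tau (nb, R).  Returns (nb, n_volumes, R).  Raises on non-positive
    hemodynamic states.
    """
    U = np.ascontiguousarray(design.u, dtype=float)
    sample_idx = np.round(np.arange(n_volumes) * tr / design.dt).astype(np.int64)
    y, status = _integrate.rk4_bold(
        np.ascontiguousarray(A), np.ascontiguousarray(B), np.ascontiguousarray(C),
        U, design.dt, hemo.kappa, hemo.gamma, np.ascontiguousarray(tau),
        hemo.alpha, hemo.E0, hemo.V0, sample_idx,
    )
    if status:
        raise FloatingPointError(
            f"hemodynamic state became non-positive at step {status} (dt={design.dt})"
        )
    return y
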