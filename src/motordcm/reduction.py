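"""Post-hoc model reduction via the generalised Savage-Dickey ratio.

Only the full model is inverted; the log evidence of any nested reduction
(obtained by shrinking prior variances of selected parameters toward zero)
follows analytically from the full model's Gaussian prior and posterior:

    dF = ln  integral  q(theta) p_r(theta) / p(theta)  dtheta

with q the full posterior, p the full prior and p_r the reduced prior.  A
greedy backward search over candidate parameters (all modulatory couplings
by default) switches off the single parameter whose removal most increases
dF until no removal helps; ties favour the simpler model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .inversion import ParameterPacking, PosteriorDensity, PriorDensity

OFF_VARIANCE = 1e-8


@dataclass(frozen=True)
class ReducedModel:
    """One scored reduction of the full model."""

    off_mask: np.ndarray  # boolean over free parameters; True = switched off
    delta_F: float  # log evidence relative to the full model
    posterior_prob: float = float("nan")

    @property
    def n_off(self) -> int:
        return int(np.sum(self.off_mask))


def _gauss_terms(mean: np.ndarray, cov: np.ndarray):
    P = np.linalg.inv(cov)
    sign, ld = np.linalg.slogdet(P)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    return P, ld, P @ mean


def reduced_log_evidence(
    posterior: PosteriorDensity,
    prior: PriorDensity,
    reduced_prior: PriorDensity,
) -> float:
    """Log-evidence difference of a nested reduced model vs the full model.

    Closed-form Gaussian algebra over (prior, posterior, reduced prior,
    implied reduced posterior).  Raises on singular covariances.
    """
    try:
        P, ldP, b = _gauss_terms(posterior.mean, posterior.cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("posterior covariance is singular") from err
    try:
        P0, ldP0, b0 = _gauss_terms(prior.mean, prior.cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("prior covariance is singular") from err
    try:
        Pr, ldPr, br = _gauss_terms(reduced_prior.mean, reduced_prior.cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("reduced prior covariance is singular") from err
    Pc = P + Pr - P0
    sign, ldPc = np.linalg.slogdet(Pc)
    if sign <= 0:
        raise ValueError("implied reduced posterior precision is not positive definite")
    bc = b + br - b0
    quad = float(bc @ np.linalg.solve(Pc, bc))
    quad -= float(posterior.mean @ b)
    quad -= float(reduced_prior.mean @ br)
    quad += float(prior.mean @ b0)
    return 0.5 * (ldPr - ldP0 + ldP - ldPc) + 0.5 * quad


def modulatory_candidates(packing: ParameterPacking) -> np.ndarray:
    """Default search space: indices of all modulatory (B) parameters."""
    return packing.indices("B")


def _greedy_backward(score, candidates, p):
    """Shared greedy elimination: score(off_mask) -> pooled dF."""
    off = np.zeros(p, dtype=bool)
    scored = [ReducedModel(off.copy(), 0.0)]
    best_F = 0.0
    remaining = list(candidates)
    while remaining:
        trials = []
        for c in remaining:
            trial = off.copy()
            trial[c] = True
            trials.append((score(trial), c))
        dF_best, c_best = max(trials, key=lambda t: (t[0], -t[1]))
        if dF_best < best_F:  # ties (==) favour the simpler model
            break
        off[c_best] = True
        best_F = dF_best
        remaining.remove(c_best)
        scored.append(ReducedModel(off.copy(), best_F))
    probs = model_posterior_probs(np.array([m.delta_F for m in scored]))
    scored = [
        ReducedModel(m.off_mask, m.delta_F, float(pr)) for m, pr in zip(scored, probs)
    ]
    winner = max(scored, key=lambda m: (m.delta_F, m.n_off))
    return winner, scored


def posthoc_search(
    posterior: PosteriorDensity,
    prior: PriorDensity,
    candidate_params: np.ndarray | None = None,
    *,
    off_variance: float = OFF_VARIANCE,
    include_intrinsic: bool = False,
) -> tuple[ReducedModel, list[ReducedModel]]:
    """Greedy backward elimination over candidate parameters.

    At each step the single remaining candidate whose removal maximises the
    Savage-Dickey log-evidence gain is switched off; the search stops when
    no removal increases the score (ties break toward pruning).  Returns
    the winner and every model scored along the trajectory, with posterior
    probabilities over that scored set.
    """
    packing = posterior.packing
    if candidate_params is None:
        candidates = list(modulatory_candidates(packing))
        if include_intrinsic:
            candidates += list(packing.indices("A"))
    else:
        candidates = list(np.atleast_1d(np.asarray(candidate_params, dtype=int)))

    def score(off_mask):
        rp = prior.shrink(np.where(off_mask)[0], off_variance)
        return reduced_log_evidence(posterior, prior, rp)

    return _greedy_backward(score, candidates, packing.n_params)


def pooled_posthoc_search(
    posteriors: list[PosteriorDensity],
    prior: PriorDensity,
    candidate_params: np.ndarray | None = None,
    *,
    off_variance: float = OFF_VARIANCE,
) -> tuple[ReducedModel, list[ReducedModel]]:
    """Greedy search scoring each reduction by its summed dF over subjects.

    Fixed-effects pooling: the group-level evidence for a reduction is the
    sum of per-subject Savage-Dickey log-evidence differences, so the
    result is invariant to subject order.
    """
    packing = prior.packing
    if candidate_params is None:
        candidates = list(modulatory_candidates(packing))
    else:
        candidates = list(np.atleast_1d(np.asarray(candidate_params, dtype=int)))

    def score(off_mask):
        rp = prior.shrink(np.where(off_mask)[0], off_variance)
        return sum(reduced_log_evidence(q, prior, rp) for q in posteriors)

    return _greedy_backward(score, candidates, packing.n_params)


def model_posterior_probs(delta_Fs: np.ndarray) -> np.ndarray:
    """Posterior model probabilities: softmax of log evidences."""
    delta_Fs = np.asarray(delta_Fs, dtype=float)
    if not np.all(np.isfinite(delta_Fs)):
        raise ValueError("delta_F values must be finite")
    return softmax(delta_Fs)
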