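"""Self-contained validation experiments.

Each function builds its own synthetic data, runs the relevant part of the
pipeline, and returns summary numbers.  They are used by the test suite and
by the results-reproduction script; sizes are scaled for a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    CohortSpec,
    PlantedCluster,
    _mean_params,
    _physiological,
    covariate_table,
    generate_cohort,
    true_coupling_table,
)
from .generative import DCMParameters, HemoParams, ROITimeSeries, simulate_bold
from .inversion import default_priors, invert, qc_filter
from .network import motor_network_preset, winning_model_preset
from .paradigm import build_paradigm
from .reduction import modulatory_candidates, posthoc_search
from .stats import ancova_per_connection, bonferroni_threshold

KEY_CONNECTION = "B:complexity:lPMd<-lSPC"


def scaled_cohort_spec(seed: int, n_per_group=(15, 15, 15)) -> CohortSpec:
    """Study conditions scaled for test speed; the planted sub-cluster
    scales with the pre-symptomatic pool (9 of 62 in the full design)."""
    planted = PlantedCluster(size=max(0, round(9 * n_per_group[1] / 62)))
    return CohortSpec(n_per_group=tuple(n_per_group), planted_cluster=planted,
                      seed=seed)


@dataclass
class RecoveryResult:
    pooled_correlation: float
    per_kind: dict[str, float]
    variance_explained: list[float]
    f_histories: list[tuple[float, ...]]
    n_subjects: int


def recovery_experiment(
    seed: int = 7,
    n_per_group=(7, 7, 6),
    *,
    dt: float | None = None,
    max_iter: int = 96,
    tol: float = 1e-3,
) -> RecoveryResult:
    """Simulate a scaled cohort at default SNR, invert every subject, and
    correlate true vs posterior-mean couplings pooled over subjects."""
    net = winning_model_preset()
    priors = default_priors(net)
    pack = priors.packing
    design = build_paradigm(seed=seed)
    spec = scaled_cohort_spec(seed, n_per_group)
    subjects = generate_cohort(spec, design=design, network=net,
                               with_behavior=False)
    truths, estimates, ves, hists = [], [], [], []
    for s in subjects:
        post, diag = invert(s.timeseries, design, net, priors,
                            dt=dt, max_iter=max_iter, tol=tol)
        truths.append(pack.pack_params(s.params))
        estimates.append(post.mean)
        ves.append(diag.variance_explained)
        hists.append(post.f_history)
    T = np.vstack(truths)
    E = np.vstack(estimates)
    ci = pack.coupling_indices
    pooled = float(np.corrcoef(T[:, ci].ravel(), E[:, ci].ravel())[0, 1])
    per_kind = {
        k: float(np.corrcoef(T[:, pack.indices(k)].ravel(),
                             E[:, pack.indices(k)].ravel())[0, 1])
        for k in ("A", "B", "C")
    }
    return RecoveryResult(pooled, per_kind, ves, hists, len(subjects))


@dataclass
class SparsityResult:
    hit_rate: float  # fraction of truly-off modulatory couplings pruned
    false_prune_rate: float  # fraction of truly-on couplings pruned
    per_seed: list[tuple[float, float]]


def _sparse_truth_subject(rng: np.random.Generator, b_magnitude: float,
                          drive: float) -> DCMParameters:
    """A subject whose on-couplings are decisively non-zero (the winning
    structure), for validating the reduction search."""
    win = winning_model_preset()
    base = _mean_params(win)
    for _ in range(1000):
        A = base.A.copy()
        off = win.A_mask & ~np.eye(win.n_regions, dtype=bool)
        A[off] += rng.normal(0, 0.05, int(off.sum()))
        B = {k: np.zeros_like(v, dtype=float) for k, v in win.B_masks.items()}
        for inp, mask in win.B_masks.items():
            B[inp][mask] = b_magnitude * rng.choice([-1.0, 1.0], size=int(mask.sum()))
        C = np.where(base.C != 0, drive, 0.0)
        p = DCMParameters(A=A, B=B, C=C, hemo=HemoParams())
        if _physiological(p, win):
            return p
    raise RuntimeError("no feasible sparse-truth subject")


def sparsity_experiment(
    n_seeds: int = 10,
    seed: int = 0,
    *,
    b_magnitude: float = 0.3,
    drive: float = 0.3,
    snr: float = 12.0,
    dt: float | None = None,
    max_iter: int = 64,
) -> SparsityResult:
    """Simulate subjects from the winning structure (absent modulatory
    couplings truly zero, present ones +/- ``b_magnitude``), invert the
    full model, and run the greedy Savage-Dickey search.

    High SNR and full drive isolate the search from estimation noise: the
    quantity under test is whether an informative posterior recovers the
    planted sparsity, not the inversion's noise robustness.
    """
    full = motor_network_preset()
    win = winning_model_preset()
    priors = default_priors(full)
    pack = priors.packing
    candidates = modulatory_candidates(pack)
    true_off = {
        k for k in candidates
        if not win.B_masks[pack.entries[k][1]][pack.entries[k][2], pack.entries[k][3]]
    }
    design = build_paradigm(seed=9)
    per_seed = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        truth = _sparse_truth_subject(rng, b_magnitude, drive)
        ts, _ = simulate_bold(truth, design, return_states=False,
                              labels=full.regions)
        noise_rng = np.random.default_rng(seed + i + 10_000)
        sd = ts.data.std(axis=0) / snr
        ts = ROITimeSeries(data=ts.data + noise_rng.standard_normal(ts.data.shape) * sd,
                           tr=ts.tr, labels=ts.labels)
        post, _ = invert(ts, design, full, priors, dt=dt, max_iter=max_iter,
                         tol=1e-3)
        winner, _ = posthoc_search(post, priors)
        off = set(np.where(winner.off_mask)[0])
        hit = len(off & true_off) / len(true_off)
        fp = len(off - true_off) / (len(candidates) - len(true_off))
        per_seed.append((hit, fp))
    hits, fps = zip(*per_seed)
    return SparsityResult(float(np.mean(hits)), float(np.mean(fps)), per_seed)


@dataclass
class DetectionResult:
    F: float
    p: float
    detected: bool
    threshold: float
    n_qc_passed: int
    n_subjects: int


def detection_experiment(
    seed: int,
    n_per_group=(15, 15, 15),
    *,
    dt: float = 1.5,
    max_iter: int = 12,
    n_tests: int = 47,
) -> DetectionResult:
    """One scaled end-to-end run: does the connection-wise ANCOVA flag the
    planted lSPC->lPMd complexity effect below the Bonferroni threshold?"""
    net = winning_model_preset()
    priors = default_priors(net)
    labels = priors.packing.labels
    design = build_paradigm(seed=seed)
    spec = scaled_cohort_spec(seed, n_per_group)
    subjects = generate_cohort(spec, design=design, network=net,
                               with_behavior=False)
    posts, diags = [], []
    for s in subjects:
        post, diag = invert(s.timeseries, design, net, priors,
                            dt=dt, max_iter=max_iter)
        posts.append(post)
        diags.append(diag)
    kept, _ = qc_filter(diags)
    cov = covariate_table(subjects)
    rows = [
        {"subject": subjects[i].subject_id, **dict(zip(labels, posts[i].mean))}
        for i in kept
    ]
    table = pd.DataFrame(rows).merge(cov, on="subject")
    conn = [l for l in labels if l.startswith(("A:", "B:"))]
    results = ancova_per_connection(table, conn, n_tests=n_tests)
    key = next(r for r in results if r.connection == KEY_CONNECTION)
    threshold = bonferroni_threshold(n_tests)
    return DetectionResult(key.F, key.p, bool(key.p < threshold), threshold,
                           len(kept), len(subjects))


def carrier_truth_features(seed: int = 0) -> tuple[np.ndarray, list[int]]:
    """Ground-truth coupling features and cluster labels of the default
    cohort's 78 gene carriers (no BOLD simulation needed)."""
    net = winning_model_preset()
    subjects = generate_cohort(CohortSpec(seed=seed), network=net,
                               with_bold=False, with_behavior=False)
    carriers = [s for s in subjects if s.group != "HC"]
    tab = true_coupling_table(carriers, net)
    X = tab.drop(columns=["subject", "group"]).to_numpy(float)
    return X, [s.cluster_truth for s in carriers]
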