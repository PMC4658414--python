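"""Synthetic cohort generator.

Emulates the study population downstream of image preprocessing: 77
healthy controls, 62 pre-symptomatic and 16 early-manifest huntingtin-
mutation carriers, each with demographic/clinical covariates, ground-truth
coupling parameters for the winning seven-region model, BOLD time series
simulated under the tapping paradigm, and metronome-paced press logs.

Group structure planted in the couplings (Hz):

====================  =====  ======  =======
modulatory coupling    HC    preHD   earlyHD
====================  =====  ======  =======
lSPC->lPMd (complex)   0.0   -0.3    +0.3
rSPC->pSMA (speed)    -0.2   -0.2    +0.3
cSMA->pSMA (speed)     0.0    0.0    -0.4
====================  =====  ======  =======

plus a planted sub-cluster of 9 pre-symptomatic carriers whose
cSMA->pSMA speed coupling is shifted by +0.4 and lSPC->lPMd complexity
coupling by -0.4, mirroring the reversed third sub-group.  A latent
severity variable links putamen volume to the lSPC->lPMd coupling; its
loading is solved analytically so the putamen-coupling correlation over
all carriers approximates the target (-0.302 by default).

All randomness flows from a single seed through named sub-streams, so a
cohort is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import PressBlock, PressLog, expected_sequence
from .generative import (
    DCMParameters,
    HemoParams,
    ROITimeSeries,
    SELF_DECAY_DEFAULT,
    is_stable,
    simulate_bold_batch,
)
from .network import NetworkSpec, winning_model_preset
from .paradigm import (
    N_VOLUMES_DEFAULT,
    TAPPING_CONDITIONS,
    TR_DEFAULT,
    StimulusDesign,
    build_paradigm,
)

GROUPS = ("HC", "preHD", "earlyHD")

#: per-group covariate moments: (mean, sd, low, high)
AGE_DIST = {"HC": (48.53, 9.56, 27, 67), "preHD": (41.89, 8.58, 24, 61),
            "earlyHD": (46.18, 8.59, 34, 67)}
CAG_DIST = {"preHD": (43.19, 2.55, 39, 50), "earlyHD": (43.25, 1.73, 41, 48)}
PUTAMEN_DIST = {"HC": (0.58, 0.07, 0.40, 0.75), "preHD": (0.50, 0.08, 0.29, 0.75),
                "earlyHD": (0.42, 0.12, 0.24, 0.66)}
FEMALE_FRACTION = {"HC": 45 / 77, "preHD": 30 / 62, "earlyHD": 6 / 16}
SITES = ("Paris", "London", "Vancouver", "Leiden")
EDUCATION_DIST = (13.0, 3.0)  # years; not reported, invented default

#: baseline means of the true couplings (Hz)
A_OFFDIAG_MEAN = 0.05
C_TASK_MEAN = 0.2
STABILITY_MARGIN = 0.15  # Hz; min damping of the slowest effective mode
#: admissible neural steady states under any input pattern.  The Balloon
#: model cannot sustain z below -gamma (inflow would turn negative), so
#: draws whose fixed points leave this band are rejected and redrawn.
Z_STEADY_BOUNDS = (-0.22, 1.2)

KEY_COMPLEXITY = ("complexity", "lPMd", "lSPC")
KEY_SPEED_RSPC = ("speed", "pSMA", "rSPC")
KEY_SPEED_CSMA = ("speed", "pSMA", "cSMA")


@dataclass(frozen=True)
class PlantedCluster:
    size: int = 9
    offsets: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: {KEY_SPEED_CSMA: +0.4, KEY_COMPLEXITY: -0.4}
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of the synthetic cohort."""

    n_per_group: tuple[int, int, int] = (77, 62, 16)
    effect_table: dict[tuple[str, str, str], tuple[float, float, float]] = field(
        default_factory=lambda: {
            KEY_COMPLEXITY: (0.0, -0.3, 0.3),
            KEY_SPEED_RSPC: (-0.2, -0.2, 0.3),
            KEY_SPEED_CSMA: (0.0, 0.0, -0.4),
        }
    )
    between_subject_sd: float = 0.1  # Hz, on every free coupling
    planted_cluster: PlantedCluster = field(default_factory=PlantedCluster)
    severity_correlation: float = -0.302  # target putamen vs lSPC->lPMd coupling
    snr: float = 1.0  # per-region signal sd / noise sd
    #: per-group press-timing jitter sd (s) and correct-button probability
    behavior_jitter_sd: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.08, "preHD": 0.10, "earlyHD": 0.15}
    )
    correct_button_prob: float = 0.97
    press_lag_mean: float = 0.05  # s, mean cue-response latency
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        n_carriers = self.n_per_group[1] + self.n_per_group[2]
        if self.planted_cluster.size > n_carriers:
            raise ValueError("planted cluster larger than the carrier pool")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    covariates: dict[str, object]
    params: DCMParameters
    timeseries: ROITimeSeries | None = None
    press_log: PressLog | None = None
    cluster_truth: int = 0  # 0 HC; 1 preHD bulk; 2 earlyHD; 3 planted sub-cluster


def _solve_within_correlation(spec: CohortSpec) -> float:
    """Within-group correlation needed to hit the carrier-wide target.

    Decomposes the putamen x key-coupling covariance over carriers into
    between-group and within-group parts given the spec's effect table and
    planted offsets, then solves for the within-group component.
    """
    n_pre, n_early = spec.n_per_group[1], spec.n_per_group[2]
    n = n_pre + n_early
    if n == 0:
        return 0.0
    w = np.array([n_pre, n_early]) / n
    mu_p = np.array([PUTAMEN_DIST["preHD"][0], PUTAMEN_DIST["earlyHD"][0]])
    sd_p = np.array([PUTAMEN_DIST["preHD"][1], PUTAMEN_DIST["earlyHD"][1]])
    eff = spec.effect_table.get(KEY_COMPLEXITY, (0.0, 0.0, 0.0))
    mu_c = np.array([eff[1], eff[2]])
    # planted members sit inside preHD and shift the key coupling
    frac_planted = spec.planted_cluster.size / n_pre if n_pre else 0.0
    off = spec.planted_cluster.offsets.get(KEY_COMPLEXITY, 0.0)
    mu_c_pre = mu_c[0] + frac_planted * off
    var_c_pre = spec.between_subject_sd**2 + frac_planted * (1 - frac_planted) * off**2
    mu_cs = np.array([mu_c_pre, mu_c[1]])
    var_cs = np.array([var_c_pre, spec.between_subject_sd**2])
    pbar = float(w @ mu_p)
    cbar = float(w @ mu_cs)
    var_p = float(w @ (sd_p**2) + w @ (mu_p - pbar) ** 2)
    var_c = float(w @ var_cs + w @ (mu_cs - cbar) ** 2)
    cov_between = float(w @ ((mu_p - pbar) * (mu_cs - cbar)))
    cov_total = spec.severity_correlation * np.sqrt(var_p * var_c)
    cov_within = cov_total - cov_between
    # within draws: putamen sd_g and coupling sd between_subject_sd per group
    denom = float(w @ (sd_p * spec.between_subject_sd))
    rho = cov_within / denom if denom > 0 else 0.0
    return float(np.clip(rho, -0.95, 0.95))


def _draw_truncated(rng, mean, sd, low, high, size):
    x = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (x < low) | (x > high)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(x, low, high)


def _coupling_keys(net: NetworkSpec) -> list[tuple]:
    """Free coupling entries of a network spec: A off-diagonal, B, C."""
    keys = []
    R = net.n_regions
    for i in range(R):
        for j in range(R):
            if i != j and net.A_mask[i, j]:
                keys.append(("A", None, i, j))
    for inp, mask in net.B_masks.items():
        for i in range(R):
            for j in range(R):
                if mask[i, j]:
                    keys.append(("B", inp, i, j))
    for jcol, inp in enumerate(net.inputs):
        for i in range(R):
            if net.C_mask[i, jcol]:
                keys.append(("C", inp, i, jcol))
    return keys


def _mean_params(net: NetworkSpec) -> DCMParameters:
    R = net.n_regions
    A = np.where(net.A_mask & ~np.eye(R, dtype=bool), A_OFFDIAG_MEAN, 0.0)
    np.fill_diagonal(A, SELF_DECAY_DEFAULT)
    B = {k: np.zeros((R, R)) for k in net.B_masks}
    C = np.where(net.C_mask, C_TASK_MEAN, 0.0)
    return DCMParameters(A=A, B=B, C=C)


_INPUT_PATTERNS = ([0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1])


def _physiological(params: DCMParameters, net: NetworkSpec) -> bool:
    """Stable with margin and admissible steady states under all inputs."""
    from .generative import steady_state

    for u in _INPUT_PATTERNS:
        if not is_stable(params, u, list(net.inputs), margin=STABILITY_MARGIN):
            return False
        z = steady_state(params, np.asarray(u, float), list(net.inputs))
        if z.min() < Z_STEADY_BOUNDS[0] or z.max() > Z_STEADY_BOUNDS[1]:
            return False
    return True


def _subject_params(
    net: NetworkSpec,
    group_idx: int,
    spec: CohortSpec,
    rng: np.random.Generator,
    key_coupling_value: float | None,
    planted: bool,
    max_retries: int = 250,
) -> tuple[DCMParameters, int]:
    """Draw one subject's stable true parameters; returns (params, retries)."""
    base = _mean_params(net)
    idx = {r: i for i, r in enumerate(net.regions)}
    for attempt in range(max_retries):
        A = base.A.copy()
        off = net.A_mask & ~np.eye(net.n_regions, dtype=bool)
        A[off] += rng.normal(0.0, spec.between_subject_sd, int(off.sum()))
        B = {k: v.copy() for k, v in base.B.items()}
        for inp, mask in net.B_masks.items():
            B[inp][mask] += rng.normal(0.0, spec.between_subject_sd, int(mask.sum()))
        C = base.C.copy()
        C[net.C_mask] += rng.normal(0.0, spec.between_subject_sd, int(net.C_mask.sum()))
        for (inp, tgt, src), means in spec.effect_table.items():
            B[inp][idx[tgt], idx[src]] += means[group_idx]
        if planted:
            for (inp, tgt, src), offset in spec.planted_cluster.offsets.items():
                B[inp][idx[tgt], idx[src]] += offset
        if key_coupling_value is not None:
            inp, tgt, src = KEY_COMPLEXITY
            B[inp][idx[tgt], idx[src]] = key_coupling_value
        params = DCMParameters(A=A, B=B, C=C, hemo=HemoParams())
        if _physiological(params, net):
            return params, attempt
    raise RuntimeError(f"no stable parameter draw in {max_retries} attempts")


def generate_press_log(
    group: str,
    design: StimulusDesign,
    seed_or_rng,
    *,
    jitter_sd: float | None = None,
    correct_prob: float = 0.97,
    lag_mean: float = 0.05,
    subject_id: str = "",
    jitter_by_group: dict[str, float] | None = None,
) -> PressLog:
    """Simulate one subject's presses: clicks + Gaussian jitter.

    Tapping blocks get one press per click at ``click + lag + jitter`` with
    the expected button with probability ``correct_prob`` (else a uniform
    wrong button); rest blocks produce no presses.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    sd = jitter_sd
    if sd is None:
        table = jitter_by_group or CohortSpec().behavior_jitter_sd
        sd = table[group]
    blocks = []
    for k, (label, onset, dur) in enumerate(design.schedule.blocks):
        clicks = design.click_times[k]
        seq = expected_sequence(label)
        if seq is None or label not in TAPPING_CONDITIONS:
            blocks.append(PressBlock(label, clicks, (), ()))
            continue
        times = np.asarray(clicks) + lag_mean + rng.normal(0.0, sd, len(clicks))
        order = np.argsort(times, kind="stable")
        buttons = []
        for j in range(len(clicks)):
            exp_b = seq[j % len(seq)]
            if rng.random() < correct_prob:
                buttons.append(exp_b)
            else:
                buttons.append(int(rng.choice([b for b in (1, 2, 3, 4) if b != exp_b])))
        blocks.append(
            PressBlock(
                label,
                clicks,
                tuple(float(times[i]) for i in order),
                tuple(buttons[i] for i in order),
            )
        )
    return PressLog(subject_id=subject_id, blocks=tuple(blocks))


def generate_cohort(
    spec: CohortSpec,
    *,
    design: StimulusDesign | None = None,
    network: NetworkSpec | None = None,
    with_bold: bool = True,
    with_behavior: bool = True,
    tr: float = TR_DEFAULT,
    n_volumes: int = N_VOLUMES_DEFAULT,
) -> list[SyntheticSubject]:
    """Generate the full synthetic cohort, reproducible from ``spec.seed``."""
    net = network or winning_model_preset()
    ss = np.random.SeedSequence(spec.seed)
    rngs = {name: np.random.default_rng(child) for name, child in
            zip(("covariates", "params", "noise", "behavior", "assign"),
                ss.spawn(5))}
    if design is None:
        design = build_paradigm(seed=int(ss.generate_state(1)[0] % (2**31)))

    rho_w = _solve_within_correlation(spec)
    idx = {r: i for i, r in enumerate(net.regions)}
    subjects: list[SyntheticSubject] = []
    n_pre = spec.n_per_group[1]
    n_planted = min(spec.planted_cluster.size, n_pre)  # sub-cluster lives in preHD
    planted_ids = set(
        rngs["assign"].choice(n_pre, size=n_planted, replace=False)
    )

    counter = 0
    for g_idx, (group, n_g) in enumerate(zip(GROUPS, spec.n_per_group)):
        rng_c = rngs["covariates"]
        age = _draw_truncated(rng_c, *AGE_DIST[group], n_g)
        female = rng_c.random(n_g) < FEMALE_FRACTION[group]
        site = rng_c.choice(SITES, size=n_g)
        education = np.clip(rng_c.normal(*EDUCATION_DIST, n_g), 6, 22)
        if group == "HC":
            cag = np.full(n_g, np.nan)
        else:
            cag = np.round(_draw_truncated(rng_c, *CAG_DIST[group], n_g), 0)
        pm, psd, plo, phi = PUTAMEN_DIST[group]
        eps_p = rng_c.standard_normal(n_g)
        eps_c = rho_w * eps_p + np.sqrt(1 - rho_w**2) * rng_c.standard_normal(n_g)
        # the severity residual is fixed across stability redraws; clip its
        # tail so extreme key couplings stay hemodynamically feasible
        eps_c = np.clip(eps_c, -2.5, 2.5)
        putamen = np.clip(pm + psd * eps_p, plo, phi)

        for k in range(n_g):
            planted = group == "preHD" and k in planted_ids
            if group == "HC":
                key_val = None
            else:
                eff = spec.effect_table.get(KEY_COMPLEXITY, (0.0, 0.0, 0.0))[g_idx]
                if planted:
                    eff += spec.planted_cluster.offsets.get(KEY_COMPLEXITY, 0.0)
                key_val = eff + spec.between_subject_sd * eps_c[k]
            params, _ = _subject_params(
                net, g_idx, spec, rngs["params"], key_val, planted
            )
            covs = {
                "age": float(age[k]),
                "gender": "F" if female[k] else "M",
                "site": str(site[k]),
                "education": float(education[k]),
                "CAG": float(cag[k]),
                "putamen": float(putamen[k]),
            }
            truth = 0 if group == "HC" else (3 if planted else (1 if group == "preHD" else 2))
            subjects.append(
                SyntheticSubject(
                    subject_id=f"sub-{counter:03d}",
                    group=group,
                    covariates=covs,
                    params=params,
                    cluster_truth=truth,
                )
            )
            counter += 1

    if with_bold:
        _simulate_cohort_bold(subjects, net, design, spec, rngs["noise"], tr, n_volumes)
    if with_behavior:
        for sub in subjects:
            sub.press_log = generate_press_log(
                sub.group, design, rngs["behavior"],
                jitter_by_group=spec.behavior_jitter_sd,
                correct_prob=spec.correct_button_prob,
                lag_mean=spec.press_lag_mean,
                subject_id=sub.subject_id,
            )
    return subjects


def _simulate_cohort_bold(subjects, net, design, spec, rng, tr, n_volumes):
    """Batched noise-free simulation, then per-region noise at the SNR."""
    R = net.n_regions
    J = len(net.inputs)
    nb = len(subjects)
    A = np.stack([s.params.A for s in subjects])
    B = np.zeros((nb, J, R, R))
    for j, inp in enumerate(net.inputs):
        for b, s in enumerate(subjects):
            if inp in s.params.B:
                B[b, j] = s.params.B[inp]
    C = np.stack([s.params.C for s in subjects])
    hemo = HemoParams()
    tau = np.tile(hemo.tau_vector(R), (nb, 1))
    y = simulate_bold_batch(A, B, C, design, hemo, tau, tr=tr, n_volumes=n_volumes)
    signal_sd = y.std(axis=1)  # (nb, R)
    noise_sd = signal_sd / spec.snr
    noise = rng.standard_normal(y.shape) * noise_sd[:, None, :]
    for b, s in enumerate(subjects):
        s.timeseries = ROITimeSeries(data=y[b] + noise[b], tr=tr, labels=net.regions)
        s.params = s.params.with_noise(float(noise_sd[b].mean()))


def covariate_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append({"subject": s.subject_id, "group": s.group,
                     **s.covariates, "cluster_truth": s.cluster_truth})
    return pd.DataFrame(rows)


def true_coupling_table(
    subjects: list[SyntheticSubject], net: NetworkSpec | None = None
) -> pd.DataFrame:
    """Ground-truth couplings, one labeled column per free entry."""
    net = net or winning_model_preset()
    keys = _coupling_keys(net)
    rows = []
    for s in subjects:
        row = {"subject": s.subject_id, "group": s.group}
        for kind, inp, i, j in keys:
            if kind == "A":
                label = f"A:{net.regions[i]}<-{net.regions[j]}"
                row[label] = s.params.A[i, j]
            elif kind == "B":
                label = f"B:{inp}:{net.regions[i]}<-{net.regions[j]}"
                row[label] = s.params.B[inp][i, j]
            else:
                label = f"C:{inp}:{net.regions[i]}"
                row[label] = s.params.C[i, j]
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(subjects: list[SyntheticSubject], outdir, design: StimulusDesign) -> None:
    """Emit the cohort directory tree (covariates, time series, logs, truth)."""
    from .behavior import write_press_log
    from .paradigm import write_events_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    covariate_table(subjects).to_csv(out / "covariates.csv", index=False)
    write_events_tsv(design.schedule, out / "events.tsv")
    truth = {}
    for s in subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        if s.timeseries is not None:
            pd.DataFrame(s.timeseries.data, columns=list(s.timeseries.labels)).to_csv(
                sdir / "timeseries.csv", index=False
            )
            (sdir / "timeseries.json").write_text(
                json.dumps({"tr": s.timeseries.tr})
            )
        if s.press_log is not None:
            write_press_log(s.press_log, sdir / "presses.tsv")
        truth[s.subject_id] = {
            "group": s.group,
            "cluster_truth": s.cluster_truth,
            "A": s.params.A.tolist(),
            "B": {k: v.tolist() for k, v in s.params.B.items()},
            "C": s.params.C.tolist(),
            "noise_sd": s.params.noise_sd,
        }
    (out / "truth.json").write_text(json.dumps(truth))
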