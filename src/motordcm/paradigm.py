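"""Paced finger-tapping block design and model input functions.

The task crosses sequence complexity (simple ``1-2-3-4`` vs complex
``4-2-3-1``) with metronome speed (0.5 vs 1.5 Hz) and adds auditory rest
blocks at both speeds: six block types of 20 s, each repeated five times in
a pseudo-randomised order in the default design.  Three model inputs are
derived from the schedule on a microtime grid:

``task``
    1 during the four tapping block types (drives bilateral SPC).
``complexity``
    1 during the two complex tapping block types.
``speed``
    1 during fast tapping blocks (optionally also during rest-fast).

The scan comprises 225 volumes at TR = 3 s with the first four discarded,
so the analysed run is 221 volumes = 663 s.  Thirty 20-s blocks preceded by
2-s instruction gaps fill 660 s; the default 3-s lead-in aligns the
schedule with the analysed scan length.  Both gaps are explicit parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = (
    "simple-slow",
    "simple-fast",
    "complex-slow",
    "complex-fast",
    "rest-slow",
    "rest-fast",
)
TAPPING_CONDITIONS: tuple[str, ...] = (
    "simple-slow",
    "simple-fast",
    "complex-slow",
    "complex-fast",
)
#: metronome click rates in Hz by speed level
CLICK_RATES: dict[str, float] = {"slow": 0.5, "fast": 1.5}

TR_DEFAULT = 3.0
N_VOLUMES_DEFAULT = 221  # 225 acquired minus 4 discarded
BLOCK_DURATION_DEFAULT = 20.0
INSTRUCTION_GAP_DEFAULT = 2.0
LEAD_IN_DEFAULT = 3.0


def condition_speed(label: str) -> str:
    return label.split("-")[1]


def condition_rate(label: str) -> float:
    return CLICK_RATES[condition_speed(label)]


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered, non-overlapping block layout of one scanning run."""

    blocks: tuple[tuple[str, float, float], ...]  # (label, onset s, duration s)
    lead_in: float = LEAD_IN_DEFAULT
    instruction_gap: float = INSTRUCTION_GAP_DEFAULT

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_label = None
        for label, onset, dur in self.blocks:
            if label not in CONDITIONS:
                raise ValueError(f"unknown condition label {label!r}")
            if dur <= 0:
                raise ValueError("block duration must be positive")
            if onset < prev_end - 1e-9:
                raise ValueError("blocks overlap or are out of order")
            if label == prev_label:
                raise ValueError("two consecutive blocks share a condition")
            prev_end = onset + dur
            prev_label = label

    @property
    def end_time(self) -> float:
        label, onset, dur = self.blocks[-1]
        return onset + dur

    def to_events(self) -> pd.DataFrame:
        """BIDS-events-like table (onset, duration, trial_type)."""
        return pd.DataFrame(
            [(o, d, lbl) for lbl, o, d in self.blocks],
            columns=["onset", "duration", "trial_type"],
        )

    @classmethod
    def from_events(cls, events: pd.DataFrame, **kwargs) -> "BlockSchedule":
        blocks = tuple(
            (str(r.trial_type), float(r.onset), float(r.duration))
            for r in events.itertuples()
        )
        return cls(blocks=blocks, **kwargs)


@dataclass(frozen=True)
class StimulusDesign:
    """Block schedule plus input functions sampled on a microtime grid."""

    schedule: BlockSchedule
    dt: float
    u: np.ndarray = field(repr=False)  # (n_bins, 3): task, complexity, speed
    click_times: tuple[tuple[float, ...], ...]  # per block
    click_rates: tuple[float, ...]  # Hz per block
    input_names: tuple[str, ...] = ("task", "complexity", "speed")

    @property
    def n_bins(self) -> int:
        return self.u.shape[0]

    @property
    def total_scan(self) -> float:
        return self.n_bins * self.dt

    def centered_inputs(self) -> np.ndarray:
        """Copy of ``u`` with the modulatory columns mean-centred."""
        uc = self.u.astype(float).copy()
        uc[:, 1:] -= uc[:, 1:].mean(axis=0)
        return uc

    def inputs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.u, columns=list(self.input_names))


def _pseudo_random_order(
    labels: tuple[str, ...], n_reps: int, rng: np.random.Generator, max_tries: int = 10_000
) -> list[str]:
    """Uniform shuffle rejected until no two consecutive labels repeat."""
    pool = list(labels) * n_reps
    for _ in range(max_tries):
        order = list(rng.permutation(pool))
        if all(a != b for a, b in zip(order, order[1:])):
            return order
    raise RuntimeError(
        "could not find a pseudo-randomised order without consecutive repeats"
    )


def block_click_times(label: str, onset: float, duration: float) -> tuple[float, ...]:
    """Metronome click times of one block: spacing 1/rate from block onset."""
    rate = condition_rate(label)
    n = int(np.floor(duration * rate + 1e-9))
    return tuple(onset + k / rate for k in range(n))


def build_paradigm(
    n_reps: int = 5,
    block_duration: float = BLOCK_DURATION_DEFAULT,
    seed: int = 0,
    *,
    instruction_gap: float = INSTRUCTION_GAP_DEFAULT,
    lead_in: float = LEAD_IN_DEFAULT,
    dt: float = TR_DEFAULT / 16,
    total_scan: float | None = None,
    speed_during_rest: bool = False,
) -> StimulusDesign:
    """Construct a seeded pseudo-randomised tapping design.

    Six block types x ``n_reps`` repetitions, each ``block_duration`` s,
    each preceded by an instruction gap.  Rest blocks carry metronome
    clicks but require no presses.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if block_duration <= 0:
        raise ValueError("block_duration must be positive")
    rng = np.random.default_rng(seed)
    order = _pseudo_random_order(CONDITIONS, n_reps, rng)
    blocks = []
    t = lead_in
    for label in order:
        t += instruction_gap
        blocks.append((label, t, block_duration))
        t += block_duration
    schedule = BlockSchedule(
        blocks=tuple(blocks), lead_in=lead_in, instruction_gap=instruction_gap
    )
    if total_scan is None:
        total_scan = schedule.end_time
    return inputs_at_microtime(
        schedule, dt, total_scan, speed_during_rest=speed_during_rest
    )


def inputs_at_microtime(
    schedule: BlockSchedule,
    dt: float,
    total_scan: float,
    *,
    speed_during_rest: bool = False,
    tr: float | None = None,
) -> StimulusDesign:
    """Sample boxcar input functions on a microtime grid.

    ``task`` marks tapping blocks, ``complexity`` complex tapping blocks,
    ``speed`` fast tapping blocks (plus rest-fast when
    ``speed_during_rest``).  Values are 0/1; any mean-centring is left to
    :meth:`StimulusDesign.centered_inputs`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if total_scan < schedule.end_time - 1e-9:
        raise ValueError("total_scan shorter than the schedule")
    if tr is not None:
        ratio = tr / dt
        if abs(ratio - round(ratio)) > 1e-6:
            warnings.warn(
                f"dt={dt} does not divide the repetition time {tr}; "
                "volume sampling will resample to the nearest microtime bin",
                stacklevel=2,
            )
    n_bins = int(np.ceil(total_scan / dt - 1e-9))
    u = np.zeros((n_bins, 3))
    clicks = []
    rates = []
    for label, onset, dur in schedule.blocks:
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + dur) / dt)), n_bins)
        tapping = label in TAPPING_CONDITIONS
        if tapping:
            u[i0:i1, 0] = 1.0
        if label.startswith("complex"):
            u[i0:i1, 1] = 1.0
        if label.endswith("fast") and (tapping or speed_during_rest):
            u[i0:i1, 2] = 1.0
        clicks.append(block_click_times(label, onset, dur))
        rates.append(condition_rate(label))
    return StimulusDesign(
        schedule=schedule,
        dt=dt,
        u=u,
        click_times=tuple(clicks),
        click_rates=tuple(rates),
    )


def resample_design(design: StimulusDesign, dt: float) -> StimulusDesign:
    """Rebuild the input functions of an existing design on a new grid."""
    if abs(dt - design.dt) < 1e-12:
        return design
    speed_rest = _speed_during_rest(design)
    return inputs_at_microtime(
        design.schedule, dt, design.total_scan, speed_during_rest=speed_rest
    )


def _speed_during_rest(design: StimulusDesign) -> bool:
    for (label, onset, dur) in design.schedule.blocks:
        if label == "rest-fast":
            i0 = int(round(onset / design.dt))
            return bool(design.u[i0, 2] > 0)
    return False


def schedule_from_inputs(design: StimulusDesign) -> list[tuple[str, float, float]]:
    """Reconstruct (coarse) block intervals from the u matrix.

    Used as a round-trip check: returns (kind, onset, duration) intervals at
    dt resolution, where kind is a condition label for tapping blocks.
    """
    u = design.u
    dt = design.dt
    out = []
    in_block = False
    start = 0
    for i in range(u.shape[0] + 1):
        active = i < u.shape[0] and u[i, 0] > 0
        if active and not in_block:
            in_block, start = True, i
        elif not active and in_block:
            in_block = False
            comp = "complex" if u[start, 1] > 0 else "simple"
            spd = "fast" if u[start, 2] > 0 else "slow"
            out.append((f"{comp}-{spd}", start * dt, (i - start) * dt))
    return out


def write_events_tsv(schedule: BlockSchedule, path) -> None:
    schedule.to_events().to_csv(path, sep="\t", index=False)


def read_events_tsv(path, **kwargs) -> BlockSchedule:
    return BlockSchedule.from_events(pd.read_csv(path, sep="\t"), **kwargs)
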