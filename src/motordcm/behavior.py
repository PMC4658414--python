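"""Scoring of paced finger-tapping press logs.

Buttons 1-4 map to index, middle, ring and little finger of the right
hand.  The expected sequence is 1-2-3-4 for simple blocks and 4-2-3-1 for
complex blocks, cycled for as long as the metronome runs.  Timing
inaccuracy is the signed cue-response interval between each metronome
click and the button press matched to it (positive = late); a block's
score is the mean and sample SD of those intervals.

Mistake rules: a single omitted or wrongly added press counts as one
mistake, as does a wrong button at a matched click.  When a block
accumulates more than two mistakes, accuracy is re-scored by crediting
only maximal runs of three or more presses that follow the cyclic expected
order.  Subjects scoring below 50% accuracy overall, or performing a
completely wrong condition (e.g. the simple sequence during a complex
block, or pressing throughout rest), are flagged for exclusion.

The disease burden score is DBS = age x (CAG - 35.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import TAPPING_CONDITIONS

SEQUENCES: dict[str, tuple[int, ...]] = {"simple": (1, 2, 3, 4), "complex": (4, 2, 3, 1)}
MISTAKE_RESCORE_THRESHOLD = 2
EXCLUSION_ACCURACY = 50.0


def expected_sequence(condition: str) -> tuple[int, ...] | None:
    """Cyclic finger sequence of a condition; None for rest."""
    kind = condition.split("-")[0]
    return SEQUENCES.get(kind)


@dataclass(frozen=True)
class PressBlock:
    """One block's press record with its cues."""

    condition: str
    clicks: tuple[float, ...]
    press_times: tuple[float, ...]
    press_buttons: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.press_times) != len(self.press_buttons):
            raise ValueError("press times and buttons differ in length")
        if any(b < a - 1e-12 for a, b in zip(self.press_times, self.press_times[1:])):
            raise ValueError("press times must be non-decreasing")


@dataclass(frozen=True)
class PressLog:
    """All blocks of one subject's run."""

    subject_id: str
    blocks: tuple[PressBlock, ...]


@dataclass(frozen=True)
class BlockScore:
    condition: str
    mean_inaccuracy: float  # s; NaN when no press was matched
    sd_inaccuracy: float  # s; NaN when fewer than 2 matches
    accuracy_pct: float
    n_mistakes: int
    wrong_condition: bool
    n_clicks: int
    flagged_empty: bool = False


def _match_presses(
    clicks: np.ndarray, press_times: np.ndarray, window: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-click matching within +/- window.

    Returns (match index per press, -1 for unmatched additions; press index
    per click, -1 for omissions).  When two presses claim one click the
    earlier press wins and the later counts as an addition.
    """
    press_match = np.full(len(press_times), -1, dtype=int)
    click_match = np.full(len(clicks), -1, dtype=int)
    for p, t in enumerate(press_times):
        if len(clicks) == 0:
            break
        c = int(np.argmin(np.abs(clicks - t)))
        if abs(clicks[c] - t) <= window and click_match[c] == -1:
            press_match[p] = c
            click_match[c] = p
    return press_match, click_match


def _credited_runs(buttons: np.ndarray, seq: tuple[int, ...], min_run: int = 3) -> int:
    """Presses inside maximal runs >= min_run that follow the cyclic order."""
    if len(buttons) == 0:
        return 0
    nxt = {seq[i]: seq[(i + 1) % len(seq)] for i in range(len(seq))}
    credited = 0
    run = 1 if buttons[0] in seq else 0
    for prev, cur in zip(buttons, buttons[1:]):
        if run > 0 and cur == nxt.get(prev):
            run += 1
        else:
            if run >= min_run:
                credited += run
            run = 1 if cur in seq else 0
    if run >= min_run:
        credited += run
    return credited


def _accuracy_against(block: PressBlock, seq: tuple[int, ...]) -> tuple[float, int]:
    """(accuracy %, mistakes) of a tapping block against a given sequence."""
    clicks = np.asarray(block.clicks, dtype=float)
    times = np.asarray(block.press_times, dtype=float)
    buttons = np.asarray(block.press_buttons, dtype=int)
    ici = float(np.median(np.diff(clicks))) if len(clicks) > 1 else 1.0
    press_match, click_match = _match_presses(clicks, times, ici / 2.0)
    expected = np.array([seq[k % len(seq)] for k in range(len(clicks))])
    matched = press_match >= 0
    correct = np.zeros(len(times), dtype=bool)
    correct[matched] = buttons[matched] == expected[press_match[matched]]
    n_omissions = int(np.sum(click_match == -1))
    n_additions = int(np.sum(~matched))
    n_wrong = int(np.sum(matched & ~correct))
    mistakes = n_omissions + n_additions + n_wrong
    if mistakes > MISTAKE_RESCORE_THRESHOLD:
        credited = _credited_runs(buttons, seq)
        credited = min(credited, len(clicks))
    else:
        credited = int(np.sum(correct))
    accuracy = 100.0 * credited / len(clicks) if len(clicks) else 0.0
    return accuracy, mistakes


def score_block(block: PressBlock) -> BlockScore:
    """Score one block: timing inaccuracy, accuracy and mistake count."""
    if len(block.clicks) == 0:
        raise ValueError("a block must contain at least one click")
    clicks = np.asarray(block.clicks, dtype=float)
    times = np.asarray(block.press_times, dtype=float)
    seq = expected_sequence(block.condition)

    if seq is None:  # rest: expected silence
        n_press = len(times)
        wrong = n_press >= 0.5 * len(clicks)
        return BlockScore(
            condition=block.condition,
            mean_inaccuracy=float("nan"),
            sd_inaccuracy=float("nan"),
            accuracy_pct=100.0 if n_press == 0 else max(0.0, 100.0 * (1 - n_press / len(clicks))),
            n_mistakes=n_press,
            wrong_condition=bool(wrong),
            n_clicks=len(clicks),
            flagged_empty=False,
        )

    if len(times) == 0:
        return BlockScore(
            condition=block.condition,
            mean_inaccuracy=float("nan"),
            sd_inaccuracy=float("nan"),
            accuracy_pct=0.0,
            n_mistakes=len(clicks),
            wrong_condition=False,
            n_clicks=len(clicks),
            flagged_empty=True,
        )

    ici = float(np.median(np.diff(clicks))) if len(clicks) > 1 else 1.0
    press_match, _ = _match_presses(clicks, times, ici / 2.0)
    matched = press_match >= 0
    intervals = times[matched] - clicks[press_match[matched]]
    mean_i = float(np.mean(intervals)) if len(intervals) else float("nan")
    sd_i = float(np.std(intervals, ddof=1)) if len(intervals) > 1 else float("nan")

    accuracy, mistakes = _accuracy_against(block, seq)
    alt = SEQUENCES["complex" if seq == SEQUENCES["simple"] else "simple"]
    acc_alt, _ = _accuracy_against(block, alt)
    wrong = accuracy < 50.0 <= acc_alt
    return BlockScore(
        condition=block.condition,
        mean_inaccuracy=mean_i,
        sd_inaccuracy=sd_i,
        accuracy_pct=accuracy,
        n_mistakes=mistakes,
        wrong_condition=bool(wrong),
        n_clicks=len(clicks),
    )


@dataclass(frozen=True)
class SubjectSummary:
    per_condition: pd.DataFrame = field(repr=False)
    overall_accuracy: float = float("nan")
    excluded: bool = False


def subject_summary(scores: list[BlockScore]) -> SubjectSummary:
    """Aggregate block scores by tapping condition and flag exclusions.

    Excluded when click-weighted accuracy over tapping blocks is below 50%
    or any block was performed as a wrong condition.
    """
    if not scores:
        raise ValueError("at least one scored block is required")
    tapping = [s for s in scores if s.condition in TAPPING_CONDITIONS]
    rows = []
    for cond in TAPPING_CONDITIONS:
        blocks = [s for s in tapping if s.condition == cond]
        if not blocks:
            continue
        means = [s.mean_inaccuracy for s in blocks if np.isfinite(s.mean_inaccuracy)]
        sds = [s.sd_inaccuracy for s in blocks if np.isfinite(s.sd_inaccuracy)]
        rows.append(
            {
                "condition": cond,
                "mean_inaccuracy": float(np.mean(means)) if means else float("nan"),
                "sd_inaccuracy": float(np.mean(sds)) if sds else float("nan"),
                "accuracy_pct": float(np.mean([s.accuracy_pct for s in blocks])),
                "n_mistakes": int(np.sum([s.n_mistakes for s in blocks])),
                "n_blocks": len(blocks),
            }
        )
    table = pd.DataFrame(rows)
    if tapping:
        weights = np.array([s.n_clicks for s in tapping], dtype=float)
        acc = np.array([s.accuracy_pct for s in tapping])
        overall = float(np.sum(weights * acc) / np.sum(weights))
    else:
        overall = float("nan")
    wrong_any = any(s.wrong_condition for s in scores)
    excluded = bool(wrong_any or (np.isfinite(overall) and overall < EXCLUSION_ACCURACY))
    return SubjectSummary(per_condition=table, overall_accuracy=overall, excluded=excluded)


def dbs(age: float, cag: float) -> float:
    """Disease burden score: age x (CAG - 35.5)."""
    if age < 0:
        raise ValueError("age must be non-negative")
    return age * (cag - 35.5)


def score_log(log: PressLog) -> tuple[list[BlockScore], SubjectSummary]:
    scores = [score_block(b) for b in log.blocks]
    return scores, subject_summary(scores)


def write_press_log(log: PressLog, path) -> None:
    """Tab-separated press table: time, button, block_id."""
    rows = []
    for k, block in enumerate(log.blocks):
        for t, b in zip(block.press_times, block.press_buttons):
            rows.append({"time": t, "button": b, "block_id": k})
    pd.DataFrame(rows, columns=["time", "button", "block_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_press_log(path, design, subject_id: str = "") -> PressLog:
    """Re-attach a press table to a design's blocks and click times."""
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for k, (label, onset, dur) in enumerate(design.schedule.blocks):
        sel = df[df.block_id == k].sort_values("time")
        blocks.append(
            PressBlock(
                condition=label,
                clicks=design.click_times[k],
                press_times=tuple(float(t) for t in sel.time),
                press_buttons=tuple(int(b) for b in sel.button),
            )
        )
    return PressLog(subject_id=subject_id, blocks=tuple(blocks))
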