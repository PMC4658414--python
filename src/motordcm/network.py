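"""Seven-region motor network structure.

Defines :class:`NetworkSpec` (which couplings are permitted) and the two
presets used throughout the package: the full model in which all
hypothesised connections are switched on, and the winning model obtained
after post-hoc reduction, in which the modulatory influences originating in
right dorsal premotor cortex and three complexity modulations out of pre-SMA
are removed.

Conventions
-----------
* Region order is fixed: ``pSMA, cSMA, lM1, lPMd, rPMd, lSPC, rSPC``.
* ``A[i, j]`` couples *from* region ``j`` *to* region ``i`` (target row,
  source column).
* Input order is fixed: ``task, complexity, speed``.  Only the task input
  drives regions directly (via bilateral superior parietal cortex); the two
  modulatory inputs act on connections through the B matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

REGIONS: tuple[str, ...] = ("pSMA", "cSMA", "lM1", "lPMd", "rPMd", "lSPC", "rSPC")
INPUTS: tuple[str, ...] = ("task", "complexity", "speed")
MODULATORY_INPUTS: tuple[str, ...] = ("complexity", "speed")

#: MNI coordinates (mm) of the regions of interest (metadata only).
MNI_COORDS: dict[str, tuple[float, float, float]] = {
    "pSMA": (-8.0, 11.0, 45.0),
    "cSMA": (-5.0, -5.0, 51.0),
    "lM1": (-38.0, -12.0, 53.0),
    "lPMd": (-24.0, -4.0, 46.0),
    "rPMd": (26.0, -3.0, 47.0),
    "lSPC": (-16.0, -63.0, 58.0),
    "rSPC": (15.0, -66.0, 58.0),
}

# Reciprocally connected region pairs of the full model.  15 pairs = 30
# directed off-diagonal couplings.  pSMA and lM1 are deliberately not
# connected directly (their influence is routed via lPMd / cSMA).
_INTRINSIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("pSMA", "cSMA"),
    ("pSMA", "lPMd"),
    ("pSMA", "rPMd"),
    ("pSMA", "lSPC"),
    ("pSMA", "rSPC"),
    ("cSMA", "lM1"),
    ("cSMA", "lPMd"),
    ("cSMA", "rPMd"),
    ("lM1", "lPMd"),
    ("lPMd", "rPMd"),
    ("lPMd", "lSPC"),
    ("rPMd", "rSPC"),
    ("rPMd", "lSPC"),
    ("lPMd", "rSPC"),
    ("lSPC", "rSPC"),
)

# Directed modulatory couplings (target <- source) of the full model:
# 10 complexity + 7 speed = 17.
_B_COMPLEXITY: tuple[tuple[str, str], ...] = (
    ("lPMd", "lSPC"),
    ("rPMd", "rSPC"),
    ("lSPC", "pSMA"),
    ("rSPC", "pSMA"),
    ("cSMA", "pSMA"),
    ("pSMA", "lSPC"),
    ("pSMA", "rSPC"),
    ("rSPC", "rPMd"),
    ("pSMA", "rPMd"),
    ("lM1", "lPMd"),
)
_B_SPEED: tuple[tuple[str, str], ...] = (
    ("pSMA", "cSMA"),
    ("pSMA", "rSPC"),
    ("lM1", "cSMA"),
    ("cSMA", "lM1"),
    ("rSPC", "rPMd"),
    ("rPMd", "rSPC"),
    ("cSMA", "rPMd"),
)

# Modulatory couplings absent from the winning model: everything leaving
# rPMd, plus the complexity modulations out of pSMA.
_WINNING_REMOVED: tuple[tuple[str, str, str], ...] = (
    ("complexity", "rSPC", "rPMd"),
    ("complexity", "pSMA", "rPMd"),
    ("complexity", "lSPC", "pSMA"),
    ("complexity", "rSPC", "pSMA"),
    ("complexity", "cSMA", "pSMA"),
    ("speed", "rSPC", "rPMd"),
    ("speed", "cSMA", "rPMd"),
)


@dataclass(frozen=True)
class NetworkSpec:
    """Permission structure of a dynamic causal model.

    Boolean masks say which entries of the coupling matrices are allowed to
    be non-zero.  ``A_mask`` always has a true diagonal (every region has a
    self-decay).
    """

    regions: tuple[str, ...]
    coords: dict[str, tuple[float, float, float]] = field(repr=False)
    A_mask: np.ndarray = field(repr=False)
    B_masks: dict[str, np.ndarray] = field(repr=False)
    C_mask: np.ndarray = field(repr=False)
    inputs: tuple[str, ...] = INPUTS

    def __post_init__(self) -> None:
        R = len(self.regions)
        if self.A_mask.shape != (R, R):
            raise ValueError("A_mask shape does not match region count")
        if not np.all(np.diag(self.A_mask)):
            raise ValueError("A_mask diagonal must be all true (self-decay)")
        for name, mask in self.B_masks.items():
            if mask.shape != (R, R):
                raise ValueError(f"B_mask[{name}] shape mismatch")
            offdiag = mask & ~np.eye(R, dtype=bool)
            if np.any(offdiag & ~self.A_mask):
                raise ValueError(f"B_mask[{name}] permits entries outside A_mask")
        if self.C_mask.shape != (R, len(self.inputs)):
            raise ValueError("C_mask shape mismatch")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def index(self, region: str) -> int:
        return self.regions.index(region)

    def to_json(self) -> str:
        return json.dumps(
            {
                "regions": list(self.regions),
                "coords": {r: list(c) for r, c in self.coords.items()},
                "inputs": list(self.inputs),
                "A_mask": self.A_mask.astype(int).tolist(),
                "B_masks": {k: v.astype(int).tolist() for k, v in self.B_masks.items()},
                "C_mask": self.C_mask.astype(int).tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            regions=tuple(d["regions"]),
            coords={r: tuple(c) for r, c in d["coords"].items()},
            A_mask=np.asarray(d["A_mask"], dtype=bool),
            B_masks={k: np.asarray(v, dtype=bool) for k, v in d["B_masks"].items()},
            C_mask=np.asarray(d["C_mask"], dtype=bool),
            inputs=tuple(d["inputs"]),
        )


def _pair_mask() -> np.ndarray:
    R = len(REGIONS)
    idx = {r: i for i, r in enumerate(REGIONS)}
    A = np.eye(R, dtype=bool)
    # deduplicate the pair list while preserving intent (15 unique pairs)
    pairs = {frozenset(p) for p in _INTRINSIC_PAIRS}
    for p in pairs:
        a, b = tuple(p)
        A[idx[a], idx[b]] = True
        A[idx[b], idx[a]] = True
    return A


def _edges_to_mask(edges: tuple[tuple[str, str], ...]) -> np.ndarray:
    R = len(REGIONS)
    idx = {r: i for i, r in enumerate(REGIONS)}
    M = np.zeros((R, R), dtype=bool)
    for tgt, src in edges:
        M[idx[tgt], idx[src]] = True
    return M


def motor_network_preset() -> NetworkSpec:
    """Full seven-region model: 30 intrinsic and 17 modulatory couplings.

    All experimental input enters through bilateral superior parietal
    cortex; no direct coupling between pre-SMA and M1.
    """
    R = len(REGIONS)
    C = np.zeros((R, len(INPUTS)), dtype=bool)
    C[REGIONS.index("lSPC"), INPUTS.index("task")] = True
    C[REGIONS.index("rSPC"), INPUTS.index("task")] = True
    return NetworkSpec(
        regions=REGIONS,
        coords=dict(MNI_COORDS),
        A_mask=_pair_mask(),
        B_masks={
            "complexity": _edges_to_mask(_B_COMPLEXITY),
            "speed": _edges_to_mask(_B_SPEED),
        },
        C_mask=C,
    )


def winning_model_preset() -> NetworkSpec:
    """Reduced model selected by post-hoc search (same intrinsic structure).

    Removes every modulatory influence whose source is rPMd and the
    complexity modulations from pSMA to cSMA and bilateral SPC.
    """
    full = motor_network_preset()
    idx = {r: i for i, r in enumerate(REGIONS)}
    B = {k: v.copy() for k, v in full.B_masks.items()}
    for inp, tgt, src in _WINNING_REMOVED:
        B[inp][idx[tgt], idx[src]] = False
    return NetworkSpec(
        regions=full.regions,
        coords=dict(full.coords),
        A_mask=full.A_mask.copy(),
        B_masks=B,
        C_mask=full.C_mask.copy(),
    )


def count_connections(spec: NetworkSpec) -> tuple[int, int]:
    """Count (intrinsic, modulatory) couplings.

    Intrinsic counts permitted off-diagonal A entries (self-connections are
    always present and not counted); modulatory counts all permitted B
    entries over every modulatory input.
    """
    off = spec.A_mask & ~np.eye(spec.n_regions, dtype=bool)
    n_intrinsic = int(off.sum())
    n_modulatory = int(sum(int(m.sum()) for m in spec.B_masks.values()))
    return n_intrinsic, n_modulatory
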