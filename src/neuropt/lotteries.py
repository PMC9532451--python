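"""The lottery stimulus space.

A lottery pays a liquid-reward magnitude ``m`` (mL) with probability ``p``
and nothing otherwise.  The task presents lotteries from a fixed 10 x 10
grid: p in {0.1, ..., 1.0} and m in {0.1, ..., 1.0} mL, i.e. 100 unique
cues.  External data may be off-grid, but p must stay strictly positive
because the Prelec weight needs log(p) finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRID_LEVELS = np.round(np.arange(1, 11) * 0.1, 10)


@dataclass(frozen=True)
class Lottery:
    """A (probability, magnitude) reward cue."""

    p: float
    m: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"reward probability must lie in (0, 1], got {self.p}")
        if self.m <= 0.0:
            raise ValueError(f"reward magnitude must be positive, got {self.m}")


def make_lottery_grid() -> list[Lottery]:
    """Return the task's 100 lotteries: the Cartesian grid {0.1..1.0} x {0.1..1.0}."""
    return [Lottery(float(p), float(m)) for p in GRID_LEVELS for m in GRID_LEVELS]


def grid_arrays() -> tuple[np.ndarray, np.ndarray]:
    """Vectorized grid: arrays of p and m for the 100 lotteries, p-major order."""
    pp, mm = np.meshgrid(GRID_LEVELS, GRID_LEVELS, indexing="ij")
    return pp.ravel(), mm.ravel()


def on_grid(p: float, m: float, atol: float = 1e-9) -> bool:
    """True if (p, m) is one of the 100 task lotteries."""
    return bool(
        np.any(np.isclose(p, GRID_LEVELS, atol=atol))
        and np.any(np.isclose(m, GRID_LEVELS, atol=atol))
    )
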