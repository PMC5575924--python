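"""Chromosomal-position standardization and uniformity testing.

Replicons differ in length, so array start coordinates are standardized to
a common circle: ``degrees = (start_bp / replicon_length) * 360``, wrapped
into [0, 360).  Polar histograms round each position to the nearest integer
degree (359.5 and above wrap to bin 0), giving a 360-bin circular histogram
of where arrays begin.

Uniformity of the *unrounded* positions is tested with a one-sample K-S
test of degrees/360 against Uniform(0, 1); rounding is for display only.
Note the K-S statistic is anchored at the 0-degree origin (the deposited
sequence start): it is not rotation-invariant, which is a property of the
method, not a defect.  Groups with fewer than ``min_n`` positions are
flagged as underpowered rather than suppressed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .records import IntegratedSystem

UNDERPOWERED_N = 30


@dataclass(frozen=True)
class CircularPosition:
    degrees: float
    strand: str
    accession: str

    def __post_init__(self):
        if not (0.0 <= self.degrees < 360.0):
            raise ValueError(f"degrees must be in [0, 360), got {self.degrees}")


@dataclass(frozen=True)
class PolarHistogram:
    bin_counts: np.ndarray  # 360 ints, index = degree
    strand: Optional[str]
    total: int


@dataclass(frozen=True)
class UniformityResult:
    statistic_D: float
    p_value: float
    n: int
    strand: Optional[str]
    underpowered: bool


def standardize_location(start_bp, replicon_length) -> np.ndarray:
    """Map 1-based start coordinates to degrees on the standard circle.

    Accepts scalars or arrays; a start equal to the replicon length wraps
    to 0.0 so the result always lies in [0, 360).
    """
    start = np.asarray(start_bp, dtype=float)
    length = np.asarray(replicon_length, dtype=float)
    if np.any(start < 1) or np.any(start > length):
        raise ValueError("start_bp must satisfy 1 <= start_bp <= replicon_length")
    degrees = (start / length * 360.0) % 360.0
    # float round-off can produce exactly 360.0 before the mod; be safe
    degrees = np.where(degrees >= 360.0, degrees - 360.0, degrees)
    if np.ndim(start_bp) == 0 and np.ndim(replicon_length) == 0:
        return float(degrees)
    return degrees


def positions_from_systems(systems: Sequence[IntegratedSystem]) -> List[CircularPosition]:
    """Proximal-array start positions of integrated systems, with the
    array's strand attached."""
    return [
        CircularPosition(
            degrees=standardize_location(
                s.proximal_array.start_bp, s.proximal_array.replicon_length
            ),
            strand=s.proximal_array.strand,
            accession=s.accession,
        )
        for s in systems
    ]


def _degrees(positions) -> np.ndarray:
    if len(positions) and isinstance(positions[0], CircularPosition):
        return np.array([p.degrees for p in positions], dtype=float)
    return np.asarray(positions, dtype=float)


def polar_histogram(
    positions: Sequence, strand: Optional[str] = None
) -> PolarHistogram:
    """360-bin circular histogram at integer-degree resolution.

    Each position is rounded half-up to the nearest integer degree;
    values of 359.5 and above wrap to bin 0.
    """
    deg = _degrees(positions)
    bins = np.zeros(360, dtype=np.int64)
    if deg.size:
        idx = (np.floor(deg + 0.5).astype(np.int64)) % 360
        np.add.at(bins, idx, 1)
    return PolarHistogram(bin_counts=bins, strand=strand, total=int(deg.size))


def uniformity_test(
    positions: Sequence,
    strand: Optional[str] = None,
    min_n: int = UNDERPOWERED_N,
) -> UniformityResult:
    """One-sample K-S test of positions/360 against Uniform(0, 1).

    Uses the unrounded degrees.  Results on fewer than ``min_n`` positions
    carry ``underpowered=True`` — with too few observations the test has
    little power, so its large p-values are not evidence of uniformity.
    """
    deg = _degrees(positions)
    if deg.size < 1:
        raise ValueError("uniformity test needs at least one position")
    res = stats.kstest(deg / 360.0, "uniform")
    return UniformityResult(
        statistic_D=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(deg.size),
        strand=strand,
        underpowered=deg.size < min_n,
    )
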