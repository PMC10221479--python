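"""Arch index: equal-height thirds, per-third areas, and classification.

The arch index AI is the ratio of the middle-third footprint area to the
whole toe-free footprint area,

    AI = B / (A + B + C),

where A, B and C are the areas (pixel counts) of the front, middle and
rear thirds of the footprint height.  It is dimensionless and lies in
[0, 1].  Conventional thresholds classify the foot: AI < 0.17 indicates a
hollow foot (pes cavus), AI > 0.28 a flat foot (pes planus), and
0.17 ≤ AI ≤ 0.28 a healthy foot.

The thirds are measured over the tight bounding-box height of the cleaned
binary footprint, not the padded crop, so empty margins cannot dilute the
band heights.  Band boundaries use round-half-up at H/3 and 2H/3; any
leftover rows therefore land in the middle band, never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DomainError, EmptyFootprintError
from .toe_removal import BinaryFootprint

__all__ = [
    "FootCategory",
    "ThirdsAreas",
    "ArchIndexResult",
    "CAVUS_THRESHOLD",
    "PLANUS_THRESHOLD",
    "split_thirds",
    "measure_areas",
    "arch_index",
    "classify",
    "compute_arch_index",
]

#: Literature decision boundaries on the arch index.
CAVUS_THRESHOLD = 0.17
PLANUS_THRESHOLD = 0.28


class FootCategory(Enum):
    PES_CAVUS = "pes_cavus"
    HEALTHY = "healthy"
    PES_PLANUS = "pes_planus"


@dataclass(frozen=True)
class ThirdsAreas:
    """Foreground areas (pixel counts) of the three height bands."""

    a: int  # front / forefoot, top third
    b: int  # middle third
    c: int  # rear / heel, bottom third

    @property
    def total(self) -> int:
        return self.a + self.b + self.c


@dataclass(frozen=True)
class ArchIndexResult:
    ai: float
    category: FootCategory
    thirds: ThirdsAreas


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_thirds(height: int) -> list[tuple[int, int]]:
    """Partition ``height`` rows into three equal-height bands.

    Returns half-open row intervals [(0, b1), (b1, b2), (b2, H)] with
    b1 = round(H/3) and b2 = round(2H/3) (round half up).  The bands
    always partition all rows.
    """
    if height < 3:
        raise EmptyFootprintError(f"footprint height {height} < 3: cannot split thirds")
    b1 = _round_half_up(height / 3.0)
    b2 = _round_half_up(2.0 * height / 3.0)
    return [(0, b1), (b1, b2), (b2, height)]


def measure_areas(mask: np.ndarray, bands: list[tuple[int, int]]) -> ThirdsAreas:
    """Foreground pixel counts in the top, middle and bottom bands."""
    mask = np.asarray(mask, dtype=bool)
    counts = [int(mask[lo:hi].sum()) for lo, hi in bands]
    return ThirdsAreas(a=counts[0], b=counts[1], c=counts[2])


def arch_index(thirds: ThirdsAreas) -> float:
    """AI = B / (A + B + C)."""
    if thirds.total <= 0:
        raise DomainError("arch index undefined for an empty footprint")
    return thirds.b / thirds.total


def classify(
    ai: float,
    cavus_threshold: float = CAVUS_THRESHOLD,
    planus_threshold: float = PLANUS_THRESHOLD,
) -> FootCategory:
    """Map an arch index to a deformity category (boundaries are healthy)."""
    if not 0.0 <= ai <= 1.0 or not np.isfinite(ai):
        raise DomainError(f"arch index {ai} outside [0, 1]")
    if ai < cavus_threshold:
        return FootCategory.PES_CAVUS
    if ai > planus_threshold:
        return FootCategory.PES_PLANUS
    return FootCategory.HEALTHY


def compute_arch_index(
    footprint: BinaryFootprint,
    cavus_threshold: float = CAVUS_THRESHOLD,
    planus_threshold: float = PLANUS_THRESHOLD,
) -> ArchIndexResult:
    """Thirds, areas, AI and category of a cleaned binary footprint.

    The mask is first reduced to the tight bounding box of its foreground
    so the thirds span the footprint itself.
    """
    mask = np.asarray(footprint.mask, dtype=bool)
    if not mask.any():
        raise EmptyFootprintError("empty binary footprint")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    tight = mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    bands = split_thirds(tight.shape[0])
    thirds = measure_areas(tight, bands)
    ai = arch_index(thirds)
    return ArchIndexResult(
        ai=ai,
        category=classify(ai, cavus_threshold, planus_threshold),
        thirds=thirds,
    )
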