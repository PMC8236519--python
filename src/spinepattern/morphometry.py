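"""Spine silhouette morphometry: geometry, RAW/RCW metrics and classification.

The cytoskeleton field ``Y`` is bimodal (its self-switch term makes cells
settle near 0 or near 1), so thresholding at 0.5 yields a robust binary
silhouette.  A spine growing from a seed or trunk is measured only over its
*newborn* part — the rows above ``base_row``, the top row of the original
structure.

Three geometric quantities are measured from the silhouette: the height
``h``, the extreme width of the head ``w_head`` and the extreme width of the
neck ``w_neck``.  Two dimensionless shape metrics follow:

    RAW = (w_head + w_neck) / (2 h)     relative average width
    RCW = (w_head - w_neck) / h         relative constriction width

and the classification flow chart is: a branching structure is branched-type;
otherwise RAW < 0.4 is thin-type; otherwise RCW < 0.25 is stubby-type;
otherwise mushroom-type.  For a branched spine the head width is meaningless
and is not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

#: Default silhouette threshold on Y.
Y_THRESHOLD = 0.5

#: Classification thresholds.
RAW_THRESHOLD = 0.4
RCW_THRESHOLD = 0.25

SHAPE_CLASSES = ("mushroom", "stubby", "thin", "branched")


class EmptySpineError(ValueError):
    """Raised when a mask contains no spine cells above its base row."""


@dataclass(frozen=True)
class SpineMask:
    """Binary silhouette with the row separating newborn spine from its base.

    ``mask[base_row]`` and everything below belongs to the original seed or
    trunk; rows above it are the newborn spine.  ``dx`` converts pixel counts
    to physical lengths.
    """

    mask: np.ndarray
    base_row: int
    dx: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)
        if not 0 <= self.base_row < m.shape[0]:
            raise ValueError(f"base_row {self.base_row} outside mask of {m.shape[0]} rows")
        if not self.dx > 0:
            raise ValueError("dx must be positive")

    @property
    def spine_rows(self) -> np.ndarray:
        """Rows strictly above base_row (newborn part), top to bottom."""
        return self.mask[: self.base_row]


def cell_mask(Y: np.ndarray, threshold: float = Y_THRESHOLD) -> np.ndarray:
    """Binary cell silhouette: true where ``Y >= threshold``."""
    Y = np.asarray(Y)
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    return Y >= threshold


def width_profile(mask: SpineMask) -> np.ndarray:
    """Per-row physical widths of the newborn spine, tip first.

    Entry ``i`` is (number of true cells in row ``tip_row + i``) * dx; rows
    above the spine tip are excluded, so the profile has exactly
    ``h / dx`` entries.
    """
    counts = mask.spine_rows.sum(axis=1)
    occupied = np.nonzero(counts)[0]
    if occupied.size == 0:
        raise EmptySpineError("no spine cells above base_row")
    return counts[occupied[0] :] * mask.dx


def measure_spine(
    mask: SpineMask,
    head_fraction: float = 1.0,
    neck_depth: int = 8,
) -> tuple[float, float, float]:
    """Measure (h, w_head, w_neck) of a non-branched spine.

    ``h`` is the number of occupied rows above the base times ``dx``.
    ``w_head`` is the maximum row width over the distal ``head_fraction`` of
    the newborn profile (default: the whole profile — the head of a spine is
    its widest part).  ``w_neck`` is the minimum row width between the head
    row and the attachment: rows strictly below the head row within the
    newborn part, plus up to ``neck_depth`` rows of the supporting stalk
    below ``base_row``.  A spine that protrudes from a narrower stalk (the
    knob-on-stalk geometry the simulation produces) thus measures its neck
    at the junction, as a human reading the silhouette would.  When no row
    lies below the head row, ``w_neck`` falls back to ``w_head`` (no
    constriction).
    """
    if not 0 < head_fraction <= 1:
        raise ValueError("head_fraction must be in (0, 1]")
    profile = width_profile(mask)
    n = len(profile)
    h = n * mask.dx
    distal = profile[: max(1, int(np.ceil(n * head_fraction)))]
    head_idx = int(np.argmax(distal))
    w_head = float(distal[head_idx])
    candidates = list(profile[head_idx + 1 :])
    stalk = mask.mask[mask.base_row + 1 : mask.base_row + 1 + neck_depth]
    if stalk.size:
        stalk_widths = stalk.sum(axis=1) * mask.dx
        candidates.extend(float(w) for w in stalk_widths if w > 0)
    w_neck = min(candidates) if candidates else w_head
    return float(h), w_head, float(w_neck)


def raw_metric(h: float, w_head: float, w_neck: float) -> float:
    """Relative average width (w_head + w_neck) / (2 h)."""
    if not h > 0:
        raise ValueError(f"h must be positive, got {h}")
    return (w_head + w_neck) / (2.0 * h)


def rcw_metric(h: float, w_head: float, w_neck: float) -> float:
    """Relative constriction width (w_head - w_neck) / h (may be negative)."""
    if not h > 0:
        raise ValueError(f"h must be positive, got {h}")
    return (w_head - w_neck) / h


def _row_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each run of true cells in a 1-D boolean row."""
    padded = np.concatenate(([False], row, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def is_branched(
    mask: SpineMask,
    min_run: int = 2,
    min_gap: int = 2,
    min_persist: int = 3,
) -> bool:
    """Detect a branching structure in the newborn spine.

    True iff at least ``min_persist`` consecutive rows above ``base_row + 2``
    (counted from the base upward) each contain >= 2 runs of true cells, every
    run at least ``min_run`` px wide and separated by gaps of at least
    ``min_gap`` px.  Persistent multi-run rows indicate two arms; single-pixel
    roughness does not trip the detector.
    """
    rows = mask.mask[: max(mask.base_row - 2, 0)]
    streak = 0
    # scan from the tip downward; persistence is over consecutive rows
    for row in rows:
        runs = [(s, ln) for s, ln in _row_runs(row) if ln >= min_run]
        multi = False
        if len(runs) >= 2:
            for (s0, l0), (s1, _) in zip(runs, runs[1:]):
                if s1 - (s0 + l0) >= min_gap:
                    multi = True
                    break
        streak = streak + 1 if multi else 0
        if streak >= min_persist:
            return True
    return False


@dataclass(frozen=True)
class SpineMetrics:
    """Measured geometry and class of one spine."""

    h: float
    w_head: float | None
    w_neck: float
    raw: float | None
    rcw: float | None
    branched: bool
    shape_class: str

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        if self.branched != (self.shape_class == "branched"):
            raise ValueError("branched flag inconsistent with shape_class")


def classify_metrics(
    raw: float,
    rcw: float,
    branched: bool = False,
    raw_threshold: float = RAW_THRESHOLD,
    rcw_threshold: float = RCW_THRESHOLD,
) -> str:
    """Apply the classification flow chart to precomputed metrics."""
    if branched:
        return "branched"
    if raw < raw_threshold:
        return "thin"
    if rcw < rcw_threshold:
        return "stubby"
    return "mushroom"


def classify_spine(
    mask: SpineMask,
    raw_threshold: float = RAW_THRESHOLD,
    rcw_threshold: float = RCW_THRESHOLD,
    head_fraction: float = 1.0,
    neck_depth: int = 8,
) -> SpineMetrics:
    """Measure a spine silhouette and classify it.

    Branch detection runs first; for a branched spine the head width is
    undefined and ``raw``/``rcw`` are not reported.
    """
    profile = width_profile(mask)  # raises EmptySpineError if empty
    if is_branched(mask):
        h = len(profile) * mask.dx
        return SpineMetrics(
            h=float(h),
            w_head=None,
            w_neck=float(profile.min()),
            raw=None,
            rcw=None,
            branched=True,
            shape_class="branched",
        )
    h, w_head, w_neck = measure_spine(mask, head_fraction, neck_depth)
    raw = raw_metric(h, w_head, w_neck)
    rcw = rcw_metric(h, w_head, w_neck)
    cls = classify_metrics(raw, rcw, False, raw_threshold, rcw_threshold)
    return SpineMetrics(h, w_head, w_neck, raw, rcw, False, cls)


@dataclass(frozen=True)
class DensityResult:
    """Spine count and linear density along a dendrite trunk."""

    spine_count: int
    trunk_length: float
    density: float
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.spine_count < 0:
            raise ValueError("spine_count must be >= 0")
        if not np.isclose(self.density, self.spine_count / self.trunk_length):
            raise ValueError("density != spine_count / trunk_length")


def spine_density(
    mask: np.ndarray,
    trunk_band: tuple[int, int],
    dx: float = 1.0,
    min_area: int = 4,
) -> DensityResult:
    """Count spines as connected protrusions outside a trunk column band.

    ``trunk_band`` is the half-open column interval [lo, hi) covering the
    trunk.  The band is removed, remaining true cells are labelled with
    4-connectivity, and components of at least ``min_area`` px count as
    spines.  Trunk length is the trunk's occupied row extent times ``dx``.
    """
    mask = np.asarray(mask, dtype=bool)
    lo, hi = trunk_band
    trunk = mask[:, lo:hi]
    trunk_rows = np.nonzero(trunk.any(axis=1))[0]
    if trunk_rows.size == 0:
        raise EmptySpineError("trunk band contains no cells")
    trunk_length = (trunk_rows[-1] - trunk_rows[0] + 1) * dx

    pruned = mask.copy()
    pruned[:, lo:hi] = False
    labels, n = ndimage.label(pruned, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    ))
    areas = ndimage.sum_labels(pruned, labels, index=np.arange(1, n + 1))
    count = int(np.count_nonzero(areas >= min_area))
    return DensityResult(
        spine_count=count,
        trunk_length=float(trunk_length),
        density=count / float(trunk_length),
        labels=labels,
    )


def trunk_band_from_mask(trunk_mask: np.ndarray, margin: int = 1) -> tuple[int, int]:
    """Column band covering a vertical trunk: median row extent + margin.

    The band is derived from the stage-1 (pre-spine) mask so that later
    protrusions do not widen it.
    """
    trunk_mask = np.asarray(trunk_mask, dtype=bool)
    rows = [r for r in trunk_mask if r.any()]
    if not rows:
        raise EmptySpineError("trunk mask is empty")
    los, his = [], []
    for r in rows:
        cols = np.nonzero(r)[0]
        los.append(cols[0])
        his.append(cols[-1])
    lo = int(np.median(los)) - margin
    hi = int(np.median(his)) + 1 + margin
    return max(lo, 0), min(hi, trunk_mask.shape[1])


def newborn_mask(
    Y: np.ndarray,
    seed_top_row: int,
    dx: float,
    threshold: float = Y_THRESHOLD,
) -> SpineMask:
    """SpineMask of the newborn part of a single-spine simulation.

    ``seed_top_row`` is the topmost row of the initial seed rectangle; only
    rows strictly above it count as newborn spine.
    """
    return SpineMask(cell_mask(Y, threshold), base_row=seed_top_row, dx=dx)
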