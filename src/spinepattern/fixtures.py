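"""Deterministic synthetic inputs for testing without long simulations.

Parametric spine silhouettes (pixel-exact, no anti-aliasing, so morphometry
tests are bit-stable), uniform field states, and seeded random Jacobians
with the activator–inhibitor sign structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .morphometry import SpineMask
from .params import Grid
from .rd_core import FieldState
from .turing import AHJacobian

FAMILIES = ("mushroom", "stubby", "thin", "branched")


@dataclass(frozen=True)
class SpineSpec:
    """Blueprint of a synthetic spine silhouette.

    Heights/widths in pixels; the silhouette occupies rows
    ``base_row - h_px .. base_row - 1`` of the canvas (rows above
    ``base_row`` are the newborn spine, matching :class:`SpineMask`).
    """

    family: str
    h_px: int = 20
    head_w_px: int = 12
    neck_w_px: int = 4
    canvas: tuple[int, int] = (40, 40)
    base_row: int | None = None
    dx: float = 0.3

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.h_px < 5:
            raise ValueError("h_px must be >= 5")
        if min(self.head_w_px, self.neck_w_px) < 1:
            raise ValueError("widths must be >= 1 px")
        if self.base_row is None:
            object.__setattr__(self, "base_row", self.canvas[0] - 2)
        if self.h_px > self.base_row:
            raise ValueError("spine does not fit canvas above base_row")
        if max(self.head_w_px, self.neck_w_px) > self.canvas[1] - 2:
            raise ValueError("spine wider than canvas")

    def to_json(self) -> str:
        d = asdict(self)
        d["canvas"] = list(d["canvas"])
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SpineSpec":
        d = json.loads(text)
        d["canvas"] = tuple(d["canvas"])
        return cls(**d)


@dataclass(frozen=True)
class SynthSpine:
    """A rasterised spine plus its construction ground truth."""

    mask: SpineMask
    spec: SpineSpec
    true_h: float
    true_w_head: float | None
    true_w_neck: float


def _sym_row(canvas_w: int, width: int) -> np.ndarray:
    """Boolean row with ``width`` true cells centred on the canvas."""
    row = np.zeros(canvas_w, dtype=bool)
    c0 = (canvas_w - width) // 2
    row[c0 : c0 + width] = True
    return row


def _disc_widths(diameter: int) -> list[int]:
    """Per-row widths of a rasterised disc whose maximum width is exact."""
    R = diameter / 2.0
    widths = []
    for i in range(diameter):
        y = i + 0.5 - R
        w = 2.0 * np.sqrt(max(R * R - y * y, 0.0))
        widths.append(max(1, int(round(w))))
    mid = len(widths) // 2
    widths[mid] = diameter
    if diameter % 2 == 0 and mid > 0:
        widths[mid - 1] = diameter
    return widths


def synth_spine_mask(spec: SpineSpec) -> SynthSpine:
    """Rasterise a spine family blueprint into a :class:`SpineMask`.

    mushroom: disc head of width ``head_w_px`` atop a ``neck_w_px`` column;
    stubby: trapezoid widening toward the base (head measures as the widest
    row; there is no constriction, so RCW <= 0); thin: narrow column of width
    ``neck_w_px`` with a small rounded cap; branched: two diverging 2-px arms
    atop a short stem.  Ground-truth (h, w_head, w_neck) is recorded on the
    returned object (w_head is None for branched spines).
    """
    ny, nx = spec.canvas
    canvas = np.zeros((ny, nx), dtype=bool)
    base = spec.base_row
    h = spec.h_px
    tip = base - h  # topmost spine row index

    if spec.family == "mushroom":
        if spec.head_w_px <= spec.neck_w_px:
            raise ValueError("mushroom head must be wider than its neck")
        head_rows = min(spec.head_w_px, h - 2)
        widths = _disc_widths(spec.head_w_px)[:head_rows]
        for i, w in enumerate(widths):
            canvas[tip + i] = _sym_row(nx, w)
        # the neck runs up through the head's lower half, so the disc's
        # lower taper never dips below the neck width
        for r in range(tip + head_rows // 2, base):
            canvas[r] |= _sym_row(nx, spec.neck_w_px)
        truth = (h, spec.head_w_px, spec.neck_w_px)
    elif spec.family == "stubby":
        # width ramps linearly from head_w at the tip to neck_w at the base;
        # neck_w >= head_w gives the flat/inverted taper of a stubby spine
        for i in range(h):
            frac = i / max(h - 1, 1)
            w = int(round(spec.head_w_px + frac * (spec.neck_w_px - spec.head_w_px)))
            canvas[tip + i] = _sym_row(nx, w)
        wmax = max(spec.head_w_px, spec.neck_w_px)
        truth = (h, wmax, wmax)
    elif spec.family == "thin":
        cap = min(spec.head_w_px, spec.neck_w_px + 2)
        canvas[tip] = _sym_row(nx, max(cap - 2, 1))
        canvas[tip + 1] = _sym_row(nx, cap)
        for r in range(tip + 2, base):
            canvas[r] = _sym_row(nx, spec.neck_w_px)
        truth = (h, cap, spec.neck_w_px)
    else:  # branched
        stem_rows = max(3, h // 4)
        arm_rows = h - stem_rows
        arm_w = 2
        for i in range(arm_rows):
            r = tip + i
            # arms diverge going down from the fork toward the tips, i.e.
            # the gap widens toward the top of the canvas
            gap = 2 + 2 * (arm_rows - 1 - i) // 3
            row = np.zeros(nx, dtype=bool)
            mid = nx // 2
            left0 = mid - gap // 2 - arm_w
            row[left0 : left0 + arm_w] = True
            right0 = mid + (gap + 1) // 2
            row[right0 : right0 + arm_w] = True
            canvas[r] = row
        for r in range(tip + arm_rows, base):
            canvas[r] = _sym_row(nx, spec.neck_w_px)
        truth = (h, None, spec.neck_w_px)

    mask = SpineMask(canvas, base_row=base, dx=spec.dx)
    th, twh, twn = truth
    return SynthSpine(
        mask=mask,
        spec=spec,
        true_h=th * spec.dx,
        true_w_head=None if twh is None else twh * spec.dx,
        true_w_neck=twn * spec.dx,
    )


def fixture_battery(dx: float = 0.3) -> list[SynthSpine]:
    """A deterministic battery of >= 30 fixtures spanning all four classes."""
    out: list[SynthSpine] = []
    for h, head, neck in [(10, 8, 3), (12, 9, 3), (12, 10, 4), (14, 10, 4),
                          (14, 12, 4), (16, 12, 5), (18, 12, 4), (20, 12, 4)]:
        out.append(synth_spine_mask(SpineSpec("mushroom", h, head, neck)))
    for h, w in [(8, 8), (8, 10), (10, 10), (10, 12), (12, 12), (9, 9), (11, 12), (12, 14)]:
        out.append(synth_spine_mask(SpineSpec("stubby", h, w, w)))
    for h, neck in [(16, 2), (18, 2), (20, 2), (20, 3), (24, 3), (26, 3), (28, 4), (30, 4)]:
        out.append(synth_spine_mask(SpineSpec("thin", h, neck + 2, neck, canvas=(40, 40))))
    for h in [12, 14, 16, 18, 20, 22, 24, 26]:
        out.append(synth_spine_mask(SpineSpec("branched", h, 2, 4)))
    assert len(out) >= 30
    return out


def uniform_state(
    values: dict[str, float],
    grid: Grid,
) -> FieldState:
    """Spatially constant state with the given per-field values."""
    for name, v in values.items():
        if v < 0:
            raise ValueError(f"field {name} value must be >= 0, got {v}")
    arrs = {
        name: np.full(grid.shape, float(values[name]), dtype=np.float64)
        for name in ("A", "H", "S", "Y")
    }
    return FieldState(**arrs, t=0.0)


def seeded_random_jacobians(n: int, rng_seed: int = 0) -> list[AHJacobian]:
    """Reproducible random 2x2 Jacobians with activator–inhibitor signs.

    f_H < 0, g_A > 0, g_H < 0 by construction; f_A spans both signs so the
    batch contains stable and unstable reaction parts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n):
        out.append(
            AHJacobian(
                f_A=rng.uniform(-0.5, 0.5),
                f_H=-rng.uniform(0.01, 5.0),
                g_A=rng.uniform(0.01, 5.0),
                g_H=-rng.uniform(0.01, 1.0),
            )
        )
    return out
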