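"""Renderer-independent geometry for shark, dolphin and plaice plots.

Dolphin and plaice plots are stacked-band ("fish") charts: every clone owns
a vertical band whose thickness at each time point equals its CCF.  Children
are nested inside their parent band.  Two vertical modes exist:

* ``centered`` -- the tumor is stacked around the vertical center; inside a
  parent band the children are stacked centrally, the parent's unique CCF
  split into equal gaps around and between them;
* ``bottom`` -- bands lie on the x axis; inside each clone the child whose
  branch reaches deepest hugs the lower edge, the parent's own unique CCF
  sits on top.

A clone first appearing at time point ``t_f`` is given a zero-thickness
birth vertex at ``x(t_{f-1}) + birth_offset`` (default 0.1 axis units) so
bands emerge smoothly from inside their parent.  Band borders can be drawn
as polygons (straight segments through the support points) or as
shape-preserving monotone cubic splines through the very same points
(plain cubic splines can overshoot and break the nesting, so they are not
offered).

Shark plots are plain layered node/edge drawings of the phylogeny with the
x coordinate equal to the nested level, optionally extended by per-time-point
bubbles whose area tracks the CCF.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .coloring import ColorAssignment
from .errors import CloneLookupError, UsageError
from .model import DEFAULT_TOLERANCE, NORMAL, ClonalEvolution

SHAPE_SPLINE = "spline"
SHAPE_POLYGON = "polygon"
MODE_CENTERED = "centered"
MODE_BOTTOM = "bottom"

#: Offset on the time axis between a clone's drawn birth vertex and the
#: time point preceding its first appearance.
BIRTH_OFFSET = 0.1


@dataclass(frozen=True)
class LayoutConfig:
    shape: str = SHAPE_SPLINE
    vertical_mode: str = MODE_CENTERED
    separate_independent: bool = False
    birth_offset: float = BIRTH_OFFSET
    independent_gap: float = 2.0  # percent of plot height
    show_timepoint_labels: bool = True

    def __post_init__(self):
        if self.shape not in (SHAPE_SPLINE, SHAPE_POLYGON):
            raise UsageError(f"unknown shape {self.shape!r}")
        if self.vertical_mode not in (MODE_CENTERED, MODE_BOTTOM):
            raise UsageError(f"unknown vertical mode {self.vertical_mode!r}")
        if self.birth_offset <= 0:
            raise UsageError("birth_offset must be positive")


@dataclass(frozen=True)
class BandLayout:
    """Per-clone band geometry: ordered (x, y_lower, y_upper) support points."""

    clone_labels: tuple[str, ...]
    support: dict[str, np.ndarray]  # (k, 3) arrays
    x: np.ndarray  # time point coordinates
    timepoint_labels: tuple[str, ...]
    timepoint_kind: tuple[str, ...]
    shape: str
    colors: dict[str, str]
    draw_order: tuple[str, ...]  # parents before children

    def boundaries(self, clone: str, num: int = 200):
        """Sampled (xs, lower, upper) of a band, honoring the shape."""
        pts = self.support[clone]
        if len(pts) == 0:
            return np.empty(0), np.empty(0), np.empty(0)
        if len(pts) == 1:
            return pts[:, 0], pts[:, 1], pts[:, 2]
        xs = np.linspace(pts[0, 0], pts[-1, 0], num)
        if self.shape == SHAPE_POLYGON:
            lo = np.interp(xs, pts[:, 0], pts[:, 1])
            hi = np.interp(xs, pts[:, 0], pts[:, 2])
        else:
            lo = PchipInterpolator(pts[:, 0], pts[:, 1])(xs)
            hi = PchipInterpolator(pts[:, 0], pts[:, 2])(xs)
        return xs, lo, hi

    def thickness_at(self, clone: str, x: float) -> float:
        pts = self.support[clone]
        if len(pts) == 0:
            return 0.0
        if len(pts) == 1:
            return float(pts[0, 2] - pts[0, 1]) if pts[0, 0] == x else 0.0
        # support points are interpolated exactly by both shapes
        lo = np.interp(x, pts[:, 0], pts[:, 1])
        hi = np.interp(x, pts[:, 0], pts[:, 2])
        return float(hi - lo)

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape": self.shape,
                "x": self.x.tolist(),
                "timepoint_labels": list(self.timepoint_labels),
                "timepoint_kind": list(self.timepoint_kind),
                "clones": {
                    lab: {
                        "support": self.support[lab].tolist(),
                        "color": self.colors.get(lab),
                    }
                    for lab in self.clone_labels
                },
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class SharkLayout:
    clone_labels: tuple[str, ...]
    nodes: dict[str, tuple[float, float]]
    edges: tuple[tuple[str, str], ...]  # (parent, child)
    colors: dict[str, str]
    radii: np.ndarray | None  # (n, m) bubble radii, or None
    x: np.ndarray
    timepoint_labels: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": {k: list(v) for k, v in self.nodes.items()},
                "edges": [list(e) for e in self.edges],
                "colors": self.colors,
                "radii": None if self.radii is None else self.radii.tolist(),
                "timepoint_labels": list(self.timepoint_labels),
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class PlaiceLayout:
    upper: BandLayout
    lower: BandLayout
    lower_fill: dict[str, str | None]  # clone -> color-source clone or None

    def to_json(self) -> str:
        return json.dumps(
            {
                "upper": json.loads(self.upper.to_json()),
                "lower": json.loads(self.lower.to_json()),
                "lower_fill": self.lower_fill,
            },
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# band stacking


def _first_positive(evo: ClonalEvolution, tolerance: float) -> np.ndarray:
    """First positive column index per clone, or -1 when never positive."""
    out = np.full(evo.n_clones, -1)
    for k in range(evo.n_clones):
        pos = np.nonzero(evo.ccf[k] > tolerance)[0]
        if len(pos):
            out[k] = pos[0]
    return out


def _child_order(
    evo: ClonalEvolution,
    clone: str,
    mode: str,
    first_pos: np.ndarray,
) -> list[str]:
    kids = list(evo.children_of(clone))

    def appearance(lab: str) -> float:
        f = first_pos[evo.index(lab)]
        return math.inf if f < 0 else float(f)

    if mode == MODE_BOTTOM:
        # deepest branch hugs the lower edge
        kids.sort(key=lambda l: (-evo.subtree_depth(l), appearance(l), l))
    else:
        kids.sort(key=lambda l: (appearance(l), l))
    return kids


def _stack_positions(
    evo: ClonalEvolution, config: LayoutConfig, tolerance: float
):
    """Lower/upper band edges (n, m) for every clone at every time point."""
    n, m = evo.n_clones, evo.n_timepoints
    uccf = np.clip(evo.unique_ccf_matrix(), 0.0, None)
    lo = np.zeros((n, m))
    hi = np.zeros((n, m))
    first_pos = _first_positive(evo, tolerance)
    mode = config.vertical_mode

    founders = list(evo.founders)
    if mode == MODE_BOTTOM:
        founders.sort(
            key=lambda l: (
                -evo.subtree_depth(l),
                math.inf if first_pos[evo.index(l)] < 0 else first_pos[evo.index(l)],
                l,
            )
        )

    child_orders = {
        lab: _child_order(evo, lab, mode, first_pos) for lab in evo.clone_labels
    }

    def place(lab: str, bottom: float, t: int) -> None:
        k = evo.index(lab)
        thick = evo.ccf[k, t]
        lo[k, t] = bottom
        hi[k, t] = bottom + thick
        kids = child_orders[lab]
        if not kids:
            return
        if mode == MODE_CENTERED:
            gap = uccf[k, t] / (len(kids) + 1)
            cursor = bottom + gap
            for ch in kids:
                place(ch, cursor, t)
                cursor += evo.ccf[evo.index(ch), t] + gap
        else:
            cursor = bottom
            for ch in kids:
                place(ch, cursor, t)
                cursor += evo.ccf[evo.index(ch), t]

    gap_pct = config.independent_gap if config.separate_independent else 0.0
    for t in range(m):
        active = [f for f in founders if evo.ccf[evo.index(f), t] > tolerance]
        total = sum(evo.ccf[evo.index(f), t] for f in active)
        total += gap_pct * max(len(active) - 1, 0)
        base = (100.0 - total) / 2.0 if mode == MODE_CENTERED else 0.0
        cursor = base
        for f in founders:
            thick = evo.ccf[evo.index(f), t]
            place(f, cursor, t)
            cursor += thick
            if thick > tolerance:
                cursor += gap_pct
    return lo, hi, first_pos


def _draw_order(evo: ClonalEvolution) -> tuple[str, ...]:
    levels = evo.nested_level_array()
    order = sorted(range(evo.n_clones), key=lambda k: (levels[k], k))
    return tuple(evo.clone_labels[k] for k in order)


def dolphin_layout(
    evo: ClonalEvolution,
    colors: ColorAssignment | Mapping[str, str] | None = None,
    config: LayoutConfig | None = None,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
) -> BandLayout:
    """Stacked-band geometry for a dolphin plot."""
    config = config or LayoutConfig()
    lo, hi, first_pos = _stack_positions(evo, config, tolerance)
    xs = evo.timepoints

    support: dict[str, np.ndarray] = {}
    for k, lab in enumerate(evo.clone_labels):
        f = first_pos[k]
        if f < 0:
            support[lab] = np.empty((0, 3))
            continue
        rows = []
        if f > 0:
            gap = xs[f] - xs[f - 1]
            bx = xs[f - 1] + min(config.birth_offset, 0.5 * gap)
            by = (lo[k, f - 1] + hi[k, f - 1]) / 2.0
            rows.append((bx, by, by))
        for t in range(f, evo.n_timepoints):
            rows.append((xs[t], lo[k, t], hi[k, t]))
        support[lab] = np.array(rows, dtype=float)

    color_map = _hex_map(evo, colors)
    return BandLayout(
        clone_labels=evo.clone_labels,
        support=support,
        x=xs.copy(),
        timepoint_labels=evo.timepoint_labels,
        timepoint_kind=evo.timepoint_kind,
        shape=config.shape,
        colors=color_map,
        draw_order=_draw_order(evo),
    )


def _hex_map(evo, colors) -> dict[str, str]:
    if colors is None:
        from .coloring import assign_colors

        colors = assign_colors(evo)
    if isinstance(colors, ColorAssignment):
        return dict(colors.hex)
    return {lab: colors[lab] for lab in evo.clone_labels}


def shark_layout(
    evo: ClonalEvolution,
    colors: ColorAssignment | Mapping[str, str] | None = None,
    config: LayoutConfig | None = None,
    *,
    with_bubbles: bool = True,
    tolerance: float = DEFAULT_TOLERANCE,
) -> SharkLayout:
    """Layered left-to-right tree drawing; x = nested level.

    Independent founders form disconnected components (no shared root).
    Bubble radii grow strictly with CCF and are zero exactly at CCF 0.
    """
    config = config or LayoutConfig()
    ys: dict[str, float] = {}
    next_leaf = [0.0]

    def place(lab: str) -> float:
        kids = evo.children_of(lab)
        if not kids:
            ys[lab] = next_leaf[0]
            next_leaf[0] += 1.0
        else:
            ys[lab] = float(np.mean([place(k) for k in kids]))
        return ys[lab]

    for f in evo.founders:
        place(f)
        next_leaf[0] += 0.5  # gap between independent components

    nodes = {
        lab: (float(evo.nested_level(lab)), ys[lab]) for lab in evo.clone_labels
    }
    edges = tuple(
        (p, lab)
        for lab, p in zip(evo.clone_labels, evo.parents)
        if p != NORMAL
    )
    radii = None
    if with_bubbles:
        radii = 0.45 * np.sqrt(np.clip(evo.ccf, 0.0, None) / 100.0)
        radii[evo.ccf <= tolerance] = 0.0
    return SharkLayout(
        clone_labels=evo.clone_labels,
        nodes=nodes,
        edges=edges,
        colors=_hex_map(evo, colors),
        radii=radii,
        x=evo.timepoints.copy(),
        timepoint_labels=evo.timepoint_labels,
    )


def mirror_band_layout(layout: BandLayout) -> BandLayout:
    """Exact reflection of a band layout across the x axis."""
    support = {}
    for lab, pts in layout.support.items():
        if len(pts) == 0:
            support[lab] = pts.copy()
            continue
        mirrored = pts.copy()
        mirrored[:, 1] = -pts[:, 2]
        mirrored[:, 2] = -pts[:, 1]
        support[lab] = mirrored
    return BandLayout(
        clone_labels=layout.clone_labels,
        support=support,
        x=layout.x.copy(),
        timepoint_labels=layout.timepoint_labels,
        timepoint_kind=layout.timepoint_kind,
        shape=layout.shape,
        colors=dict(layout.colors),
        draw_order=layout.draw_order,
    )


def plaice_layout(
    evo: ClonalEvolution,
    colors: ColorAssignment | Mapping[str, str] | None = None,
    annotations: Mapping[str, str] | None = None,
    config: LayoutConfig | None = None,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
) -> PlaiceLayout:
    """Mirrored bottom-layout band charts for allele-aware visualization.

    ``annotations`` maps a clone carrying a completing (second-hit) event to
    the clone carrying the first hit; its mirrored band is filled with the
    first-hit clone's hue.  Unannotated clones stay unfilled, representing
    100% remaining healthy alleles.
    """
    config = config or LayoutConfig()
    if config.vertical_mode != MODE_BOTTOM:
        config = LayoutConfig(
            shape=config.shape,
            vertical_mode=MODE_BOTTOM,
            separate_independent=config.separate_independent,
            birth_offset=config.birth_offset,
            independent_gap=config.independent_gap,
            show_timepoint_labels=config.show_timepoint_labels,
        )
    upper = dolphin_layout(evo, colors, config, tolerance=tolerance)
    lower = mirror_band_layout(upper)
    fill: dict[str, str | None] = {lab: None for lab in evo.clone_labels}
    if annotations:
        for clone, source in annotations.items():
            if clone not in upper.support:
                raise CloneLookupError(f"annotation names unknown clone {clone!r}")
            if source not in upper.support:
                raise CloneLookupError(
                    f"annotation for {clone!r} names unknown clone {source!r}"
                )
            fill[clone] = source
    return PlaiceLayout(upper=upper, lower=lower, lower_fill=fill)
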