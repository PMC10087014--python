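"""Static rendering of layouts to SVG and PNG.

SVG is the source of truth: it is written by hand with fixed number
formatting, so identical layout + options give byte-identical files.  PNG is
rasterized from the same sampled geometry via matplotlib (Agg).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import UsageError
from .layout import BandLayout, PlaiceLayout, SharkLayout

_KIND_MARK = {"measured": "", "interpolated": "*", "therapy": "†"}


@dataclass(frozen=True)
class RenderOptions:
    format: str | None = None  # svg | png; inferred from the path if None
    width: int = 960
    height: int = 540
    dpi: int = 100
    show_clone_labels: bool = True
    annotate_estimated: bool = True
    spline_samples: int = 200

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise UsageError("width and height must be positive")


def _fmt(v: float) -> str:
    return f"{v:.3f}"


class _Canvas:
    """Affine data->pixel mapping with margins, plus an SVG element buffer."""

    def __init__(self, options: RenderOptions, x_range, y_range):
        self.o = options
        self.ml, self.mr, self.mt, self.mb = 55.0, 110.0, 20.0, 45.0
        self.x0, self.x1 = x_range
        self.y0, self.y1 = y_range
        if self.x1 == self.x0:
            self.x0, self.x1 = self.x0 - 0.5, self.x1 + 0.5
        self.elements: list[str] = []

    def px(self, x: float) -> float:
        span = self.o.width - self.ml - self.mr
        return self.ml + (x - self.x0) / (self.x1 - self.x0) * span

    def py(self, y: float) -> float:
        span = self.o.height - self.mt - self.mb
        return self.mt + (self.y1 - y) / (self.y1 - self.y0) * span

    def add(self, element: str) -> None:
        self.elements.append(element)

    def svg(self) -> str:
        head = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{self.o.width}" '
            f'height="{self.o.height}" viewBox="0 0 {self.o.width} '
            f'{self.o.height}">\n'
            f'<rect width="{self.o.width}" height="{self.o.height}" '
            'fill="#ffffff"/>\n'
        )
        return head + "\n".join(self.elements) + "\n</svg>\n"


def _band_path(canvas: _Canvas, xs, lo, hi) -> str:
    parts = [f"M {_fmt(canvas.px(xs[0]))},{_fmt(canvas.py(lo[0]))}"]
    for x, y in zip(xs[1:], lo[1:]):
        parts.append(f"L {_fmt(canvas.px(x))},{_fmt(canvas.py(y))}")
    for x, y in zip(xs[::-1], hi[::-1]):
        parts.append(f"L {_fmt(canvas.px(x))},{_fmt(canvas.py(y))}")
    return " ".join(parts) + " Z"


def _tick_elements(canvas: _Canvas, layout, options: RenderOptions, y_axis=0.0):
    for x, lab, kind in zip(
        layout.x, layout.timepoint_labels, layout.timepoint_kind
    ):
        px = canvas.px(float(x))
        y_bot = canvas.o.height - canvas.mb
        canvas.add(
            f'<line x1="{_fmt(px)}" y1="{_fmt(y_bot)}" x2="{_fmt(px)}" '
            f'y2="{_fmt(y_bot + 5)}" stroke="#333333" stroke-width="1"/>'
        )
        text = lab + (_KIND_MARK[kind] if options.annotate_estimated else "")
        canvas.add(
            f'<text x="{_fmt(px)}" y="{_fmt(y_bot + 18)}" font-size="11" '
            f'font-family="sans-serif" text-anchor="middle">{_esc(text)}</text>'
        )


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def _sampled_bands(layout: BandLayout, options: RenderOptions):
    """(clone, xs, lo, hi) for every clone with a visible band, draw order."""
    out = []
    for lab in layout.draw_order:
        pts = layout.support[lab]
        if len(pts) == 0 or np.all(pts[:, 2] - pts[:, 1] <= 0):
            continue
        xs, lo, hi = layout.boundaries(lab, num=options.spline_samples)
        out.append((lab, xs, lo, hi))
    return out


def _label_anchor(xs, lo, hi):
    k = int(np.argmax(hi - lo))
    return xs[k], (lo[k] + hi[k]) / 2.0


def _render_band_svg(
    layout: BandLayout, options: RenderOptions, *, mirror: PlaiceLayout | None = None
) -> str:
    if mirror is not None:
        y_range = (-102.0, 102.0)
    else:
        y_range = (0.0, 102.0)
    all_x = [layout.x.min(), layout.x.max()]
    canvas = _Canvas(options, (float(all_x[0]), float(all_x[1])), y_range)

    axis_y = canvas.py(0.0)
    for lab, xs, lo, hi in _sampled_bands(layout, options):
        path = _band_path(canvas, xs, lo, hi)
        canvas.add(
            f'<path d="{path}" fill="{layout.colors[lab]}" stroke="#333333" '
            f'stroke-width="0.5" data-clone="{_esc(lab)}"/>'
        )
    if mirror is not None:
        for lab, xs, lo, hi in _sampled_bands(mirror.lower, options):
            source = mirror.lower_fill.get(lab)
            fill = mirror.lower.colors[source] if source else "none"
            canvas.add(
                f'<path d="{_band_path(canvas, xs, lo, hi)}" fill="{fill}" '
                f'stroke="#888888" stroke-width="0.5" '
                f'data-clone="{_esc(lab)}" data-lower="1"/>'
            )
        canvas.add(
            f'<line x1="{_fmt(canvas.ml)}" y1="{_fmt(axis_y)}" '
            f'x2="{_fmt(options.width - canvas.mr)}" y2="{_fmt(axis_y)}" '
            'stroke="#000000" stroke-width="1"/>'
        )
    if options.show_clone_labels:
        for lab, xs, lo, hi in _sampled_bands(layout, options):
            lx, ly = _label_anchor(xs, lo, hi)
            canvas.add(
                f'<text x="{_fmt(canvas.px(lx))}" y="{_fmt(canvas.py(ly))}" '
                'font-size="10" font-family="sans-serif" '
                f'text-anchor="middle">{_esc(lab)}</text>'
            )
    _tick_elements(canvas, layout, options)
    return canvas.svg()


def _render_shark_svg(layout: SharkLayout, options: RenderOptions) -> str:
    xs = [p[0] for p in layout.nodes.values()] or [0.0]
    ys = [p[1] for p in layout.nodes.values()] or [0.0]
    max_level = max(xs)
    n_tp = len(layout.timepoint_labels)
    bubble_x0 = max_level + 1.5
    x_hi = bubble_x0 + n_tp if layout.radii is not None else max_level + 0.5
    canvas = _Canvas(
        options,
        (min(xs) - 0.5, max(x_hi, min(xs) + 0.5)),
        (min(ys) - 0.7, max(ys) + 0.7),
    )
    for parent, child in layout.edges:
        x1, y1 = layout.nodes[parent]
        x2, y2 = layout.nodes[child]
        canvas.add(
            f'<line x1="{_fmt(canvas.px(x1))}" y1="{_fmt(canvas.py(y1))}" '
            f'x2="{_fmt(canvas.px(x2))}" y2="{_fmt(canvas.py(y2))}" '
            'stroke="#555555" stroke-width="1.5"/>'
        )
    r_node = 9.0
    for lab in layout.clone_labels:
        x, y = layout.nodes[lab]
        canvas.add(
            f'<circle cx="{_fmt(canvas.px(x))}" cy="{_fmt(canvas.py(y))}" '
            f'r="{_fmt(r_node)}" fill="{layout.colors[lab]}" '
            f'stroke="#333333" stroke-width="0.8" data-clone="{_esc(lab)}"/>'
        )
        if options.show_clone_labels:
            canvas.add(
                f'<text x="{_fmt(canvas.px(x))}" '
                f'y="{_fmt(canvas.py(y) - r_node - 4)}" font-size="10" '
                f'font-family="sans-serif" text-anchor="middle">{_esc(lab)}</text>'
            )
    if layout.radii is not None:
        # per-time-point bubble strip, clones stacked like the tree's y order
        px_unit = canvas.px(1.0) - canvas.px(0.0)
        for t in range(n_tp):
            cx = bubble_x0 + t
            for k, lab in enumerate(layout.clone_labels):
                r = float(layout.radii[k, t])
                if r <= 0:
                    continue
                y = layout.nodes[lab][1]
                canvas.add(
                    f'<circle cx="{_fmt(canvas.px(cx))}" '
                    f'cy="{_fmt(canvas.py(y))}" r="{_fmt(r * px_unit)}" '
                    f'fill="{layout.colors[lab]}" fill-opacity="0.85" '
                    f'stroke="none" data-clone="{_esc(lab)}" data-tp="{t}"/>'
                )
            canvas.add(
                f'<text x="{_fmt(canvas.px(cx))}" '
                f'y="{_fmt(canvas.o.height - 27)}" font-size="10" '
                f'font-family="sans-serif" text-anchor="middle">'
                f"{_esc(layout.timepoint_labels[t])}</text>"
            )
    return canvas.svg()


def render_svg(layout, options: RenderOptions | None = None) -> str:
    """Render any layout object to an SVG string (pure function)."""
    options = options or RenderOptions()
    if isinstance(layout, PlaiceLayout):
        return _render_band_svg(layout.upper, options, mirror=layout)
    if isinstance(layout, BandLayout):
        return _render_band_svg(layout, options)
    if isinstance(layout, SharkLayout):
        return _render_shark_svg(layout, options)
    raise UsageError(f"cannot render object of type {type(layout).__name__}")


def _render_png(layout, options: RenderOptions, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(options.width / options.dpi, options.height / options.dpi),
        dpi=options.dpi,
    )
    if isinstance(layout, SharkLayout):
        for parent, child in layout.edges:
            x1, y1 = layout.nodes[parent]
            x2, y2 = layout.nodes[child]
            ax.plot([x1, x2], [y1, y2], color="#555555", lw=1.5, zorder=1)
        for lab in layout.clone_labels:
            x, y = layout.nodes[lab]
            ax.scatter([x], [y], s=120, color=layout.colors[lab], zorder=2)
            ax.annotate(lab, (x, y), textcoords="offset points", xytext=(0, 10),
                        ha="center", fontsize=8)
        ax.invert_yaxis()
    else:
        bands = (
            [(layout.upper, None), (layout.lower, layout.lower_fill)]
            if isinstance(layout, PlaiceLayout)
            else [(layout, None)]
        )
        for band, fills in bands:
            for lab, xs, lo, hi in _sampled_bands(band, options):
                if fills is None:
                    color = band.colors[lab]
                else:
                    source = fills.get(lab)
                    color = band.colors[source] if source else "none"
                ax.fill_between(
                    xs, lo, hi, facecolor=color, edgecolor="#333333", lw=0.5
                )
        if isinstance(layout, PlaiceLayout):
            ax.axhline(0.0, color="#000000", lw=1.0)
        first = (
            layout.upper if isinstance(layout, PlaiceLayout) else layout
        )
        ax.set_xticks([float(x) for x in first.x])
        ax.set_xticklabels(
            [
                lab + (_KIND_MARK[k] if options.annotate_estimated else "")
                for lab, k in zip(first.timepoint_labels, first.timepoint_kind)
            ],
            fontsize=8,
        )
    ax.set_yticks([])
    for side in ("top", "right", "left"):
        ax.spines[side].set_visible(False)
    fig.savefig(path, dpi=options.dpi)
    plt.close(fig)


def render(layout, path, options: RenderOptions | None = None) -> None:
    """Write a layout to ``path`` as SVG or PNG.

    The format is taken from ``options.format`` or inferred from the file
    extension.  Unknown formats raise :class:`UsageError`.
    """
    options = options or RenderOptions()
    path = Path(path)
    fmt = options.format or path.suffix.lstrip(".").lower()
    if fmt == "svg":
        path.write_text(render_svg(layout, options), encoding="utf-8")
    elif fmt == "png":
        _render_png(layout, options, path)
    else:
        raise UsageError(f"unknown render format {fmt!r}")
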