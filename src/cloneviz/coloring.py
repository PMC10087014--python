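"""Phylogeny-aware color assignment.

Four rules drive the palette:

1. the deeper the nested level, the darker the color (lightness steps down);
2. clones of the same branch share a similar hue;
3. sibling branches below a common ancestor get similar but diverging hues;
4. independent founders get hues of maximum pairwise difference.

Founders are spread evenly over the hue wheel; each founder's subtree owns a
hue sector, and siblings recursively subdivide the *central* fraction of
their parent's sector (proportionally to subtree leaf counts), which keeps
the hue spread within any one founder's subtree strictly smaller than the
gap between two different founders' subtrees.  At most
:data:`MAX_INDEPENDENT_CLONES` founders are supported; related clones are
unlimited (sectors below a width floor only trigger a warning).
"""

from __future__ import annotations

import colorsys
import warnings
from dataclasses import dataclass, field

from .errors import CapacityError
from .model import NORMAL, ClonalEvolution

#: Hard limit on clones developing directly from normal cells.
MAX_INDEPENDENT_CLONES = 25


@dataclass(frozen=True)
class PaletteConfig:
    max_independent: int = MAX_INDEPENDENT_CLONES
    saturation: float = 0.65
    lightness_max: float = 0.75  # founders
    lightness_min: float = 0.35  # deepest level
    subtree_hue_fraction: float = 0.4  # < 0.5 keeps founder sectors separated
    min_sector_width: float = 1e-3  # degrees; warn below


@dataclass(frozen=True)
class ColorAssignment:
    """Clone -> (hue degrees, saturation, lightness) plus hex rendering."""

    hsl: dict[str, tuple[float, float, float]]
    hex: dict[str, str]

    def __getitem__(self, clone: str) -> str:
        return self.hex[clone]

    def to_dict(self) -> dict:
        return {
            lab: {"hsl": list(self.hsl[lab]), "hex": self.hex[lab]}
            for lab in self.hsl
        }


def _hsl_to_hex(h: float, s: float, l: float) -> str:
    r, g, b = colorsys.hls_to_rgb((h % 360.0) / 360.0, l, s)
    return "#{:02x}{:02x}{:02x}".format(
        round(r * 255), round(g * 255), round(b * 255)
    )


def _leaf_count(evo: ClonalEvolution, clone: str) -> int:
    kids = evo.children_of(clone)
    if not kids:
        return 1
    return sum(_leaf_count(evo, k) for k in kids)


def assign_colors(
    evo: ClonalEvolution, config: PaletteConfig | None = None
) -> ColorAssignment:
    """Deterministic phylogeny-aware colors for every clone.

    Raises :class:`CapacityError` when the evolution has more founders than
    ``config.max_independent``.
    """
    config = config or PaletteConfig()
    founders = evo.founders
    if len(founders) > config.max_independent:
        raise CapacityError(
            f"{len(founders)} independent clones exceed the supported "
            f"maximum of {config.max_independent}"
        )

    max_level = int(evo.nested_level_array().max(initial=0))
    l_step = (config.lightness_max - config.lightness_min) / (max_level + 1)
    hsl: dict[str, tuple[float, float, float]] = {}

    def visit(clone: str, lo: float, hi: float) -> None:
        width = hi - lo
        if width < config.min_sector_width:
            warnings.warn(
                f"hue sector for clone {clone!r} narrower than "
                f"{config.min_sector_width} degrees; closely related clones "
                "may be hard to distinguish",
                stacklevel=2,
            )
        mid = (lo + hi) / 2.0
        level = evo.nested_level(clone)
        lightness = config.lightness_max - level * l_step
        hsl[clone] = (mid % 360.0, config.saturation, lightness)
        kids = evo.children_of(clone)
        if not kids:
            return
        f = config.subtree_hue_fraction
        inner_lo = mid - f * width / 2.0
        inner_width = f * width
        total_leaves = sum(_leaf_count(evo, k) for k in kids)
        cursor = inner_lo
        for k in kids:
            share = inner_width * _leaf_count(evo, k) / total_leaves
            visit(k, cursor, cursor + share)
            cursor += share

    n_f = len(founders)
    sector = 360.0 / max(n_f, 1)
    for i, f_lab in enumerate(founders):
        center = i * sector
        visit(f_lab, center - sector / 2.0, center + sector / 2.0)

    # deterministic collision resolution: 8-bit rounding can merge very
    # similar hues; nudge saturation until every hex is unique (hue and
    # lightness -- the rule-bearing channels -- stay untouched)
    hexes: dict[str, str] = {}
    used: set[str] = set()
    for lab in evo.clone_labels:
        h, s, l = hsl[lab]
        hx = _hsl_to_hex(h, s, l)
        attempt = 1
        while hx in used:
            delta = 0.015 * ((attempt + 1) // 2) * (1 if attempt % 2 else -1)
            s_adj = min(max(s + delta, 0.15), 0.98)
            hx = _hsl_to_hex(h, s_adj, l)
            attempt += 1
            if attempt > 200:  # pragma: no cover - defensive
                break
        hsl[lab] = (h, s, l)
        used.add(hx)
        hexes[lab] = hx
    return ColorAssignment(hsl=hsl, hex=hexes)
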