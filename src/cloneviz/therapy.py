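"""Therapy-effect estimation.

A single estimated time point is inserted between two adjacent measured
time points.  In the presence of therapy, any decrease of a clone's unique
CCF between the flanking measurements is attributed to the therapy, so every
clone present before therapy gets the *minimum* of its unique CCFs at the
two flanking points; clones only appearing afterwards are set to zero.

Optionally the re-expansion between the therapy point and the next
measurement is interpolated as well.  For that, nested levels of the newly
appearing clones are recalculated *ignoring* the clones that survived
therapy: a deep clone whose surviving ancestors are all present is only
"one step" away and gets recalculated level 0.  One point is inserted per
recalculated level; childless new clones then grow linearly while new clones
with children hold their unique CCF at its measured end value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import UsageError
from .interpolate import _resolve_adjacent_pair
from .model import (
    DEFAULT_TOLERANCE,
    INTERPOLATED,
    NORMAL,
    THERAPY,
    ClonalEvolution,
    ccf_from_unique,
    unique_ccf_matrix,
)
from .validity import check_validity


@dataclass(frozen=True)
class TherapyWindow:
    """Placement of an estimated end-of-therapy time point.

    ``interval`` is an adjacent measured pair, given as a pair of column
    indices or time point labels.  ``position`` is the fraction in (0, 1)
    locating the therapy point inside the interval; when ``None`` the
    therapy point and any post-therapy interpolated points divide the
    interval into equal parts.  ``extra_interpolation=None`` resolves to
    True exactly when new clones appear in the interval.
    """

    interval: tuple
    position: float | None = None
    extra_interpolation: bool | None = None

    def __post_init__(self):
        if self.position is not None and not 0 < self.position < 1:
            raise UsageError("therapy position must lie strictly in (0, 1)")


def recalculated_nested_levels(
    evo: ClonalEvolution, therapy_clones: Iterable[str]
) -> dict[str, int]:
    """Nested levels counting only ancestors absent at the therapy point.

    ``therapy_clones`` are the clones with nonzero CCF at the therapy time
    point.  Every clone *not* in that set receives a level equal to the
    number of its ancestors that are also absent.
    """
    present = set(therapy_clones)
    for lab in present:
        evo.index(lab)  # raises for unknown labels
    return {
        lab: sum(1 for a in evo.ancestors(lab) if a not in present)
        for lab in evo.clone_labels
        if lab not in present
    }


def _window_geometry(
    evo: ClonalEvolution, window: TherapyWindow, tolerance: float
):
    i, j = _resolve_adjacent_pair(evo, window.interval)
    old = evo.ccf[:, i] > tolerance
    new = ~old & (evo.ccf[:, j] > tolerance)
    new_labels = [lab for k, lab in enumerate(evo.clone_labels) if new[k]]
    extra = window.extra_interpolation
    if extra is None:
        extra = bool(new_labels)
    return i, j, old, new, new_labels, extra


def estimate_therapy_effect(
    evo: ClonalEvolution,
    window: TherapyWindow,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ClonalEvolution:
    """Insert the estimated end-of-therapy time point (tagged ``therapy``).

    Every clone present before therapy gets
    ``uccf(therapy) = min(uccf(t_i), uccf(t_j))``; CCFs are rebuilt leaf-up;
    clones absent before therapy are zero at the therapy point.
    """
    i, j, old, new, new_labels, extra = _window_geometry(evo, window, tolerance)
    ti, tj = evo.timepoints[i], evo.timepoints[j]

    position = window.position
    if position is None:
        k = 0
        if extra and new_labels:
            survivors = _predicted_survivors(evo, i, j, old, tolerance)
            recalc = recalculated_nested_levels(evo, survivors)
            k = max((recalc[lab] for lab in new_labels), default=0)
        position = 1.0 / (k + 2)
    x = ti + position * (tj - ti)

    uccf = unique_ccf_matrix(evo.ccf, evo.clone_labels, evo.parents)
    col_uccf = np.where(
        old, np.minimum(uccf[:, i], uccf[:, j]), 0.0
    )
    col = ccf_from_unique(
        np.clip(col_uccf, 0.0, None).reshape(-1, 1),
        evo.clone_labels,
        evo.parents,
    )[:, 0]
    # a clone absent before therapy contributes nothing, even via children
    col[~old] = 0.0

    out = evo.with_inserted_timepoints(j, [x], col.reshape(-1, 1), THERAPY)
    report = check_validity(
        out.ccf, out.parents, out.clone_labels, tolerance=max(tolerance, 1e-9)
    )
    if not report.passed:
        warnings.warn(
            "therapy estimation produced a transiently invalid trajectory: "
            + "; ".join(v.message for v in report.violations),
            stacklevel=2,
        )
    return out


def _predicted_survivors(evo, i, j, old, tolerance) -> set[str]:
    """Clones that will be nonzero at the therapy point (min rule)."""
    uccf = unique_ccf_matrix(evo.ccf, evo.clone_labels, evo.parents)
    col_uccf = np.where(old, np.minimum(uccf[:, i], uccf[:, j]), 0.0)
    col = ccf_from_unique(
        np.clip(col_uccf, 0.0, None).reshape(-1, 1),
        evo.clone_labels,
        evo.parents,
    )[:, 0]
    col[~old] = 0.0
    return {
        lab for k, lab in enumerate(evo.clone_labels) if col[k] > tolerance
    }


def _find_therapy_column(evo: ClonalEvolution) -> int:
    cols = [k for k, kind in enumerate(evo.timepoint_kind) if kind == THERAPY]
    if not cols:
        raise UsageError("no therapy time point present; estimate it first")
    return cols[-1]


def interpolate_post_therapy(
    evo: ClonalEvolution,
    window: TherapyWindow | None = None,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ClonalEvolution:
    """Interpolate the re-expansion between the therapy point and the next
    measured time point.

    Inserts ``max(recalculated nested levels)`` points.  A new clone with
    recalculated level ``z`` is zero at the first ``z`` inserted points;
    afterwards childless clones develop linearly to their measured end value
    while clones with children hold their unique CCF at the measured end
    value.  Surviving clones' unique CCFs move linearly.  No-op when no new
    clones exist.
    """
    p = _find_therapy_column(evo)
    j = p + 1
    if j >= evo.n_timepoints:
        raise UsageError("therapy point has no following measured time point")
    xp, xj = evo.timepoints[p], evo.timepoints[j]

    therapy_clones = {
        lab
        for k, lab in enumerate(evo.clone_labels)
        if evo.ccf[k, p] > tolerance
    }
    new_final = [
        lab
        for k, lab in enumerate(evo.clone_labels)
        if evo.ccf[k, p] <= tolerance and evo.ccf[k, j] > tolerance
    ]
    if not new_final:
        return evo
    recalc = recalculated_nested_levels(evo, therapy_clones)
    n_insert = max(recalc[lab] for lab in new_final)
    if n_insert == 0:
        return evo

    fracs = [(q + 1) / (n_insert + 1) for q in range(n_insert)]
    xs = xp + np.asarray(fracs) * (xj - xp)

    uccf = unique_ccf_matrix(evo.ccf, evo.clone_labels, evo.parents)
    live_children = {
        lab: [
            ch
            for ch in evo.children_of(lab)
            if evo.ccf[evo.index(ch), j] > tolerance
        ]
        for lab in evo.clone_labels
    }

    col_uccf = np.zeros((evo.n_clones, n_insert))
    for k, lab in enumerate(evo.clone_labels):
        if lab in therapy_clones:
            col_uccf[k] = np.interp(
                xs, [xp, xj], [max(uccf[k, p], 0.0), max(uccf[k, j], 0.0)]
            )
        elif lab in new_final:
            z = recalc[lab]
            x_start = xp if z == 0 else xs[z - 1]
            for q in range(n_insert):
                if q < z:
                    col_uccf[k, q] = 0.0
                elif live_children[lab]:
                    col_uccf[k, q] = max(uccf[k, j], 0.0)
                else:
                    col_uccf[k, q] = (
                        max(uccf[k, j], 0.0) * (xs[q] - x_start) / (xj - x_start)
                    )
        # clones absent at both the therapy point and t_j stay zero

    columns = ccf_from_unique(col_uccf, evo.clone_labels, evo.parents)
    # staging: zero out a new clone (and its contribution) where q < z is
    # already handled through col_uccf; children of staged clones are staged
    # no later than their parent by construction of recalculated levels.
    out = evo.with_inserted_timepoints(j, xs, columns, INTERPOLATED)
    report = check_validity(
        out.ccf, out.parents, out.clone_labels, tolerance=max(tolerance, 1e-9)
    )
    if not report.passed:
        warnings.warn(
            "post-therapy interpolation produced a transiently invalid "
            "trajectory: " + "; ".join(v.message for v in report.violations),
            stacklevel=2,
        )
    return out


def apply_therapy(
    evo: ClonalEvolution,
    window: TherapyWindow,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ClonalEvolution:
    """Estimate the therapy point and, if enabled, the re-expansion."""
    i, j, old, new, new_labels, extra = _window_geometry(evo, window, tolerance)
    out = estimate_therapy_effect(evo, window, tolerance=tolerance)
    if extra:
        out = interpolate_post_therapy(out, window, tolerance=tolerance)
    return out
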