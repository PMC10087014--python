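"""Automatic interpolation of time points.

Two operations are provided, mirroring the two halves of the published
procedure:

* :func:`interpolate_initial` -- reconstructs the development *before* the
  first measured time point.  Clones of the same nested level are assumed to
  have developed at approximately the same time, with higher levels arising
  later.  One point is inserted per nested level present at ``t_1``; walking
  backwards, the deepest remaining level is zeroed at each step while the
  surviving clones keep their unique CCF from ``t_1``.
* :func:`interpolate_between` -- fills the gap between two adjacent measured
  time points.  Clones already present follow a straight line; newly
  appearing clones start successively, one inserted point per unique new
  nested level beyond the first, then develop linearly towards their
  measured end value.

:func:`interpolate_all` composes both over the whole axis.  Interpolated
columns are tagged ``interpolated``; measured columns are never modified.
Inserted points are evenly spaced inside their interval by default; a list
of fractional positions can skew them.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .errors import UsageError
from .model import (
    DEFAULT_TOLERANCE,
    INTERPOLATED,
    MEASURED,
    ClonalEvolution,
    ccf_from_unique,
    unique_ccf_matrix,
)
from .validity import check_validity


def _initial_step(evo: ClonalEvolution) -> float:
    """Axis step used when extending the axis before the first time point."""
    measured = [evo.timepoints[i] for i in evo.measured_indices]
    if len(measured) < 2:
        return 1.0
    return float(np.min(np.diff(measured)))


def interpolate_initial(
    evo: ClonalEvolution, *, tolerance: float = DEFAULT_TOLERANCE
) -> ClonalEvolution:
    """Insert the reconstructed development before the first time point.

    The number of inserted points equals the maximum nested level among the
    clones present at the first time point.  No-op when all initial clones
    are founders.
    """
    first = 0
    initial = [
        lab
        for lab in evo.clone_labels
        if evo.ccf[evo.index(lab), first] > tolerance
    ]
    if not initial:
        return evo
    levels = {lab: evo.nested_level(lab) for lab in initial}
    max_level = max(levels.values())
    if max_level == 0:
        return evo

    uccf_t1 = unique_ccf_matrix(evo.ccf, evo.clone_labels, evo.parents)[:, first]
    step = _initial_step(evo)
    t1 = evo.timepoints[first]
    # k = 1 is the inserted point closest to t_1; clones with nested level
    # deeper than (max_level - k) have not developed yet at that point.
    columns = np.zeros((evo.n_clones, max_level))
    coords = np.empty(max_level)
    for k in range(1, max_level + 1):
        coords[max_level - k] = t1 - step * k
        cutoff = max_level - k
        col_uccf = np.zeros(evo.n_clones)
        for lab in initial:
            if levels[lab] <= cutoff:
                col_uccf[evo.index(lab)] = max(uccf_t1[evo.index(lab)], 0.0)
        columns[:, max_level - k] = ccf_from_unique(
            col_uccf.reshape(-1, 1), evo.clone_labels, evo.parents
        )[:, 0]

    out = evo.with_inserted_timepoints(0, coords, columns, INTERPOLATED)
    _assert_valid(out, tolerance)
    return out


def _resolve_adjacent_pair(evo: ClonalEvolution, interval) -> tuple[int, int]:
    """Resolve an interval given as (index, index) or (label, label)."""
    a, b = interval
    if isinstance(a, str) or isinstance(b, str):
        try:
            a = evo.timepoint_labels.index(str(a))
            b = evo.timepoint_labels.index(str(b))
        except ValueError as exc:
            raise UsageError(f"unknown time point in interval {interval}") from exc
    a, b = int(a), int(b)
    if b != a + 1:
        raise UsageError(
            f"interval ({evo.timepoint_labels[a]}, {evo.timepoint_labels[b]}) "
            "is not an adjacent pair"
        )
    for i in (a, b):
        if evo.timepoint_kind[i] != MEASURED:
            raise UsageError(
                f"time point {evo.timepoint_labels[i]} is not measured"
            )
    return a, b


def interpolate_between(
    evo: ClonalEvolution,
    interval,
    *,
    positions: Sequence[float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ClonalEvolution:
    """Interpolate between two adjacent measured time points.

    ``positions`` optionally gives fractional locations in the open interval
    (0, 1) for the inserted points (default: evenly distributed).  The number
    of points is fixed by the evolution itself: (count of unique nested
    levels among newly appearing clones) - 1.
    """
    i, j = _resolve_adjacent_pair(evo, interval)
    ti, tj = evo.timepoints[i], evo.timepoints[j]

    old = evo.ccf[:, i] > tolerance
    new = ~old & (evo.ccf[:, j] > tolerance)
    new_labels = [lab for k, lab in enumerate(evo.clone_labels) if new[k]]
    unique_levels = sorted({evo.nested_level(lab) for lab in new_labels})
    n_insert = max(len(unique_levels) - 1, 0)
    if n_insert == 0:
        return evo

    if positions is None:
        fracs = [(p + 1) / (n_insert + 1) for p in range(n_insert)]
    else:
        fracs = [float(f) for f in positions]
        if len(fracs) != n_insert:
            raise UsageError(
                f"{n_insert} inserted point(s) required, {len(fracs)} "
                "position(s) given"
            )
        if any(not 0 < f < 1 for f in fracs) or any(np.diff(fracs) <= 0):
            raise UsageError("positions must be strictly increasing in (0, 1)")
    xs = ti + np.asarray(fracs) * (tj - ti)

    columns = np.zeros((evo.n_clones, n_insert))
    for k, lab in enumerate(evo.clone_labels):
        if old[k]:
            columns[k] = np.interp(xs, [ti, tj], [evo.ccf[k, i], evo.ccf[k, j]])
        elif new[k]:
            z = sum(1 for u in unique_levels if u < evo.nested_level(lab))
            x_start = ti if z == 0 else xs[z - 1]
            for p in range(n_insert):
                if p < z:
                    columns[k, p] = 0.0
                else:
                    columns[k, p] = (
                        evo.ccf[k, j] * (xs[p] - x_start) / (tj - x_start)
                    )
        # clones absent at both endpoints stay zero

    out = evo.with_inserted_timepoints(j, xs, columns, INTERPOLATED)
    out = _repair_nesting(out, range(j, j + n_insert), tolerance)
    _assert_valid(out, tolerance)
    return out


def interpolate_all(
    evo: ClonalEvolution, *, tolerance: float = DEFAULT_TOLERANCE
) -> ClonalEvolution:
    """Initial interpolation plus between-interpolation of every adjacent
    measured pair."""
    measured = evo.measured_indices
    # right-to-left keeps the indices of untouched pairs stable
    for a, b in zip(measured[-2::-1], measured[-1:0:-1]):
        if b == a + 1:
            evo = interpolate_between(evo, (a, b), tolerance=tolerance)
    return interpolate_initial(evo, tolerance=tolerance)


def _repair_nesting(
    evo: ClonalEvolution, inserted_columns, tolerance: float
) -> ClonalEvolution:
    """Floor negative unique CCFs at inserted columns and rebuild parents.

    Skewed positions can transiently let late-starting children exceed a
    linearly moving parent; only inserted columns are adjusted, and only
    upwards.
    """
    uccf = unique_ccf_matrix(evo.ccf, evo.clone_labels, evo.parents)
    cols = list(inserted_columns)
    bad = uccf[:, cols] < -tolerance
    if not np.any(bad):
        return evo
    warnings.warn(
        "interpolation produced children exceeding a parent at inserted "
        "time point(s); parent CCFs were raised to restore nesting",
        stacklevel=3,
    )
    ccf = evo.ccf.copy()
    fixed = ccf_from_unique(
        np.clip(uccf[:, cols], 0.0, None), evo.clone_labels, evo.parents
    )
    # only raise clones whose unique CCF went negative (keeps others linear)
    for k in range(evo.n_clones):
        for c_local, c in enumerate(cols):
            if uccf[k, c] < -tolerance:
                ccf[k, c] = fixed[k, c_local]
    return evo.with_ccf(ccf)


def _assert_valid(evo: ClonalEvolution, tolerance: float) -> None:
    report = check_validity(
        evo.ccf, evo.parents, evo.clone_labels, tolerance=max(tolerance, 1e-9)
    )
    if not report.passed:  # pragma: no cover - guarded by construction
        warnings.warn(
            "interpolated evolution failed the validity check: "
            + "; ".join(v.message for v in report.violations),
            stacklevel=3,
        )
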