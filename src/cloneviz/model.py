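"""Core data model for clonal evolutions.

A :class:`ClonalEvolution` holds a matrix of cancer cell fractions (CCF, in
percent) for ``n`` clones over ``m`` time points, together with a
parental-relation forest rooted in normal cells.  All derived quantities used
by the algorithms in this package (children sets, nested levels, unique CCFs
and their inverse) live here.

Conventions
-----------
* CCFs are percentages in ``[0, 100]``.  A clone's CCF includes all of its
  descendants; the *unique* CCF (``unique_ccf``) subtracts the direct
  children and is the fraction of cells belonging to exactly that clone.
* The parent of a founding clone is the reserved value :data:`NORMAL`.
  ``"normal"`` (any case) and the numeral ``0`` are accepted on input.
* Time points carry numeric coordinates (strictly increasing) plus display
  labels, and a per-column kind tag: ``measured``, ``interpolated`` or
  ``therapy``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    CloneLookupError,
    FractionScaleError,
    StructuralError,
    UsageError,
    ValidationError,
)

#: Reserved parent value for clones developing directly from normal cells.
NORMAL = "normal"

_NORMAL_ALIASES = {"normal", "0"}

MEASURED = "measured"
INTERPOLATED = "interpolated"
THERAPY = "therapy"
TIMEPOINT_KINDS = (MEASURED, INTERPOLATED, THERAPY)

#: Absolute tolerance (in percent) for all inequality checks.
DEFAULT_TOLERANCE = 1e-9


def normalize_parent(value) -> str:
    """Map the accepted spellings of the normal-cell parent onto NORMAL."""
    if value is None:
        return NORMAL
    if isinstance(value, (int, np.integer)) and value == 0:
        return NORMAL
    text = str(value).strip()
    if text.lower() in _NORMAL_ALIASES:
        return NORMAL
    return text


def is_normal(value) -> bool:
    return normalize_parent(value) == NORMAL


def children_map(
    clone_labels: Sequence[str], parents: Sequence[str]
) -> dict[str, tuple[str, ...]]:
    """Children of every clone (and of NORMAL), in clone input order."""
    known = set(clone_labels)
    cm: dict[str, list[str]] = {lab: [] for lab in clone_labels}
    cm[NORMAL] = []
    for lab, parent in zip(clone_labels, parents):
        p = normalize_parent(parent)
        if p != NORMAL and p not in known:
            raise CloneLookupError(f"parent {p!r} of clone {lab!r} is not a clone")
        cm[p].append(lab)
    return {k: tuple(v) for k, v in cm.items()}


def assert_forest(clone_labels: Sequence[str], parents: Sequence[str]) -> None:
    """Raise StructuralError if following parent links does not reach NORMAL."""
    if len(clone_labels) != len(set(clone_labels)):
        seen: set[str] = set()
        dupes = sorted({lab for lab in clone_labels if lab in seen or seen.add(lab)})
        raise StructuralError(f"duplicate clone labels: {dupes}")
    parent_of = {
        lab: normalize_parent(p) for lab, p in zip(clone_labels, parents)
    }
    known = set(clone_labels)
    for lab, p in parent_of.items():
        if p != NORMAL and p not in known:
            raise CloneLookupError(f"parent {p!r} of clone {lab!r} is not a clone")
        if p == lab:
            raise StructuralError(
                f"clone {lab!r} is its own parent", cycle=(lab, lab)
            )
    resolved: set[str] = set()
    for start in clone_labels:
        path: list[str] = []
        on_path: set[str] = set()
        node = start
        while node != NORMAL and node not in resolved:
            if node in on_path:
                i = path.index(node)
                raise StructuralError(
                    "cycle in parental relations: "
                    + " -> ".join(path[i:] + [node]),
                    cycle=tuple(path[i:] + [node]),
                )
            path.append(node)
            on_path.add(node)
            node = parent_of[node]
        resolved.update(path)


def nested_levels(
    clone_labels: Sequence[str], parents: Sequence[str]
) -> dict[str, int]:
    """Depth of every clone: 0 for founders, parent's level + 1 otherwise."""
    assert_forest(clone_labels, parents)
    parent_of = {lab: normalize_parent(p) for lab, p in zip(clone_labels, parents)}
    levels: dict[str, int] = {}

    def level(lab: str) -> int:
        if lab in levels:
            return levels[lab]
        p = parent_of[lab]
        lv = 0 if p == NORMAL else level(p) + 1
        levels[lab] = lv
        return lv

    for lab in clone_labels:
        level(lab)
    return levels


def _leaf_first_order(
    clone_labels: Sequence[str], parents: Sequence[str]
) -> list[int]:
    """Clone indices ordered so every clone precedes its parent."""
    levels = nested_levels(clone_labels, parents)
    idx = {lab: i for i, lab in enumerate(clone_labels)}
    return [idx[lab] for lab in sorted(clone_labels, key=lambda l: -levels[l])]


def unique_ccf_matrix(
    ccf: np.ndarray, clone_labels: Sequence[str], parents: Sequence[str]
) -> np.ndarray:
    """ccf minus the summed ccf of each clone's direct children."""
    cm = children_map(clone_labels, parents)
    idx = {lab: i for i, lab in enumerate(clone_labels)}
    uccf = np.asarray(ccf, dtype=float).copy()
    for lab in clone_labels:
        for child in cm[lab]:
            uccf[idx[lab]] -= ccf[idx[child]]
    return uccf


def ccf_from_unique(
    uccf: np.ndarray,
    clone_labels: Sequence[str],
    parents: Sequence[str],
    *,
    tolerance: float = DEFAULT_TOLERANCE,
) -> np.ndarray:
    """Leaf-to-root accumulation; exact inverse of :func:`unique_ccf_matrix`.

    Raises UsageError for negative unique CCFs (beyond tolerance).
    """
    uccf = np.asarray(uccf, dtype=float)
    if np.any(uccf < -tolerance):
        c, t = np.argwhere(uccf < -tolerance)[0]
        raise UsageError(
            f"negative unique CCF {uccf[c, t]:g} for clone "
            f"{clone_labels[c]!r} at time point index {t}"
        )
    ccf = np.clip(uccf, 0.0, None).copy()
    idx = {lab: i for i, lab in enumerate(clone_labels)}
    for i in _leaf_first_order(clone_labels, parents):
        p = normalize_parent(parents[i])
        if p != NORMAL:
            ccf[idx[p]] += ccf[i]
    return ccf


@dataclass(frozen=True)
class UniqueCCF:
    """Derived matrix of unique CCFs (clone CCF minus its children's sum)."""

    uccf: np.ndarray
    clone_labels: tuple[str, ...]


@dataclass(frozen=True)
class ClonalEvolution:
    """Immutable clonal-evolution object: CCF matrix + parental forest + axis.

    Use :func:`build_evolution` to construct one from raw inputs: it performs
    the full structural and validity checking.  The plain constructor is used
    internally by algorithms that guarantee validity by construction.
    """

    clone_labels: tuple[str, ...]
    parents: tuple[str, ...]
    timepoints: np.ndarray
    ccf: np.ndarray
    timepoint_labels: tuple[str, ...]
    timepoint_kind: tuple[str, ...]

    # -- basic shape ------------------------------------------------------

    @property
    def n_clones(self) -> int:
        return len(self.clone_labels)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_labels)

    def index(self, clone: str) -> int:
        try:
            return self._index[clone]
        except KeyError:
            raise CloneLookupError(f"unknown clone {clone!r}") from None

    @cached_property
    def _index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.clone_labels)}

    # -- phylogeny --------------------------------------------------------

    @cached_property
    def _children(self) -> dict[str, tuple[str, ...]]:
        return children_map(self.clone_labels, self.parents)

    def children_of(self, clone: str) -> tuple[str, ...]:
        """Direct children of ``clone``; ``children_of(NORMAL)`` = founders."""
        key = normalize_parent(clone)
        if key != NORMAL and key not in self._index:
            raise CloneLookupError(f"unknown clone {clone!r}")
        return self._children[key]

    @property
    def founders(self) -> tuple[str, ...]:
        return self._children[NORMAL]

    @cached_property
    def _levels(self) -> dict[str, int]:
        return nested_levels(self.clone_labels, self.parents)

    def nested_level(self, clone: str) -> int:
        if clone not in self._index:
            raise CloneLookupError(f"unknown clone {clone!r}")
        return self._levels[clone]

    def nested_level_array(self) -> np.ndarray:
        return np.array([self._levels[lab] for lab in self.clone_labels])

    def parent_of(self, clone: str) -> str:
        return self.parents[self.index(clone)]

    def ancestors(self, clone: str) -> tuple[str, ...]:
        out = []
        node = self.parent_of(clone)
        while node != NORMAL:
            out.append(node)
            node = self.parent_of(node)
        return tuple(out)

    def subtree_depth(self, clone: str) -> int:
        """Height of the subtree rooted at ``clone`` (leaf = 0)."""
        kids = self.children_of(clone)
        if not kids:
            return 0
        return 1 + max(self.subtree_depth(k) for k in kids)

    # -- derived matrices -------------------------------------------------

    def unique_ccf(self) -> UniqueCCF:
        return UniqueCCF(
            unique_ccf_matrix(self.ccf, self.clone_labels, self.parents),
            self.clone_labels,
        )

    def unique_ccf_matrix(self) -> np.ndarray:
        return unique_ccf_matrix(self.ccf, self.clone_labels, self.parents)

    # -- time axis --------------------------------------------------------

    @property
    def measured_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, k in enumerate(self.timepoint_kind) if k == MEASURED
        )

    def first_positive_index(
        self, clone: str, tolerance: float = DEFAULT_TOLERANCE
    ) -> int | None:
        row = self.ccf[self.index(clone)]
        pos = np.nonzero(row > tolerance)[0]
        return int(pos[0]) if len(pos) else None

    # -- editing helpers (internal; callers must keep the result valid) ---

    def with_inserted_timepoints(
        self,
        at: int,
        coords: Sequence[float],
        columns: np.ndarray,
        kind: str,
        labels: Sequence[str] | None = None,
    ) -> "ClonalEvolution":
        """Insert columns before existing column index ``at``."""
        coords = np.asarray(coords, dtype=float)
        columns = np.asarray(columns, dtype=float)
        if columns.shape != (self.n_clones, len(coords)):
            raise UsageError("inserted column block has wrong shape")
        if labels is None:
            labels = tuple(_default_tp_label(c) for c in coords)
        new_tp = np.concatenate(
            [self.timepoints[:at], coords, self.timepoints[at:]]
        )
        if np.any(np.diff(new_tp) <= 0):
            raise UsageError("inserted time coordinates break strict ordering")
        new_ccf = np.concatenate(
            [self.ccf[:, :at], columns, self.ccf[:, at:]], axis=1
        )
        new_labels = (
            self.timepoint_labels[:at] + tuple(labels) + self.timepoint_labels[at:]
        )
        new_kind = (
            self.timepoint_kind[:at]
            + tuple([kind] * len(coords))
            + self.timepoint_kind[at:]
        )
        return replace(
            self,
            timepoints=new_tp,
            ccf=new_ccf,
            timepoint_labels=new_labels,
            timepoint_kind=new_kind,
        )

    def with_ccf(self, ccf: np.ndarray) -> "ClonalEvolution":
        ccf = np.asarray(ccf, dtype=float)
        if ccf.shape != self.ccf.shape:
            raise UsageError("replacement CCF matrix has wrong shape")
        return replace(self, ccf=ccf)


def _default_tp_label(coord: float) -> str:
    return f"t{coord:g}"


def build_evolution(
    ccf_table,
    parents,
    timepoints: Sequence[float] | None = None,
    *,
    clone_labels: Sequence[str] | None = None,
    timepoint_labels: Sequence[str] | None = None,
    timepoint_kind: Sequence[str] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ClonalEvolution:
    """Build and validate a :class:`ClonalEvolution` from raw inputs.

    Parameters
    ----------
    ccf_table:
        Either an ``n x m`` array-like of percent values, or a mapping
        ``{clone label: row}`` (in which case ``clone_labels`` is implied).
    parents:
        Sequence of per-clone parent references (label, ``"normal"`` or 0),
        or a mapping ``{clone label: parent}``.
    timepoints:
        Strictly increasing numeric coordinates; defaults to ``0..m-1``.

    Raises
    ------
    StructuralError
        For cycles, duplicate labels or shape mismatches.
    ValidationError
        When the table violates any of the four validity rules; the
        exception carries the structured report.
    FractionScaleError
        When every value is <= 1 (fractions instead of percent suspected).
    """
    if isinstance(ccf_table, Mapping):
        if clone_labels is None:
            clone_labels = list(ccf_table.keys())
        ccf = np.array([ccf_table[lab] for lab in clone_labels], dtype=float)
    else:
        ccf = np.array(ccf_table, dtype=float)
        if ccf.ndim == 1:
            ccf = ccf.reshape(1, -1)
        if clone_labels is None:
            clone_labels = [str(i + 1) for i in range(ccf.shape[0])]
    clone_labels = tuple(str(lab) for lab in clone_labels)

    for lab in clone_labels:
        if normalize_parent(lab) == NORMAL:
            raise StructuralError(
                f"clone label {lab!r} collides with the reserved normal-cell label"
            )

    if isinstance(parents, Mapping):
        missing = [lab for lab in clone_labels if lab not in parents]
        if missing:
            raise CloneLookupError(f"no parent given for clones {missing}")
        parents = [parents[lab] for lab in clone_labels]
    parents = tuple(normalize_parent(p) for p in parents)
    if len(parents) != len(clone_labels):
        raise StructuralError(
            f"{len(clone_labels)} clones but {len(parents)} parent references"
        )

    if ccf.ndim != 2:
        raise StructuralError("CCF table must be two-dimensional")
    n, m = ccf.shape
    if n != len(clone_labels):
        raise StructuralError("CCF row count does not match clone labels")
    if m < 1:
        raise StructuralError("at least one time point is required")
    if np.any(np.isnan(ccf)):
        c, t = np.argwhere(np.isnan(ccf))[0]
        raise StructuralError(
            f"missing CCF value for clone {clone_labels[c]!r} at time point "
            f"index {t}; absent cells are not implicit zeros"
        )
    if np.any(ccf < -tolerance) or np.any(ccf > 100 + tolerance):
        c, t = np.argwhere((ccf < -tolerance) | (ccf > 100 + tolerance))[0]
        raise ValueError(
            f"CCF {ccf[c, t]:g} for clone {clone_labels[c]!r} out of [0, 100]"
        )
    if np.nanmax(ccf, initial=0.0) <= 1.0 and np.any(ccf > 0):
        raise FractionScaleError(
            "all CCF values are <= 1: the table looks like fractions; "
            "percent values in [0, 100] are required"
        )

    if timepoints is None:
        timepoints = np.arange(m, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.shape != (m,):
        raise StructuralError("time coordinates do not match CCF columns")
    if np.any(np.diff(timepoints) <= 0):
        raise StructuralError("time coordinates must be strictly increasing")
    if timepoint_labels is None:
        timepoint_labels = tuple(_default_tp_label(c) for c in timepoints)
    else:
        timepoint_labels = tuple(str(x) for x in timepoint_labels)
    if timepoint_kind is None:
        timepoint_kind = tuple([MEASURED] * m)
    else:
        timepoint_kind = tuple(timepoint_kind)
        bad = [k for k in timepoint_kind if k not in TIMEPOINT_KINDS]
        if bad:
            raise StructuralError(f"unknown time point kind(s): {bad}")

    assert_forest(clone_labels, parents)

    from .validity import check_validity  # local import: avoids module cycle

    report = check_validity(ccf, parents, clone_labels, tolerance=tolerance)
    if not report.passed:
        raise ValidationError(report)

    return ClonalEvolution(
        clone_labels=clone_labels,
        parents=parents,
        timepoints=timepoints,
        ccf=ccf,
        timepoint_labels=timepoint_labels,
        timepoint_kind=timepoint_kind,
    )
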