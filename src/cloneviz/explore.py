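"""Enumeration of alternative parental-relation vectors for a CCF table.

Given ``n`` clones, every clone can take one of ``n`` parents (the ``n - 1``
other clones, or normal cells), giving an ``n^n`` space.  Two pre-filters
shrink the space before the expensive per-vector validity check:

* **filter 1** (linear relations): clone ``c`` cannot parent clone ``j`` if
  ``ccf(c, t) < ccf(j, t)`` at any time point.
* **filter 2** (branched relations): if clone ``j``'s candidate set is the
  singleton ``{c}``, then ``c`` cannot additionally parent clone ``k``
  unless ``ccf(c, t) - ccf(j, t) >= ccf(k, t)`` at every time point.
  Applied repeatedly until no candidate set changes.

The surviving Cartesian product is bounded by a hard permutation cap
(default 20,000); exceeding it aborts with :class:`PermutationCapError`
rather than silently truncating the enumeration.  Each surviving vector is
screened for forest-ness (no cycles) and then run through the full validity
check; exactly the valid vectors are returned, in lexicographic order by
clone with ``NORMAL`` sorting before all clone labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import PermutationCapError, UsageError
from .model import DEFAULT_TOLERANCE, NORMAL, normalize_parent
from .validity import check_validity

#: Hard default on the number of candidate vectors submitted to the
#: thorough validity check.
MAX_PERMUTATIONS = 20000


@dataclass(frozen=True)
class ExplorerConfig:
    max_permutations: int = MAX_PERMUTATIONS
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self):
        if self.max_permutations < 1:
            raise UsageError("max_permutations must be >= 1")


@dataclass(frozen=True)
class ExplorationSummary:
    n_clones: int
    total_space: int
    after_filter1: int
    after_filter2: int
    forests: int
    valid: int

    def to_dict(self) -> dict:
        return {
            "n_clones": self.n_clones,
            "total_space": self.total_space,
            "after_filter1": self.after_filter1,
            "after_filter2": self.after_filter2,
            "forests": self.forests,
            "valid": self.valid,
        }


def _ordered(candidates: set[str], clone_labels: Sequence[str]) -> list[str]:
    """NORMAL first, then clone labels in sorted order."""
    out = [NORMAL] if NORMAL in candidates else []
    out += sorted(c for c in candidates if c != NORMAL)
    return out


def candidate_parents(
    ccf,
    clone_labels: Sequence[str] | None = None,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
    constraints: Mapping[str, set] | None = None,
) -> dict[str, list[str]]:
    """Admissible parents per clone after both CCF pre-filters.

    ``constraints`` optionally restricts a clone's initial candidate set
    (e.g. pinning a known relation); the CCF filters themselves never remove
    ``NORMAL`` from a set.  Returns an ordered candidate list per clone
    (NORMAL first, then sorted labels).
    """
    ccf = np.asarray(ccf, dtype=float)
    if ccf.ndim == 1:
        ccf = ccf.reshape(1, -1)
    n = ccf.shape[0]
    if clone_labels is None:
        clone_labels = tuple(str(i + 1) for i in range(n))
    clone_labels = tuple(str(lab) for lab in clone_labels)
    idx = {lab: i for i, lab in enumerate(clone_labels)}

    cand: dict[str, set[str]] = {
        j: {NORMAL} | {c for c in clone_labels if c != j} for j in clone_labels
    }
    if constraints:
        for lab, allowed in constraints.items():
            if lab not in idx:
                raise UsageError(f"constraint names unknown clone {lab!r}")
            allowed = {normalize_parent(a) for a in allowed}
            if lab in allowed:
                raise UsageError(f"clone {lab!r} cannot be its own parent")
            cand[lab] &= allowed

    # filter 1: c cannot parent j if ccf(c, t) < ccf(j, t) anywhere
    for c in clone_labels:
        for j in clone_labels:
            if c == j or c not in cand[j]:
                continue
            if np.any(ccf[idx[c]] < ccf[idx[j]] - tolerance):
                cand[j].discard(c)

    # filter 2 to fixpoint: forced child j of c tightens c's budget for k
    changed = True
    while changed:
        changed = False
        for j in clone_labels:
            if len(cand[j]) != 1:
                continue
            (c,) = cand[j]
            if c == NORMAL:
                continue
            budget = ccf[idx[c]] - ccf[idx[j]]
            for k in clone_labels:
                if k in (c, j) or c not in cand[k]:
                    continue
                if np.any(budget < ccf[idx[k]] - tolerance):
                    cand[k].discard(c)
                    changed = True

    return {j: _ordered(cand[j], clone_labels) for j in clone_labels}


def is_forest(clone_labels: Sequence[str], parents: Sequence[str]) -> bool:
    """True iff following parent links always reaches NORMAL (no cycles)."""
    parent_of = dict(zip(clone_labels, parents))
    resolved: set[str] = set()
    for start in clone_labels:
        node, on_path = start, set()
        while node != NORMAL and node not in resolved:
            if node in on_path:
                return False
            on_path.add(node)
            node = parent_of[node]
        resolved |= on_path
    return True


def enumerate_trees(
    ccf,
    clone_labels: Sequence[str] | None = None,
    config: ExplorerConfig | None = None,
    *,
    constraints: Mapping[str, set] | None = None,
    return_summary: bool = False,
):
    """All parent vectors consistent with the CCF table.

    Returns a list of parent tuples aligned with ``clone_labels`` (entries
    are clone labels or :data:`NORMAL`).  With ``return_summary=True``
    additionally returns an :class:`ExplorationSummary` with the counts
    before/after each filter.

    Raises
    ------
    PermutationCapError
        If the filtered Cartesian product exceeds
        ``config.max_permutations``; no partial result is produced.
    """
    config = config or ExplorerConfig()
    ccf = np.asarray(ccf, dtype=float)
    if ccf.ndim == 1:
        ccf = ccf.reshape(1, -1)
    n = ccf.shape[0]
    if clone_labels is None:
        clone_labels = tuple(str(i + 1) for i in range(n))
    clone_labels = tuple(str(lab) for lab in clone_labels)

    after_f1 = candidate_parents(
        ccf, clone_labels, tolerance=config.tolerance, constraints=constraints
    )
    # recompute the filter-1-only sizes for the summary
    f1_only = candidate_parents(
        ccf, clone_labels, tolerance=config.tolerance
    )
    size_f1 = math.prod(len(f1_only[j]) for j in clone_labels)
    size = math.prod(len(after_f1[j]) for j in clone_labels)
    if size > config.max_permutations:
        raise PermutationCapError(size, config.max_permutations)

    forests = 0
    valid: list[tuple[str, ...]] = []
    for vector in itertools.product(*(after_f1[j] for j in clone_labels)):
        if not is_forest(clone_labels, vector):
            continue
        forests += 1
        report = check_validity(
            ccf, vector, clone_labels, tolerance=config.tolerance
        )
        if report.passed:
            valid.append(vector)

    if return_summary:
        summary = ExplorationSummary(
            n_clones=n,
            total_space=n**n,
            after_filter1=size_f1,
            after_filter2=size,
            forests=forests,
            valid=len(valid),
        )
        return valid, summary
    return valid
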