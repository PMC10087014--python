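"""Validity checking for CCF tables with parental relations.

Four rules are enforced:

* **V1** -- children-clones cannot exceed their parent at any time point.
* **V2** -- clones developing from normal cells cannot add up to more than
  100% at any time point.
* **V3** -- a clone cannot reappear: once its CCF was positive and then
  dropped to zero, it must stay zero.
* **V4** -- the same rule on unique CCFs: a parent thoroughly replaced by
  its children cannot reappear.

V3/V4 are implemented as the general "once positive, then zero, forever
zero" rule.  A ``literal_reappearance`` flag restores the narrower scan of
three consecutive time points (positive, zero, positive) for compatibility;
the general rule additionally catches patterns such as ``[5, 0, 0, 5]``.

The check operates on raw matrices so that the tree explorer can evaluate
candidate parent vectors cheaply; it raises :class:`StructuralError` for
cycles and shape mismatches (distinct from the V1-V4 report).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import StructuralError
from .model import (
    DEFAULT_TOLERANCE,
    NORMAL,
    assert_forest,
    children_map,
    normalize_parent,
    unique_ccf_matrix,
)

RULE_SUMMARY = {
    "V1": "children-clones cannot exceed their parents",
    "V2": "clones developing from normal cells cannot add up to more than 100%",
    "V3": "a clone cannot reappear",
    "V4": "a thoroughly replaced parent-clone cannot reappear",
}


@dataclass(frozen=True)
class Violation:
    rule_id: str
    clone: str | None
    timepoint: int | None
    message: str

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "clone": self.clone,
            "timepoint": self.timepoint,
            "message": self.message,
        }


@dataclass(frozen=True)
class ValidityReport:
    violations: tuple[Violation, ...]

    @property
    def passed(self) -> bool:
        return not self.violations

    def to_json_lines(self) -> str:
        return "\n".join(json.dumps(v.to_dict()) for v in self.violations)

    def __bool__(self) -> bool:  # truthiness == passed, like a check result
        return self.passed


def _reappearance_indices(
    row: np.ndarray, tolerance: float, literal: bool
) -> list[int]:
    """Time point indices at which the trajectory illegally reappears."""
    pos = row > tolerance
    out: list[int] = []
    if literal:
        for t in range(len(row) - 2):
            if pos[t] and not pos[t + 1] and pos[t + 2]:
                out.append(t + 2)
        return out
    seen_positive = False
    seen_gap = False
    for t, p in enumerate(pos):
        if p:
            if seen_gap:
                out.append(t)
                break  # one report per clone suffices for the general rule
            seen_positive = True
        elif seen_positive:
            seen_gap = True
    return out


def check_validity(
    ccf,
    parents: Sequence,
    clone_labels: Sequence[str] | None = None,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
    literal_reappearance: bool = False,
) -> ValidityReport:
    """Evaluate the four validity rules on a raw CCF matrix.

    Returns a structured report listing every violated rule instance.
    Cycles in ``parents`` and shape mismatches raise
    :class:`StructuralError` instead of appearing in the report.
    """
    ccf = np.asarray(ccf, dtype=float)
    if ccf.ndim == 1:
        ccf = ccf.reshape(1, -1)
    n, m = ccf.shape
    if clone_labels is None:
        clone_labels = tuple(str(i + 1) for i in range(n))
    else:
        clone_labels = tuple(str(lab) for lab in clone_labels)
    if len(parents) != n:
        raise StructuralError(
            f"{n} CCF rows but {len(parents)} parent references"
        )
    parents = tuple(normalize_parent(p) for p in parents)
    assert_forest(clone_labels, parents)

    cm = children_map(clone_labels, parents)
    idx = {lab: i for i, lab in enumerate(clone_labels)}
    uccf = unique_ccf_matrix(ccf, clone_labels, parents)

    violations: list[Violation] = []

    # V1: parent must cover the sum of its children everywhere.
    for lab in clone_labels:
        kids = cm[lab]
        if not kids:
            continue
        child_sum = ccf[[idx[k] for k in kids]].sum(axis=0)
        row = ccf[idx[lab]]
        for t in np.nonzero(row + tolerance < child_sum)[0]:
            violations.append(
                Violation(
                    "V1",
                    lab,
                    int(t),
                    f"V1: children of {lab!r} sum to {child_sum[t]:g} > "
                    f"parent CCF {row[t]:g} at time point index {t}",
                )
            )

    # V2: founders may not exceed 100% jointly.
    founders = cm[NORMAL]
    if founders:
        founder_sum = ccf[[idx[f] for f in founders]].sum(axis=0)
        for t in np.nonzero(founder_sum > 100 + tolerance)[0]:
            violations.append(
                Violation(
                    "V2",
                    None,
                    int(t),
                    f"V2: founder CCFs sum to {founder_sum[t]:g} > 100 "
                    f"at time point index {t}",
                )
            )

    # V3 / V4: no reappearance, on ccf and on unique ccf.
    for rule, matrix in (("V3", ccf), ("V4", uccf)):
        for lab in clone_labels:
            for t in _reappearance_indices(
                matrix[idx[lab]], tolerance, literal_reappearance
            ):
                what = "CCF" if rule == "V3" else "unique CCF"
                violations.append(
                    Violation(
                        rule,
                        lab,
                        int(t),
                        f"{rule}: {what} of {lab!r} reappears at time point "
                        f"index {t} after dropping to zero",
                    )
                )

    order = {"V1": 0, "V2": 1, "V3": 2, "V4": 3}
    violations.sort(
        key=lambda v: (order[v.rule_id], v.timepoint or 0, v.clone or "")
    )
    return ValidityReport(tuple(violations))
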