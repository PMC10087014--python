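"""Reading and writing of CCF tables.

Dialect: CSV or TSV (UTF-8).  The first column is ``clone``, an optional
second column ``parent`` (another clone label or ``normal``/``0``), and the
remaining column headers are numeric time coordinates, optionally prefixed
with ``t`` (``t0``, ``t53``, ...).  Values are CCFs in percent.  An optional
second row whose first cell is ``#kind`` tags every time point as
``measured``, ``interpolated`` or ``therapy``.

The writer is deterministic: fixed column order, 6 significant digits,
``\n`` line endings -- identical evolutions yield byte-identical files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError, UsageError
from .model import (
    MEASURED,
    NORMAL,
    TIMEPOINT_KINDS,
    ClonalEvolution,
    build_evolution,
    normalize_parent,
)


@dataclass(frozen=True)
class CCFTable:
    """Raw parse result of a CCF table file."""

    clone_labels: tuple[str, ...]
    parents: tuple[str, ...] | None
    timepoints: np.ndarray
    timepoint_labels: tuple[str, ...]
    timepoint_kind: tuple[str, ...] | None
    ccf: np.ndarray


def _delimiter_for(path: Path, override: str | None = None) -> str:
    if override:
        return override
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _parse_time_header(header: str, column: int) -> float:
    text = header.strip()
    if text and text[0] in "tT":
        candidate = text[1:]
    else:
        candidate = text
    try:
        return float(candidate)
    except ValueError:
        raise ParseError(
            f"column {column + 1} header {header!r} is not a time coordinate"
        ) from None


def read_ccf_table(path, *, delimiter: str | None = None) -> CCFTable:
    """Parse a CCF table; the parent column is optional.

    Raises :class:`ParseError` for duplicate clone labels, non-numeric
    cells, and non-increasing time columns.
    """
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delim) if row]
    if not rows:
        raise ParseError(f"{path}: empty file")

    header = [cell.strip() for cell in rows[0]]
    if not header or header[0].lower() != "clone":
        raise ParseError(f"{path}: first column header must be 'clone'")
    has_parent = len(header) > 1 and header[1].lower() == "parent"
    tp_start = 2 if has_parent else 1
    tp_labels = tuple(header[tp_start:])
    if not tp_labels:
        raise ParseError(f"{path}: no time point columns")
    timepoints = np.array(
        [_parse_time_header(h, tp_start + i) for i, h in enumerate(tp_labels)]
    )
    if np.any(np.diff(timepoints) <= 0):
        raise ParseError(f"{path}: time coordinates must be strictly increasing")

    body = rows[1:]
    kinds: tuple[str, ...] | None = None
    if body and body[0][0].strip().lower() == "#kind":
        kind_cells = [c.strip() for c in body[0][tp_start:]]
        if len(kind_cells) != len(tp_labels):
            raise ParseError(f"{path}: #kind row has wrong length")
        bad = [k for k in kind_cells if k not in TIMEPOINT_KINDS]
        if bad:
            raise ParseError(f"{path}: unknown time point kind(s) {bad}")
        kinds = tuple(kind_cells)
        body = body[1:]

    labels: list[str] = []
    parents: list[str] = []
    values: list[list[float]] = []
    for r, row in enumerate(body, start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: row {r} has {len(row)} cells, expected {len(header)}"
            )
        lab = row[0].strip()
        if not lab:
            raise ParseError(f"{path}: row {r} has an empty clone label")
        if lab in labels:
            raise ParseError(f"{path}: duplicate clone label {lab!r}")
        labels.append(lab)
        if has_parent:
            cell = row[1].strip()
            if not cell:
                raise ParseError(
                    f"{path}: row {r}: empty parent cell (use 'normal' for "
                    "founders)"
                )
            parents.append(normalize_parent(cell))
        row_values = []
        for c, cell in enumerate(row[tp_start:]):
            try:
                row_values.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric CCF {cell!r} for clone {lab!r}, "
                    f"column {tp_labels[c]!r}"
                ) from None
        values.append(row_values)
    if not labels:
        raise ParseError(f"{path}: no clone rows")

    return CCFTable(
        clone_labels=tuple(labels),
        parents=tuple(parents) if has_parent else None,
        timepoints=timepoints,
        timepoint_labels=tp_labels,
        timepoint_kind=kinds,
        ccf=np.array(values, dtype=float),
    )


def read_evolution(path, *, tolerance: float | None = None) -> ClonalEvolution:
    """Read a table that includes parental relations and build the model."""
    table = read_ccf_table(path)
    if table.parents is None:
        raise UsageError(
            f"{path}: no parent column; supply parental relations or run the "
            "tree explorer"
        )
    kwargs = {} if tolerance is None else {"tolerance": tolerance}
    return build_evolution(
        table.ccf,
        table.parents,
        table.timepoints,
        clone_labels=table.clone_labels,
        timepoint_labels=table.timepoint_labels,
        timepoint_kind=table.timepoint_kind,
        **kwargs,
    )


def _time_header(label: str, coord: float) -> str:
    """Reuse the display label when it parses back to the coordinate."""
    try:
        if _parse_time_header(label, 0) == coord:
            return label
    except ParseError:
        pass
    return "t" + format(coord, ".17g")


def write_ccf_table(
    evo: ClonalEvolution,
    path,
    *,
    delimiter: str | None = None,
    precision: int = 6,
) -> None:
    """Write an evolution in the CCF-table dialect (deterministic bytes).

    ``precision`` is the number of significant digits for CCF values
    (default 6); raise it for lossless round trips.
    """
    if evo.n_clones == 0:
        raise UsageError("refusing to write an evolution without clones")
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    lines = []
    headers = [
        _time_header(lab, float(c))
        for lab, c in zip(evo.timepoint_labels, evo.timepoints)
    ]
    lines.append(delim.join(["clone", "parent", *headers]))
    if any(k != MEASURED for k in evo.timepoint_kind):
        lines.append(delim.join(["#kind", "", *evo.timepoint_kind]))
    for k, lab in enumerate(evo.clone_labels):
        cells = [lab, evo.parents[k] if evo.parents[k] != NORMAL else "normal"]
        cells += [format(v, f".{precision}g") for v in evo.ccf[k]]
        lines.append(delim.join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
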