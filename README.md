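# cloneviz

A toolkit for working with clonal-evolution trajectories of tumor clones.
The core object is a table of cancer cell fractions (CCF, in percent) for
`n` clones over `m` time points plus a parental-relation forest rooted in
normal cells. On top of that model, the package provides:

* **Validity checking** — four structured rules (children cannot exceed their
  parent; founders cannot jointly exceed 100%; a clone cannot reappear;
  a thoroughly replaced parent cannot reappear), reported per rule, clone
  and time point rather than as a bare boolean.
* **Alternative-tree exploration** — enumeration of every parental-relation
  vector consistent with a CCF table, with two CCF-based pre-filters and a
  hard 20,000-permutation cap (exceeding it aborts; no silent truncation).
* **Time-point interpolation** — fully automatic reconstruction of the
  development before the first measurement and between consecutive
  measurements, staged by nested level.
* **Therapy-effect estimation** — insertion of an estimated end-of-therapy
  time point (each surviving clone's unique CCF is the minimum of its values
  at the flanking measurements), with optional interpolation of the
  post-therapy re-expansion using recalculated nested levels.
* **Phylogeny-aware color coding** — founders spread maximally over the hue
  wheel (max. 25 independent clones), branches occupy hue sectors,
  lightness darkens with nesting depth.
* **Plot geometry and rendering** — shark plots (node/edge phylogeny with
  optional CCF bubbles), dolphin plots (centered or bottom stacked-band
  charts, polygon or monotone-spline borders), and plaice plots (mirrored
  bottom-layout bands whose lower half visualizes loss of the remaining
  healthy allele for biallelic events). SVG output is deterministic; PNG is
  rasterized from the same geometry.
* **A seeded simulator** of valid clonal evolutions for testing and stress
  cases (valid by construction, up to 100 clones × 100 time points and
  beyond).

## Input format

CSV or TSV: first column `clone`, optional column `parent` (another clone
label, or `normal`/`0` for clones arising from normal cells), remaining
headers are numeric time coordinates (optionally `t`-prefixed: `t0`, `t53`).
Values are CCFs in percent; fraction-scaled tables (all values ≤ 1) are
rejected with a hint rather than silently rescaled. An optional second row
starting with `#kind` tags each time point as `measured`, `interpolated` or
`therapy`.

```csv
clone,parent,t0,t60
A,normal,70,70
B,A,20,60
```

## Command line

```sh
cloneviz check table.csv                 # validity report (JSON lines)
cloneviz explore table.csv               # all consistent parent vectors
cloneviz interpolate table.csv -o out.csv
cloneviz therapy table.csv -o out.csv --interval t0,t60 [--position 0.4]
cloneviz plot dolphin table.csv -o plot.svg --vertical-mode bottom
cloneviz plot plaice table.csv -o plot.svg --annotation B=A
cloneviz plot shark table.csv -o plot.png
cloneviz simulate -o sim.csv --clones 20 --timepoints 10 --seed 1
```

## Python API

```python
import cloneviz as cv

evo = cv.build_evolution(
    {"A": [70, 70], "B": [20, 60]}, {"A": "normal", "B": "A"}
)
evo = cv.interpolate_all(evo)
evo = cv.apply_therapy(evo, cv.TherapyWindow(interval=("t0", "t1")))
colors = cv.assign_colors(evo)
layout = cv.dolphin_layout(evo, colors, cv.LayoutConfig(vertical_mode="bottom"))
cv.render(layout, "plot.svg")
```

## Tests and acceptance report

```sh
python -m pytest -q tests/            # full suite incl. tests/test_acceptance.py
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the externally checkable constants from
scratch by driving the package (largest admissible founder sum, enforced
permutation cap, founder-palette capacity, drawn birth offset) and writes
them as JSON.
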