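"""Seeded generation of valid clonal evolutions.

A test-fixture generator, not a tumor simulator: trajectories are random
walks on the unique-CCF scale, constructed so that every instance passes the
validity check *by construction*:

* each clone's unique CCF is strictly positive on one contiguous window of
  time points and zero elsewhere (no reappearance, rules V3/V4);
* a child's window starts inside its parent's window, so subtree CCFs are
  contiguous as well;
* CCFs accumulate leaf-to-root from nonnegative unique CCFs (rule V1);
* founder columns are rescaled to <= 100 when needed (rule V2).

Identical seeds give identical instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SimulationSpecError
from .model import (
    MEASURED,
    NORMAL,
    ClonalEvolution,
    build_evolution,
    ccf_from_unique,
)

MODELS = ("linear", "branched_dependent", "branched_independent", "mixed")


@dataclass(frozen=True)
class SimulationSpec:
    n_clones: int
    n_timepoints: int
    model: str = "mixed"
    seed: int | None = None
    max_founders: int = 25  # keeps the output colorable
    extinction_prob: float = 0.1

    def __post_init__(self):
        if self.n_clones < 1 or self.n_timepoints < 1:
            raise SimulationSpecError(
                "n_clones and n_timepoints must be at least 1"
            )
        if self.model not in MODELS:
            raise SimulationSpecError(
                f"unknown model {self.model!r}; choose from {MODELS}"
            )
        if self.model == "branched_independent" and self.n_clones < 2:
            raise SimulationSpecError(
                "branched_independent requires at least 2 clones"
            )
        if self.max_founders < 1:
            raise SimulationSpecError("max_founders must be at least 1")
        if not 0 <= self.extinction_prob <= 1:
            raise SimulationSpecError("extinction_prob must lie in [0, 1]")


def _sample_parents(spec: SimulationSpec, rng: np.random.Generator) -> list:
    n = spec.n_clones
    parents: list = [NORMAL]
    n_founders = 1
    for k in range(1, n):
        if spec.model == "linear":
            parents.append(k - 1)  # chain
        elif spec.model == "branched_dependent":
            parents.append(int(rng.integers(0, k)))
        elif spec.model == "branched_independent":
            must_found = n_founders < 2 and k == n - 1
            if must_found or (
                n_founders < spec.max_founders and rng.random() < 0.3
            ):
                parents.append(NORMAL)
                n_founders += 1
            else:
                parents.append(int(rng.integers(0, k)))
        else:  # mixed
            if n_founders < spec.max_founders and rng.random() < 0.25:
                parents.append(NORMAL)
                n_founders += 1
            else:
                parents.append(int(rng.integers(0, k)))
    return parents


def simulate_evolution(spec: SimulationSpec) -> ClonalEvolution:
    """Generate a random valid :class:`ClonalEvolution` for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_clones, spec.n_timepoints
    labels = [f"C{k + 1}" for k in range(n)]
    parent_idx = _sample_parents(spec, rng)
    founder_rows = [k for k, p in enumerate(parent_idx) if not isinstance(p, int)]
    parents = [p if not isinstance(p, int) else labels[p] for p in parent_idx]

    # birth/death windows on the time grid; a child is born while its
    # parent's own unique CCF is still positive, keeping subtree CCFs
    # contiguous in time
    birth = np.zeros(n, dtype=int)
    death = np.zeros(n, dtype=int)  # first index with zero unique CCF
    for k in range(n):
        p = parent_idx[k]
        if not isinstance(p, int):
            b = 0 if m == 1 else int(rng.integers(0, max(m // 2, 1)))
        else:
            b_lo, b_hi = birth[p], max(int(death[p]) - 1, birth[p])
            b = int(rng.integers(b_lo, b_hi + 1))
        birth[k] = b
        if rng.random() < spec.extinction_prob and b + 1 < m:
            death[k] = int(rng.integers(b + 1, m + 1))
        else:
            death[k] = m

    uccf = np.zeros((n, m))
    for k in range(n):
        v = float(rng.uniform(2.0, 40.0))
        for t in range(birth[k], death[k]):
            uccf[k, t] = v
            v = max(v + float(rng.normal(0.0, 8.0)), 0.5)

    ccf = ccf_from_unique(uccf, labels, parents)
    founder_sum = ccf[founder_rows].sum(axis=0)
    over = founder_sum > 100.0
    if np.any(over):
        scale = np.ones(m)
        scale[over] = 99.5 / founder_sum[over]
        ccf = ccf * scale

    return build_evolution(
        ccf,
        parents,
        np.arange(m, dtype=float),
        clone_labels=labels,
        timepoint_kind=[MEASURED] * m,
    )
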