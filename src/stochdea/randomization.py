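"""Monte-Carlo sampling layer: per-cell distributions built from observed rates.

Each observed cell value ``x`` is replaced by a statistical distribution
expressing structural uncertainty around it:

* triangular ``T[w_tl * x, x, w_tr * x]`` (the default; weights 0.9/1.1), or
* uniform ``U[x, w_ur * x]`` for cells singled out by expert choice, or
* degenerate at ``x`` for cells exempted from randomization.

A :class:`RandomizationPlan` is the full matrix of cell distributions
aligned with a dataset; :func:`sample_realization` draws one complete
dataset realization from it.  Zero-valued cells stay degenerate at zero:
the laws scale multiplicatively, so no relative range exists around 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .dataset import EcosystemDataset
from .exceptions import ResolutionError, ValidationError

TRIANGULAR = "triangular"
UNIFORM = "uniform"
DEGENERATE = "degenerate"


@dataclass(frozen=True)
class CellDistribution:
    """The randomization law of a single cell."""

    kind: str  # "triangular" | "uniform" | "degenerate"
    params: tuple[float, ...]  # (min, mode, max) | (min, max) | (value,)
    source_value: float

    def __post_init__(self) -> None:
        if self.kind == TRIANGULAR:
            a, m, b = self.params
            if not (a <= m <= b):
                raise ValidationError(f"triangular params out of order: {self.params}")
        elif self.kind == UNIFORM:
            a, b = self.params
            if a > b:
                raise ValidationError(f"uniform params out of order: {self.params}")
        elif self.kind != DEGENERATE:
            raise ValidationError(f"unknown distribution kind {self.kind!r}")

    @property
    def support(self) -> tuple[float, float]:
        return self.params[0], self.params[-1]

    def mean(self) -> float:
        if self.kind == TRIANGULAR:
            return sum(self.params) / 3.0
        if self.kind == UNIFORM:
            return sum(self.params) / 2.0
        return self.params[0]


@dataclass(frozen=True)
class Weights:
    """Range weights for the randomization laws."""

    w_tl: float = 0.9
    w_tr: float = 1.1
    w_ur: float = 1.1

    def __post_init__(self) -> None:
        if not (0 < self.w_tl <= 1 <= self.w_tr):
            raise ValidationError(f"triangular weights out of range: {self}")
        if self.w_ur < 1:
            raise ValidationError(f"uniform weight must be >= 1: {self}")


def triangularize(x: float, w_tl: float = 0.9, w_tr: float = 1.1) -> CellDistribution:
    """Triangular law ``T[w_tl*x, x, w_tr*x]`` around an observed value."""
    Weights(w_tl=w_tl, w_tr=w_tr)
    if x < 0:
        raise ValidationError(f"observed value must be non-negative, got {x}")
    a, b = w_tl * x, w_tr * x
    if a == b:  # x == 0 or unit weights
        return CellDistribution(DEGENERATE, (float(x),), float(x))
    return CellDistribution(TRIANGULAR, (a, float(x), b), float(x))


def uniformize(x: float, w_ur: float = 1.1) -> CellDistribution:
    """Uniform law ``U[x, w_ur*x]`` around an observed value."""
    Weights(w_ur=w_ur)
    if x < 0:
        raise ValidationError(f"observed value must be non-negative, got {x}")
    b = w_ur * x
    if b == x:
        return CellDistribution(DEGENERATE, (float(x),), float(x))
    return CellDistribution(UNIFORM, (float(x), b), float(x))


@dataclass
class RandomizationPlan:
    """Matrix of cell distributions aligned with a dataset.

    Internally stored as parallel (n, p) arrays for vectorized sampling:
    ``lo``/``mode``/``hi`` and an integer ``kinds`` code (0 degenerate,
    1 triangular, 2 uniform).
    """

    dataset: EcosystemDataset
    weights: Weights
    kinds: np.ndarray
    lo: np.ndarray
    mode: np.ndarray
    hi: np.ndarray
    uniform_cells: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    degenerate_cells: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    _KIND_NAMES = {0: DEGENERATE, 1: TRIANGULAR, 2: UNIFORM}

    @property
    def shape(self) -> tuple[int, int]:
        return self.kinds.shape

    def distribution(self, dmu: str, variable: str) -> CellDistribution:
        i = self.dataset.dmu_index(dmu)
        j = self.dataset.variable_index(variable)
        kind = self._KIND_NAMES[int(self.kinds[i, j])]
        x = float(self.dataset.values[i, j])
        if kind == TRIANGULAR:
            params: tuple[float, ...] = (
                float(self.lo[i, j]), float(self.mode[i, j]), float(self.hi[i, j]))
        elif kind == UNIFORM:
            params = (float(self.lo[i, j]), float(self.hi[i, j]))
        else:
            params = (x,)
        return CellDistribution(kind, params, x)

    def kind_counts(self) -> dict[str, int]:
        return {
            name: int((self.kinds == code).sum())
            for code, name in self._KIND_NAMES.items()
        }

    def to_dict(self) -> dict:
        return {
            "weights": {
                "w_tl": self.weights.w_tl,
                "w_tr": self.weights.w_tr,
                "w_ur": self.weights.w_ur,
            },
            "uniform_cells": [
                {"dmu": d, "variable": v} for d, v in sorted(self.uniform_cells)
            ],
            "degenerate_cells": [
                {"dmu": d, "variable": v} for d, v in sorted(self.degenerate_cells)
            ],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_plan_config(path: str | Path) -> dict:
    """Read a plan config (weights + uniform/degenerate cell lists) from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    weights = Weights(**(doc.get("weights") or {}))
    cells = lambda key: [
        (str(c["dmu"]), str(c["variable"])) for c in (doc.get(key) or [])
    ]
    return {
        "weights": weights,
        "uniform_cells": cells("uniform_cells"),
        "degenerate_cells": cells("degenerate_cells"),
    }


def build_plan(
    ds: EcosystemDataset,
    uniform_cells: Iterable[tuple[str, str]] = (),
    weights: Weights = Weights(),
    degenerate_cells: Iterable[tuple[str, str]] = (),
) -> RandomizationPlan:
    """Build the per-cell distribution matrix for a dataset.

    Every cell becomes triangular except those listed in ``uniform_cells``
    (uniform) or ``degenerate_cells`` (kept fixed).  Zero cells are always
    degenerate.
    """
    n, p = ds.values.shape
    kinds = np.ones((n, p), dtype=np.int8)
    x = ds.values
    uniform_cells = frozenset(uniform_cells)
    degenerate_cells = frozenset(degenerate_cells)
    for dmu, var in uniform_cells | degenerate_cells:
        i, j = ds.dmu_index(dmu), ds.variable_index(var)  # raises ResolutionError
        kinds[i, j] = 2 if (dmu, var) in uniform_cells else 0
    overlap = uniform_cells & degenerate_cells
    if overlap:
        raise ResolutionError(f"cells listed as both uniform and degenerate: {overlap}")

    lo = np.where(kinds == 2, x, weights.w_tl * x)
    hi = np.where(kinds == 2, weights.w_ur * x, weights.w_tr * x)
    mode = x.copy()
    # zero-width supports (x == 0 or unit weights) collapse to degenerate
    kinds = np.where(hi == lo, 0, kinds).astype(np.int8)
    return RandomizationPlan(
        dataset=ds,
        weights=weights,
        kinds=kinds,
        lo=lo,
        mode=mode,
        hi=hi,
        uniform_cells=uniform_cells,
        degenerate_cells=degenerate_cells,
    )


def sample_realization(
    plan: RandomizationPlan, rng: np.random.Generator
) -> np.ndarray:
    """Draw one full dataset realization from a plan.

    Each cell is drawn independently via inverse-CDF on a single uniform
    variate, which makes draws exact and reproducible across platforms.
    """
    u = rng.random(plan.shape)
    lo, mode, hi = plan.lo, plan.mode, plan.hi
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(span > 0, (mode - lo) / np.where(span > 0, span, 1.0), 0.0)
        left = lo + np.sqrt(u * span * (mode - lo))
        right = hi - np.sqrt((1.0 - u) * span * (hi - mode))
    tri = np.where(u < fc, left, right)
    uni = lo + u * span
    out = np.where(plan.kinds == 1, tri, np.where(plan.kinds == 2, uni, mode))
    return np.clip(out, lo, hi)
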