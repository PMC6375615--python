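"""Frequency analysis of simulated RTE pools: histogram, estimators,
stability and entropy indicators.

A pool of simulated RTE scores is binned into 22 ordered intervals: 20
half-open score bins [0, 0.05), [0.05, 0.1), ..., [0.95, 1), then one
bin for weakly efficient runs (score 1 with nonzero slacks) and one for
fully efficient runs (score 1, zero slacks).

Two bespoke indicators summarize how concentrated the distribution is,
both on a [0, 100] scale (0 completely unstable, 100 completely stable):

* interval stability   ``intstab = 100 - 100 * (nint - 1) / (inttot - 1)``
  with ``nint`` the number of populated bins;
* density stability    ``denstab = 100 * (ln(acprob * 100 / nintprob) - minln)
  / (maxln - minln)`` where bins are accumulated in descending frequency
  order until the running sum first strictly exceeds ``prob``; ``acprob``
  is that sum and ``nintprob`` the number of bins used.

The final stability is the weighted sum ``w_int * intstab +
w_den * denstab``.  Shannon entropy (base 2, ``0 * log 0 = 0``) measures
the inner uncertainty of the distribution, reported in bits and as a
percentage of its maximum ``log2(inttot)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: 20 score bins + weakly-efficient + fully-efficient
DEFAULT_INTTOT = 22
N_SCORE_BINS = 20
WEAK_BIN = 20
EFFICIENT_BIN = 21

POOL_COLUMNS = ("dmu", "scenario", "simulation", "orientation", "rte",
                "efficiency_class")


@dataclass
class RTEPool:
    """The solution pool: one record per (DMU, scenario, simulation, orientation)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(POOL_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValidationError(f"pool is missing columns {sorted(missing)}")
        rte = self.records["rte"].to_numpy()
        if ((rte < 0) | (rte > 1)).any():
            raise ValidationError("pool contains RTE scores outside [0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(cls, rows: Iterable[dict]) -> "RTEPool":
        return cls(pd.DataFrame(list(rows), columns=list(POOL_COLUMNS)))

    def filter(self, **criteria) -> "RTEPool":
        """Subset by equality on any pool column, e.g. ``filter(dmu="SHA-01")``."""
        mask = np.ones(len(self.records), dtype=bool)
        for col, value in criteria.items():
            if col not in self.records.columns:
                raise ValidationError(f"unknown pool column {col!r}")
            mask &= (self.records[col] == value).to_numpy()
        return RTEPool(self.records[mask].reset_index(drop=True))

    @property
    def scores(self) -> np.ndarray:
        return self.records["rte"].to_numpy(dtype=float)

    @property
    def classes(self) -> np.ndarray:
        return self.records["efficiency_class"].to_numpy()

    def save(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "RTEPool":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class RTEHistogram:
    """Relative frequencies over the 22-interval scheme."""

    freqs: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError("histogram frequencies must be >= 0 and sum to 1")

    @property
    def inttot(self) -> int:
        return len(self.freqs)

    @property
    def nint(self) -> int:
        """Number of bins with probability greater than zero."""
        return int(np.count_nonzero(np.asarray(self.freqs) > 0))


def bin_pool(pool: RTEPool, inttot: int = DEFAULT_INTTOT) -> RTEHistogram:
    """Bin one (filtered) pool into the 22-interval frequency scheme.

    Inefficient records go into the score bins by value; weakly
    efficient and fully efficient records into the last two bins by
    class, regardless of rounding of their score.
    """
    if len(pool) == 0:
        raise ValidationError("cannot bin an empty pool")
    if inttot != DEFAULT_INTTOT:
        raise ValidationError(
            "only the 20 + 2 scheme is supported for binning pools"
        )
    counts = np.zeros(inttot, dtype=np.int64)
    scores, classes = pool.scores, pool.classes
    for score, cls_ in zip(scores, classes):
        if cls_ == "efficient":
            counts[EFFICIENT_BIN] += 1
        elif cls_ == "weakly_efficient":
            counts[WEAK_BIN] += 1
        else:
            counts[min(int(score / 0.05), N_SCORE_BINS - 1)] += 1
    freqs = counts / counts.sum()
    return RTEHistogram(freqs=tuple(freqs.tolist()), n=int(counts.sum()))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

@dataclass
class EstimatorReport:
    """Summary statistics of one RTE pool.

    ``error`` is a configurable multiple of the standard deviation
    (default factor 1) and ``error_pct`` expresses it relative to the
    mean, since the published estimator list names an "efficiency error"
    without printing its definition.
    """

    p_efficient: float
    p_weak: float
    p_inefficient: float
    mean: float
    sd: float
    error: float
    error_pct: float
    _scores: np.ndarray = field(repr=False, default=None)

    def p_above(self, c: float) -> float:
        """P(RTE > c)."""
        return float(np.mean(self._scores > c))

    def p_range(self, a: float, b: float) -> float:
        """P(a <= RTE < b), half-open as in the histogram bins."""
        return float(np.mean((self._scores >= a) & (self._scores < b)))


def estimators(pool: RTEPool, error_factor: float = 1.0) -> EstimatorReport:
    if len(pool) == 0:
        raise ValidationError("cannot summarize an empty pool")
    scores = pool.scores
    classes = pool.classes
    n = len(scores)
    p_eff = float(np.mean(classes == "efficient"))
    p_weak = float(np.mean(classes == "weakly_efficient"))
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if n > 1 else 0.0
    error = error_factor * sd
    return EstimatorReport(
        p_efficient=p_eff,
        p_weak=p_weak,
        p_inefficient=1.0 - p_eff - p_weak,
        mean=mean,
        sd=sd,
        error=error,
        error_pct=100.0 * error / mean if mean > 0 else float("nan"),
        _scores=scores,
    )


# ---------------------------------------------------------------------------
# stability and entropy
# ---------------------------------------------------------------------------

def derived_log_bounds(prob: float, inttot: int) -> tuple[float, float]:
    """Closed-form log anchors: ``minln = ln(100 * prob / inttot)`` (the
    density ratio of a threshold-wide uniform spread) and
    ``maxln = ln(100)`` (all mass in one bin)."""
    return math.log(100.0 * prob / inttot), math.log(100.0)


@dataclass(frozen=True)
class StabilityParams:
    """Parameters of the stability indicators.

    The default ``minln``/``maxln`` are the published four-decimal
    constants; they agree with :func:`derived_log_bounds` (1.2910 and
    4.6052) to printed precision.  Set ``derive_log_bounds=True`` to use
    the closed forms for non-default ``prob``/``inttot``.
    """

    inttot: int = DEFAULT_INTTOT
    prob: float = 0.8
    minln: float = 1.2909
    maxln: float = 4.6051
    w_int: float = 0.5
    w_den: float = 0.5
    derive_log_bounds: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.prob < 1:
            raise ValidationError(f"prob must be in (0, 1), got {self.prob}")
        if self.inttot < 2:
            raise ValidationError("need at least two intervals")
        if self.w_int < 0 or self.w_den < 0:
            raise ValidationError("stability weights must be >= 0")
        if self.derive_log_bounds:
            minln, maxln = derived_log_bounds(self.prob, self.inttot)
            object.__setattr__(self, "minln", minln)
            object.__setattr__(self, "maxln", maxln)
        if self.minln >= self.maxln:
            raise ValidationError("minln must be below maxln")


def interval_stability(
    h: RTEHistogram, params: StabilityParams = StabilityParams()
) -> float:
    """``100 - 100 * (nint - 1) / (inttot - 1)``: 100 when all mass sits
    in a single bin, 0 when every bin is populated."""
    return 100.0 - 100.0 * (h.nint - 1) / (params.inttot - 1)


def density_stability(
    h: RTEHistogram, params: StabilityParams = StabilityParams()
) -> tuple[float, float, int]:
    """Density stability with its accumulation inputs.

    Bins are visited in descending frequency order (ties toward the
    higher-RTE bin) and accumulated until the running probability first
    strictly exceeds ``prob``.  Returns ``(denstab, acprob, nintprob)``.
    The score is clipped to [0, 100]: the printed log anchors are
    four-decimal roundings of ln(100 * prob / inttot) and ln(100), so the
    raw expression can overshoot the boundary by a few thousandths.
    """
    freqs = np.asarray(h.freqs)
    # descending frequency; ties broken toward the higher-RTE (later) bin
    order = sorted(range(len(freqs)), key=lambda i: (-freqs[i], -i))
    acc = 0.0
    nintprob = 0
    for idx in order:
        acc += freqs[idx]
        nintprob += 1
        if acc > params.prob:
            break
    if acc <= params.prob:
        raise ValidationError(
            f"accumulated probability {acc} never exceeds prob={params.prob}"
        )
    ratio = acc * 100.0 / nintprob
    denstab = 100.0 * (math.log(ratio) - params.minln) / (params.maxln - params.minln)
    return float(np.clip(denstab, 0.0, 100.0)), acc, nintprob


def weighted_stability(
    intstab: float, denstab: float, params: StabilityParams = StabilityParams()
) -> float:
    """Final stability: ``w_int * intstab + w_den * denstab``."""
    return params.w_int * intstab + params.w_den * denstab


def shannon_entropy(h: RTEHistogram) -> tuple[float, float]:
    """Base-2 Shannon entropy of the histogram and its percentage of the
    maximum ``log2(inttot)``."""
    freqs = np.asarray(h.freqs)
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log2(nz)).sum() + 0.0)  # +0.0 drops negative zero
    return entropy, 100.0 * entropy / math.log2(h.inttot)


@dataclass(frozen=True)
class StabilityReport:
    """All stability/entropy indicators for one RTE distribution."""

    nint: int
    acprob: float
    nintprob: int
    intstab: float
    denstab: float
    stab: float
    entropy: float
    entropy_pct_of_max: float


def stability_report(
    h: RTEHistogram, params: StabilityParams = StabilityParams()
) -> StabilityReport:
    intstab = interval_stability(h, params)
    denstab, acprob, nintprob = density_stability(h, params)
    entropy, entropy_pct = shannon_entropy(h)
    return StabilityReport(
        nint=h.nint,
        acprob=acprob,
        nintprob=nintprob,
        intstab=intstab,
        denstab=denstab,
        stab=weighted_stability(intstab, denstab, params),
        entropy=entropy,
        entropy_pct_of_max=entropy_pct,
    )
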