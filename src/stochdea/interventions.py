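"""Management interventions as dataset edits, and pre/post pool comparison.

An intervention is a list of cell edits (area, variable, signed change):
typically paired decrease/increase rows describing staff reassigned from
one service to another.  Applying an intervention produces a new dataset;
randomization plans must then be rebuilt from the edited values so the
post-intervention Monte-Carlo runs draw from updated distributions.

Pre/post RTE pools are compared with variation percentages and three
standard tests: two-sample t (Welch fallback when Levene rejects equal
variances), Levene, and two-sample Kolmogorov-Smirnov, each reported at
alpha = 0.05 and 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .dataset import EcosystemDataset
from .distribution import RTEPool, StabilityParams, bin_pool, estimators, \
    stability_report
from .exceptions import ConfigurationError, ValidationError


@dataclass(frozen=True)
class Edit:
    """One cell edit.

    ``amount`` is an absolute increment by default (mode ``"absolute"``);
    mode ``"factor"`` multiplies the cell instead.  When a population
    mapping is supplied at apply time, absolute amounts are understood as
    raw counts (e.g. full-time equivalents) and converted to rates per
    100,000 inhabitants.
    """

    dmu: str
    variable: str
    amount: float
    mode: str = "absolute"  # "absolute" | "factor"
    direction: str = ""  # optional tag: "increasing" | "decreasing"

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "factor"):
            raise ValidationError(f"unknown edit mode {self.mode!r}")


@dataclass(frozen=True)
class InterventionSpec:
    """A named bundle of cell edits."""

    id: str
    description: str
    edits: tuple[Edit, ...]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InterventionSpec":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            id=str(doc["id"]),
            description=str(doc.get("description", "")),
            edits=tuple(Edit(**e) for e in doc.get("edits", [])),
        )

    def save(self, path: str | Path) -> None:
        doc = {
            "id": self.id,
            "description": self.description,
            "edits": [
                {
                    "dmu": e.dmu,
                    "variable": e.variable,
                    "amount": e.amount,
                    "mode": e.mode,
                    "direction": e.direction,
                }
                for e in self.edits
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def apply_intervention(
    ds: EcosystemDataset,
    spec: InterventionSpec,
    populations: Mapping[str, float] | None = None,
) -> EcosystemDataset:
    """Apply an intervention, returning a new dataset.

    Exactly the listed cells change; everything else is untouched.  With
    ``populations`` (inhabitants per DMU), absolute amounts are converted
    from raw counts to rates per 100,000.  An edit driving a cell
    negative raises a validation error naming the cell.
    """
    values = ds.values.copy()
    for e in spec.edits:
        i, j = ds.dmu_index(e.dmu), ds.variable_index(e.variable)
        if e.mode == "factor":
            values[i, j] *= e.amount
        else:
            delta = e.amount
            if populations is not None:
                if e.dmu not in populations:
                    raise ConfigurationError(f"no population for DMU {e.dmu!r}")
                delta = e.amount / populations[e.dmu] * 1e5
            values[i, j] += delta
        if values[i, j] < 0:
            raise ValidationError(
                f"intervention {spec.id}: edit drives ({e.dmu}, {e.variable}) "
                f"negative ({values[i, j]})"
            )
    return ds.replace_values(values)


# ---------------------------------------------------------------------------
# pre/post comparison
# ---------------------------------------------------------------------------

def _variation_pct(pre: float, post: float) -> float:
    if pre == 0:
        return float("nan")
    return 100.0 * (post - pre) / pre


@dataclass
class ComparisonReport:
    """Pre/post statistics for one unit of analysis (system, scenario or DMU).

    ``rows`` is a tidy frame with columns statistic / pre / post /
    variation_pct; ``tests`` holds the p-values and alpha-level decisions
    of the t, Levene and Kolmogorov-Smirnov tests.
    """

    unit: str
    rows: pd.DataFrame
    tests: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        frame = self.rows.rename(
            columns={
                "pre": "Pre-Interventions",
                "post": "Post-Interventions",
                "variation_pct": "Variation (%)",
            }
        )
        frame.insert(0, "Unit of analysis", self.unit)
        return frame


def compare_pools(
    pre: RTEPool,
    post: RTEPool,
    unit: str = "Global System",
    p_above_threshold: float = 0.75,
    stability: StabilityParams = StabilityParams(),
    alphas: Sequence[float] = (0.05, 0.01),
) -> ComparisonReport:
    """Compare two RTE pools computed under identical configuration apart
    from the intervention."""
    if len(pre) == 0 or len(post) == 0:
        raise ConfigurationError("cannot compare empty pools")
    est_pre, est_post = estimators(pre), estimators(post)
    stab_pre = stability_report(bin_pool(pre), stability)
    stab_post = stability_report(bin_pool(post), stability)

    stats_rows = [
        ("Probability of being efficient", est_pre.p_efficient, est_post.p_efficient),
        ("Efficiency average", est_pre.mean, est_post.mean),
        ("Efficiency standard deviation", est_pre.sd, est_post.sd),
        ("Efficiency error", est_pre.error, est_post.error),
        (
            f"Probability of having a RTE score greater than {p_above_threshold}",
            est_pre.p_above(p_above_threshold),
            est_post.p_above(p_above_threshold),
        ),
        ("Weighted stability", stab_pre.stab, stab_post.stab),
        ("Shannon entropy", stab_pre.entropy, stab_post.entropy),
        ("Entropy % of maximum", stab_pre.entropy_pct_of_max,
         stab_post.entropy_pct_of_max),
    ]
    rows = pd.DataFrame(
        [
            {
                "statistic": name,
                "pre": a,
                "post": b,
                "variation_pct": _variation_pct(a, b),
            }
            for name, a, b in stats_rows
        ]
    )

    a, b = pre.scores, post.scores
    lev_stat, lev_p = stats.levene(a, b)
    equal_var = bool(lev_p > max(alphas))
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=equal_var)
    ks_stat, ks_p = stats.ks_2samp(a, b)
    tests = {
        "t": {
            "statistic": float(t_stat),
            "p": float(t_p),
            "equal_var_assumed": equal_var,
            "reject": {alpha: bool(t_p < alpha) for alpha in alphas},
        },
        "levene": {
            "statistic": float(lev_stat),
            "p": float(lev_p),
            "reject": {alpha: bool(lev_p < alpha) for alpha in alphas},
        },
        "ks": {
            "statistic": float(ks_stat),
            "p": float(ks_p),
            "reject": {alpha: bool(ks_p < alpha) for alpha in alphas},
        },
    }
    return ComparisonReport(unit=unit, rows=rows, tests=tests)
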