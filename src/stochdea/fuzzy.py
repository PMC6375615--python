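"""Fuzzy inference layer: expert interpretation of sampled variable values.

The engine encodes a community-care model in which the appropriateness of
residential (R) provision depends on how much day (D) and outpatient (O)
care is available.  It works in four steps:

1. **Constructs** — summarize each area's D and O provision (availability,
   places/beds and workforce rates) as scores in [0, 100].
2. **Rules** — standard "IF D is <label> AND O is <label> THEN the lower
   appropriateness bound of an R variable is <label>" production rules,
   fired with product inference and sum aggregation.
3. **Range displacement** — the fired rules defuzzify (product-sum
   gravity) into a new lower bound for the variable's appropriateness
   range; the upper bound follows so the range *width is preserved
   exactly*.  Scarcer D/O provision displaces the range to the right:
   more residential care becomes appropriate.
4. **Value interpretation** — each sampled value is mapped through a
   monotone piecewise-linear profile defined by its (possibly displaced)
   appropriateness range before entering the DEA model.

Every fuzzy variable uses the same 5-set partition: *very little,
little, standard, much, very much*, with shoulder sets at the extremes
and triangles in between.  Peaks are evenly spaced by default, sets
overlap only pairwise, and memberships always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .dataset import EcosystemDataset
from .exceptions import ConfigurationError, ResolutionError, ValidationError

LABELS = ("very little", "little", "standard", "much", "very much")
N_SETS = len(LABELS)


@dataclass(frozen=True)
class FuzzyPartition:
    """A 5-set fuzzy partition of a closed interval.

    The two extreme sets are shoulders (membership 1 beyond the outermost
    peaks), the three interior sets are triangles spanning peak to peak.
    This geometry guarantees a partition of unity with at most two
    nonzero memberships at any point.

    For defuzzification each set contributes a centroid and an area.  The
    default treats every set as a symmetric triangle of equal area
    centred on its peak (the shoulder sets are virtually extended past
    the universe bounds), so the product-sum gravity centre reduces to a
    membership-weighted average of the peaks.  This keeps the two
    boundary behaviours exact: full membership of an extreme set
    defuzzifies to the universe bound itself.
    """

    universe: tuple[float, float]
    peaks: tuple[float, ...] = ()
    areas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not hi > lo:
            raise ConfigurationError(f"degenerate universe [{lo}, {hi}]")
        if not self.peaks:
            object.__setattr__(
                self, "peaks", tuple(np.linspace(lo, hi, N_SETS).tolist())
            )
        if len(self.peaks) != N_SETS:
            raise ConfigurationError(f"expected {N_SETS} peaks, got {len(self.peaks)}")
        if any(b <= a for a, b in zip(self.peaks, self.peaks[1:])):
            raise ConfigurationError(f"peaks must be strictly increasing: {self.peaks}")
        if not self.areas:
            object.__setattr__(self, "areas", (1.0,) * N_SETS)
        if len(self.areas) != N_SETS or any(a <= 0 for a in self.areas):
            raise ConfigurationError(f"need {N_SETS} positive set areas: {self.areas}")

    @property
    def centroids(self) -> tuple[float, ...]:
        return self.peaks


def fuzzify(x: float, p: FuzzyPartition) -> np.ndarray:
    """Membership vector of a crisp value (clamped to the universe).

    At most two adjacent sets are active and their degrees sum to 1.
    """
    peaks = np.asarray(p.peaks)
    m = np.zeros(N_SETS)
    if x <= peaks[0]:
        m[0] = 1.0
        return m
    if x >= peaks[-1]:
        m[-1] = 1.0
        return m
    k = int(np.searchsorted(peaks, x, side="right")) - 1  # peaks[k] <= x < peaks[k+1]
    t = (x - peaks[k]) / (peaks[k + 1] - peaks[k])
    m[k] = 1.0 - t
    m[k + 1] = t
    return m


def defuzzify(m: Sequence[float], p: FuzzyPartition) -> float:
    """Product-sum gravity defuzzification.

    Centre of gravity of the membership-scaled sets:
    ``sum(m_k * c_k * A_k) / sum(m_k * A_k)`` with each set's centroid
    ``c_k`` and area ``A_k``.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (N_SETS,):
        raise ValidationError(f"membership vector must have {N_SETS} entries")
    if (m < 0).any():
        raise ValidationError("memberships must be non-negative")
    areas = np.asarray(p.areas)
    denom = float(np.sum(m * areas))
    if denom <= 0:
        raise ValidationError("cannot defuzzify an all-zero membership vector")
    return float(np.sum(m * areas * np.asarray(p.centroids)) / denom)


@dataclass(frozen=True)
class ConstructScores:
    """Day-care (D) and outpatient (O) provision scores on [0, 100]."""

    D: float
    O: float

    def __post_init__(self) -> None:
        for name, v in (("D", self.D), ("O", self.O)):
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"construct {name}={v} outside [0, 100]")


# unit partition for normalized provision levels and the [0, 100] output scale
_UNIT = FuzzyPartition(universe=(0.0, 1.0))
_SCORE = FuzzyPartition(universe=(0.0, 100.0))


def _construct_score(
    row: Mapping[str, float],
    var_names: Sequence[str],
    norms: Mapping[str, tuple[float, float]],
) -> float:
    if not var_names:
        raise ConfigurationError("construct has no contributing variables")
    zs = []
    for name in var_names:
        if name not in row:
            raise ResolutionError(f"construct variable {name!r} missing from row")
        lo, hi = norms[name]
        if not hi > lo:
            raise ConfigurationError(f"degenerate normalization range for {name!r}")
        zs.append(float(np.clip((row[name] - lo) / (hi - lo), 0.0, 1.0)))
    z = float(np.mean(zs))
    return defuzzify(fuzzify(z, _UNIT), _SCORE)


def compute_constructs(
    row: Mapping[str, float],
    d_vars: Sequence[str],
    o_vars: Sequence[str],
    norms: Mapping[str, tuple[float, float]],
) -> ConstructScores:
    """D and O provision scores for one area.

    Provision variables are min-max normalized over their expert
    universes (``norms``), averaged per care group, mapped through the
    5-set partition and defuzzified onto [0, 100].  The map is monotone
    non-decreasing in every contributing variable, 0 when all provision
    is absent and 100 when all variables sit at their universe maxima.
    """
    return ConstructScores(
        D=_construct_score(row, d_vars, norms),
        O=_construct_score(row, o_vars, norms),
    )


@dataclass(frozen=True)
class FuzzyRule:
    """IF D is <label> AND O is <label> THEN lower bound is <label>."""

    d_label: str
    o_label: str
    consequent: str

    def __post_init__(self) -> None:
        for lbl in (self.d_label, self.o_label, self.consequent):
            if lbl not in LABELS:
                raise ConfigurationError(f"unknown semantic label {lbl!r}")


def default_rule_base() -> tuple[FuzzyRule, ...]:
    """The shipped 5x5 monotone rule table.

    Scarcer day/outpatient provision raises the residential
    appropriateness floor: both antecedents at "very little" fire a
    "very much" consequent, both at "very much" fire "very little", and
    the table is monotone in between (consequent index
    ``4 - (iD + iO + 1) // 2``).
    """
    rules = []
    for i_d in range(N_SETS):
        for i_o in range(N_SETS):
            i_c = (N_SETS - 1) - (i_d + i_o + 1) // 2
            rules.append(
                FuzzyRule(
                    d_label=LABELS[i_d],
                    o_label=LABELS[i_o],
                    consequent=LABELS[i_c],
                )
            )
    return tuple(rules)


@dataclass(frozen=True)
class InterpretationRange:
    """The appropriateness range [x_left, x_right] of one variable in one area.

    ``width`` is stored, not recomputed, so rule-based displacement can
    carry it over bit-for-bit (the displaced upper bound is
    ``x_left' + width``, and ``x_left' + width - x_left'`` need not equal
    ``width`` in floating point).
    """

    x_left: float
    x_right: float
    variable: str = ""
    dmu: str = ""
    width: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.x_left > self.x_right:
            raise ValidationError(
                f"range bounds out of order for {self.variable or '?'}: "
                f"({self.x_left}, {self.x_right})"
            )
        if self.width is None:
            object.__setattr__(self, "width", self.x_right - self.x_left)


def adjust_range(
    base: InterpretationRange,
    scores: ConstructScores,
    rules: Iterable[FuzzyRule],
    left_universe: FuzzyPartition,
) -> InterpretationRange:
    """Displace an appropriateness range according to the D/O rule base.

    The construct scores are fuzzified on the [0, 100] scale, every rule
    fires with strength ``mu_D * mu_O`` (product inference), strengths
    accumulate per consequent label (sum aggregation), and the aggregate
    defuzzifies over ``left_universe`` into the new lower bound.  The
    upper bound keeps the base width exactly.  If no rule fires, the base
    range is returned unchanged.
    """
    m_d = fuzzify(scores.D, _SCORE)
    m_o = fuzzify(scores.O, _SCORE)
    mass = np.zeros(N_SETS)
    for rule in rules:
        strength = m_d[LABELS.index(rule.d_label)] * m_o[LABELS.index(rule.o_label)]
        mass[LABELS.index(rule.consequent)] += strength
    if mass.sum() <= 0:
        return base
    new_left = defuzzify(mass, left_universe)
    return InterpretationRange(
        x_left=new_left,
        x_right=new_left + base.width,
        variable=base.variable,
        dmu=base.dmu,
        width=base.width,
    )


# ---------------------------------------------------------------------------
# value-interpretation profiles
# ---------------------------------------------------------------------------

class Profile:
    """A monotone piecewise-linear interpretation of a sampled value.

    ``pieces(r)`` returns the ordered breakpoints and one linear function
    per piece; ``__call__`` evaluates the profile.
    """

    name: str = "base"

    def pieces(
        self, r: InterpretationRange
    ) -> tuple[tuple[float, ...], tuple[Callable[[float], float], ...]]:
        raise NotImplementedError

    def __call__(self, x: float, r: InterpretationRange) -> float:
        breaks, fns = self.pieces(r)
        k = int(np.searchsorted(breaks, x, side="right"))
        return fns[k](x)


class IdentityProfile(Profile):
    """No interpretation: the sampled value passes through unchanged."""

    name = "identity"

    def pieces(self, r):
        return (), (lambda x: x,)


class WidthMinusValueProfile(Profile):
    """The literal published transform: ``x_int = (x_right - x_left) - x``.

    A single decreasing linear map applied on all three pieces.  Note it
    goes negative whenever ``x`` exceeds the range width, so downstream
    DEA inputs are floored at a small epsilon.
    """

    name = "width_minus_value"

    def pieces(self, r):
        w = r.width
        return (), (lambda x: w - x,)


class CentredTentProfile(Profile):
    """Appropriateness as distance to the range centre.

    Peaks at ``width / 2`` when the value sits exactly at the centre of
    the appropriateness range and falls off linearly (slope +/-1), so
    "the more centred the value the more appropriate".  Zero at the
    range bounds, negative outside.
    """

    name = "centred_tent"

    def pieces(self, r):
        c = 0.5 * (r.x_left + r.x_right)
        w = r.width
        up = lambda x: 0.5 * w - (c - x)
        down = lambda x: 0.5 * w - (x - c)
        return (r.x_left, c, r.x_right), (up, up, down, down)


PROFILES: dict[str, Profile] = {
    p.name: p
    for p in (IdentityProfile(), WidthMinusValueProfile(), CentredTentProfile())
}


def interpret_value(
    x: float, r: InterpretationRange, profile: str | Profile = "identity"
) -> float:
    """Interpret one sampled value through a named profile."""
    if isinstance(profile, str):
        try:
            profile = PROFILES[profile]
        except KeyError:
            raise ConfigurationError(f"unknown profile {profile!r}") from None
    return profile(x, r)


# ---------------------------------------------------------------------------
# whole-dataset interpretation
# ---------------------------------------------------------------------------

@dataclass
class FuzzyConfig:
    """Configuration bundle for the interpretation layer.

    * ``d_vars`` / ``o_vars`` — provision variables feeding the D and O
      constructs.
    * ``norms`` — per-variable (min, max) universes used both for
      construct normalization and as expert value ranges.
    * ``base_ranges`` — static appropriateness ranges per interpreted
      variable (R-group variables get rule-based displacement; any other
      listed variable keeps its static range).
    * ``left_universes`` — expert partition for each displaced lower
      bound.
    * ``profiles`` — interpretation profile name per variable; variables
      not listed pass through untouched.
    """

    d_vars: tuple[str, ...]
    o_vars: tuple[str, ...]
    norms: dict[str, tuple[float, float]]
    base_ranges: dict[str, InterpretationRange] = field(default_factory=dict)
    left_universes: dict[str, FuzzyPartition] = field(default_factory=dict)
    profiles: dict[str, str] = field(default_factory=dict)
    rules: tuple[FuzzyRule, ...] = field(default_factory=default_rule_base)
    adjusted_vars: tuple[str, ...] = ()

    @classmethod
    def default_for(cls, ds: EcosystemDataset) -> "FuzzyConfig":
        """A deterministic default configuration derived from a dataset.

        D and O constructs use all provision (input) variables of the
        respective care groups, normalized on [0, 1.2 * column max].
        Residential input variables are interpreted through the centred
        tent profile with base ranges spanning the central half of the
        observed values and rule-displaced lower bounds.
        """
        d_vars = tuple(
            v.name for v in ds.variables if v.role == "input" and v.care_group == "D"
        )
        o_vars = tuple(
            v.name for v in ds.variables if v.role == "input" and v.care_group == "O"
        )
        norms = {}
        for name in (*d_vars, *o_vars):
            top = float(ds.column(name).max())
            norms[name] = (0.0, 1.2 * top if top > 0 else 1.0)
        base_ranges, left_universes, profiles = {}, {}, {}
        r_vars = tuple(
            v.name for v in ds.variables if v.role == "input" and v.care_group == "R"
        )
        for name in r_vars:
            col = ds.column(name)
            q25, q75 = np.percentile(col, [25.0, 75.0])
            if q75 <= q25:  # flat column: keep a token range, no displacement
                q25, q75 = float(col.min()), float(col.min()) + 1.0
            base_ranges[name] = InterpretationRange(
                x_left=float(q25), x_right=float(q75), variable=name
            )
            top = float(col.max())
            left_universes[name] = FuzzyPartition(
                universe=(0.0, 1.2 * top if top > 0 else 1.0)
            )
            profiles[name] = "centred_tent"
        return cls(
            d_vars=d_vars,
            o_vars=o_vars,
            norms=norms,
            base_ranges=base_ranges,
            left_universes=left_universes,
            profiles=profiles,
            adjusted_vars=r_vars,
        )


def interpretation_ranges(
    ds: EcosystemDataset, cfg: FuzzyConfig, row_values: Mapping[str, float]
) -> dict[str, InterpretationRange]:
    """Per-variable ranges for one DMU row, with rule-based displacement
    applied to the configured (residential) variables."""
    scores = compute_constructs(row_values, cfg.d_vars, cfg.o_vars, cfg.norms)
    ranges = {}
    for name, base in cfg.base_ranges.items():
        if name in cfg.adjusted_vars and name in cfg.left_universes:
            ranges[name] = adjust_range(
                base, scores, cfg.rules, cfg.left_universes[name]
            )
        else:
            ranges[name] = base
    return ranges


def interpret_dataset(
    sampled: np.ndarray,
    ds: EcosystemDataset,
    ranges: Mapping[str, Mapping[str, InterpretationRange]],
    profiles: Mapping[str, str],
) -> np.ndarray:
    """Interpret a sampled matrix cell by cell.

    ``ranges`` maps DMU name -> variable name -> range; ``profiles`` maps
    variable name -> profile name.  Variables without a profile pass
    through unchanged.  The result has the same shape as ``sampled``.
    """
    out = np.array(sampled, dtype=float, copy=True)
    for var, profile_name in profiles.items():
        j = ds.variable_index(var)
        for i, dmu in enumerate(ds.dmu_names):
            r = ranges[dmu][var]
            out[i, j] = interpret_value(sampled[i, j], r, profile_name)
    return out
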