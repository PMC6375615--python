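"""Synthetic fixtures: ecosystem datasets, interventions and RTE pools.

The generator emulates the *structure* of a real small-area mental-health
dataset — 19 areas by 57 DESDE-LTC-style indicators, non-negative rates
per 100,000 inhabitants, utilization outputs positively coupled to the
matching provision inputs so DEA frontiers are non-degenerate — without
attempting to match any real province's magnitudes.

Per-area provision follows a latent log-normal "care level" per care
group (R/D/O); input indicators scale that level with measure-specific
magnitudes and multiplicative noise, and utilization outputs are a
monotone function of the group level plus noise, which induces the
positive input-output correlation the frontier analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import EcosystemDataset, VariableDescriptor, parse_variable_name
from .distribution import DEFAULT_INTTOT, EFFICIENT_BIN, RTEPool, WEAK_BIN
from .exceptions import ValidationError
from .interventions import Edit, InterventionSpec

# 43 input + 14 output indicator names.  Names used in published scenario
# and intervention tables appear verbatim; the remainder are synthetic
# fill following the same taxonomy (marked below).
INPUT_NAMES: tuple[str, ...] = (
    # availability (T)
    "TR2", "TR4-R7", "TR8-R13", "TR12", "TD1", "TD41", "TD4other",
    "TD2-D3", "TO8+O10",
    # placement capacity (P)
    "PR2", "PR4-R7", "PR2-R7", "PR8-R13", "PR8+R11", "PR12",
    "PD1", "PD41", "PD1+D41", "PD4other", "PD4other+D2-D3",
    # workforce capacity (Prof)
    "ProfTotR2", "ProfPsychiR2", "ProfPsychoDUER2",
    "ProfTotR4-R7", "ProfPsychiR4-R7", "ProfPsychoDUER4-R7",
    "ProfTotR2-R7", "ProfTotR8-R13",
    "ProfTotD1+D41", "ProfPsychiD1+D41", "ProfPsychoDUED1+D41",
    "ProfTotD4+D2-D3",
    "ProfTotO8+O10", "ProfPsychiO8+O10", "ProfPsychoO8+O10", "ProfDUEO8+O10",
    # synthetic fill (same taxonomy, not from any published table)
    "TR11", "TR13", "TD2", "TD3", "ProfDUER2", "ProfPsychoR8-R13",
    "ProfTotD41",
)
OUTPUT_NAMES: tuple[str, ...] = (
    "UDischargesR2", "UStayR2", "UReAdmissionR2",
    "UD1", "UD41",
    "UPrevO8+O10", "UIncO8+O10", "UFrecO8+O10",
    # synthetic fill
    "UDischargesR4-R7", "UStayR4-R7", "UReAdmissionR4-R7",
    "UD4other", "UD2-D3", "UStayR8-R13",
)

#: typical magnitude of each measure type (rates per 100,000 inhabitants)
DEFAULT_SCALES = {"T": 1.0, "P": 25.0, "Prof": 15.0, "U": 300.0}


def default_taxonomy() -> list[VariableDescriptor]:
    """The 57-variable descriptor template (43 inputs, 14 outputs)."""
    return [parse_variable_name(n) for n in (*INPUT_NAMES, *OUTPUT_NAMES)]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic ecosystem generator."""

    n_dmu: int = 19
    seed: int = 0
    scales: dict = field(default_factory=lambda: dict(DEFAULT_SCALES))
    latent_sigma: float = 0.4  # spread of the per-area care level
    noise_sigma: float = 0.25  # per-indicator multiplicative noise
    effect: float = 1.0  # elasticity of utilization w.r.t. provision


def generate_ecosystem(cfg: FixtureConfig = FixtureConfig()) -> EcosystemDataset:
    """Generate a synthetic 19 x 57 ecosystem dataset (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    variables = default_taxonomy()
    dmu_names = [f"SHA-{i + 1:02d}" for i in range(cfg.n_dmu)]
    # latent per-area care level per care group (plus one for mixed names)
    groups = ("R", "D", "O", "mixed")
    latent = {
        g: np.exp(rng.normal(0.0, cfg.latent_sigma, size=cfg.n_dmu))
        for g in groups
    }
    values = np.empty((cfg.n_dmu, len(variables)))
    for j, var in enumerate(variables):
        level = latent[var.care_group]
        noise = np.exp(rng.normal(0.0, cfg.noise_sigma, size=cfg.n_dmu))
        scale = cfg.scales[var.measure]
        if var.role == "output":
            values[:, j] = scale * level**cfg.effect * noise
        else:
            values[:, j] = scale * level * noise
    return EcosystemDataset(dmu_names=dmu_names, variables=variables, values=values)


def generate_intervention(
    ds: EcosystemDataset,
    n_edits: int = 2,
    seed: int = 0,
    amount: float = 1.0,
) -> InterventionSpec:
    """Random paired staff reassignments on workforce variables.

    ``n_edits`` must be even: each pair is a source-area decrease and a
    target-area increase on the same variable, so column totals are
    conserved.  The source cell is chosen with enough headroom to stay
    non-negative.
    """
    if n_edits % 2:
        raise ValidationError("n_edits must be even (edits come in pairs)")
    rng = np.random.default_rng(seed)
    prof_vars = [v.name for v in ds.variables if v.measure == "Prof"]
    edits: list[Edit] = []
    for _ in range(n_edits // 2):
        for _attempt in range(100):
            var = prof_vars[rng.integers(len(prof_vars))]
            src, dst = rng.choice(ds.n_dmu, size=2, replace=False)
            if ds.values[src, ds.variable_index(var)] >= amount:
                break
        else:
            raise ValidationError("could not find a source cell with headroom")
        edits.append(Edit(dmu=ds.dmu_names[src], variable=var,
                          amount=-amount, direction="decreasing"))
        edits.append(Edit(dmu=ds.dmu_names[dst], variable=var,
                          amount=amount, direction="increasing"))
    return InterventionSpec(
        id=f"synthetic-{seed}",
        description=f"{n_edits // 2} synthetic paired staff reassignment(s)",
        edits=tuple(edits),
    )


def fig2_style_pool(
    shape,
    n: int = 100,
    seed: int | None = None,
    dmu: str = "synthetic",
    scenario: str = "synthetic",
    orientation: str = "input",
) -> RTEPool:
    """A pool whose 22-bin histogram matches ``shape`` exactly.

    ``shape`` is a sequence of 22 relative frequencies summing to 1.
    Scores are placed at bin midpoints; records falling in the last two
    bins get score 1 with the matching efficiency class.  ``n`` must make
    every frequency an exact multiple of 1/n, otherwise counts are
    rounded to the nearest achievable histogram (largest-remainder) and a
    warning is raised.  ``seed`` only shuffles the record order (the
    histogram is exact either way).
    """
    freqs = np.asarray(shape, dtype=float)
    if freqs.shape != (DEFAULT_INTTOT,):
        raise ValidationError(f"shape must have {DEFAULT_INTTOT} frequencies")
    if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValidationError("frequencies must be >= 0 and sum to 1")
    raw = freqs * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
    if not np.allclose(raw, counts):
        import warnings

        warnings.warn(
            f"n={n} cannot represent the requested frequencies exactly; "
            "using the nearest achievable counts",
            stacklevel=2,
        )
    rows = []
    sim = 0
    for h, count in enumerate(counts):
        if h == EFFICIENT_BIN:
            score, cls_ = 1.0, "efficient"
        elif h == WEAK_BIN:
            score, cls_ = 1.0, "weakly_efficient"
        else:
            score, cls_ = 0.05 * h + 0.025, "inefficient"
        for _ in range(count):
            rows.append(
                {
                    "dmu": dmu,
                    "scenario": scenario,
                    "simulation": sim,
                    "orientation": orientation,
                    "rte": score,
                    "efficiency_class": cls_,
                }
            )
            sim += 1
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(rows))
        rows = [
            {**rows[i], "simulation": sim_idx}
            for sim_idx, i in enumerate(order)
        ]
    return RTEPool.from_records(rows)
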