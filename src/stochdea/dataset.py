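"""Data model and I/O for the DMU-by-variable ecosystem dataset.

A dataset holds one row per decision-making unit (DMU; here, a small
health area served by a reference community mental-health centre) and one
column per indicator, expressed as a rate per 100,000 inhabitants.
Indicators follow a DESDE-LTC-style naming taxonomy: a measure prefix
(``T`` availability, ``P`` placement capacity, ``Prof`` workforce
capacity, ``U`` utilization) followed by a care-type code (``R``
residential, ``D`` day, ``O`` outpatient) and service codes, e.g.
``TD1``, ``PR4-R7``, ``ProfTotO8+O10``, ``UFrecO8+O10``.

Utilization indicators are the DEA outputs; availability, placement and
workforce indicators are the DEA inputs.  A *scenario* selects a named
subset of inputs and outputs, giving one "point of view" on efficiency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ResolutionError, ValidationError

INPUT_MEASURES = frozenset({"T", "P", "Prof"})
OUTPUT_MEASURE = "U"
CARE_GROUPS = ("R", "D", "O", "mixed")

_MEASURE_RE = re.compile(r"^(Prof|U|T|P)")
_CARE_CODE_RE = re.compile(r"([RDO])(?=\d)")


@dataclass(frozen=True)
class VariableDescriptor:
    """Metadata for one indicator column.

    ``role`` is derivable from ``measure``: utilization variables are the
    outputs, everything else is an input.
    """

    name: str
    role: str  # "input" | "output"
    care_group: str  # "R" | "D" | "O" | "mixed"
    measure: str  # "T" | "P" | "Prof" | "U"

    def __post_init__(self) -> None:
        if self.role not in ("input", "output"):
            raise ValidationError(f"{self.name}: unknown role {self.role!r}")
        if self.care_group not in CARE_GROUPS:
            raise ValidationError(
                f"{self.name}: unknown care group {self.care_group!r}"
            )
        if self.measure not in INPUT_MEASURES | {OUTPUT_MEASURE}:
            raise ValidationError(f"{self.name}: unknown measure {self.measure!r}")
        if (self.measure == OUTPUT_MEASURE) != (self.role == "output"):
            raise ValidationError(
                f"{self.name}: role {self.role!r} inconsistent with "
                f"measure {self.measure!r} (utilization variables are outputs, "
                "provision variables are inputs)"
            )


def parse_variable_name(name: str) -> VariableDescriptor:
    """Best-effort descriptor from a DESDE-LTC-style variable name.

    The measure is read from the prefix (``Prof`` before ``P``!), the care
    group from the service codes (``R``/``D``/``O`` followed by a digit).
    Names mixing several care types get ``care_group="mixed"``.  Compound
    names such as ``PD4other+D2-D3`` are handled, but a curated descriptor
    table should be preferred when available.
    """
    m = _MEASURE_RE.match(name)
    if m is None:
        raise FormatError(f"cannot infer measure prefix from variable {name!r}")
    measure = m.group(1)
    codes = set(_CARE_CODE_RE.findall(name))
    if len(codes) == 1:
        care = codes.pop()
    elif len(codes) > 1:
        care = "mixed"
    else:
        raise FormatError(f"cannot infer care group from variable {name!r}")
    role = "output" if measure == OUTPUT_MEASURE else "input"
    return VariableDescriptor(name=name, role=role, care_group=care, measure=measure)


@dataclass
class EcosystemDataset:
    """A validated DMU x variable matrix of non-negative rates."""

    dmu_names: list[str]
    variables: list[VariableDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.dmu_names), len(self.variables)
        if self.values.shape != (n, p):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"({n} DMUs, {p} variables)"
            )
        if len(set(self.dmu_names)) != n:
            raise FormatError("duplicate DMU names")
        names = [v.name for v in self.variables]
        if len(set(names)) != p:
            raise FormatError("duplicate variable names")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing value at ({self.dmu_names[i]}, {names[j]})"
            )
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative value {self.values[i, j]} at "
                f"({self.dmu_names[i]}, {names[j]})"
            )
        self._name_index = {v.name: j for j, v in enumerate(self.variables)}
        self._dmu_index = {d: i for i, d in enumerate(self.dmu_names)}

    @property
    def n_dmu(self) -> int:
        return len(self.dmu_names)

    @property
    def n_var(self) -> int:
        return len(self.variables)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable_index(self, name: str) -> int:
        try:
            return self._name_index[name]
        except KeyError:
            raise ResolutionError(f"unknown variable {name!r}") from None

    def dmu_index(self, name: str) -> int:
        try:
            return self._dmu_index[name]
        except KeyError:
            raise ResolutionError(f"unknown DMU {name!r}") from None

    def descriptor(self, name: str) -> VariableDescriptor:
        return self.variables[self.variable_index(name)]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.dmu_names, columns=self.variable_names
        )

    def replace_values(self, values: np.ndarray) -> "EcosystemDataset":
        """Same DMUs and metadata with a new value matrix (re-validated)."""
        return EcosystemDataset(
            dmu_names=list(self.dmu_names),
            variables=list(self.variables),
            values=np.asarray(values, dtype=float).copy(),
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """A named selection of input and output variables for one analysis."""

    id: str
    label: str
    input_vars: tuple[str, ...]
    output_vars: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.input_vars:
            raise ValidationError(f"scenario {self.id}: empty input side")
        if not self.output_vars:
            raise ValidationError(f"scenario {self.id}: empty output side")
        overlap = set(self.input_vars) & set(self.output_vars)
        if overlap:
            raise ValidationError(
                f"scenario {self.id}: variables on both sides: {sorted(overlap)}"
            )

    def validate_against(self, ds: EcosystemDataset) -> None:
        for name in (*self.input_vars, *self.output_vars):
            ds.variable_index(name)  # raises ResolutionError
        for name in self.input_vars:
            if ds.descriptor(name).role != "input":
                raise ValidationError(
                    f"scenario {self.id}: {name} is not an input variable"
                )
        for name in self.output_vars:
            if ds.descriptor(name).role != "output":
                raise ValidationError(
                    f"scenario {self.id}: {name} is not an output variable"
                )


def read_dataset(
    path: str | Path,
    descriptors: Sequence[VariableDescriptor] | str | Path | None = None,
) -> EcosystemDataset:
    """Read a dataset CSV (DMU name in the first column, header row of
    variable names).

    ``descriptors`` may be a sequence of :class:`VariableDescriptor`, a
    path to a descriptor table (CSV with columns name, role, care_group,
    measure), or ``None`` to infer metadata from the variable names.
    """
    frame = pd.read_csv(path, index_col=0)
    if frame.index.has_duplicates:
        raise FormatError(f"{path}: duplicate DMU names")
    if frame.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate variable names")
    columns = [str(c) for c in frame.columns]
    if descriptors is None:
        descs = [parse_variable_name(c) for c in columns]
    elif isinstance(descriptors, (str, Path)):
        descs = _align_descriptors(read_descriptors(descriptors), columns)
    else:
        descs = _align_descriptors(list(descriptors), columns)
    return EcosystemDataset(
        dmu_names=[str(i) for i in frame.index],
        variables=descs,
        values=frame.to_numpy(dtype=float),
    )


def _align_descriptors(
    descs: list[VariableDescriptor], columns: list[str]
) -> list[VariableDescriptor]:
    by_name = {d.name: d for d in descs}
    missing = [c for c in columns if c not in by_name]
    if missing:
        raise ResolutionError(f"no descriptor for variables: {missing}")
    return [by_name[c] for c in columns]


def write_dataset(ds: EcosystemDataset, path: str | Path) -> None:
    ds.to_frame().to_csv(path, index_label="dmu")


def read_descriptors(path: str | Path) -> list[VariableDescriptor]:
    frame = pd.read_csv(path)
    required = {"name", "role", "care_group", "measure"}
    if not required <= set(frame.columns):
        raise FormatError(
            f"{path}: descriptor table needs columns {sorted(required)}"
        )
    return [
        VariableDescriptor(
            name=str(r["name"]),
            role=str(r["role"]),
            care_group=str(r["care_group"]),
            measure=str(r["measure"]),
        )
        for _, r in frame.iterrows()
    ]


def write_descriptors(
    descs: Iterable[VariableDescriptor], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "name": d.name,
                "role": d.role,
                "care_group": d.care_group,
                "measure": d.measure,
            }
            for d in descs
        ]
    ).to_csv(path, index=False)


def load_scenarios(
    path: str | Path, dataset: EcosystemDataset | None = None
) -> list[ScenarioSpec]:
    """Load scenario definitions from a YAML/JSON file.

    The file is a mapping with a ``scenarios`` list; each entry has keys
    ``id``, ``label``, ``input_vars``, ``output_vars``.  When ``dataset``
    is given every referenced variable is resolved against it.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = doc["scenarios"] if isinstance(doc, dict) else doc
    scenarios = []
    for entry in entries:
        spec = ScenarioSpec(
            id=str(entry["id"]),
            label=str(entry.get("label", "")),
            input_vars=tuple(entry["input_vars"]),
            output_vars=tuple(entry["output_vars"]),
        )
        if dataset is not None:
            spec.validate_against(dataset)
        scenarios.append(spec)
    ids = [s.id for s in scenarios]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate scenario ids")
    return scenarios


def default_scenarios(
    dataset: EcosystemDataset | None = None,
) -> list[ScenarioSpec]:
    """The scenario set shipped with the package (see ``data/scenarios.yaml``)."""
    path = Path(__file__).parent / "data" / "scenarios.yaml"
    return load_scenarios(path, dataset)


def subset_for_scenario(
    ds: EcosystemDataset, sc: ScenarioSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Return (input matrix, output matrix) for a scenario, DMU order preserved."""
    sc.validate_against(ds)
    xi = [ds.variable_index(v) for v in sc.input_vars]
    yi = [ds.variable_index(v) for v in sc.output_vars]
    return ds.values[:, xi].copy(), ds.values[:, yi].copy()
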