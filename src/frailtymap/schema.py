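"""The canonical frailty variable schema.

A frailty assessment compares patients over a fixed catalogue of 61
mixed-type variables drawn from the geriatric patient record, organised
in six clinical domains:

========================  ====  =========================================
domain                    size  content
========================  ====  =========================================
anthropometric               9  demographics and body composition
functional                   6  gait/balance and dependence scores
nutritional                 13  blood biochemistry
cognitive                    2  mental-state scores
geriatric_syndromes         11  binary syndrome checks
dispersion                  20  accelerometer-derived gait statistics
========================  ====  =========================================

Each variable is quantitative (a number with a canonical unit),
qualitative (a closed category label) or binary (present/absent of a
condition).  The drug-count item of the anthropometric record row is
covered by the geriatric ``polypharmacy`` flag rather than duplicated as
a tenth anthropometric variable; chronic-pathology groupings fall
outside the six domains and are not part of the catalogue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import SchemaError

GROUPS = (
    "anthropometric",
    "functional",
    "nutritional",
    "cognitive",
    "geriatric_syndromes",
    "dispersion",
)

KINDS = ("quantitative", "qualitative", "binary")

#: expected number of variables per group in the canonical schema
GROUP_SIZES = {
    "anthropometric": 9,
    "functional": 6,
    "nutritional": 13,
    "cognitive": 2,
    "geriatric_syndromes": 11,
    "dispersion": 20,
}

ADL_CATEGORIES = (
    "independent",
    "mild_dependent",
    "moderate_dependent",
    "great_dependent",
    "serious_dependent",
)


@dataclass(frozen=True)
class VariableSpec:
    """One frailty variable: identity, domain, type and default weight."""

    name: str
    group: str
    kind: str
    unit: str = ""
    default_weight: float = 1.0
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group {self.group!r} for variable {self.name!r}")
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.kind == "quantitative" and not self.unit:
            raise SchemaError(f"quantitative variable {self.name!r} must carry a unit")
        if not 0.0 <= self.default_weight <= 1.0:
            raise SchemaError(f"default_weight of {self.name!r} outside [0, 1]")
        if self.kind == "qualitative" and not self.categories:
            raise SchemaError(f"qualitative variable {self.name!r} needs categories")


@dataclass(frozen=True)
class FrailtySchema:
    """An ordered, name-unique collection of :class:`VariableSpec`."""

    variables: tuple[VariableSpec, ...]
    _by_name: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        by_name = {}
        for spec in self.variables:
            if spec.name in by_name:
                raise SchemaError(f"duplicate variable name {spec.name!r}")
            by_name[spec.name] = spec
        object.__setattr__(self, "_by_name", by_name)

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(spec.name for spec in self.variables)

    def group_members(self, group: str) -> tuple[VariableSpec, ...]:
        if group not in GROUPS:
            raise SchemaError(f"unknown group {group!r}")
        return tuple(s for s in self.variables if s.group == group)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUPS}
        for spec in self.variables:
            sizes[spec.group] += 1
        return sizes

    # -- JSON round trip ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        records = []
        for s in self.variables:
            rec = {
                "name": s.name,
                "group": s.group,
                "kind": s.kind,
                "unit": s.unit,
                "default_weight": s.default_weight,
            }
            if s.categories:
                rec["categories"] = list(s.categories)
            records.append(rec)
        text = json.dumps(records, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FrailtySchema":
        text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("["):
            text = Path(source).read_text(encoding="utf-8")
        records = json.loads(text)
        return cls(tuple(
            VariableSpec(
                name=r["name"],
                group=r["group"],
                kind=r["kind"],
                unit=r.get("unit", ""),
                default_weight=r.get("default_weight", 1.0),
                categories=tuple(r.get("categories", ())),
            )
            for r in records
        ))


def _quant(name: str, group: str, unit: str) -> VariableSpec:
    return VariableSpec(name, group, "quantitative", unit=unit)


#: the 20 accelerometer dispersion-measure variable names, in schema order
DISPERSION_VARIABLES: tuple[str, ...] = tuple(
    f"{axis}_{stat}"
    for axis in ("x", "y", "z")
    for stat in (
        "arithmetic_mean",
        "standard_deviation",
        "absolute_mean_difference",
        "variance",
        "amplitude",
        "pearson_cv",
    )
) + ("acceleration_mean", "acceleration_sd")


def canonical_schema() -> FrailtySchema:
    """Build the fixed 61-variable frailty schema (9/6/13/2/11/20)."""
    variables: list[VariableSpec] = []

    # anthropometric and general data (9)
    variables += [
        VariableSpec("gender", "anthropometric", "qualitative", categories=("M", "F")),
        _quant("age", "anthropometric", "years"),
        _quant("size", "anthropometric", "cm"),
        _quant("weight", "anthropometric", "kg"),
        _quant("body_mass_index", "anthropometric", "kg/m2"),
        _quant("body_mass", "anthropometric", "kg"),
        _quant("lean_mass", "anthropometric", "kg"),
        _quant("fat_mass", "anthropometric", "%"),
        _quant("total_water", "anthropometric", "kg"),
    ]

    # functional assessment (6): gait/balance and dependence scores
    variables += [
        _quant("tinetti_score", "functional", "points"),
        _quant("barthel_index", "functional", "points"),
        _quant("lawton_brody_score", "functional", "points"),
        _quant("get_up_and_go_score", "functional", "points"),
        VariableSpec("needs_physical_help", "functional", "binary"),
        VariableSpec("adl_independence", "functional", "qualitative",
                     categories=ADL_CATEGORIES),
    ]

    # nutritional assessment (13): blood biochemistry
    variables += [
        _quant("total_protein", "nutritional", "g/dl"),
        _quant("serum_albumin", "nutritional", "g/dl"),
        _quant("cholesterol", "nutritional", "mg/dl"),
        _quant("triglycerides", "nutritional", "mg/dl"),
        _quant("blood_iron", "nutritional", "ug/dl"),
        _quant("ferritin", "nutritional", "ng/ml"),
        _quant("vitamin_b12", "nutritional", "pg/ml"),
        _quant("serum_folic_acid", "nutritional", "ng/ml"),
        _quant("serum_transferrin", "nutritional", "mg/dl"),
        _quant("leukocytes", "nutritional", "thousand/mcl"),
        _quant("lymphocytes", "nutritional", "thousand/mcl"),
        _quant("hemoglobin", "nutritional", "g/dl"),
        _quant("calcium", "nutritional", "mg/dl"),
    ]

    # cognitive assessment (2)
    variables += [
        _quant("mini_mental_status", "cognitive", "points"),
        _quant("cruz_roja_mental_scale", "cognitive", "points"),
    ]

    # geriatric syndromes (11): binary checks
    for syndrome in (
        "dementia", "depression", "incontinence", "immobility",
        "recurrent_falls", "polypharmacy", "comorbidity",
        "sensory_deprivation", "pressure_ulcers", "malnutrition",
        "terminal_illness",
    ):
        variables.append(VariableSpec(syndrome, "geriatric_syndromes", "binary"))

    # dispersion measures (20): gait statistics per axis + magnitude
    for name in DISPERSION_VARIABLES:
        unit = "ratio" if name.endswith("pearson_cv") else (
            "(m/s2)^2" if name.endswith("variance") else "m/s2")
        variables.append(_quant(name, "dispersion", unit))

    schema = FrailtySchema(tuple(variables))
    assert schema.group_sizes() == GROUP_SIZES, "canonical schema partition broken"
    return schema
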