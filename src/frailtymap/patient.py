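"""Patient instances and the patient stack.

A *patient instance* is the full set of frailty-variable values for one
patient at one assessment time; the *patient stack* is the stored
collection of instances a newly studied patient is compared against.
At a follow-up assessment a clinician may mark a variable as *kept*
("k"): not re-measured, to be carried forward from the patient's most
recent earlier value.  Values never measured are *missing*.

Stack files are plain CSV: ``patient_id, instance_id, iteration, sex,
age`` followed by the schema's variable columns in schema order.  An
empty cell is missing, a literal ``k`` is kept, binary cells are
``true``/``false``, and a quantitative cell may carry a unit after a
space (``"70000 g"``) when it is not yet in the canonical unit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import SchemaError, StackIntegrityError, StackParseError
from .schema import FrailtySchema, VariableSpec

PRESENT = "present"
MISSING = "missing"
KEPT = "kept"

_METADATA_COLUMNS = ("patient_id", "instance_id", "iteration", "sex", "age")


@dataclass(frozen=True)
class VariableValue:
    """The state of one variable in one instance.

    ``value`` is set only when ``state == "present"``; ``unit`` is set
    only for quantitative values not yet in the canonical unit.
    """

    state: str
    value: float | str | bool | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.state not in (PRESENT, MISSING, KEPT):
            raise ValueError(f"invalid state {self.state!r}")
        if self.state != PRESENT and self.value is not None:
            raise ValueError(f"{self.state} value must not carry a payload")

    @classmethod
    def present(cls, value: float | str | bool, unit: str | None = None) -> "VariableValue":
        return cls(PRESENT, value, unit)

    @classmethod
    def missing(cls) -> "VariableValue":
        return cls(MISSING)

    @classmethod
    def kept(cls) -> "VariableValue":
        return cls(KEPT)

    @property
    def is_present(self) -> bool:
        return self.state == PRESENT


@dataclass(frozen=True)
class PatientInstance:
    """All variable values for one patient at one assessment time."""

    patient_id: str
    instance_id: int
    iteration: int
    sex: str
    age: float
    values: dict[str, VariableValue] = field(default_factory=dict)

    def value(self, name: str) -> VariableValue:
        return self.values.get(name, VariableValue.missing())

    def with_values(self, updates: dict[str, VariableValue]) -> "PatientInstance":
        merged = dict(self.values)
        merged.update(updates)
        return replace(self, values=merged)


@dataclass(frozen=True)
class PatientStack:
    """A schema plus a collection of patient instances.

    Construction is permissive so that :func:`validate_stack` can
    report violations; :func:`load_stack` enforces integrity on input.
    """

    schema: FrailtySchema
    instances: tuple[PatientInstance, ...]

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[PatientInstance]:
        return iter(self.instances)

    def get(self, instance_id: int) -> PatientInstance:
        for inst in self.instances:
            if inst.instance_id == instance_id:
                return inst
        from .errors import InstanceLookupError
        raise InstanceLookupError(f"no instance with id {instance_id}")

    def iterations(self) -> tuple[int, ...]:
        return tuple(sorted({inst.iteration for inst in self.instances}))

    def of_iteration(self, iteration: int) -> tuple[PatientInstance, ...]:
        return tuple(i for i in self.instances if i.iteration == iteration)

    def replace_instances(self, instances: Iterable[PatientInstance]) -> "PatientStack":
        return PatientStack(self.schema, tuple(instances))


@dataclass(frozen=True)
class WeightProfile:
    """Per-variable importance weights in [0, 1].

    A usable profile has at least one positive weight.  Weights default
    to 0 for variables not named, so a profile built from a short list
    of variables restricts the similarity to exactly those.
    """

    weights: dict[str, float]

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight of {name!r} outside [0, 1]: {w}")

    def get(self, name: str) -> float:
        return self.weights.get(name, 0.0)

    def total(self) -> float:
        return sum(self.weights.values())

    @classmethod
    def uniform(cls, schema: FrailtySchema, weight: float = 1.0) -> "WeightProfile":
        return cls({name: weight for name in schema.names})

    @classmethod
    def from_mapping(cls, mapping: dict[str, float], schema: FrailtySchema) -> "WeightProfile":
        """Build from a map whose keys are variable names or group names.

        A group key assigns its weight uniformly to every member
        variable of that group; explicit variable keys win over group
        shorthand.
        """
        weights: dict[str, float] = {}
        for key, w in mapping.items():
            if key in schema:
                continue
            members = schema.group_members(key)  # raises SchemaError if unknown
            for spec in members:
                weights[spec.name] = float(w)
        for key, w in mapping.items():
            if key in schema:
                weights[key] = float(w)
        return cls(weights)


# ---------------------------------------------------------------------------
# CSV serialization


def _format_cell(vv: VariableValue, spec: VariableSpec) -> str:
    if vv.state == MISSING:
        return ""
    if vv.state == KEPT:
        return "k"
    if spec.kind == "binary":
        return "true" if vv.value else "false"
    if spec.kind == "qualitative":
        return str(vv.value)
    text = repr(float(vv.value))
    if vv.unit is not None:
        text += f" {vv.unit}"
    return text


def _parse_cell(cell: object, spec: VariableSpec, iteration: int,
                row_label: object) -> VariableValue:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return VariableValue.missing()
    text = str(cell).strip()
    if text == "":
        return VariableValue.missing()
    if text == "k":
        if iteration <= 1:
            raise StackParseError(
                "kept marker 'k' in a first-iteration row has no antecedent",
                row=row_label, column=spec.name)
        return VariableValue.kept()
    if spec.kind == "binary":
        low = text.lower()
        if low in ("true", "1", "yes"):
            return VariableValue.present(True)
        if low in ("false", "0", "no"):
            return VariableValue.present(False)
        raise StackParseError(f"invalid binary cell {text!r}", row=row_label,
                              column=spec.name)
    if spec.kind == "qualitative":
        if text not in spec.categories:
            raise StackParseError(
                f"category {text!r} not in {spec.categories}", row=row_label,
                column=spec.name)
        return VariableValue.present(text)
    parts = text.split()
    try:
        number = float(parts[0])
    except ValueError:
        raise StackParseError(f"invalid numeric cell {text!r}", row=row_label,
                              column=spec.name) from None
    unit = parts[1] if len(parts) > 1 else None
    return VariableValue.present(number, unit)


def save_stack(stack: PatientStack, path: str | Path) -> None:
    """Write a stack to the documented CSV dialect."""
    columns = list(_METADATA_COLUMNS) + list(stack.schema.names)
    rows = []
    for inst in stack.instances:
        row = [inst.patient_id, inst.instance_id, inst.iteration, inst.sex,
               inst.age]
        for spec in stack.schema:
            row.append(_format_cell(inst.value(spec.name), spec))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False, encoding="utf-8")


def load_stack(path: str | Path, schema: FrailtySchema) -> PatientStack:
    """Read a stack CSV, parsing every cell into a :class:`VariableValue`.

    The canonical layout is positional (five metadata columns, then the
    schema's variables in schema order), which also disambiguates a
    variable sharing its name with a metadata column (``age``); a file
    carrying only a subset of variable columns is matched by name.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False,
                        encoding="utf-8")
    # pandas mangles duplicate headers ("age" -> "age.1"); undo for matching
    demangled = [re.sub(r"\.\d+$", "", c) for c in frame.columns]
    positional = (demangled[:len(_METADATA_COLUMNS)] == list(_METADATA_COLUMNS)
                  and demangled[len(_METADATA_COLUMNS):] == list(schema.names))
    if not positional:
        missing_meta = [c for c in _METADATA_COLUMNS if c not in demangled]
        if missing_meta:
            raise StackParseError(f"missing metadata columns {missing_meta}")
        unknown = [c for c in demangled
                   if c not in _METADATA_COLUMNS and c not in schema]
        if unknown:
            raise SchemaError(f"unknown variable columns {unknown}")

    instances = []
    for idx, row in frame.iterrows():
        try:
            instance_id = int(row.iloc[1] if positional else row["instance_id"])
            iteration = int(row.iloc[2] if positional else row["iteration"])
            age = float(row.iloc[4] if positional else row["age"])
        except ValueError as exc:
            raise StackParseError(f"bad metadata: {exc}", row=idx) from None
        values: dict[str, VariableValue] = {}
        for pos, spec in enumerate(schema):
            if positional:
                cell = row.iloc[len(_METADATA_COLUMNS) + pos]
            elif spec.name in frame.columns:
                cell = row[spec.name]
            else:
                continue
            vv = _parse_cell(cell, spec, iteration, idx)
            if vv.state != MISSING:
                values[spec.name] = vv
        instances.append(PatientInstance(
            patient_id=str(row["patient_id"]), instance_id=instance_id,
            iteration=iteration, sex=str(row["sex"]), age=age, values=values))
    ids = [inst.instance_id for inst in instances]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise StackIntegrityError(f"duplicate instance_id {dupes}")
    return PatientStack(schema, tuple(instances))


# ---------------------------------------------------------------------------
# Kept resolution and accounting


def resolve_kept_values(stack: PatientStack) -> PatientStack:
    """Forward-fill kept values from the same patient's earlier iterations.

    A kept marker is replaced by that patient's most recent *present*
    value for the variable in an earlier iteration; when no such value
    exists it becomes missing.  Idempotent: a resolved stack contains no
    kept states.
    """
    by_patient: dict[str, list[PatientInstance]] = {}
    for inst in stack.instances:
        by_patient.setdefault(inst.patient_id, []).append(inst)
    for insts in by_patient.values():
        insts.sort(key=lambda i: i.iteration)

    resolved: dict[int, PatientInstance] = {}
    for insts in by_patient.values():
        for pos, inst in enumerate(insts):
            updates: dict[str, VariableValue] = {}
            for name, vv in inst.values.items():
                if vv.state != KEPT:
                    continue
                filled = VariableValue.missing()
                for earlier in reversed(insts[:pos]):
                    prior = resolved[earlier.instance_id].value(name)
                    if prior.is_present:
                        filled = prior
                        break
                updates[name] = filled
            new = inst.with_values(updates) if updates else inst
            if updates:
                # drop values that resolved to missing
                new = replace(new, values={n: v for n, v in new.values.items()
                                           if v.state != MISSING})
            resolved[inst.instance_id] = new

    return stack.replace_instances(resolved[i.instance_id] for i in stack.instances)


def count_existing_values(stack: PatientStack, iteration: int,
                          count_kept: bool = False) -> int:
    """Number of variables with a value across all instances of an iteration.

    With ``count_kept`` enabled, kept markers that forward-fill to a
    real value count as existing too (they resolve to the carried-over
    measurement); unresolvable kept markers never count.
    """
    target = resolve_kept_values(stack) if count_kept else stack
    total = 0
    for inst in target.of_iteration(iteration):
        total += sum(1 for vv in inst.values.values() if vv.is_present)
    return total


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationFinding:
    category: str  # "schema" | "integrity" | "type" | "range"
    instance_id: int | None
    variable: str | None
    message: str


def validate_stack(stack: PatientStack) -> list[ValidationFinding]:
    """Report every invariant violation; an empty report means valid."""
    findings: list[ValidationFinding] = []
    seen_ids: set[int] = set()
    for inst in stack.instances:
        if inst.instance_id in seen_ids:
            findings.append(ValidationFinding(
                "integrity", inst.instance_id, None,
                f"duplicate instance_id {inst.instance_id}"))
        seen_ids.add(inst.instance_id)
        if inst.sex not in ("M", "F"):
            findings.append(ValidationFinding(
                "type", inst.instance_id, None, f"invalid sex {inst.sex!r}"))
        if not 0 < inst.age < 130:
            findings.append(ValidationFinding(
                "range", inst.instance_id, None,
                f"implausible age {inst.age}"))
        if inst.iteration < 1:
            findings.append(ValidationFinding(
                "range", inst.instance_id, None,
                f"iteration must be >= 1, got {inst.iteration}"))
        for name, vv in inst.values.items():
            if name not in stack.schema:
                findings.append(ValidationFinding(
                    "schema", inst.instance_id, name,
                    f"unknown variable {name!r}"))
                continue
            if vv.state == KEPT and inst.iteration <= 1:
                findings.append(ValidationFinding(
                    "integrity", inst.instance_id, name,
                    "kept value in first iteration"))
            if not vv.is_present:
                continue
            spec = stack.schema[name]
            if spec.kind == "quantitative" and (
                    isinstance(vv.value, bool)
                    or not isinstance(vv.value, (int, float))):
                findings.append(ValidationFinding(
                    "type", inst.instance_id, name,
                    f"expected a number, got {vv.value!r}"))
            elif spec.kind == "binary" and not isinstance(vv.value, bool):
                findings.append(ValidationFinding(
                    "type", inst.instance_id, name,
                    f"expected a boolean, got {vv.value!r}"))
            elif spec.kind == "qualitative" and vv.value not in spec.categories:
                findings.append(ValidationFinding(
                    "type", inst.instance_id, name,
                    f"category {vv.value!r} not in {spec.categories}"))
    return findings
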