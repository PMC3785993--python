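"""Shared test helpers: tiny ad-hoc schemas, instance builders, and
independent oracles written straight from the defining formulas."""

from __future__ import annotations

import math

import numpy as np

from frailtymap import (FrailtySchema, PatientInstance, PatientStack,
                        VariableSpec, VariableValue, WeightProfile)


def mini_schema(*specs: tuple) -> FrailtySchema:
    """Build a small schema from (name, kind[, unit/categories]) tuples."""
    variables = []
    for item in specs:
        name, kind = item[0], item[1]
        if kind == "quantitative":
            unit = item[2] if len(item) > 2 else "u"
            variables.append(VariableSpec(name, "nutritional", kind, unit=unit))
        elif kind == "qualitative":
            cats = item[2] if len(item) > 2 else ("a", "b", "c")
            variables.append(VariableSpec(name, "functional", kind,
                                          categories=tuple(cats)))
        else:
            variables.append(VariableSpec(name, "geriatric_syndromes", kind))
    return FrailtySchema(tuple(variables))


def make_instance(iid: int, values: dict, iteration: int = 1, sex: str = "M",
                  age: float = 80.0, patient_id: str | None = None,
                  ) -> PatientInstance:
    """Instance from a plain value dict; None marks a missing variable."""
    vv = {}
    for name, value in values.items():
        if value is None:
            continue
        if value == "KEPT":
            vv[name] = VariableValue.kept()
        else:
            vv[name] = VariableValue.present(value)
    return PatientInstance(patient_id=patient_id or f"P{iid}", instance_id=iid,
                           iteration=iteration, sex=sex, age=age, values=vv)


def make_stack(schema: FrailtySchema, *instances: PatientInstance) -> PatientStack:
    return PatientStack(schema, tuple(instances))


def random_mixed_stack(rng: np.random.Generator, n_instances: int,
                       n_variables: int, missing_rate: float = 0.2,
                       ) -> PatientStack:
    """A random stack over a random mixed-type schema, for oracle checks."""
    kinds = rng.choice(["quantitative", "qualitative", "binary"],
                       size=n_variables)
    specs = []
    for k, kind in enumerate(kinds):
        specs.append((f"v{k}", str(kind)))
    schema = mini_schema(*specs)
    instances = []
    for i in range(n_instances):
        values = {}
        for spec in schema:
            if rng.random() < missing_rate:
                continue
            if spec.kind == "quantitative":
                values[spec.name] = float(rng.uniform(-5, 5))
            elif spec.kind == "qualitative":
                values[spec.name] = str(rng.choice(spec.categories))
            else:
                values[spec.name] = bool(rng.random() < 0.5)
        instances.append(make_instance(i + 1, values))
    return make_stack(schema, *instances)


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_gower(inst_i: PatientInstance, inst_j: PatientInstance,
                      schema: FrailtySchema, weights: WeightProfile,
                      ranges: dict[str, float],
                      binary_mode: str = "symmetric"):
    """Direct term-by-term evaluation of the weighted Gower sum.

    Returns (coefficient, effective_weight, terms) where terms is the
    list of (name, w, s, delta) actually entering the sums, or None
    when no variable is comparable.
    """
    terms = []
    for spec in schema:
        w = weights.get(spec.name)
        if w == 0.0:
            continue
        a = inst_i.values.get(spec.name)
        b = inst_j.values.get(spec.name)
        pa = a is not None and a.state == "present"
        pb = b is not None and b.state == "present"
        if not (pa and pb):
            continue
        if spec.kind == "quantitative":
            r = ranges.get(spec.name, 0.0)
            s = 1.0 if r == 0 else 1.0 - abs(float(a.value) - float(b.value)) / r
            delta = 1
        elif spec.kind == "qualitative":
            s, delta = (1.0 if a.value == b.value else 0.0), 1
        else:
            va, vb = bool(a.value), bool(b.value)
            if binary_mode == "asymmetric" and not va and not vb:
                continue
            if binary_mode == "asymmetric":
                s, delta = (1.0 if va and vb else 0.0), 1
            else:
                s, delta = (1.0 if va == vb else 0.0), 1
        terms.append((spec.name, w, s, delta))
    den = sum(w for _, w, _, _ in terms)
    if den == 0.0:
        return None
    num = sum(w * s for _, w, s, _ in terms)
    return num / den, den, terms


def two_pass_stats(values) -> dict[str, float]:
    """Loop-based reference statistics (no numpy reductions)."""
    n = len(values)
    total = 0.0
    for v in values:
        total += v
    mean = total / n
    ss = 0.0
    abs_dev = 0.0
    lo = hi = values[0]
    for v in values:
        ss += (v - mean) ** 2
        abs_dev += abs(v - mean)
        lo = min(lo, v)
        hi = max(hi, v)
    variance = ss / (n - 1)
    sd = math.sqrt(variance)
    return {
        "mean": mean,
        "sd": sd,
        "variance": variance,
        "abs_mean_diff": abs_dev / n,
        "amplitude": hi - lo,
        "cv": (sd / abs(mean)) if mean != 0 else (0.0 if sd == 0 else float("nan")),
    }
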