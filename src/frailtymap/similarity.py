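"""Weighted Gower similarity for mixed-type patient instances.

The Gower general similarity coefficient compares two records i, j over
K variables of mixed type:

    S_ij = sum_k w_k * delta_ijk * s_ijk / sum_k w_k * delta_ijk

where s_ijk in [0, 1] scores variable k, delta_ijk indicates whether
the pair is comparable on k (both values present, modulo the binary
mode), and w_k is the clinician-chosen importance weight.  Per-variable
scores:

* quantitative: s = 1 - |a - b| / R_k with R_k the variable's value
  range over the study population; a degenerate range scores 1;
* qualitative: s = 1 iff the categories match;
* binary, symmetric mode: s = 1 iff the flags match (two patients both
  without a syndrome count as alike);
* binary, asymmetric mode (Gower's dichotomous rule): joint absence is
  not comparable (delta = 0); s = 1 only for joint presence.

Missing values on either side give delta = 0 and drop out of both
sums.  A pair with no comparable weighted variable has no defined
similarity and raises :class:`IncomparablePairError` rather than
silently scoring 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IncomparablePairError
from .patient import PatientInstance, PatientStack, VariableValue, WeightProfile
from .schema import VariableSpec
from .units import convert

BINARY_MODES = ("symmetric", "asymmetric")


@dataclass(frozen=True)
class SimilarityConfig:
    """Dispatch rules for the pairwise comparison.

    ``binary_mode`` selects symmetric matching (default: co-absence of
    a syndrome counts as agreement) or Gower's asymmetric dichotomous
    rule.  Quantitative ranges always come from the current stack
    (``range_policy = "stack_range"``); a zero range scores 1.  Ties in
    rankings break by ascending instance id.
    """

    binary_mode: str = "symmetric"
    range_policy: str = "stack_range"

    def __post_init__(self) -> None:
        if self.binary_mode not in BINARY_MODES:
            raise ValueError(f"binary_mode must be one of {BINARY_MODES}")
        if self.range_policy != "stack_range":
            raise ValueError("only the stack_range policy is supported")


@dataclass(frozen=True)
class PairSimilarity:
    """Gower coefficient for one unordered instance pair."""

    i: int
    j: int
    coefficient: float
    effective_weight: float  # sum_k w_k * delta_ijk


def normalize_units(stack: PatientStack) -> PatientStack:
    """Express every quantitative value in its variable's canonical unit."""
    instances = []
    for inst in stack.instances:
        updates = {}
        for name, vv in inst.values.items():
            if not vv.is_present or vv.unit is None:
                continue
            spec = stack.schema[name]
            converted = convert(float(vv.value), vv.unit, spec.unit, name)
            updates[name] = VariableValue.present(converted)
        instances.append(inst.with_values(updates) if updates else inst)
    return stack.replace_instances(instances)


def quantitative_ranges(stack: PatientStack) -> dict[str, float]:
    """Per-variable value range R_k over the stack's present values."""
    ranges: dict[str, float] = {}
    for spec in stack.schema:
        if spec.kind != "quantitative":
            continue
        observed = [float(inst.value(spec.name).value)
                    for inst in stack.instances
                    if inst.value(spec.name).is_present]
        ranges[spec.name] = (max(observed) - min(observed)) if observed else 0.0
    return ranges


def variable_similarity(a: VariableValue, b: VariableValue, spec: VariableSpec,
                        value_range: float = 0.0,
                        config: SimilarityConfig = SimilarityConfig(),
                        ) -> tuple[float, int]:
    """Score one variable for one pair: returns ``(s_ijk, delta_ijk)``."""
    if not (a.is_present and b.is_present):
        return 0.0, 0
    if spec.kind == "quantitative":
        if value_range < 0:
            raise AssertionError("negative quantitative range")
        if value_range == 0:
            return 1.0, 1
        s = 1.0 - abs(float(a.value) - float(b.value)) / value_range
        return min(max(s, 0.0), 1.0), 1
    if spec.kind == "qualitative":
        return (1.0 if a.value == b.value else 0.0), 1
    # binary
    if config.binary_mode == "symmetric":
        return (1.0 if bool(a.value) == bool(b.value) else 0.0), 1
    if not (bool(a.value) or bool(b.value)):  # joint absence: not comparable
        return 0.0, 0
    return (1.0 if bool(a.value) and bool(b.value) else 0.0), 1


def gower_similarity(i: PatientInstance | int, j: PatientInstance | int,
                     stack: PatientStack, weights: WeightProfile,
                     config: SimilarityConfig = SimilarityConfig(),
                     ranges: dict[str, float] | None = None) -> PairSimilarity:
    """Weighted Gower coefficient between two instances of a stack.

    The stack must be unit-normalized and kept-resolved.  ``ranges``
    may be supplied to avoid recomputing the per-variable stack ranges
    in a loop over pairs.
    """
    inst_i = stack.get(i) if isinstance(i, int) else i
    inst_j = stack.get(j) if isinstance(j, int) else j
    if ranges is None:
        ranges = quantitative_ranges(stack)

    numerator = 0.0
    denominator = 0.0
    for spec in stack.schema:
        w = weights.get(spec.name)
        if w == 0.0:
            continue
        s, delta = variable_similarity(
            inst_i.value(spec.name), inst_j.value(spec.name), spec,
            ranges.get(spec.name, 0.0), config)
        if delta:
            numerator += w * s
            denominator += w
    if denominator == 0.0:
        raise IncomparablePairError(
            f"instances {inst_i.instance_id} and {inst_j.instance_id} share "
            "no weighted comparable variable")
    coefficient = numerator / denominator
    return PairSimilarity(inst_i.instance_id, inst_j.instance_id,
                          min(max(coefficient, 0.0), 1.0), denominator)


def similarity_matrix(stack: PatientStack, weights: WeightProfile,
                      config: SimilarityConfig = SimilarityConfig(),
                      ) -> pd.DataFrame:
    """Symmetric instance-by-instance Gower coefficient matrix.

    Incomparable pairs are flagged as NaN.  The diagonal is 1.
    """
    if len(stack) < 2:
        raise ValueError("similarity matrix needs at least 2 instances")
    ids = [inst.instance_id for inst in stack.instances]
    ranges = quantitative_ranges(stack)
    matrix = np.ones((len(ids), len(ids)))
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            try:
                pair = gower_similarity(stack.instances[a], stack.instances[b],
                                        stack, weights, config, ranges)
                matrix[a, b] = matrix[b, a] = pair.coefficient
            except IncomparablePairError:
                matrix[a, b] = matrix[b, a] = np.nan
    return pd.DataFrame(matrix, index=ids, columns=ids)


def export_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index_label="instance_id", encoding="utf-8")


def rank_neighbors(target: int, stack: PatientStack, weights: WeightProfile,
                   config: SimilarityConfig = SimilarityConfig(),
                   exclude: frozenset[int] | set[int] = frozenset(),
                   ranges: dict[str, float] | None = None,
                   ) -> list[PairSimilarity]:
    """All candidates ranked by similarity to ``target``, best first.

    Candidates are every stack instance except the target and the
    excluded ids; incomparable candidates are dropped.  Ties break by
    ascending instance id.
    """
    inst_t = stack.get(target)
    if ranges is None:
        ranges = quantitative_ranges(stack)
    pairs = []
    for inst in stack.instances:
        if inst.instance_id == target or inst.instance_id in exclude:
            continue
        try:
            pairs.append(gower_similarity(inst_t, inst, stack, weights,
                                          config, ranges))
        except IncomparablePairError:
            continue
    pairs.sort(key=lambda p: (-p.coefficient, p.j))
    return pairs
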