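"""Longitudinal nutritional evolution analysis.

A cohort assessed three times — initially, after a period of
spontaneous evolution, and after protein supplementation — is
summarised per sex and stage as arithmetic means of nine nutritional
and anthropometric variables: weight, body-mass index, fat mass, lean
mass, total water, total protein, hemoglobin, serum albumin and
lymphocytes.  These nine carry weight 1 in the similarity profile and
everything else weight 0, so a frailty comparison under the profile is
driven purely by nutrition.

A mean is only reported when enough patients contribute a value
(``min_n``, default 3); otherwise the cell carries a no-data marker,
mirroring how sparse laboratory panels are reported.  Stage-to-stage
deltas are signed differences of the means and are classified as
declined / maintained / improved by sign (with an optional dead band
``epsilon``); clinical direction semantics (whether a lower weight is
good or bad) are deliberately left to the reader.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

from .errors import SchemaError
from .patient import PatientStack, WeightProfile
from .schema import FrailtySchema

#: the nine nutrition-focused variables of the longitudinal analysis
NUTRITIONAL_PROFILE_VARIABLES = (
    "weight",
    "body_mass_index",
    "fat_mass",
    "lean_mass",
    "total_water",
    "total_protein",
    "hemoglobin",
    "serum_albumin",
    "lymphocytes",
)

STAGES = ("initial", "spontaneous", "post_supplementation")
STAGE_ITERATION = {"initial": 1, "spontaneous": 2, "post_supplementation": 3}

DECLINED = "declined"
MAINTAINED = "maintained"
IMPROVED = "improved"


def nutritional_weight_profile(schema: FrailtySchema) -> WeightProfile:
    """Weight the nine nutrition variables 1 and everything else 0."""
    missing = [n for n in NUTRITIONAL_PROFILE_VARIABLES if n not in schema]
    if missing:
        raise SchemaError(f"schema lacks profile variables {missing}")
    weights = {name: 0.0 for name in schema.names}
    for name in NUTRITIONAL_PROFILE_VARIABLES:
        weights[name] = 1.0
    return WeightProfile(weights)


@dataclass(frozen=True)
class StageSummary:
    """Per-variable means for one sex at one stage.

    ``means[name]`` is None when fewer than ``min_n`` patients
    contributed a value (the no-data marker); ``counts[name]`` always
    holds the contributing count.
    """

    stage: str
    sex: str
    means: dict[str, float | None] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    min_n: int = 3


def stage_means(stack: PatientStack, profile: WeightProfile, sex: str,
                stage: str, min_n: int = 3) -> StageSummary:
    """Arithmetic means of the profile's variables for one sex and stage.

    The stack should be kept-resolved and unit-normalized; only present
    values contribute.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    iteration = STAGE_ITERATION[stage]
    selected = [name for name, w in profile.weights.items() if w > 0]
    # keep schema order for stable reporting
    selected = [name for name in stack.schema.names if name in selected]
    means: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for name in selected:
        observed = [float(inst.value(name).value)
                    for inst in stack.of_iteration(iteration)
                    if inst.sex == sex and inst.value(name).is_present]
        counts[name] = len(observed)
        means[name] = (sum(observed) / len(observed)
                       if len(observed) >= min_n else None)
    return StageSummary(stage=stage, sex=sex, means=means, counts=counts,
                        min_n=min_n)


@dataclass(frozen=True)
class StageDelta:
    """Signed per-variable differences between two stage summaries."""

    from_stage: str
    to_stage: str
    sex: str
    deltas: dict[str, float | None] = field(default_factory=dict)
    trends: dict[str, str | None] = field(default_factory=dict)


def stage_delta(s1: StageSummary, s2: StageSummary,
                epsilon: float = 0.0) -> StageDelta:
    """Per-variable change s2 − s1 with a sign-based trend label.

    A delta is undefined (None) wherever either side carries the
    no-data marker.  Trends: declined if delta < −epsilon, improved if
    delta > epsilon, maintained otherwise.
    """
    if s1.sex != s2.sex:
        raise ValueError("stage summaries compare only within one sex")
    if set(s1.means) != set(s2.means):
        raise ValueError("stage summaries must cover the same variables")
    deltas: dict[str, float | None] = {}
    trends: dict[str, str | None] = {}
    for name in s1.means:
        a, b = s1.means[name], s2.means[name]
        if a is None or b is None:
            deltas[name] = None
            trends[name] = None
            continue
        delta = b - a
        deltas[name] = delta
        if delta < -epsilon:
            trends[name] = DECLINED
        elif delta > epsilon:
            trends[name] = IMPROVED
        else:
            trends[name] = MAINTAINED
    return StageDelta(from_stage=s1.stage, to_stage=s2.stage, sex=s1.sex,
                      deltas=deltas, trends=trends)


@dataclass(frozen=True)
class EvolutionReport:
    """Stage x sex summaries plus consecutive-stage deltas."""

    summaries: tuple[StageSummary, ...]
    deltas: tuple[StageDelta, ...]


def analyze_evolution(stack: PatientStack, profile: WeightProfile,
                      stages: tuple[str, ...] = STAGES,
                      sexes: tuple[str, ...] = ("M", "F"),
                      min_n: int = 3, epsilon: float = 0.0) -> EvolutionReport:
    """Full longitudinal report: per-stage means and inter-stage deltas."""
    summaries = []
    deltas = []
    for sex in sexes:
        per_stage = [stage_means(stack, profile, sex, stage, min_n)
                     for stage in stages]
        summaries.extend(per_stage)
        for s1, s2 in zip(per_stage, per_stage[1:]):
            deltas.append(stage_delta(s1, s2, epsilon))
    return EvolutionReport(summaries=tuple(summaries), deltas=tuple(deltas))


NO_DATA = "no data"


def render_report(report: EvolutionReport, path: str | Path | None = None) -> str:
    """CSV table: one row per stage x sex, one column per variable,
    followed by the delta rows with their trend labels."""
    variables: list[str] = []
    for summary in report.summaries:
        for name in summary.means:
            if name not in variables:
                variables.append(name)
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(["row_type", "stage", "sex"] + variables)
    for s in report.summaries:
        writer.writerow(
            ["mean", s.stage, s.sex]
            + [NO_DATA if s.means.get(v) is None else f"{s.means[v]:.4f}"
               for v in variables])
    for d in report.deltas:
        writer.writerow(
            ["delta", f"{d.from_stage}->{d.to_stage}", d.sex]
            + ["" if d.deltas.get(v) is None else f"{d.deltas[v]:+.4f}"
               for v in variables])
        writer.writerow(
            ["trend", f"{d.from_stage}->{d.to_stage}", d.sex]
            + [d.trends.get(v) or "" for v in variables])
    text = buffer.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
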