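"""Synthetic study data.

Two generators stand in for the unpublished clinical data:

* :func:`generate_cohort` builds a nursing-home cohort with the study
  demographics — 20 elders, 10 men (age 81.80, SD 4.74) and 10 women
  (age 85.43, SD 3.22), assessed up to three times.  Ages are
  moment-matched: a seeded normal draw is affinely rescaled so the
  *sample* mean and SD equal the spec exactly, making the printed
  demographics deterministic targets rather than expectations.
* :func:`table_pattern_fixture` reproduces the study's recorded
  missingness structure: for every patient, iteration and variable
  group it realises exactly the transcribed number of present values,
  the kept ("k") group markers of later iterations, and the two
  patients without a third assessment.  Values are synthetic (seeded
  uniform draws within plausible clinical ranges); only structure,
  counts and demographics are emulated.

Gait recordings are simulated as per-axis sinusoids at a step
frequency plus seeded Gaussian noise; dispersion variables of
generated cohorts are computed from such signals rather than drawn
independently, so they satisfy the same internal relationships as
measured ones (variance = sd², etc.).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accelerometry import GaitRecording, attach_to_instance, compute_dispersion_measures
from .errors import FrailtyMapError
from .patient import PatientInstance, PatientStack, VariableValue
from .schema import DISPERSION_VARIABLES, FrailtySchema, canonical_schema

#: plausible value ranges for the non-dispersion quantitative variables
SIMULATION_RANGES: dict[str, tuple[float, float]] = {
    "size": (145.0, 178.0),
    "weight": (45.0, 85.0),
    "body_mass_index": (19.0, 33.0),
    "body_mass": (45.0, 85.0),
    "lean_mass": (30.0, 55.0),
    "fat_mass": (18.0, 42.0),
    "total_water": (25.0, 40.0),
    "tinetti_score": (10.0, 28.0),
    "barthel_index": (20.0, 100.0),
    "lawton_brody_score": (0.0, 8.0),
    "get_up_and_go_score": (10.0, 30.0),
    "total_protein": (5.5, 7.5),
    "serum_albumin": (3.0, 4.5),
    "cholesterol": (130.0, 240.0),
    "triglycerides": (70.0, 200.0),
    "blood_iron": (40.0, 150.0),
    "ferritin": (20.0, 300.0),
    "vitamin_b12": (200.0, 900.0),
    "serum_folic_acid": (3.0, 17.0),
    "serum_transferrin": (200.0, 360.0),
    "leukocytes": (4.0, 11.0),
    "lymphocytes": (1.0, 4.0),
    "hemoglobin": (11.0, 16.0),
    "calcium": (8.5, 10.5),
    "mini_mental_status": (10.0, 30.0),
    "cruz_roja_mental_scale": (0.0, 5.0),
}

_SYNDROME_PREVALENCE = 0.35  # geriatric syndromes in institutionalised elders


@dataclass(frozen=True)
class CohortSpec:
    """Demographics and structure of a generated cohort.

    ``quantitative_stage_shifts`` adds a known per-iteration offset to
    every anthropometric and nutritional quantitative value (relative
    to the patient's baseline draw); it is the handle used to plant a
    recoverable longitudinal trend.
    """

    n_male: int = 10
    n_female: int = 10
    male_age_mean: float = 81.80
    male_age_sd: float = 4.74
    female_age_mean: float = 85.43
    female_age_sd: float = 3.22
    iterations: int = 3
    seed: int = 0
    quantitative_stage_shifts: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise FrailtyMapError("cohort counts must be non-negative")
        if self.male_age_sd < 0 or self.female_age_sd < 0:
            raise FrailtyMapError("age SDs must be non-negative")
        if self.iterations < 1:
            raise FrailtyMapError("iterations must be >= 1")
        if (self.n_male < 2 and self.male_age_sd > 0) or \
           (self.n_female < 2 and self.female_age_sd > 0):
            raise FrailtyMapError(
                "a positive age SD needs at least 2 patients of that sex")


def _moment_matched_ages(n: int, mean: float, sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Seeded draw rescaled so the sample mean and SD (n-1) are exact."""
    if n == 0:
        return np.empty(0)
    if n == 1 or sd == 0.0:
        return np.full(n, mean)
    draw = rng.normal(size=n)
    z = (draw - draw.mean()) / draw.std(ddof=1)
    return mean + sd * z


def simulate_gait_signal(duration: float = 10.0, rate: float = 50.0,
                         step_frequency: float = 1.7, noise_sd: float = 0.3,
                         seed: int = 0,
                         amplitudes: tuple[float, float, float] = (1.0, 0.6, 0.4),
                         offsets: tuple[float, float, float] = (0.0, 0.0, 9.81),
                         ) -> GaitRecording:
    """Sinusoidal walking signal per axis plus seeded Gaussian noise."""
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("duration * rate must give at least 2 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    phases = (0.0, np.pi / 3.0, np.pi / 2.0)
    axes = []
    for amp, offset, phase in zip(amplitudes, offsets, phases):
        axis = offset + amp * np.sin(2.0 * np.pi * step_frequency * t + phase)
        if noise_sd > 0:
            axis = axis + rng.normal(0.0, noise_sd, size=n)
        axes.append(axis)
    return GaitRecording(t=t, ax=axes[0], ay=axes[1], az=axes[2],
                         sampling_rate=rate)


def _draw_value(spec, rng: np.random.Generator) -> VariableValue:
    if spec.kind == "binary":
        return VariableValue.present(bool(rng.random() < _SYNDROME_PREVALENCE))
    if spec.kind == "qualitative":
        return VariableValue.present(str(rng.choice(spec.categories)))
    lo, hi = SIMULATION_RANGES.get(spec.name, (0.0, 1.0))
    return VariableValue.present(float(rng.uniform(lo, hi)))


def _baseline_values(schema: FrailtySchema, sex: str, age: float,
                     rng: np.random.Generator) -> dict[str, VariableValue]:
    values: dict[str, VariableValue] = {}
    for spec in schema:
        if spec.group == "dispersion":
            continue
        if spec.name == "gender":
            values[spec.name] = VariableValue.present(sex)
        elif spec.name == "age":
            values[spec.name] = VariableValue.present(age)
        else:
            values[spec.name] = _draw_value(spec, rng)
    return values


_SHIFTED_GROUPS = ("anthropometric", "nutritional")


def _apply_shift(schema: FrailtySchema, values: dict[str, VariableValue],
                 shift: float) -> dict[str, VariableValue]:
    if shift == 0.0:
        return dict(values)
    out = dict(values)
    for spec in schema:
        if spec.group in _SHIFTED_GROUPS and spec.kind == "quantitative" \
                and spec.name != "age" and spec.name in out:
            out[spec.name] = VariableValue.present(
                float(out[spec.name].value) + shift)
    return out


def generate_cohort(spec: CohortSpec = CohortSpec()) -> PatientStack:
    """Generate a fully observed synthetic cohort with exact demographics."""
    schema = canonical_schema()
    rng = np.random.default_rng(spec.seed)
    sexes = ["M"] * spec.n_male + ["F"] * spec.n_female
    male_ages = _moment_matched_ages(spec.n_male, spec.male_age_mean,
                                     spec.male_age_sd, rng)
    female_ages = _moment_matched_ages(spec.n_female, spec.female_age_mean,
                                       spec.female_age_sd, rng)
    ages = np.concatenate([male_ages, female_ages])
    n = len(sexes)

    shifts = spec.quantitative_stage_shifts or (0.0,) * spec.iterations
    if len(shifts) != spec.iterations:
        raise FrailtyMapError("one stage shift per iteration is required")

    baselines = [_baseline_values(schema, sexes[p], float(ages[p]), rng)
                 for p in range(n)]
    step_freqs = rng.uniform(1.4, 2.0, size=n)

    instances = []
    instance_id = 1
    for iteration in range(1, spec.iterations + 1):
        for p in range(n):
            values = _apply_shift(schema, baselines[p], shifts[iteration - 1])
            inst = PatientInstance(
                patient_id=f"P{p + 1:02d}", instance_id=instance_id,
                iteration=iteration, sex=sexes[p], age=float(ages[p]),
                values=values)
            gait_seed = int(rng.integers(0, 2 ** 31 - 1))
            signal = simulate_gait_signal(duration=8.0, rate=50.0,
                                          step_frequency=float(step_freqs[p]),
                                          noise_sd=0.3, seed=gait_seed)
            inst = attach_to_instance(inst, compute_dispersion_measures(signal))
            instances.append(inst)
            instance_id += 1
    return PatientStack(schema, tuple(instances))


# ---------------------------------------------------------------------------
# The transcribed missingness pattern of the 20-patient study stack


@dataclass(frozen=True)
class MissingnessPattern:
    """Per patient x iteration x group: present-value counts or markers.

    A cell is an ``int`` (number of present values), ``"k"`` (whole
    group kept from an earlier assessment) or ``None`` (the patient has
    no instance at that iteration).
    """

    sex: str
    instance_ids: tuple[int, int | None, int | None]
    cells: dict[str, tuple[object, object, object]] = field(default_factory=dict)


_GROUP_ORDER = ("anthropometric", "functional", "nutritional", "cognitive",
                "geriatric_syndromes", "dispersion")

# patient -> (sex, it3 id, anth, func, nutr, cog, ger, disp); "k" = kept group,
# None = no instance at that iteration
_RAW_PATTERN: dict[int, tuple] = {
    1:  ("M", 47, (9, 8, 8), (4, "k", 0), (11, 9, 8),  (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    2:  ("M", 48, (9, 8, 8), (5, "k", 0), (11, 8, 8),  (1, 0, 0), (11, "k", "k"), (17, 0, 20)),
    3:  ("M", 49, (9, 8, 8), (4, "k", 0), (0, 7, 0),   (0, 0, 0), (11, "k", "k"), (17, 0, 20)),
    4:  ("M", 50, (9, 8, 8), (5, "k", 0), (12, 8, 8),  (1, 0, 0), (11, "k", "k"), (17, 0, 20)),
    5:  ("M", 51, (8, 8, 8), (4, "k", 0), (11, 8, 9),  (0, 0, 0), (11, "k", "k"), (17, 0, 20)),
    6:  ("F", None, (9, 8, None), (4, "k", None), (11, 10, None),
         (1, 0, None), (11, "k", None), (17, 0, None)),
    7:  ("F", 52, (8, 8, 8), (5, "k", 0), (12, 7, 8),  (1, 0, 0), (11, "k", "k"), (17, 0, 20)),
    8:  ("F", 53, (8, 8, 8), (4, "k", 0), (12, 9, 8),  (1, 0, 0), (11, "k", "k"), (17, 0, 20)),
    9:  ("F", 54, (9, 8, 8), (4, "k", 0), (12, 8, 8),  (0, 0, 0), (11, "k", "k"), (17, 0, 20)),
    10: ("F", 55, (8, 8, 8), (5, "k", 0), (12, 8, 8),  (1, 0, 0), (11, "k", "k"), (17, 0, 20)),
    11: ("F", 56, (9, 8, 8), (4, "k", 0), (11, 10, 9), (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    12: ("F", 57, (9, 8, 8), (4, "k", 0), (11, 10, 9), (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    13: ("F", 58, (9, 8, 8), (4, "k", 0), (11, 9, 9),  (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    14: ("F", None, (2, 8, None), (4, "k", None), (10, 10, None),
         (2, 0, None), (11, "k", None), (17, 0, None)),
    15: ("F", 59, (9, 8, 8), (4, "k", 0), (11, 12, 10), (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    16: ("M", 60, (9, 8, 8), (4, "k", 0), (12, 10, 10), (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    17: ("M", 61, (9, 8, 8), (4, "k", 0), (12, 10, 9), (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    18: ("M", 62, (9, 8, 8), (4, "k", 0), (12, 9, 10), (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    19: ("M", 63, (9, 8, 8), (4, "k", 0), (12, 9, 9),  (2, 0, 0), (11, "k", "k"), (17, 0, 20)),
    20: ("M", 64, (9, 8, 8), (4, "k", 0), (11, 9, 9),  (1, 0, 0), (11, "k", "k"), (17, 0, 20)),
}

#: seed fixing the packaged fixture's synthetic values
PACKAGED_FIXTURE_SEED = 12345


def packaged_fixture_stack() -> PatientStack:
    """Load the packaged copy of the study-pattern stack CSV.

    Identical to :func:`table_pattern_fixture` under the packaged
    seed; shipped as CSV so the file format doubles as documentation.
    """
    from importlib import resources

    from .patient import load_stack

    data = resources.files("frailtymap") / "data"
    with resources.as_file(data / "table_fixture.csv") as path:
        return load_stack(path, canonical_schema())


def table_pattern() -> dict[int, MissingnessPattern]:
    """The study stack's missingness structure, patient by patient."""
    out = {}
    for patient, row in _RAW_PATTERN.items():
        sex, it3_id = row[0], row[1]
        cells = dict(zip(_GROUP_ORDER, row[2:]))
        out[patient] = MissingnessPattern(
            sex=sex, instance_ids=(patient, 21 + patient, it3_id), cells=cells)
    return out


def table_pattern_fixture(seed: int = PACKAGED_FIXTURE_SEED) -> PatientStack:
    """The 20-patient, 3-iteration stack realising the study's structure.

    Present/kept/missing states follow the transcribed per-group
    counts exactly (within a group, the first *n* variables in schema
    order are the present ones); synthetic values are fixed by the
    packaged seed and constant across a patient's iterations.
    """
    schema = canonical_schema()
    pattern = table_pattern()
    rng = np.random.default_rng(seed)

    sexes = [pattern[p].sex for p in sorted(pattern)]
    n_male = sexes.count("M")
    male_ages = iter(_moment_matched_ages(n_male, 81.80, 4.74, rng))
    female_ages = iter(_moment_matched_ages(len(sexes) - n_male, 85.43, 3.22, rng))

    instances = []
    for patient in sorted(pattern):
        pat = pattern[patient]
        age = float(next(male_ages) if pat.sex == "M" else next(female_ages))
        baseline = _baseline_values(schema, pat.sex, age, rng)
        # dispersion baseline from a simulated gait signal
        gait = simulate_gait_signal(duration=8.0, rate=50.0,
                                    step_frequency=float(rng.uniform(1.4, 2.0)),
                                    noise_sd=0.3,
                                    seed=int(rng.integers(0, 2 ** 31 - 1)))
        dm = compute_dispersion_measures(gait)
        for name in DISPERSION_VARIABLES:
            baseline[name] = VariableValue.present(float(dm.values[name]))

        for it_index, instance_id in enumerate(pat.instance_ids):
            if instance_id is None:
                continue
            values: dict[str, VariableValue] = {}
            for group in _GROUP_ORDER:
                members = schema.group_members(group)
                cell = pat.cells[group][it_index]
                if cell == "k":
                    for spec in members:
                        values[spec.name] = VariableValue.kept()
                else:
                    for spec in members[:int(cell)]:
                        values[spec.name] = baseline[spec.name]
            instances.append(PatientInstance(
                patient_id=f"P{patient:02d}", instance_id=instance_id,
                iteration=it_index + 1, sex=pat.sex, age=age, values=values))
    return PatientStack(schema, tuple(instances))
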