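"""Synthetic trauma-cohort generator with planted, recoverable structure.

Emulates a longitudinal blunt-trauma cohort: integer MOF-score
trajectories over days 0-28 with a planted acute day (optionally a
multi-day plateau / unstable window), sparse expression sampling days,
clinical covariates, random gene sets, and a log-scale expression matrix
carrying additive sex-specific effects confined to designated gene sets
in designated temporal phases, plus Gaussian noise. Every planted
quantity is returned in a truth record so downstream stages can be
tested for exact recovery.

The defaults mirror the reference cohort scale where stated — 129
patients with roughly 36% female, draws near days 0, 1, 4, 7, 14, 21
and 28, ages 16-50 — with the expression dimension reduced to a few
thousand genes for tractable permutation testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from mofsync.genesets import GeneSet, GeneSetCollection
from mofsync.sync import AcuteWindow, PhaseLabel, assign_phase

_PHASE_VALUES = {p.value for p in PhaseLabel} - {PhaseLabel.UNMAPPED.value}


@dataclass(frozen=True)
class PlantedEffect:
    """A sex-specific additive expression effect in one gene set and phase.

    ``up_in_female`` raises member-gene expression of female samples in
    the phase by ``effect_size`` (log-intensity units, i.e. noise-SD
    units at the default noise); ``down_in_female`` raises male samples
    instead.
    """

    set_name: str
    phase: str
    direction: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.phase not in _PHASE_VALUES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.direction not in {"up_in_female", "down_in_female"}:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class MOFDrivenEffect:
    """An expression effect proportional to peak MOF severity, sex-blind.

    Adds ``slope * (peak_mof - cohort mean peak)`` to member genes of
    samples in the phase for every patient. Combined with a sex-biased
    severity distribution this creates a spurious sex association that
    severity matching should remove.
    """

    set_name: str
    phase: str
    slope: float

    def __post_init__(self) -> None:
        if self.phase not in _PHASE_VALUES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class SimulationConfig:
    n_patients: int = 129
    sex_ratio: float = 0.36  # fraction female
    age_range: tuple[int, int] = (16, 50)
    n_genes: int = 2000
    n_gene_sets: int = 100
    set_size_range: tuple[int, int] = (5, 50)
    planted_effects: Sequence[PlantedEffect] = ()
    mof_driven_effects: Sequence[MOFDrivenEffect] = ()
    noise_sd: float = 1.0
    acute_day_range: tuple[int, int] = (2, 7)
    plateau_prob: float = 0.3
    plateau_span_range: tuple[int, int] = (2, 3)
    baseline_mof: int = 2
    peak_mof_range: tuple[int, int] = (6, 12)
    #: Extra peak MOF added to male patients (severity confounding).
    male_mof_shift: int = 0
    sampling_days: tuple[int, ...] = (0, 1, 4, 7, 14, 21, 28)
    sample_day_jitter: int = 0
    #: Fractions of patients planted to violate each inclusion filter.
    age_violation_prob: float = 0.0
    low_mof_prob: float = 0.0
    long_span_prob: float = 0.0
    #: Fraction of genes annotated on a sex chromosome (filtered downstream).
    frac_sex_chrom_genes: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("set sizes must lie in [1, n_genes]")
        lo, hi = self.acute_day_range
        if not 0 <= lo <= hi <= 28:
            raise ValueError("acute_day_range must lie within 0..28")
        if self.plateau_span_range[0] < 1:
            raise ValueError("plateau span must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PatientTruth:
    acute_day: int
    span: int
    peak_mof: int
    sex: str
    age: int
    violation: str  # none | age | max_mof | unstable_span


@dataclass
class SyntheticTruth:
    planted_effects: list[PlantedEffect]
    mof_driven_effects: list[MOFDrivenEffect]
    patients: dict[str, PatientTruth] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    trajectory_table: pd.DataFrame
    expression: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_sets: GeneSetCollection
    annotation: pd.DataFrame
    truth: SyntheticTruth


def simulate_mof_trajectory(
    patient_id: str,
    acute_day: int,
    span: int,
    baseline: int,
    peak: int,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Integer daily MOF scores for days 0-28 with a planted maximal window.

    The envelope rises piecewise-linearly from ``baseline`` at day 0 to
    ``peak`` over the window ``[acute_day, acute_day + span - 1]`` and
    falls back to ``baseline`` by day 28. Outside the window, +-1 jitter
    is added but clipped to stay strictly below the peak, so the first
    and last day attaining the maximum are exactly the planted window
    bounds. Interior plateau days may dip one point below the peak
    ("days of lower scores in between").
    """
    first, last = acute_day, acute_day + span - 1
    if last > 28:
        raise ValueError(f"plateau window {first}..{last} extends beyond day 28")
    if peak <= baseline:
        raise ValueError("peak must exceed baseline")
    scores: dict[int, int] = {}
    for day in range(29):
        if day < first:
            frac = day / first if first > 0 else 1.0
            env = baseline + (peak - baseline) * frac
        elif day > last:
            frac = (28 - day) / (28 - last) if last < 28 else 1.0
            env = baseline + (peak - baseline) * frac
        else:
            env = peak
        score = int(round(env))
        if first <= day <= last:
            if span >= 3 and first < day < last and rng.random() < 0.5:
                score = peak - 1
            else:
                score = peak
        else:
            score += int(rng.integers(-1, 2))
            score = max(0, min(score, peak - 1))
        scores[day] = score
    # plateau endpoints always attain the maximum
    scores[first] = peak
    scores[last] = peak
    return scores


def generate_gene_sets(
    n_sets: int,
    size_range: tuple[int, int],
    gene_universe: Sequence[str],
    rng: np.random.Generator,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Random gene sets sampled without replacement from the universe."""
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(gene_universe):
        raise ValueError("set sizes must lie in [1, |universe|]")
    universe = np.asarray(list(gene_universe))
    collection = GeneSetCollection()
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        collection.add(
            GeneSet(f"{prefix}_{i:04d}", "synthetic gene set", tuple(sorted(genes)))
        )
    return collection


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from one seeded configuration.

    One expression sample is emitted per patient per scheduled draw day.
    A sample's expression is Gaussian noise plus, for member genes of a
    planted set, the planted effect whenever the patient's sex and the
    sample's phase (under the planted acute window) match the plant.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_ids = [f"P{i:04d}" for i in range(n)]

    n_female = int(round(config.sex_ratio * n))
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sexes)

    # gene universe and annotation; planted sets are drawn from the
    # autosomal sub-universe so they survive the autosomal filter
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_sex_genes = int(round(config.frac_sex_chrom_genes * config.n_genes))
    chroms = [str(int(c)) for c in rng.integers(1, 23, size=config.n_genes)]
    if n_sex_genes:
        sex_idx = rng.choice(config.n_genes, size=n_sex_genes, replace=False)
        for i in sex_idx:
            chroms[i] = "X" if rng.random() < 0.5 else "Y"
    annotation = pd.DataFrame({"gene_id": genes, "chromosome": chroms})
    autosomal = [g for g, c in zip(genes, chroms) if c not in ("X", "Y")]

    gene_sets = generate_gene_sets(
        config.n_gene_sets, config.set_size_range, autosomal, rng
    )
    for eff in list(config.planted_effects) + list(config.mof_driven_effects):
        if eff.set_name not in gene_sets:
            raise ValueError(f"planted set {eff.set_name!r} not in the collection")

    truth = SyntheticTruth(
        planted_effects=list(config.planted_effects),
        mof_driven_effects=list(config.mof_driven_effects),
    )

    clinical_rows = []
    traj_rows = []
    windows: dict[str, AcuteWindow] = {}
    peaks: dict[str, int] = {}
    lo_age, hi_age = config.age_range
    for pid, sex in zip(patient_ids, sexes):
        violation = "none"
        age = int(rng.integers(lo_age, hi_age + 1))
        if rng.random() < config.age_violation_prob:
            violation = "age"
            age = int(rng.integers(51, 81)) if rng.random() < 0.5 else int(
                rng.integers(5, 16)
            )

        acute_day = int(rng.integers(config.acute_day_range[0], config.acute_day_range[1] + 1))
        if rng.random() < config.plateau_prob:
            span = int(
                rng.integers(config.plateau_span_range[0], config.plateau_span_range[1] + 1)
            )
        else:
            span = 1
        peak = int(rng.integers(config.peak_mof_range[0], config.peak_mof_range[1] + 1))
        if sex == "male":
            peak += config.male_mof_shift
        baseline = config.baseline_mof

        if violation == "none" and rng.random() < config.low_mof_prob:
            violation = "max_mof"
            baseline, peak, span = 0, 1, 1
        if violation == "none" and rng.random() < config.long_span_prob:
            violation = "unstable_span"
            span = int(rng.integers(4, 7))

        span = min(span, 29 - acute_day)
        scores = simulate_mof_trajectory(pid, acute_day, span, baseline, peak, rng)
        windows[pid] = AcuteWindow(pid, acute_day, acute_day + span - 1, peak)
        peaks[pid] = peak
        for day, score in scores.items():
            traj_rows.append((pid, day, score))

        clinical_rows.append(
            (pid, sex, age, int(rng.integers(2, 6)), f"B{int(rng.integers(0, 4))}")
        )
        truth.patients[pid] = PatientTruth(acute_day, span, peak, sex, age, violation)

    clinical = pd.DataFrame(
        clinical_rows, columns=["patient_id", "sex", "age", "ais_baseline", "batch"]
    )
    trajectory_table = pd.DataFrame(
        traj_rows, columns=["patient_id", "day", "mof_score"]
    )

    # sampling schedule and expression
    meta_rows = []
    for pid in patient_ids:
        for day in config.sampling_days:
            if config.sample_day_jitter:
                day = day + int(
                    rng.integers(-config.sample_day_jitter, config.sample_day_jitter + 1)
                )
                day = max(0, min(28, day))
            meta_rows.append((f"{pid}_d{day:02d}", pid, int(day)))
    sample_meta = pd.DataFrame(meta_rows, columns=["sample_id", "patient_id", "day"])

    n_samples = len(sample_meta)
    expr = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    sex_of = dict(zip(patient_ids, sexes))
    mean_peak = float(np.mean(list(peaks.values())))

    sample_phase = {}
    for j, rec in enumerate(sample_meta.itertuples(index=False)):
        _, phase = assign_phase(int(rec.day), windows[rec.patient_id])
        sample_phase[j] = phase.value

    for eff in config.planted_effects:
        member_idx = [gene_pos[g] for g in gene_sets[eff.set_name].genes]
        target_sex = "female" if eff.direction == "up_in_female" else "male"
        for j, rec in enumerate(sample_meta.itertuples(index=False)):
            if sample_phase[j] == eff.phase and sex_of[rec.patient_id] == target_sex:
                expr[member_idx, j] += eff.effect_size

    for eff in config.mof_driven_effects:
        member_idx = [gene_pos[g] for g in gene_sets[eff.set_name].genes]
        for j, rec in enumerate(sample_meta.itertuples(index=False)):
            if sample_phase[j] == eff.phase:
                expr[member_idx, j] += eff.slope * (peaks[rec.patient_id] - mean_peak)

    expression = pd.DataFrame(
        expr, index=pd.Index(genes, name="gene"), columns=sample_meta["sample_id"]
    )
    return SyntheticCohort(
        clinical=clinical,
        trajectory_table=trajectory_table,
        expression=expression,
        sample_meta=sample_meta,
        gene_sets=gene_sets,
        annotation=annotation,
        truth=truth,
    )


def simulate_detection_stub(
    n_probes: int, n_samples: int, rng: np.random.Generator, detected_frac: float = 0.95
) -> np.ndarray:
    """Uniform detection-p stub: a ``detected_frac`` fraction of entries
    drawn from U(0, 0.05), the rest from U(0.05, 1)."""
    low = rng.uniform(0.0, 0.05, size=(n_probes, n_samples))
    high = rng.uniform(0.05, 1.0, size=(n_probes, n_samples))
    mask = rng.random((n_probes, n_samples)) < detected_frac
    return np.where(mask, low, high)
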