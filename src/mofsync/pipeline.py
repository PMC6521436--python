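"""End-to-end pipeline driver.

Runs filter -> sync -> prep -> diffexp -> cluster -> stats on the
tabular inputs, writing every stage's outputs and a manifest (package
version, resolved configuration, seed, per-stage row counts) into one
run directory. Reruns with the same configuration and seed reproduce
the output tree byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import mofsync
from mofsync import io as mio
from mofsync.clustering import (
    cluster_profiles,
    select_significant,
    signed_lod_profiles,
)
from mofsync.enrichment import (
    DEFAULT_MAX_SET_SIZE,
    DEFAULT_MIN_SET_SIZE,
    DEFAULT_N_PERM,
    run_all_phases,
)
from mofsync.prep import filter_autosomal, z_transform
from mofsync.stats import (
    batch_chisq,
    compare_groups_wilcoxon,
    interaction_anova,
    matched_subset_rerun,
    mof_trend_test,
    propensity_match,
)
from mofsync.sync import (
    PhaseLabel,
    assign_phases,
    filter_patients,
    find_acute_window,
    trajectories_from_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    clinical: str
    trajectories: str
    expression: str
    samples: str
    annotation: str
    gene_sets: str
    out_dir: str
    n_perm: int = DEFAULT_N_PERM
    significance_threshold: float = 0.025
    min_set_size: int = DEFAULT_MIN_SET_SIZE
    max_set_size: int = DEFAULT_MAX_SET_SIZE
    age_bounds: tuple[int, int] = (16, 50)
    min_max_mof: int = 1
    max_unstable_span: int = 3
    matching_caliper: Optional[float] = 0.2
    matched_n_perm: Optional[int] = None  # defaults to n_perm
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance_threshold must be in (0, 1)")
        for path_field in (
            "clinical", "trajectories", "expression", "samples", "annotation", "gene_sets",
        ):
            path = Path(getattr(self, path_field))
            if not path.exists():
                raise FileNotFoundError(f"{path_field} input not found: {path}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    counts: dict[str, int] = {}

    clinical = mio.read_table(config.clinical)
    clinical["patient_id"] = clinical["patient_id"].astype(str)
    trajectories = trajectories_from_table(mio.read_table(config.trajectories))
    expression = mio.read_expression(config.expression)
    sample_meta = mio.read_table(config.samples)
    sample_meta["patient_id"] = sample_meta["patient_id"].astype(str)
    annotation = mio.read_annotation(config.annotation)
    gene_sets = mio.read_gmt(config.gene_sets)

    # --- filter + sync -------------------------------------------------
    report = filter_patients(
        clinical,
        trajectories,
        sample_meta,
        age_bounds=config.age_bounds,
        min_max_mof=config.min_max_mof,
        max_span=config.max_unstable_span,
    )
    mio.write_table(report, out / "filter_report.tsv")
    included = set(report.loc[report["included"], "patient_id"])
    counts["patients_total"] = len(report)
    counts["patients_included"] = len(included)

    windows = {
        pid: find_acute_window(traj)
        for pid, traj in trajectories.items()
        if pid in included
    }
    phases = assign_phases(
        sample_meta[sample_meta["patient_id"].isin(included)], windows
    )
    mio.write_table(phases, out / "phase_assignments.tsv")
    mapped = phases[phases["phase"] != PhaseLabel.UNMAPPED.value]
    counts["samples_total"] = len(sample_meta)
    counts["samples_mapped"] = len(mapped)

    # --- prep ----------------------------------------------------------
    autosomal = filter_autosomal(expression, annotation)
    counts["genes_total"] = expression.shape[0]
    counts["genes_autosomal"] = autosomal.shape[0]
    scaled = z_transform(autosomal)
    mio.write_expression(scaled, out / "scaled_expression.tsv")

    sex_labels = dict(zip(clinical["patient_id"], clinical["sex"]))

    # --- diffexp -------------------------------------------------------
    enrichment = run_all_phases(
        autosomal,
        sex_labels,
        mapped,
        gene_sets,
        n_perm=config.n_perm,
        rng=rng,
        min_size=config.min_set_size,
        max_size=config.max_set_size,
    )
    mio.write_table(enrichment, out / "enrichment.tsv")
    counts["set_phase_tests"] = len(enrichment)

    # --- cluster -------------------------------------------------------
    profiles = signed_lod_profiles(enrichment)
    selected = select_significant(profiles, config.significance_threshold)
    clusters = cluster_profiles(selected, config.significance_threshold)
    mio.write_table(clusters, out / "clusters.tsv")
    counts["sets_selected"] = len(selected)

    # --- confirmatory statistics --------------------------------------
    stats_report: dict = {}
    day_scores = _synchronized_scores(trajectories, windows, phases)
    pre = day_scores[day_scores["offset"] <= 0]
    if len(pre) >= 3 and pre["offset"].nunique() >= 2:
        slope, t, p = mof_trend_test(pre["offset"], pre["score"])
        stats_report["pre_acute_mof_trend"] = {"slope": slope, "t": t, "p": p}

    max_mof = {pid: w.max_score for pid, w in windows.items()}
    acute_day = {pid: w.first_day for pid, w in windows.items()}
    f_ids = [p for p in max_mof if sex_labels.get(p) == "female"]
    m_ids = [p for p in max_mof if sex_labels.get(p) == "male"]
    if f_ids and m_ids:
        w, p = compare_groups_wilcoxon(
            [max_mof[p] for p in f_ids], [max_mof[p] for p in m_ids]
        )
        stats_report["max_mof_by_sex_wilcoxon"] = {"rank_sum": w, "p": p}
        w, p = compare_groups_wilcoxon(
            [acute_day[p] for p in f_ids], [acute_day[p] for p in m_ids]
        )
        stats_report["acute_day_by_sex_wilcoxon"] = {"rank_sum": w, "p": p}

    if "batch" in clinical.columns:
        inc = clinical[clinical["patient_id"].isin(included)]
        table = pd.crosstab(inc["sex"], inc["batch"])
        try:
            chi2, p = batch_chisq(table.to_numpy())
            stats_report["batch_chisq"] = {"chi2": chi2, "p": p}
        except ValueError as exc:
            stats_report["batch_chisq"] = {"error": str(exc)}

    interactions = _interaction_models(
        scaled, gene_sets, clusters, mapped, trajectories, sex_labels
    )
    if not interactions.empty:
        mio.write_table(interactions, out / "interaction_models.tsv")
    counts["interaction_models"] = len(interactions)

    match_block = _matched_rerun(
        config, clinical, windows, mapped, autosomal, sex_labels, gene_sets,
        enrichment, rng, out,
    )
    if match_block:
        stats_report["propensity_matched"] = match_block
    mio.write_json(stats_report, out / "stats_report.json")

    manifest = {
        "package": "mofsync",
        "version": mofsync.__version__,
        "config": asdict(config),
        "counts": counts,
    }
    mio.write_json(manifest, out / "manifest.json")
    return out


def _synchronized_scores(trajectories, windows, phases) -> pd.DataFrame:
    """Long table of (offset, score) over all included patients' observed days."""
    rows = []
    for pid, window in windows.items():
        for day, score in trajectories[pid].observations.items():
            if day < window.first_day:
                offset = day - window.first_day
            elif day > window.last_day:
                offset = day - window.last_day
            else:
                offset = 0
            if -3 <= offset <= 3:
                rows.append((pid, offset, score))
    return pd.DataFrame(rows, columns=["patient_id", "offset", "score"])


def _interaction_models(
    scaled, gene_sets, clusters, mapped, trajectories, sex_labels
) -> pd.DataFrame:
    """MOF x sex interaction model per significant set x significant phase."""
    rows = []
    sample_info = mapped.set_index("sample_id")
    for rec in clusters.itertuples(index=False):
        genes = [g for g in gene_sets[rec.set].genes if g in scaled.index]
        if not genes:
            continue
        for phase in rec.phase_signature.split(","):
            in_phase = mapped[mapped["phase"] == phase]
            samples = [s for s in in_phase["sample_id"] if s in scaled.columns]
            if len(samples) < 4:
                continue
            avg = scaled.loc[genes, samples].mean(axis=0).to_numpy()
            mof, sex = [], []
            for s in samples:
                pid = str(sample_info.at[s, "patient_id"])
                day = int(sample_info.at[s, "day"])
                obs = trajectories[pid].observations
                mof.append(obs.get(day, max(obs.values())))
                sex.append(sex_labels[pid])
            if len(set(sex)) < 2 or len(set(mof)) < 2:
                continue
            try:
                res = interaction_anova(avg, mof, sex, set_name=rec.set, phase=phase)
            except ValueError:
                continue
            rows.append(
                {
                    "set": rec.set,
                    "phase": phase,
                    **{f"coef_{k}": v for k, v in res.coefficients.items()},
                    **{f"p_{k}": v for k, v in res.f_pvalues.items()},
                    "n_samples": res.n_samples,
                }
            )
    return pd.DataFrame(rows)


def _matched_rerun(
    config, clinical, windows, mapped, autosomal, sex_labels, gene_sets,
    enrichment, rng, out,
) -> Optional[dict]:
    """Propensity-matched acute-phase re-analysis (one acute sample/patient)."""
    acute = mapped[mapped["phase"] == PhaseLabel.ACUTE.value]
    first_acute = (
        acute.sort_values(["patient_id", "day", "sample_id"])
        .groupby("patient_id", sort=True)
        .head(1)
    )
    ais = dict(zip(clinical["patient_id"], clinical["ais_baseline"]))
    cov_rows, ids = [], []
    for rec in first_acute.itertuples(index=False):
        pid = str(rec.patient_id)
        ids.append(str(rec.sample_id))
        cov_rows.append((float(ais[pid]), float(windows[pid].max_score)))
    if len(ids) < 4:
        return None
    covariates = pd.DataFrame(
        cov_rows, index=pd.Index(ids, name="sample_id"),
        columns=["ais_baseline", "acute_mof"],
    )
    sample_sex = {
        str(r.sample_id): sex_labels[str(r.patient_id)]
        for r in first_acute.itertuples(index=False)
    }
    if len(set(sample_sex.values())) < 2:
        return None
    match = propensity_match(covariates, sample_sex, caliper=config.matching_caliper)
    if len(match.pairs) < 2:
        return {"n_pairs": len(match.pairs), "note": "too few pairs for re-analysis"}
    pairs_df = pd.DataFrame(match.pairs, columns=["female_sample", "male_sample"])
    mio.write_table(pairs_df, out / "matched_pairs.tsv")
    try:
        matched_table, overlap = matched_subset_rerun(
            match,
            autosomal,
            sex_labels,
            mapped,
            gene_sets,
            n_perm=config.matched_n_perm or config.n_perm,
            rng=rng,
            full_enrichment=enrichment,
            threshold=config.significance_threshold,
            min_size=config.min_set_size,
            max_size=config.max_set_size,
        )
    except ValueError as exc:
        return {"n_pairs": len(match.pairs), "note": str(exc)}
    mio.write_table(matched_table, out / "matched_enrichment.tsv")
    return {
        "n_pairs": len(match.pairs),
        "smd_before": match.smd_before,
        "smd_after": match.smd_after,
        "overlap_fraction": overlap.get("overlap_fraction"),
        "matched_significant_sets": overlap["matched_significant_sets"],
        "full_significant_sets": overlap.get("full_significant_sets"),
    }
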