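"""Signed LOD profiles across phases and significance-pattern clustering.

Per gene set and phase, the working adjusted p-value is the smaller of
the two directional adjusted p-values and the LOD score is
-log10(adjusted p), signed negative when the set is down-regulated in
female patients. Sets highly significant (adjusted p < 0.025) in at
least one phase are kept and grouped combinatorially — no distance-based
algorithm — into single-phase vs. multiple-phase clusters by their
significant-phase signature, and into female (positive LOD) vs. male
(negative LOD) clusters by sign. Multi-phase sets whose significant
phases disagree in sign are reported as a separate ``mixed`` category.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mofsync.sync import PHASE_ORDER

DEFAULT_SIGNIFICANCE = 0.025

PHASE_COLUMNS = [p.value for p in PHASE_ORDER]


def directional_lod(adjusted_p: float, direction: str) -> float:
    """Signed LOD score: -log10(p), negative when down-regulated in females."""
    if adjusted_p <= 0:
        raise ValueError("adjusted p must be > 0")
    if adjusted_p > 1:
        raise ValueError("adjusted p must be <= 1")
    lod = -np.log10(adjusted_p)
    if direction == "down_in_female":
        return -lod
    if direction == "up_in_female":
        return lod
    raise ValueError(f"unknown direction {direction!r}")


def signed_lod_profiles(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-phase enrichment table to one signed LOD per set x phase.

    For each set x phase the smaller of the two directional adjusted
    p-values is taken, with the sign of its tail (positive = up in
    female). Phases absent for a set get LOD 0 (p = 1).

    Returns a DataFrame indexed by set name with one signed-LOD column
    per phase plus matching ``p::<phase>`` columns of the working
    adjusted p-values.
    """
    sets = list(dict.fromkeys(enrichment["set"]))
    lod = pd.DataFrame(0.0, index=pd.Index(sets, name="set"), columns=PHASE_COLUMNS)
    pvals = pd.DataFrame(
        1.0, index=lod.index, columns=[f"p::{c}" for c in PHASE_COLUMNS]
    )
    for row in enrichment.itertuples(index=False):
        if row.adj_p_up <= row.adj_p_dn:
            p, direction = row.adj_p_up, "up_in_female"
        else:
            p, direction = row.adj_p_dn, "down_in_female"
        lod.at[row.set, row.phase] = directional_lod(p, direction)
        pvals.at[row.set, f"p::{row.phase}"] = p
    return pd.concat([lod, pvals], axis=1)


def select_significant(
    profiles: pd.DataFrame, threshold: float = DEFAULT_SIGNIFICANCE
) -> pd.DataFrame:
    """Keep sets with adjusted p strictly below ``threshold`` in >=1 phase."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pcols = [f"p::{c}" for c in PHASE_COLUMNS]
    significant = profiles[pcols].to_numpy() < threshold
    return profiles.loc[significant.any(axis=1)]


def cluster_profiles(
    selected: pd.DataFrame, threshold: float = DEFAULT_SIGNIFICANCE
) -> pd.DataFrame:
    """Assign each selected set a significance-pattern cluster label.

    Membership is ``single_phase`` or ``multiple_phase`` by the count of
    significant phases; the phase signature lists those phases in
    temporal order; sex direction is ``female_cluster`` when the LOD is
    positive at every significant phase, ``male_cluster`` when negative
    at every one, else ``mixed``.
    """
    rows = []
    for set_name, row in selected.iterrows():
        sig_phases = [c for c in PHASE_COLUMNS if row[f"p::{c}"] < threshold]
        lods = [row[c] for c in sig_phases]
        if all(v > 0 for v in lods):
            sex = "female_cluster"
        elif all(v < 0 for v in lods):
            sex = "male_cluster"
        else:
            sex = "mixed"
        rows.append(
            {
                "set": set_name,
                "membership": "single_phase" if len(sig_phases) == 1 else "multiple_phase",
                "phase_signature": ",".join(sig_phases),
                "sex_direction": sex,
                **{c: row[c] for c in PHASE_COLUMNS},
            }
        )
    return pd.DataFrame(
        rows,
        columns=["set", "membership", "phase_signature", "sex_direction", *PHASE_COLUMNS],
    )


def gene_set_group_summary(
    scaled_expression: pd.DataFrame,
    gene_set: Sequence[str],
    group_labels: Mapping[str, str],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean +- SE of scaled member-gene expression, with t-tests.

    Pools all member-gene x sample scaled values within each sample
    group (the statistics behind group boxplot displays). ``pairs``
    selects the group pairs compared by two-sided Student's t-tests;
    all unordered pairs by default.

    Returns ``(summary, tests)``: per-group ``n, mean, se`` and
    per-pair ``group_a, group_b, t, p``.
    """
    members = [g for g in gene_set if g in scaled_expression.index]
    if not members:
        raise ValueError("gene set empty after intersection with the matrix")
    groups: dict[str, np.ndarray] = {}
    labels = sorted(set(group_labels.values()))
    for label in labels:
        cols = [c for c in scaled_expression.columns if group_labels.get(c) == label]
        if len(cols) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        groups[label] = scaled_expression.loc[members, cols].to_numpy().ravel()

    summary = pd.DataFrame(
        {
            "group": labels,
            "n": [groups[g].size for g in labels],
            "mean": [groups[g].mean() for g in labels],
            "se": [stats.sem(groups[g]) for g in labels],
        }
    )
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    tests = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        tests.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    return summary, pd.DataFrame(tests, columns=["group_a", "group_b", "t", "p"])
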