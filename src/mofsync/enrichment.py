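"""Per-phase sex-differential statistics and permutation gene-set enrichment.

Within each temporal phase, every autosomal gene gets a two-sample
pooled-variance Student's t-value oriented female minus male. Gene sets
are scored by the mean of their members' t-values and assessed against a
gene-permutation null: random same-size subsets of the tested gene
universe. Two distinct directional p-values are reported per set —
``p_up`` for up-regulation in female patients (right tail) and ``p_dn``
for down-regulation (left tail) — each corrected by Benjamini-Hochberg
within its phase x direction family.

The Monte-Carlo estimator is (1 + b) / (1 + n_perm), which never returns
zero; when the number of distinct same-size subsets is small the exact
null can be enumerated instead, giving p = #{subsets >= observed}/total
(and analogously for the left tail).
"""

from __future__ import annotations

import logging
import math
import warnings
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from mofsync.genesets import GeneSetCollection
from mofsync.sync import PHASE_ORDER, PhaseLabel

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 50_000
DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 500
DEFAULT_EXACT_CAP = 1_000_000

#: Number of permutations held in memory at once during vectorized nulls.
_PERM_CHUNK = 2_000


def phase_ttests(
    expression: pd.DataFrame,
    sex_labels: Mapping[str, str],
    phase_assignments: pd.DataFrame,
    phase: str | PhaseLabel,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Gene-wise two-sample t-statistics, female minus male, in one phase.

    Parameters
    ----------
    expression
        Genes x samples matrix (autosomal-filtered).
    sex_labels
        patient_id -> ``"female"`` or ``"male"``.
    phase_assignments
        Table with ``sample_id, patient_id, phase`` columns.
    phase
        The phase to test.
    equal_var
        Pooled-variance (classical Student) when True, Welch otherwise.

    Returns
    -------
    DataFrame indexed by gene with columns ``t, n_female, n_male``.
    Genes with zero pooled variance get t = 0 when the group means are
    equal and are dropped with a warning otherwise.
    """
    phase = PhaseLabel(phase)
    in_phase = phase_assignments[phase_assignments["phase"] == phase.value]
    sample_sex = {
        str(r.sample_id): sex_labels[str(r.patient_id)]
        for r in in_phase.itertuples(index=False)
    }
    cols = [c for c in expression.columns if c in sample_sex]
    female_cols = [c for c in cols if sample_sex[c] == "female"]
    male_cols = [c for c in cols if sample_sex[c] == "male"]
    n_f, n_m = len(female_cols), len(male_cols)
    if n_f < 2 or n_m < 2:
        raise ValueError(
            f"phase {phase.value!r}: need >=2 samples per sex "
            f"(got {n_f} female, {n_m} male)"
        )

    xf = expression[female_cols].to_numpy(dtype=float)
    xm = expression[male_cols].to_numpy(dtype=float)
    mf, mm = xf.mean(axis=1), xm.mean(axis=1)
    vf, vm = xf.var(axis=1, ddof=1), xm.var(axis=1, ddof=1)
    if equal_var:
        pooled = ((n_f - 1) * vf + (n_m - 1) * vm) / (n_f + n_m - 2)
        se = np.sqrt(pooled * (1.0 / n_f + 1.0 / n_m))
    else:
        se = np.sqrt(vf / n_f + vm / n_m)

    diff = mf - mm
    degenerate = se == 0
    t = np.zeros(len(diff))
    ok = ~degenerate
    t[ok] = diff[ok] / se[ok]
    drop = degenerate & (diff != 0)
    if drop.any():
        warnings.warn(
            f"phase {phase.value!r}: dropped {int(drop.sum())} genes with zero "
            "pooled variance and unequal means",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {"t": t, "n_female": n_f, "n_male": n_m}, index=expression.index
    )
    return out.loc[~drop]


def _tie_eps(observed: np.ndarray) -> np.ndarray:
    """Tolerance for tail counting: null means equal to the observed mean up
    to float summation order must count into both tails."""
    return 1e-9 * (1.0 + np.abs(observed))


def _exact_tail_counts(
    t: np.ndarray, size: int, observed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Enumerate all same-size subsets; count null means >=/<= each observed."""
    n = len(t)
    total = math.comb(n, size)
    sums = np.fromiter(
        (sum(c) for c in combinations(t.tolist(), size)), dtype=float, count=total
    )
    means = sums / size
    eps = _tie_eps(observed)
    ge = (means[:, None] >= (observed - eps)[None, :]).sum(axis=0)
    le = (means[:, None] <= (observed + eps)[None, :]).sum(axis=0)
    return ge, le, total


def gsea_mean_perm(
    t_values: pd.Series,
    gene_sets: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    rng: Optional[np.random.Generator] = None,
    *,
    min_size: int = 1,
    max_size: Optional[int] = None,
    exact: bool = False,
    exact_cap: int = DEFAULT_EXACT_CAP,
) -> pd.DataFrame:
    """Directional mean-statistic gene-set enrichment for one phase.

    The null draws random gene subsets of the same size from the tested
    universe without replacement (gene-label permutation). ``exact=True``
    enumerates all subsets whenever their count is at most ``exact_cap``,
    falling back to Monte-Carlo for larger sets.

    Returns a DataFrame with one row per tested set: ``set, n_genes,
    mean_stat, p_up, p_dn, direction``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(t_values) == 0:
        raise ValueError("empty gene universe")
    if rng is None:
        rng = np.random.default_rng()

    t = t_values.to_numpy(dtype=float)
    universe = set(map(str, t_values.index))
    n = len(t)

    tested: list[tuple[str, np.ndarray]] = []
    for gs in gene_sets:
        members = [g for g in gs.genes if g in universe]
        if not members:
            logger.info("set %r empty after intersection with universe; skipped", gs.name)
            continue
        if len(members) < min_size or (max_size is not None and len(members) > max_size):
            logger.info("set %r outside size bounds after intersection; skipped", gs.name)
            continue
        idx = t_values.index.get_indexer(members)
        tested.append((gs.name, np.asarray(idx)))

    names = [name for name, _ in tested]
    sizes = np.array([len(idx) for _, idx in tested], dtype=int)
    observed = np.array([t[idx].mean() for _, idx in tested], dtype=float)

    ge_counts = np.zeros(len(tested), dtype=np.int64)
    le_counts = np.zeros(len(tested), dtype=np.int64)
    p_up = np.empty(len(tested))
    p_dn = np.empty(len(tested))

    exact_mask = np.zeros(len(tested), dtype=bool)
    if exact:
        for size in np.unique(sizes):
            if math.comb(n, int(size)) <= exact_cap:
                exact_mask |= sizes == size
        for size in np.unique(sizes[exact_mask]):
            sel = sizes == size
            ge, le, total = _exact_tail_counts(t, int(size), observed[sel])
            p_up[sel] = ge / total
            p_dn[sel] = le / total

    mc_mask = ~exact_mask
    if mc_mask.any():
        mc_sizes = sorted(np.unique(sizes[mc_mask]))
        remaining = n_perm
        while remaining > 0:
            chunk = min(_PERM_CHUNK, remaining)
            remaining -= chunk
            # First k entries of a uniform random permutation form a
            # uniform random k-subset; one shuffle batch serves all sizes.
            order = np.argsort(rng.random((chunk, n)), axis=1)
            csum = np.cumsum(t[order], axis=1)
            for size in mc_sizes:
                null_means = csum[:, size - 1] / size
                sel = mc_mask & (sizes == size)
                obs = observed[sel]
                eps = _tie_eps(obs)
                ge_counts[sel] += (null_means[:, None] >= (obs - eps)[None, :]).sum(axis=0)
                le_counts[sel] += (null_means[:, None] <= (obs + eps)[None, :]).sum(axis=0)
        p_up[mc_mask] = (1.0 + ge_counts[mc_mask]) / (1.0 + n_perm)
        p_dn[mc_mask] = (1.0 + le_counts[mc_mask]) / (1.0 + n_perm)

    direction = np.where(observed < 0, "down_in_female", "up_in_female")
    return pd.DataFrame(
        {
            "set": names,
            "n_genes": sizes,
            "mean_stat": observed,
            "p_up": p_up,
            "p_dn": p_dn,
            "direction": direction,
        }
    )


def bh_adjust(p_values: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = p_(i) * m / i on the ascending order statistics, with
    monotonicity enforced from the largest rank downward and values
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_all_phases(
    expression: pd.DataFrame,
    sex_labels: Mapping[str, str],
    phase_assignments: pd.DataFrame,
    gene_sets: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    rng: Optional[np.random.Generator] = None,
    *,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: Optional[int] = DEFAULT_MAX_SET_SIZE,
    exact: bool = False,
    pool_directions: bool = False,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Run t-tests + enrichment separately in each of the five phases.

    Phases with fewer than two samples of either sex are skipped with a
    warning; it is an error if no phase is analyzable. BH correction is
    applied within each phase x direction family by default
    (``pool_directions=True`` corrects p_up and p_dn together per phase).

    Returns the concatenated per-phase enrichment table with columns
    ``set, phase, n_genes, mean_stat, p_up, p_dn, adj_p_up, adj_p_dn,
    direction``.
    """
    if rng is None:
        rng = np.random.default_rng()
    results = []
    for phase in PHASE_ORDER:
        try:
            tstats = phase_ttests(
                expression, sex_labels, phase_assignments, phase, equal_var=equal_var
            )
        except ValueError as exc:
            warnings.warn(f"skipping phase: {exc}", stacklevel=2)
            continue
        table = gsea_mean_perm(
            tstats["t"],
            gene_sets,
            n_perm=n_perm,
            rng=rng,
            min_size=min_size,
            max_size=max_size,
            exact=exact,
        )
        if table.empty:
            continue
        if pool_directions:
            pooled = bh_adjust(np.concatenate([table["p_up"], table["p_dn"]]))
            table["adj_p_up"] = pooled[: len(table)]
            table["adj_p_dn"] = pooled[len(table):]
        else:
            table["adj_p_up"] = bh_adjust(table["p_up"].to_numpy())
            table["adj_p_dn"] = bh_adjust(table["p_dn"].to_numpy())
        table.insert(1, "phase", phase.value)
        results.append(table)
    if not results:
        raise ValueError("no phase had >=2 samples of each sex")
    return pd.concat(results, ignore_index=True)[
        [
            "set",
            "phase",
            "n_genes",
            "mean_stat",
            "p_up",
            "p_dn",
            "adj_p_up",
            "adj_p_dn",
            "direction",
        ]
    ]
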