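"""Confirmatory cohort statistics.

Beyond the enrichment pipeline, the analysis is backed by: a linear
regression t-test on the MOF trend over time, Wilcoxon rank-sum group
comparisons, a chi-squared batch-confounding check, a MOF x sex
interaction linear model with per-coefficient F-tests on the average
scaled expression of a gene set, and a propensity-score-matched
re-analysis of the acute phase that removes severity confounding from
the sex comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from mofsync.enrichment import bh_adjust, gsea_mean_perm, phase_ttests
from mofsync.genesets import GeneSetCollection
from mofsync.sync import PhaseLabel


def mof_trend_test(days: Sequence[float], scores: Sequence[float]) -> tuple[float, float, float]:
    """OLS slope of score on day with a two-sided t-test on the slope.

    Returns ``(slope, t, p)``.
    """
    days = np.asarray(days, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(days) < 3:
        raise ValueError("need at least 3 points")
    if np.unique(days).size < 2:
        raise ValueError("need at least 2 distinct days")
    res = sps.linregress(days, scores)
    if not np.isfinite(res.stderr) or res.stderr == 0:
        # constant response: slope 0 with no evidence against it
        return float(res.slope), 0.0, 1.0
    t = res.slope / res.stderr
    return float(res.slope), float(t), float(res.pvalue)


def compare_groups_wilcoxon(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact p-value for small tie-free samples, mid-rank normal
    approximation otherwise. Returns ``(rank_sum_of_a, p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="auto", use_continuity=False
    )
    rank_sum = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return rank_sum, float(res.pvalue)


def batch_chisq(counts: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a sex x batch table.

    No continuity correction; df = (r-1)(k-1).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a 2-D table with >=2 rows and columns")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column sum")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class InteractionModelResult:
    set_name: str
    phase: str
    coefficients: dict[str, float]
    f_pvalues: dict[str, float]
    n_samples: int


def interaction_anova(
    avg_scaled_expr: Sequence[float],
    mof: Sequence[float],
    sex: Sequence[str],
    set_name: str = "",
    phase: str = "",
) -> InteractionModelResult:
    """Linear model avg_expr ~ mof + sex + mof:sex with coefficient F-tests.

    Sex is coded female = 1, male = 0, so the interaction coefficient is
    the extra MOF slope in female patients. Each coefficient's F-test is
    the squared-t test from the same least-squares fit.
    """
    import statsmodels.api as sm

    y = np.asarray(avg_scaled_expr, dtype=float)
    mof = np.asarray(mof, dtype=float)
    sex_num = np.asarray([1.0 if s == "female" else 0.0 for s in sex])
    if y.size < 4:
        raise ValueError("need at least 4 samples")
    if sex_num.min() == sex_num.max():
        raise ValueError("both sexes must be present")
    X = np.column_stack([np.ones_like(mof), mof, sex_num, mof * sex_num])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (e.g. constant MOF)")
    fit = sm.OLS(y, X).fit()
    names = ["intercept", "mof_effect", "sex_effect", "interaction_effect"]
    f_p = {
        name: float(sps.f.sf(t * t, 1, fit.df_resid))
        for name, t in zip(names, fit.tvalues)
    }
    return InteractionModelResult(
        set_name=set_name,
        phase=phase,
        coefficients=dict(zip(names, map(float, fit.params))),
        f_pvalues=f_p,
        n_samples=int(y.size),
    )


@dataclass
class MatchResult:
    """1:1 propensity-matched female/male pairs with balance diagnostics."""

    pairs: list[tuple[str, str]]
    propensity: pd.Series
    logit: pd.Series
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    caliper: Optional[float]

    @property
    def matched_ids(self) -> set[str]:
        return {i for pair in self.pairs for i in pair}


def _smd(cov: pd.DataFrame, female: pd.Index, male: pd.Index, sd: pd.Series) -> dict[str, float]:
    out = {}
    for col in cov.columns:
        denom = sd[col] if sd[col] > 0 else 1.0
        out[col] = float(
            abs(cov.loc[female, col].mean() - cov.loc[male, col].mean()) / denom
        )
    return out


def propensity_match(
    covariates: pd.DataFrame,
    sex_labels: Mapping[str, str],
    caliper: Optional[float] = 0.2,
) -> MatchResult:
    """Select a severity-balanced subset by 1:1 propensity matching.

    The propensity is a logistic regression of sex (female = 1) on the
    covariates (e.g. baseline AIS and acute-phase MOF score). Females
    are matched greedily to the nearest unmatched male on the logit of
    the propensity, without replacement; ``caliper`` (in SDs of the
    logit, None to disable) limits the allowed distance. Standardized
    mean differences per covariate are reported before and after
    matching, both against the full-cohort pooled SD.
    """
    from sklearn.linear_model import LogisticRegression

    ids = covariates.index
    sex = pd.Series({i: sex_labels[str(i)] for i in ids})
    female_ids = ids[sex == "female"]
    male_ids = ids[sex == "male"]
    if len(female_ids) == 0 or len(male_ids) == 0:
        raise ValueError("both sexes must be present among candidates")
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete")

    X = covariates.to_numpy(dtype=float)
    y = (sex == "female").astype(int).to_numpy()
    # standardized design keeps the bounded ridge penalty scale-free
    mu, sd_x = X.mean(axis=0), X.std(axis=0)
    sd_x[sd_x == 0] = 1.0
    model = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000)
    model.fit((X - mu) / sd_x, y)
    prop = model.predict_proba((X - mu) / sd_x)[:, 1]
    prop = np.clip(prop, 1e-12, 1 - 1e-12)
    logit = np.log(prop / (1 - prop))
    propensity = pd.Series(prop, index=ids)
    logit_s = pd.Series(logit, index=ids)

    sd_pool = covariates.std(ddof=1)
    smd_before = _smd(covariates, female_ids, male_ids, sd_pool)

    max_dist = None if caliper is None else caliper * float(np.std(logit, ddof=1))
    available = {str(m): float(logit_s[m]) for m in male_ids}
    pairs: list[tuple[str, str]] = []
    for f in female_ids:
        if not available:
            break
        lf = float(logit_s[f])
        best = min(available, key=lambda m: (abs(available[m] - lf), m))
        if max_dist is not None and abs(available[best] - lf) > max_dist:
            continue
        pairs.append((str(f), best))
        del available[best]

    if pairs:
        f_idx = pd.Index([p[0] for p in pairs])
        m_idx = pd.Index([p[1] for p in pairs])
        smd_after = _smd(covariates, f_idx, m_idx, sd_pool)
    else:
        smd_after = {c: float("nan") for c in covariates.columns}
    return MatchResult(pairs, propensity, logit_s, smd_before, smd_after, caliper)


def matched_subset_rerun(
    match: MatchResult,
    expression: pd.DataFrame,
    sex_labels: Mapping[str, str],
    phase_assignments: pd.DataFrame,
    gene_sets: GeneSetCollection,
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    *,
    full_enrichment: Optional[pd.DataFrame] = None,
    threshold: float = 0.025,
    min_size: int = 1,
    max_size: Optional[int] = None,
) -> tuple[pd.DataFrame, dict]:
    """Re-run the acute-phase enrichment on the matched samples only.

    ``match.pairs`` must reference acute-phase sample ids. Returns the
    matched-subset enrichment table (with BH-adjusted directional
    p-values) and an overlap report comparing its significant sets —
    min(adj_p_up, adj_p_dn) < ``threshold`` — with those of the
    full-cohort acute-phase table when one is supplied.
    """
    if len(match.pairs) < 2:
        raise ValueError("need at least 2 matched pairs")
    if rng is None:
        rng = np.random.default_rng()
    matched_samples = match.matched_ids
    acute = phase_assignments[
        (phase_assignments["phase"] == PhaseLabel.ACUTE.value)
        & phase_assignments["sample_id"].astype(str).isin(matched_samples)
    ]
    tstats = phase_ttests(expression, sex_labels, acute, PhaseLabel.ACUTE)
    table = gsea_mean_perm(
        tstats["t"], gene_sets, n_perm=n_perm, rng=rng,
        min_size=min_size, max_size=max_size,
    )
    table["adj_p_up"] = bh_adjust(table["p_up"].to_numpy())
    table["adj_p_dn"] = bh_adjust(table["p_dn"].to_numpy())
    table.insert(1, "phase", PhaseLabel.ACUTE.value)

    matched_sig = set(
        table.loc[
            np.minimum(table["adj_p_up"], table["adj_p_dn"]) < threshold, "set"
        ]
    )
    report: dict = {
        "n_pairs": len(match.pairs),
        "matched_significant_sets": sorted(matched_sig),
    }
    if full_enrichment is not None:
        full_acute = full_enrichment[
            full_enrichment["phase"] == PhaseLabel.ACUTE.value
        ]
        full_sig = set(
            full_acute.loc[
                np.minimum(full_acute["adj_p_up"], full_acute["adj_p_dn"]) < threshold,
                "set",
            ]
        )
        overlap = matched_sig & full_sig
        report["full_significant_sets"] = sorted(full_sig)
        report["overlap_fraction"] = (
            len(overlap) / len(full_sig) if full_sig else float("nan")
        )
    return table, report
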