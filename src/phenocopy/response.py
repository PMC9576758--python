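"""Nested linear models of drug response and FDR-controlled LR tests.

The central question: do phenocopy calls add to DNA mutation status in
explaining drug response?  For each drug, a reduced OLS model
``response ~ 1 + mutation`` is compared with a full model that adds the
phenocopy call.  The likelihood-ratio statistic for Gaussian errors is

    chi2 = n * ln(RSS_reduced / RSS_full),

with one degree of freedom per added predictor, referred to the chi-square
upper tail.  Raw p-values across all drug/pathway/dataset combinations are
corrected by Benjamini-Hochberg step-up.

Response metrics differ by dataset (IC50 z-scores, ActArea, dose-response
AUC); :func:`orient_response` puts them all on a lower-is-more-sensitive
scale so a negative coefficient always means the predictor is associated
with drug sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

METRIC_KINDS = ("ic50_z", "act_area", "auc")
#: metrics where larger raw values mean more sensitive (negated on orientation)
_NEGATE_KINDS = frozenset({"act_area"})


@dataclass
class NestedModelResult:
    drug_id: str
    pathway_name: str
    dataset_tag: str
    n: int
    coef_mutation: float
    coef_phenocopy: float
    pvalue_mutation: float
    pvalue_phenocopy: float
    chi2: float
    df: int
    p_raw: float
    se_phenocopy: float = float("nan")
    coef_pathogenic: float | None = None
    pvalue_pathogenic: float | None = None
    q_bh: float | None = None
    degenerate: bool = False
    degenerate_reason: str | None = None


def orient_response(table: pd.DataFrame) -> pd.DataFrame:
    """Re-orient response values so that lower always means more sensitive.

    ActArea is negated (a higher activity area is a stronger response); IC50
    z-scores and AUC already point the right way.  Adds an ``oriented`` flag
    column so repeated application is a no-op.
    """
    if "oriented" in table.columns and table["oriented"].all():
        return table.copy()
    unknown = set(table["metric_kind"].unique()) - set(METRIC_KINDS)
    if unknown:
        raise ValueError(f"unknown metric_kind values: {sorted(unknown)}")
    out = table.copy()
    negate = out["metric_kind"].isin(_NEGATE_KINDS)
    out.loc[negate, "value"] = -out.loc[negate, "value"]
    out["oriented"] = True
    return out


def _complete_cases(*arrays) -> np.ndarray:
    stacked = np.column_stack([np.asarray(a, dtype=float) for a in arrays])
    return np.isfinite(stacked).all(axis=1)


def _fit_lr(
    y: np.ndarray, X_reduced: np.ndarray, X_full: np.ndarray
) -> tuple[sm.regression.linear_model.RegressionResults, float, int]:
    """OLS fits of nested designs; returns the full fit, the Gaussian-ML LR
    chi-square and the df (rank difference)."""
    fit_reduced = sm.OLS(y, X_reduced).fit()
    fit_full = sm.OLS(y, X_full).fit()
    n = y.size
    rss_r, rss_f = fit_reduced.ssr, fit_full.ssr
    if rss_f <= 0:
        chi2 = np.inf
    else:
        chi2 = max(0.0, n * np.log(rss_r / rss_f))
    df = int(np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_reduced))
    return fit_full, chi2, df


def fit_nested_models(
    response: np.ndarray | pd.Series,
    mutation: np.ndarray | pd.Series,
    phenocopy: np.ndarray | pd.Series,
    drug_id: str = "",
    pathway_name: str = "",
    dataset_tag: str = "",
    n_min: int = 20,
    test: str = "lr",
) -> NestedModelResult:
    """LR test of whether the phenocopy call adds to mutation status.

    Complete cases only.  If the phenocopy column is constant or collinear
    with mutation status within the complete cases, the test is undefined and
    the result is flagged degenerate (it is excluded from the FDR family).
    ``test='f'`` swaps the chi-square reference for the exact partial F test
    of the added predictor (``chi2`` then holds the F statistic); the LR
    chi-square is the primary dialect.
    """
    if test not in ("lr", "f"):
        raise ValueError(f"unknown test {test!r}")
    y = np.asarray(response, dtype=float)
    mut = np.asarray(mutation, dtype=float)
    phe = np.asarray(phenocopy, dtype=float)
    if not (y.size == mut.size == phe.size):
        raise ValueError("response and predictor vectors must have equal length")
    keep = _complete_cases(y, mut, phe)
    y, mut, phe = y[keep], mut[keep], phe[keep]
    n = y.size
    if n < n_min:
        raise ValueError(f"only {n} complete cases (minimum {n_min})")
    if np.ptp(mut) == 0 and np.ptp(phe) == 0:
        raise ValueError("both predictors are constant")

    X_reduced = sm.add_constant(mut[:, None], has_constant="add")
    X_full = sm.add_constant(np.column_stack([mut, phe]), has_constant="add")
    result = NestedModelResult(
        drug_id=drug_id, pathway_name=pathway_name, dataset_tag=dataset_tag, n=n,
        coef_mutation=np.nan, coef_phenocopy=np.nan,
        pvalue_mutation=np.nan, pvalue_phenocopy=np.nan,
        chi2=np.nan, df=1, p_raw=np.nan,
    )
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_reduced):
        result.degenerate = True
        result.degenerate_reason = "phenocopy constant or collinear with mutation status"
        logger.info("drug %s: degenerate nested test (%s)", drug_id, result.degenerate_reason)
        return result
    fit_full, chi2, df = _fit_lr(y, X_reduced, X_full)
    result.coef_mutation = float(fit_full.params[1])
    result.coef_phenocopy = float(fit_full.params[2])
    result.pvalue_mutation = float(fit_full.pvalues[1])
    result.pvalue_phenocopy = float(fit_full.pvalues[2])
    result.se_phenocopy = float(fit_full.bse[2])
    result.df = df
    if test == "f":
        k = int(np.linalg.matrix_rank(X_full))
        f_stat = (np.expm1(chi2 / n)) * (n - k) / df
        result.chi2 = float(f_stat)
        result.p_raw = float(stats.f.sf(f_stat, df, n - k))
    else:
        result.chi2 = float(chi2)
        result.p_raw = float(stats.chi2.sf(chi2, df))
    return result


def fit_three_predictor_model(
    response: np.ndarray | pd.Series,
    mutation: np.ndarray | pd.Series,
    pathogenic: np.ndarray | pd.Series,
    phenocopy: np.ndarray | pd.Series,
    drug_id: str = "",
    pathway_name: str = "",
    dataset_tag: str = "",
    n_min: int = 20,
) -> NestedModelResult:
    """Per-predictor coefficients for the volcano view: mutation, pathogenic
    mutation and phenocopy call enter jointly.

    ``pathogenic`` must imply ``mutation`` (it refines the mutated group).
    The LR chi-square still isolates the phenocopy term: reduced model is
    intercept + mutation + pathogenic.  When no pathogenic mutations exist
    the pathogenic column is dropped and the result flagged.
    """
    y = np.asarray(response, dtype=float)
    mut = np.asarray(mutation, dtype=float)
    path = np.asarray(pathogenic, dtype=float)
    phe = np.asarray(phenocopy, dtype=float)
    keep = _complete_cases(y, mut, path, phe)
    y, mut, path, phe = y[keep], mut[keep], path[keep], phe[keep]
    if np.any(path > mut):
        raise ValueError("pathogenic=1 requires mutation=1 for every sample")
    n = y.size
    if n < n_min:
        raise ValueError(f"only {n} complete cases (minimum {n_min})")
    if np.ptp(mut) == 0 and np.ptp(path) == 0 and np.ptp(phe) == 0:
        raise ValueError("all predictors are constant")

    pathogenic_dropped = np.ptp(path) == 0
    if pathogenic_dropped:
        reduced_cols = [mut]
        full_cols = [mut, phe]
    else:
        reduced_cols = [mut, path]
        full_cols = [mut, path, phe]
    X_reduced = sm.add_constant(np.column_stack(reduced_cols), has_constant="add")
    X_full = sm.add_constant(np.column_stack(full_cols), has_constant="add")
    result = NestedModelResult(
        drug_id=drug_id, pathway_name=pathway_name, dataset_tag=dataset_tag, n=n,
        coef_mutation=np.nan, coef_phenocopy=np.nan,
        pvalue_mutation=np.nan, pvalue_phenocopy=np.nan,
        chi2=np.nan, df=1, p_raw=np.nan,
        degenerate=pathogenic_dropped,
        degenerate_reason="no pathogenic mutations present" if pathogenic_dropped else None,
    )
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_reduced):
        result.degenerate = True
        result.degenerate_reason = "phenocopy constant or collinear with mutation predictors"
        return result
    fit_full, chi2, df = _fit_lr(y, X_reduced, X_full)
    result.coef_mutation = float(fit_full.params[1])
    result.pvalue_mutation = float(fit_full.pvalues[1])
    if not pathogenic_dropped:
        result.coef_pathogenic = float(fit_full.params[2])
        result.pvalue_pathogenic = float(fit_full.pvalues[2])
    result.coef_phenocopy = float(fit_full.params[-1])
    result.pvalue_phenocopy = float(fit_full.pvalues[-1])
    result.se_phenocopy = float(fit_full.bse[-1])
    result.chi2 = float(chi2)
    result.df = df
    result.p_raw = float(stats.chi2.sf(chi2, df))
    return result


def adjust_fdr(
    results: list[NestedModelResult], family: str = "pooled"
) -> list[NestedModelResult]:
    """Fill ``q_bh`` by Benjamini-Hochberg step-up.

    ``family='pooled'`` corrects over all non-degenerate tests in the run;
    ``family='per-dataset'`` runs BH separately within each dataset tag.
    Degenerate results stay outside the family with ``q_bh=None``.
    """
    if family not in ("pooled", "per-dataset"):
        raise ValueError(f"unknown FDR family {family!r}")
    testable = [r for r in results if not r.degenerate]
    if not testable:
        raise ValueError("no non-degenerate results to correct")
    if family == "pooled":
        groups = [testable]
    else:
        tags = sorted({r.dataset_tag for r in testable})
        groups = [[r for r in testable if r.dataset_tag == tag] for tag in tags]
    for group in groups:
        pvals = np.array([r.p_raw for r in group])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(group, qvals):
            r.q_bh = float(q)
    return results


def results_to_frame(results: list[NestedModelResult]) -> pd.DataFrame:
    """Flatten results to one row per drug/pathway/dataset for TSV export."""
    return pd.DataFrame([vars(r) for r in results])
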