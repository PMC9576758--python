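"""Group-rate comparisons: CNV enrichment in phenocopy-without-mutation
samples, and pre/post-treatment phenocopy-rate shifts in clinical cohorts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import PathwayDefinition

CNV_CATEGORIES = ("amplified", "neutral", "deleted")


@dataclass
class RateComparison:
    group_a_name: str
    group_b_name: str
    rate_a: float | None
    rate_b: float | None
    n_a: int
    n_b: int
    statistic: float | None
    p_value: float | None
    test_name: str
    degenerate: bool = False


def two_proportion_chisq(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pearson chi-square for two proportions, no continuity correction.

    Equivalent to the 2x2 chi-square on [[k1, n1-k1], [k2, n2-k2]].  A pooled
    rate of exactly 0 or 1 carries no evidence of a difference: statistic 0,
    p-value 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("event counts must lie within group sizes")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    p1, p2 = k1 / n1, k2 / n2
    stat = (p1 - p2) ** 2 / (pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float(stat), float(stats.chi2.sf(stat, 1))


def pathway_cnv_flags(
    cnv: pd.DataFrame,
    pathway: PathwayDefinition,
    samples,
    mode: str = "any",
) -> pd.Series:
    """Per-sample 0/1 flag: does the sample carry a copy-number change in any
    pathway gene (driver or feature)?

    ``mode='any'`` counts amplifications and deletions; ``'amplification'``
    counts gains only.  Samples without CNV records get 0.
    """
    unknown = set(cnv["category"].unique()) - set(CNV_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown CNV categories: {sorted(unknown)}")
    if mode == "any":
        changed = cnv["category"] != "neutral"
    elif mode == "amplification":
        changed = cnv["category"] == "amplified"
    else:
        raise ValueError(f"unknown CNV mode {mode!r}")
    genes = pathway.driver_genes | pathway.feature_genes
    hits = cnv.loc[changed & cnv["gene"].isin(genes), "sample_id"]
    flags = pd.Series(0, index=pd.Index(samples, name="sample_id"), dtype=int)
    flags.loc[flags.index.intersection(hits)] = 1
    return flags


def compare_cnv_rates(
    phenocopy: pd.Series,
    mutation: pd.Series,
    cnv: pd.DataFrame,
    pathway: PathwayDefinition,
    mode: str = "any",
) -> RateComparison:
    """Pathway CNV rate in phenocopy-without-mutation samples versus the rest.

    Group A: phenocopy call positive AND no DNA mutation.  Group B: everyone
    else.  A CNV excess in group A is the mechanistic reading of why a sample
    can mimic the mutant expression state without the mutation.
    """
    samples = phenocopy.index
    mutation = mutation.reindex(samples)
    if mutation.isna().any():
        raise ValueError("mutation labels missing for some samples")
    flags = pathway_cnv_flags(cnv, pathway, samples, mode=mode)
    in_a = (phenocopy.astype(int) == 1) & (mutation.astype(int) == 0)
    if not in_a.any():
        raise ValueError("no phenocopy-without-mutation samples; CNV comparison undefined")
    k1, n1 = int(flags[in_a].sum()), int(in_a.sum())
    k2, n2 = int(flags[~in_a].sum()), int((~in_a).sum())
    stat, p = two_proportion_chisq(k1, n1, k2, n2)
    return RateComparison(
        group_a_name="phenocopy_no_mutation",
        group_b_name="rest",
        rate_a=k1 / n1,
        rate_b=k2 / n2 if n2 else None,
        n_a=n1,
        n_b=n2,
        statistic=stat,
        p_value=p,
        test_name="two_proportion_chisq",
    )


def compare_phenocopy_rates(
    calls_a: np.ndarray | pd.Series,
    calls_b: np.ndarray | pd.Series,
    names: tuple[str, str] = ("pre_treatment", "post_treatment"),
) -> RateComparison:
    """Phenocopy-positive rate in two arms (e.g. pre- vs post-treatment),
    compared by the two-proportion chi-square without continuity correction."""
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be non-empty")
    stat, p = two_proportion_chisq(int(a.sum()), a.size, int(b.sum()), b.size)
    return RateComparison(
        group_a_name=names[0],
        group_b_name=names[1],
        rate_a=float(a.mean()),
        rate_b=float(b.mean()),
        n_a=a.size,
        n_b=b.size,
        statistic=stat,
        p_value=p,
        test_name="two_proportion_chisq",
    )


def responder_stratified_rates(
    calls: np.ndarray | pd.Series,
    responder: np.ndarray | pd.Series,
) -> RateComparison:
    """Response rate among phenocopy-positive versus phenocopy-negative
    samples, with a Fisher exact p-value (clinical cohorts are small).

    If every sample falls in one call group the comparison is degenerate:
    the one observed rate is reported, the other is missing, no test is run.
    """
    calls = np.asarray(calls, dtype=int)
    resp = np.asarray(responder, dtype=float)
    if calls.size != resp.size:
        raise ValueError("calls and responder vectors must have equal length")
    keep = np.isfinite(resp)
    calls, resp = calls[keep], resp[keep].astype(int)
    if calls.size == 0:
        raise ValueError("no responder labels available")
    pos, neg = calls == 1, calls == 0
    rate_pos = float(resp[pos].mean()) if pos.any() else None
    rate_neg = float(resp[neg].mean()) if neg.any() else None
    if not pos.any() or not neg.any():
        return RateComparison(
            group_a_name="phenocopy_positive",
            group_b_name="phenocopy_negative",
            rate_a=rate_pos, rate_b=rate_neg,
            n_a=int(pos.sum()), n_b=int(neg.sum()),
            statistic=None, p_value=None,
            test_name="fisher_exact", degenerate=True,
        )
    table = [
        [int(resp[pos].sum()), int((1 - resp[pos]).sum())],
        [int(resp[neg].sum()), int((1 - resp[neg]).sum())],
    ]
    odds, p = stats.fisher_exact(table)
    return RateComparison(
        group_a_name="phenocopy_positive",
        group_b_name="phenocopy_negative",
        rate_a=rate_pos, rate_b=rate_neg,
        n_a=int(pos.sum()), n_b=int(neg.sum()),
        statistic=float(odds), p_value=float(p),
        test_name="fisher_exact",
    )
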