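"""Responder definitions and biomarker metrics over mutation/phenocopy strata.

Responders are the most-sensitive quartile of a drug's oriented response
distribution (computed over all assayed lines, before any stratification).
Sensitivity, specificity, PPV and NPV are then evaluated in five conditions:

1. phenocopy call among mutation-negative lines,
2. phenocopy call among lines with pathogenic mutations,
3. phenocopy call among lines with non-pathogenic mutations,
4. mutation status in all lines,
5. pathogenic mutation status in all lines.

Conditions 1-3 partition the cohort.  A metric whose denominator is zero is
reported as missing, never as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = (
    "phenocopy_in_no_mutation",
    "phenocopy_in_pathogenic",
    "phenocopy_in_nonpathogenic",
    "mutation_in_all",
    "pathogenic_in_all",
)


@dataclass
class StratumMetrics:
    condition: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    drug_id: str = ""
    pathway_name: str = ""
    dataset_tag: str = ""
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def define_responders(oriented_values: np.ndarray | pd.Series) -> np.ndarray:
    """Flag the most-sensitive quartile as responders.

    With oriented values (lower = more sensitive) the cutoff is the
    ceil(n/4)-th smallest value; every sample at or below the cutoff is a
    responder, so ties at the boundary are included.
    """
    values = np.asarray(oriented_values, dtype=float)
    n = values.size
    if n < 4:
        raise ValueError(f"need at least 4 samples to define a responder quartile, got {n}")
    if not np.isfinite(values).all():
        raise ValueError("oriented response values must be finite")
    k = math.ceil(n / 4)
    cutoff = np.sort(values)[k - 1]
    responders = (values <= cutoff).astype(int)
    if responders.all():
        logger.warning("degenerate responder call: all values tie at the quartile cutoff")
    return responders


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_stratum_metrics(
    responders: np.ndarray | pd.Series,
    predictor: np.ndarray | pd.Series,
    stratum_mask: np.ndarray | pd.Series,
    condition: str,
    drug_id: str = "",
    pathway_name: str = "",
    dataset_tag: str = "",
) -> StratumMetrics:
    """Confusion counts and biomarker metrics of ``predictor`` against
    responder status, restricted to the samples selected by ``stratum_mask``.

    Responder labels must be computed on the full cohort before masking.
    """
    resp = np.asarray(responders, dtype=int)
    pred = np.asarray(predictor, dtype=int)
    mask = np.asarray(stratum_mask, dtype=bool)
    if not (resp.size == pred.size == mask.size):
        raise ValueError("responders, predictor and mask must have equal length")
    if not mask.any():
        raise ValueError(f"stratum mask selects no samples (condition {condition!r})")
    resp, pred = resp[mask], pred[mask]
    tp = int(np.sum((pred == 1) & (resp == 1)))
    fp = int(np.sum((pred == 1) & (resp == 0)))
    fn = int(np.sum((pred == 0) & (resp == 1)))
    tn = int(np.sum((pred == 0) & (resp == 0)))
    return StratumMetrics(
        condition=condition,
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        drug_id=drug_id,
        pathway_name=pathway_name,
        dataset_tag=dataset_tag,
        degenerate=(pred == pred[0]).all() or (resp == resp[0]).all(),
    )


def evaluate_conditions(
    responders: np.ndarray | pd.Series,
    mutation: np.ndarray | pd.Series,
    pathogenic: np.ndarray | pd.Series,
    phenocopy: np.ndarray | pd.Series,
    drug_id: str = "",
    pathway_name: str = "",
    dataset_tag: str = "",
) -> list[StratumMetrics]:
    """All five stratified biomarker evaluations for one drug.

    Strata with no samples (e.g. no pathogenic mutations observed) are
    skipped rather than raised, since that is a property of the cohort.
    """
    mut = np.asarray(mutation, dtype=int)
    path = np.asarray(pathogenic, dtype=int)
    if np.any(path > mut):
        raise ValueError("pathogenic=1 requires mutation=1 for every sample")
    all_mask = np.ones(mut.size, dtype=bool)
    masks = {
        "phenocopy_in_no_mutation": mut == 0,
        "phenocopy_in_pathogenic": path == 1,
        "phenocopy_in_nonpathogenic": (mut == 1) & (path == 0),
        "mutation_in_all": all_mask,
        "pathogenic_in_all": all_mask,
    }
    predictors = {
        "phenocopy_in_no_mutation": phenocopy,
        "phenocopy_in_pathogenic": phenocopy,
        "phenocopy_in_nonpathogenic": phenocopy,
        "mutation_in_all": mutation,
        "pathogenic_in_all": pathogenic,
    }
    out = []
    for condition in CONDITIONS:
        if not masks[condition].any():
            logger.info("condition %s: empty stratum, skipped", condition)
            continue
        out.append(
            compute_stratum_metrics(
                responders, predictors[condition], masks[condition], condition,
                drug_id=drug_id, pathway_name=pathway_name, dataset_tag=dataset_tag,
            )
        )
    return out


def metrics_to_frame(metrics: list[StratumMetrics]) -> pd.DataFrame:
    """One row per drug x condition, for TSV export."""
    rows = []
    for m in metrics:
        row = vars(m).copy()
        row["n"] = m.n
        rows.append(row)
    return pd.DataFrame(rows)
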