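"""Expression-matrix harmonization: gene intersection, normalization, pathway
restriction, and the training cancer-type alteration-rate filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import PathwayDefinition

logger = logging.getLogger(__name__)

#: supported normalization dialects
NORMALIZATION_DIALECTS = ("none", "rank", "zscore")


@dataclass
class ExpressionMatrix:
    """A genes x samples continuous expression grid.

    ``values`` rows are genes, columns are samples.  ``cancer_types`` is an
    optional per-sample annotation (absent for cell-line cohorts).
    ``normalization`` records which dialect has been applied, so a locked
    signature can verify its inputs were prepared the way it was trained.
    """

    values: pd.DataFrame
    cancer_types: pd.Series | None = None
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.cancer_types is not None:
            missing = self.values.columns.difference(self.cancer_types.index)
            if len(missing):
                raise ValueError(f"samples without cancer-type annotation: {list(missing)[:5]}")
            self.cancer_types = self.cancer_types.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = [s for s in self.samples if s in set(samples)]
        ct = self.cancer_types.loc[samples] if self.cancer_types is not None else None
        return ExpressionMatrix(self.values.loc[:, samples], ct, self.normalization)


def intersect_genes(matrices: list[ExpressionMatrix]) -> list[str]:
    """Sorted intersection of the gene universes of one or more matrices."""
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    if not common:
        raise ValueError("gene intersection across matrices is empty")
    return sorted(common)


def normalize_expression(matrix: ExpressionMatrix, dialect: str = "rank") -> ExpressionMatrix:
    """Normalize expression to make datasets from different platforms comparable.

    The default ``rank`` dialect replaces each sample's values with fractional
    ranks over the gene universe (average ranks for ties, scaled to (0, 1]).
    It is invariant to any strictly monotone per-sample transform of the raw
    data and idempotent, which lets one locked signature score RNA-seq-,
    array- and cell-line-derived profiles on a common scale.  ``zscore``
    centers and scales each gene; ``none`` passes values through.
    """
    if dialect not in NORMALIZATION_DIALECTS:
        raise ValueError(f"unknown normalization dialect {dialect!r}")
    values = matrix.values
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")
    if dialect == "none":
        out = values.copy()
    elif dialect == "rank":
        constant = values.nunique(axis=0) == 1
        if constant.any():
            logger.warning(
                "%d constant sample(s) map to a uniform rank profile: %s",
                int(constant.sum()),
                list(values.columns[constant])[:5],
            )
        out = values.rank(axis=0, method="average") / values.shape[0]
    else:  # zscore per gene
        sd = values.std(axis=1, ddof=0).replace(0.0, 1.0)
        out = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(out, matrix.cancer_types, normalization=dialect)


def restrict_to_pathway(matrix: ExpressionMatrix, pathway: PathwayDefinition) -> ExpressionMatrix:
    """Subset the matrix to the pathway's feature genes.

    Missing feature genes are tolerated (their fraction is logged); zero
    overlap is an error because the signature would have no features.
    """
    present = [g for g in matrix.genes if g in pathway.feature_genes]
    if not present:
        raise ValueError(f"no feature genes of pathway {pathway.name!r} present in matrix")
    missing_frac = 1.0 - len(present) / len(pathway.feature_genes)
    if missing_frac > 0:
        logger.info(
            "pathway %s: %.0f%% of feature genes absent from matrix",
            pathway.name,
            100 * missing_frac,
        )
    ct = matrix.cancer_types
    return ExpressionMatrix(matrix.values.loc[present], ct, matrix.normalization)


def filter_training_cancer_types(
    labels: pd.DataFrame,
    cancer_types: pd.Series,
    min_rate: float = 0.05,
) -> list[str]:
    """Drop training samples from cancer types whose alteration rate is below
    ``min_rate`` (default 5%); types at exactly the threshold are retained.

    The rate uses ``any_mutation`` (all protein-altering alterations, not just
    pathogenic ones).  Returns the retained sample identifiers in their
    original order.
    """
    cancer_types = cancer_types.reindex(labels.index)
    if cancer_types.isna().any():
        raise ValueError("every labelled sample needs a cancer type")
    rates = labels["any_mutation"].groupby(cancer_types).mean()
    for ctype, rate in rates.items():
        logger.info("cancer type %s: alteration rate %.3f", ctype, rate)
    kept_types = set(rates.index[rates >= min_rate])
    if not kept_types:
        raise ValueError(f"all cancer types fall below the {min_rate:.0%} alteration-rate filter")
    keep = cancer_types.isin(kept_types)
    return list(labels.index[keep])
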