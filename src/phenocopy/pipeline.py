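"""Convenience wrappers chaining the pipeline stages on one cohort bundle.

These helpers keep scripts and notebooks short; each step is the public API
of the corresponding module and can be run separately.
"""

from __future__ import annotations

import pandas as pd

from .annotation import build_labels, filter_protein_altering
from .prep import (
    ExpressionMatrix,
    filter_training_cancer_types,
    normalize_expression,
    restrict_to_pathway,
)
from .response import NestedModelResult, fit_nested_models, fit_three_predictor_model, orient_response
from .signatures import DEFAULT_GRID, PhenocopySignature, predict_phenocopy, train_signature
from .synthetic import SyntheticBundle


def mutation_labels(bundle: SyntheticBundle) -> pd.DataFrame:
    """Protein-altering filter + pathogenicity consensus + per-sample labels."""
    filtered = filter_protein_altering(bundle.mutations)
    return build_labels(filtered, bundle.pathway_definition, bundle.samples)


def train_from_bundle(
    bundle: SyntheticBundle,
    grid=DEFAULT_GRID,
    folds: int = 10,
    seed: int = 0,
    apply_type_filter: bool = True,
) -> tuple[PhenocopySignature, pd.DataFrame]:
    """Full training path on a cohort: labels, normalization, pathway
    restriction, cancer-type filter, CV-tuned boosted-tree fit."""
    labels = mutation_labels(bundle)
    normalized = normalize_expression(bundle.expression)
    features = restrict_to_pathway(normalized, bundle.pathway_definition)
    if apply_type_filter and bundle.expression.cancer_types is not None:
        kept = filter_training_cancer_types(labels, bundle.expression.cancer_types)
        features = features.subset_samples(kept)
        train_labels = labels.loc[kept, "any_mutation"]
    else:
        train_labels = labels["any_mutation"]
    signature = train_signature(
        features,
        train_labels,
        pathway_name=bundle.pathway_definition.name,
        grid=grid,
        folds=folds,
        seed=seed,
    )
    return signature, labels


def call_bundle(signature: PhenocopySignature, bundle: SyntheticBundle) -> pd.DataFrame:
    """Normalize a validation cohort with the signature's dialect and predict."""
    normalized = normalize_expression(bundle.expression, signature.normalization_dialect)
    return predict_phenocopy(signature, normalized)


def evaluate_bundle(
    bundle: SyntheticBundle,
    phenocopy_calls: pd.Series,
    labels: pd.DataFrame | None = None,
    model: str = "two",
    n_min: int = 20,
) -> list[NestedModelResult]:
    """Per-drug nested-model LR tests on a cohort's drug-response table.

    ``model='two'`` tests mutation vs mutation+phenocopy; ``'three'`` adds the
    pathogenic-mutation predictor.  Call :func:`phenocopy.adjust_fdr` on the
    returned list to fill q-values.
    """
    if labels is None:
        labels = mutation_labels(bundle)
    oriented = orient_response(bundle.drug_response)
    calls = phenocopy_calls.reindex(bundle.samples)
    results = []
    for (drug_id, tag), group in oriented.groupby(["drug_id", "dataset_tag"], sort=True):
        group = group.set_index("sample_id")
        samples = group.index
        y = group["value"]
        mut = labels.loc[samples, "any_mutation"]
        phe = calls.loc[samples]
        if model == "two":
            res = fit_nested_models(
                y, mut, phe,
                drug_id=drug_id, pathway_name=bundle.pathway_definition.name,
                dataset_tag=tag, n_min=n_min,
            )
        elif model == "three":
            res = fit_three_predictor_model(
                y, mut, labels.loc[samples, "pathogenic_mutation"], phe,
                drug_id=drug_id, pathway_name=bundle.pathway_definition.name,
                dataset_tag=tag, n_min=n_min,
            )
        else:
            raise ValueError(f"unknown model {model!r}")
        results.append(res)
    return results
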