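"""Mutation filtering, pathogenicity consensus calls, and per-sample alteration labels.

Mutation tables are MAF-like :class:`pandas.DataFrame` objects with one row per
variant call and the columns ``sample_id``, ``gene``, ``variant_class`` plus
annotation columns ``sift``, ``polyphen_hdiv``, ``polyphen_hvar``, ``fathmm``
and ``clinvar`` (missing annotations are NaN/None/empty).

The pathogenicity call is a consensus OR: a variant is pathogenic when any of
the computational predictors reports a damaging category, or ClinVar labels it
pathogenic or likely pathogenic.  Missing evidence never counts as damaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "variant_class",
    "sift",
    "polyphen_hdiv",
    "polyphen_hvar",
    "fathmm",
    "clinvar",
]

#: variant classes that alter the protein sequence and are retained
PROTEIN_ALTERING_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "nonstop",
        "frameshift",
        "in_frame_ins",
        "in_frame_del",
        "start_lost",
    }
)

#: variant classes that are explicitly excluded from the analysis
EXCLUDED_CLASSES = frozenset(
    {"silent", "splicing", "intronic", "upstream", "downstream", "utr3", "utr5", "igr"}
)

#: per-tool categorical vocabularies counted as damaging (normalized tokens)
DEFAULT_DAMAGING_VOCAB: dict[str, frozenset[str]] = {
    "sift": frozenset({"d", "deleterious"}),
    "polyphen_hdiv": frozenset({"d", "p", "probably_damaging", "possibly_damaging"}),
    "polyphen_hvar": frozenset({"d", "p", "probably_damaging", "possibly_damaging"}),
    "fathmm": frozenset({"d", "deleterious"}),
}

#: ClinVar significance labels counted as pathogenic
CLINVAR_PATHOGENIC = frozenset({"pathogenic", "likely_pathogenic"})


@dataclass(frozen=True)
class PathwayDefinition:
    """A targetable pathway: the driver genes whose mutations define the label
    and the feature genes whose expression is used by the signature."""

    name: str
    driver_genes: frozenset[str]
    feature_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("pathway name must be non-empty")
        if not self.driver_genes or not self.feature_genes:
            raise ValueError(f"pathway {self.name!r}: driver and feature gene sets must be non-empty")

    @staticmethod
    def from_sets(name: str, driver_genes, feature_genes) -> "PathwayDefinition":
        return PathwayDefinition(name, frozenset(driver_genes), frozenset(feature_genes))


def _normalize_token(value) -> str | None:
    """Lower-case an annotation string and collapse spaces to underscores.

    Returns None for missing values (NaN, None, empty string).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    token = str(value).strip().lower().replace(" ", "_")
    return token or None


def filter_protein_altering(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only protein-sequence-altering variants.

    Silent, splicing, intronic, upstream and downstream calls are dropped.
    Unknown variant classes are dropped with a warning rather than an error.
    """
    if table.empty:
        return table.copy()
    classes = table["variant_class"].map(_normalize_token)
    keep = classes.isin(PROTEIN_ALTERING_CLASSES)
    unknown = ~keep & ~classes.isin(EXCLUDED_CLASSES)
    if unknown.any():
        logger.warning(
            "excluding %d records with unknown variant_class values: %s",
            int(unknown.sum()),
            sorted(classes[unknown].dropna().unique()),
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_protein_altering: excluded %d of %d records", n_dropped, len(table))
    return table.loc[keep].copy()


def call_pathogenic(
    record: pd.Series | dict,
    damaging_vocab: dict[str, frozenset[str]] | None = None,
) -> int:
    """Consensus pathogenicity call for a single protein-altering variant.

    Returns 1 iff any predictor field holds a damaging category or ClinVar is
    pathogenic / likely pathogenic.  Missing fields carry no evidence.
    """
    vocab = damaging_vocab or DEFAULT_DAMAGING_VOCAB
    get = record.get if isinstance(record, dict) else record.__getitem__
    for tool, damaging in vocab.items():
        try:
            token = _normalize_token(get(tool))
        except KeyError:
            token = None
        if token is not None and token in damaging:
            return 1
    try:
        clinvar = _normalize_token(get("clinvar"))
    except KeyError:
        clinvar = None
    if clinvar is not None and clinvar in CLINVAR_PATHOGENIC:
        return 1
    return 0


def call_pathogenic_table(
    table: pd.DataFrame,
    damaging_vocab: dict[str, frozenset[str]] | None = None,
) -> pd.Series:
    """Vectorized consensus call: one 0/1 value per row of ``table``."""
    vocab = damaging_vocab or DEFAULT_DAMAGING_VOCAB
    out = pd.Series(0, index=table.index, dtype=int)
    for tool, damaging in vocab.items():
        if tool in table.columns:
            tokens = table[tool].map(_normalize_token)
            out |= tokens.isin(damaging).astype(int)
    if "clinvar" in table.columns:
        tokens = table["clinvar"].map(_normalize_token)
        out |= tokens.isin(CLINVAR_PATHOGENIC).astype(int)
    return out


def build_labels(
    table: pd.DataFrame,
    pathway: PathwayDefinition,
    samples: list[str] | pd.Index,
    damaging_vocab: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Per-sample alteration labels for one pathway's driver genes.

    ``table`` must already have passed :func:`filter_protein_altering`.
    Returns a frame indexed by ``samples`` with integer columns
    ``any_mutation`` and ``pathogenic_mutation``; samples without any record
    get 0/0.  A record whose sample is absent from ``samples`` raises, to
    catch silent identifier mismatches between datasets.
    """
    samples = pd.Index(samples)
    if samples.has_duplicates:
        raise ValueError("duplicate sample identifiers in cohort list")
    labels = pd.DataFrame(
        {"any_mutation": 0, "pathogenic_mutation": 0}, index=samples, dtype=int
    )
    labels.index.name = "sample_id"
    if table.empty:
        return labels
    unknown = set(table["sample_id"]) - set(samples)
    if unknown:
        raise ValueError(
            f"mutation table contains samples absent from the cohort list: {sorted(unknown)[:5]}"
        )
    in_pathway = table.loc[table["gene"].isin(pathway.driver_genes)]
    if in_pathway.empty:
        return labels
    labels.loc[labels.index.intersection(in_pathway["sample_id"]), "any_mutation"] = 1
    pathogenic = call_pathogenic_table(in_pathway, damaging_vocab)
    path_samples = in_pathway.loc[pathogenic.astype(bool), "sample_id"]
    labels.loc[labels.index.intersection(path_samples), "pathogenic_mutation"] = 1
    return labels
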