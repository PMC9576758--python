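"""Plain-text readers and writers: expression TSV, MAF-like mutation TSV,
GMT gene sets, label / CNV / drug-response tables, and bundle export.

One code path serves synthetic and real inputs: the generator writes exactly
the formats these readers consume.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import MUTATION_COLUMNS, PathwayDefinition
from .prep import ExpressionMatrix

#: maps Annovar/MAF-style headers onto the canonical mutation columns
DEFAULT_MUTATION_COLUMN_MAP = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_class",
    "SIFT": "sift",
    "Polyphen2_HDIV": "polyphen_hdiv",
    "Polyphen2_HVAR": "polyphen_hvar",
    "FATHMM": "fathmm",
    "CLNSIG": "clinvar",
}


def read_expression_tsv(
    path: str | Path,
    annotations_path: str | Path | None = None,
    normalization: str = "none",
) -> ExpressionMatrix:
    """Expression TSV: first column gene IDs, header row sample IDs.

    ``annotations_path`` points to an optional two-column TSV
    (sample_id, cancer_type).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "gene"
    cancer_types = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
        cancer_types = ann.iloc[:, 0]
    return ExpressionMatrix(values, cancer_types, normalization=normalization)


def write_expression_tsv(
    matrix: ExpressionMatrix,
    path: str | Path,
    annotations_path: str | Path | None = None,
) -> None:
    matrix.values.to_csv(path, sep="\t")
    if annotations_path is not None and matrix.cancer_types is not None:
        matrix.cancer_types.rename("cancer_type").to_csv(annotations_path, sep="\t")


def read_mutations_tsv(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """MAF-like TSV; headers are renamed via ``column_map`` (canonical names
    pass through untouched).  Absent annotation columns become all-missing."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    table = table.rename(columns=column_map or DEFAULT_MUTATION_COLUMN_MAP)
    missing_core = {"sample_id", "gene", "variant_class"} - set(table.columns)
    if missing_core:
        raise ValueError(f"mutation table lacks required columns: {sorted(missing_core)}")
    for col in MUTATION_COLUMNS:
        if col not in table.columns:
            table[col] = None
    return table[MUTATION_COLUMNS]


def write_mutations_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: one set per tab-separated line
    (name, description, member genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def pathway_from_gmt(
    name: str, gmt_sets: dict[str, list[str]], driver_genes
) -> PathwayDefinition:
    """Build a pathway from a GMT feature-gene set plus a driver-gene list
    (driver lists come from run config, not from the GMT)."""
    if name not in gmt_sets:
        raise KeyError(f"gene set {name!r} not present in GMT")
    return PathwayDefinition.from_sets(name, driver_genes, gmt_sets[name])


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels_tsv(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t")


def read_drug_response_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "drug_id", "value", "metric_kind"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"drug-response table lacks columns: {sorted(missing)}")
    if "dataset_tag" not in table.columns:
        table["dataset_tag"] = "default"
    return table


def read_cnv_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "gene", "category"} - set(table.columns)
    if missing:
        raise ValueError(f"CNV table lacks columns: {sorted(missing)}")
    return table


def read_arm_labels_tsv(path: str | Path) -> pd.DataFrame:
    """Clinical arm labels: sample_id, arm in {pre, post}, responder in
    {0, 1, NA}."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if "arm" not in table.columns:
        raise ValueError("arm-label table needs an 'arm' column")
    bad = set(table["arm"].unique()) - {"pre", "post"}
    if bad:
        raise ValueError(f"unknown arm values: {sorted(bad)}")
    return table


def write_bundle(bundle, directory: str | Path) -> Path:
    """Export a synthetic bundle as the TSV/GMT files the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(
        bundle.expression,
        directory / "expression.tsv",
        directory / "sample_annotations.tsv",
    )
    write_mutations_tsv(bundle.mutations, directory / "mutations.tsv")
    bundle.cnv.to_csv(directory / "cnv.tsv", sep="\t", index=False)
    bundle.drug_response.to_csv(directory / "drug_response.tsv", sep="\t", index=False)
    bundle.sample_truth.to_csv(directory / "sample_truth.tsv", sep="\t")
    pw = bundle.pathway_definition
    write_gmt({pw.name: sorted(pw.feature_genes)}, directory / "pathway.gmt")
    (directory / "driver_genes.txt").write_text("\n".join(sorted(pw.driver_genes)) + "\n")
    return directory
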