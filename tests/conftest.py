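import numpy as np
import pandas as pd
import pytest

from phenocopy import SyntheticConfig, generate_cohort

#: reduced tuning grid used throughout the tests to keep them quick
SMALL_GRID = ((2, 50), (2, 100), (3, 50), (3, 100))


@pytest.fixture(scope="session")
def clean_config():
    """Fully penetrant, mutation-only, noise-free-annotation regime: the
    latent activation coincides exactly with the pathogenic-mutation truth,
    so classifier recovery can be read off directly."""
    return SyntheticConfig(
        seed=101,
        pathogenic_fraction=1.0,
        penetrance=1.0,
        cnv_rate=0.0,
        annotation_error_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_bundle(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def clean_signature(clean_bundle):
    """Signature trained on the clean regime with the reduced grid."""
    from phenocopy import train_from_bundle

    signature, labels = train_from_bundle(clean_bundle, grid=SMALL_GRID, folds=10, seed=0)
    return signature, labels


@pytest.fixture(scope="session")
def default_bundle():
    """A cohort drawn at the generator defaults (mixed pathogenic fractions,
    CNV-driven phenocopies, annotation noise)."""
    return generate_cohort(SyntheticConfig(seed=77))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_mutation_table(rng, n_records=50, n_samples=20):
    """A randomized MAF-like table covering the annotation vocabularies,
    for brute-force consensus oracles."""
    tool_values = {
        "sift": ["D", "T", "deleterious", "tolerated", None],
        "polyphen_hdiv": ["D", "P", "B", "probably_damaging", "possibly_damaging", "benign", None],
        "polyphen_hvar": ["D", "P", "B", "probably damaging", None],
        "fathmm": ["D", "T", None],
        "clinvar": ["Pathogenic", "Likely_pathogenic", "Likely pathogenic", "Benign", "VUS", None],
    }
    table = pd.DataFrame(
        {
            "sample_id": rng.choice([f"S{i}" for i in range(n_samples)], size=n_records),
            "gene": rng.choice(["DRV1", "DRV2", "OTHER"], size=n_records),
            "variant_class": rng.choice(
                ["missense", "nonsense", "frameshift", "silent", "intronic"], size=n_records
            ),
        }
    )
    for tool, values in tool_values.items():
        table[tool] = rng.choice(np.array(values, dtype=object), size=n_records)
    return table
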