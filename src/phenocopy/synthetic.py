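"""Synthetic cohort generator with the causal structure the pipeline assumes.

The generative model mirrors the biology the analysis is built to detect:

* each tumor may carry a driver-gene mutation (per-cancer-type rate), which is
  functional ("pathogenic") only with some probability;
* independently, the pathway may be amplified (copy-number gain);
* a functional lesion (pathogenic mutation OR amplification) activates the
  pathway with probability ``penetrance``;
* pathway activation shifts the expression of a block of signal genes and
  increases sensitivity to on-target drugs (lower oriented response value);
* annotation strings (SIFT, PolyPhen-2, FATHMM, ClinVar) reflect true
  pathogenicity, corrupted at ``annotation_error_rate``.

Samples that are activated without carrying a mutation are exactly the
"phenocopies" the signature is meant to find — their activation is routed
through copy number, so phenocopy-without-mutation samples are enriched for
pathway CNV by construction.

Ground-truth latents (activation, per-record pathogenicity) ride along in the
bundle so downstream stages can be tested against the true data-generating
process.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import PathwayDefinition
from .prep import ExpressionMatrix

_VC_PASSENGER = ("silent", "intronic", "upstream", "downstream", "missense", "splicing")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort model.

    Defaults describe a mid-sized pan-cancer training cohort: four cancer
    types of 250 samples with alteration rates spanning 4-30% (one type sits
    below the 5% training filter on purpose), mostly-functional driver
    mutations, modest pathway amplification, and unit-scale expression and
    response effects against unit noise.
    """

    seed: int = 0
    n_cancer_types: int = 4
    samples_per_type: int = 250
    alteration_rate_per_type: tuple[float, ...] | float = (0.10, 0.20, 0.30, 0.04)
    pathogenic_fraction: float = 0.7
    cnv_rate: float = 0.10
    penetrance: float = 0.9
    n_pathway_genes: int = 100
    n_signal_genes: int = 30
    n_background_genes: int = 200
    signal_shift: float = 1.0
    expr_noise_sd: float = 1.0
    n_drugs: int = 10
    on_target_fraction: float = 0.5
    drug_effect: float = 1.0
    response_noise_sd: float = 1.0
    annotation_error_rate: float = 0.05
    treatment_selection_strength: float = 0.5
    continuous_activation: bool = False
    metric_kind: str = "ic50_z"
    n_driver_genes: int = 3
    passenger_rate: float = 0.5

    def __post_init__(self) -> None:
        rates = self.rates
        fractions = {
            "pathogenic_fraction": self.pathogenic_fraction,
            "cnv_rate": self.cnv_rate,
            "penetrance": self.penetrance,
            "on_target_fraction": self.on_target_fraction,
            "annotation_error_rate": self.annotation_error_rate,
            "treatment_selection_strength": self.treatment_selection_strength,
            **{f"alteration_rate[{i}]": r for i, r in enumerate(rates)},
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_cancer_types": self.n_cancer_types,
            "samples_per_type": self.samples_per_type,
            "n_pathway_genes": self.n_pathway_genes,
            "n_signal_genes": self.n_signal_genes,
            "n_background_genes": self.n_background_genes,
            "n_drugs": self.n_drugs,
            "n_driver_genes": self.n_driver_genes,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_signal_genes > self.n_pathway_genes:
            raise ValueError(
                f"n_signal_genes ({self.n_signal_genes}) exceeds "
                f"n_pathway_genes ({self.n_pathway_genes})"
            )
        if len(rates) != self.n_cancer_types:
            raise ValueError(
                f"alteration_rate_per_type has {len(rates)} entries "
                f"for {self.n_cancer_types} cancer types"
            )

    @property
    def rates(self) -> tuple[float, ...]:
        r = self.alteration_rate_per_type
        if isinstance(r, (int, float)):
            return (float(r),) * self.n_cancer_types
        return tuple(float(x) for x in r)


@dataclass
class SyntheticBundle:
    """One simulated cohort plus its generating latents."""

    expression: ExpressionMatrix
    mutations: pd.DataFrame
    cnv: pd.DataFrame
    drug_response: pd.DataFrame
    latent_activation: pd.Series
    true_pathogenic: pd.Series  # per mutation-table row
    pathway_definition: PathwayDefinition
    sample_truth: pd.DataFrame  # per-sample mutation / pathogenic / amplified / activation
    on_target_drugs: list[str]
    config: SyntheticConfig

    @property
    def samples(self) -> pd.Index:
        return self.expression.samples

    def subset(self, samples) -> "SyntheticBundle":
        keep = [s for s in self.samples if s in set(samples)]
        keep_set = set(keep)
        mut_mask = self.mutations["sample_id"].isin(keep_set)
        return SyntheticBundle(
            expression=self.expression.subset_samples(keep),
            mutations=self.mutations.loc[mut_mask].copy(),
            cnv=self.cnv.loc[self.cnv["sample_id"].isin(keep_set)].copy(),
            drug_response=self.drug_response.loc[
                self.drug_response["sample_id"].isin(keep_set)
            ].copy(),
            latent_activation=self.latent_activation.loc[keep],
            true_pathogenic=self.true_pathogenic.loc[mut_mask],
            pathway_definition=self.pathway_definition,
            sample_truth=self.sample_truth.loc[keep],
            on_target_drugs=list(self.on_target_drugs),
            config=self.config,
        )

    def checksum(self) -> str:
        """Stable content hash over every table in the bundle."""
        h = hashlib.sha256()
        h.update(self.expression.values.to_csv().encode())
        for df in (self.mutations, self.cnv, self.drug_response, self.sample_truth):
            h.update(df.to_csv().encode())
        h.update(self.latent_activation.to_csv().encode())
        h.update(self.true_pathogenic.to_csv().encode())
        return h.hexdigest()


def _draw_annotations(
    rng: np.random.Generator, annotated_pathogenic: np.ndarray
) -> pd.DataFrame:
    """Annotation strings per record, consistent with the (possibly corrupted)
    pathogenicity flags: pathogenic records carry at least one damaging call,
    benign records carry none."""
    n = annotated_pathogenic.size
    sift = np.empty(n, dtype=object)
    hdiv = np.empty(n, dtype=object)
    hvar = np.empty(n, dtype=object)
    fathmm = np.empty(n, dtype=object)
    clinvar = np.empty(n, dtype=object)
    # evidence pattern: 0 = ClinVar only, 1 = tools only, 2 = both
    pattern = rng.integers(0, 3, size=n)
    tool_mask = rng.random(size=(n, 4)) < 0.6  # which tools fire when tools carry evidence
    no_tool = ~tool_mask.any(axis=1)
    tool_mask[no_tool, 0] = True  # guarantee >=1 damaging tool
    clinvar_path = np.where(rng.random(n) < 0.5, "Pathogenic", "Likely_pathogenic")
    clinvar_benign = rng.choice(["Benign", "VUS", None], size=n, p=[0.4, 0.4, 0.2])
    poly_damaging = np.where(rng.random(n) < 0.5, "D", "P")
    for i in range(n):
        if annotated_pathogenic[i]:
            tools_fire = pattern[i] >= 1
            sift[i] = "D" if tools_fire and tool_mask[i, 0] else "T"
            hdiv[i] = poly_damaging[i] if tools_fire and tool_mask[i, 1] else "B"
            hvar[i] = poly_damaging[i] if tools_fire and tool_mask[i, 2] else "B"
            fathmm[i] = "D" if tools_fire and tool_mask[i, 3] else "T"
            clinvar[i] = clinvar_path[i] if pattern[i] in (0, 2) else "VUS"
        else:
            sift[i], hdiv[i], hvar[i], fathmm[i] = "T", "B", "B", "T"
            clinvar[i] = clinvar_benign[i]
    return pd.DataFrame(
        {
            "sift": sift,
            "polyphen_hdiv": hdiv,
            "polyphen_hvar": hvar,
            "fathmm": fathmm,
            "clinvar": clinvar,
        }
    )


def _generate(config: SyntheticConfig, rng: np.random.Generator, prefix: str) -> SyntheticBundle:
    n = config.n_cancer_types * config.samples_per_type
    sample_ids = pd.Index([f"{prefix}S{i + 1:05d}" for i in range(n)], name="sample_id")
    cancer_types = pd.Series(
        np.repeat([f"CT{i + 1}" for i in range(config.n_cancer_types)], config.samples_per_type),
        index=sample_ids,
        name="cancer_type",
    )
    rates = np.repeat(config.rates, config.samples_per_type)

    # lesion latents, in fixed draw order for determinism
    mutated = rng.random(n) < rates
    pathogenic = mutated & (rng.random(n) < config.pathogenic_fraction)
    amplified = rng.random(n) < config.cnv_rate
    lesion = pathogenic | amplified
    penetrant = rng.random(n) < config.penetrance
    if config.continuous_activation:
        level = np.where(lesion & penetrant, rng.uniform(0.5, 1.0, size=n), 0.0)
    else:
        level = (lesion & penetrant).astype(float)
    active = level > 0

    # gene universe and pathway definition
    pathway_genes = [f"PW_G{i + 1:04d}" for i in range(config.n_pathway_genes)]
    signal_genes = pathway_genes[: config.n_signal_genes]
    background_genes = [f"BG_G{i + 1:04d}" for i in range(config.n_background_genes)]
    driver_genes = [f"DRV{i + 1}" for i in range(config.n_driver_genes)]
    pathway = PathwayDefinition.from_sets("SYN_PATHWAY", driver_genes, pathway_genes)

    genes = pathway_genes + background_genes
    values = rng.normal(0.0, config.expr_noise_sd, size=(len(genes), n))
    values[: config.n_signal_genes] += config.signal_shift * level[np.newaxis, :]
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids),
        cancer_types=cancer_types,
    )

    # driver mutation records (one per mutated sample), then passengers
    mut_idx = np.flatnonzero(mutated)
    driver_choice = rng.integers(0, config.n_driver_genes, size=mut_idx.size)
    driver_vc = rng.choice(["missense", "nonsense", "frameshift"], size=mut_idx.size, p=[0.7, 0.15, 0.15])
    n_passenger = rng.poisson(config.passenger_rate, size=n)
    pass_sample_idx = np.repeat(np.arange(n), n_passenger)
    pass_gene = rng.choice(background_genes, size=pass_sample_idx.size)
    pass_vc = rng.choice(_VC_PASSENGER, size=pass_sample_idx.size)

    rec_sample = np.concatenate([sample_ids.to_numpy()[mut_idx], sample_ids.to_numpy()[pass_sample_idx]])
    rec_gene = np.concatenate([np.asarray(driver_genes, dtype=object)[driver_choice], pass_gene])
    rec_vc = np.concatenate([driver_vc, pass_vc])
    rec_true_path = np.concatenate(
        [pathogenic[mut_idx], np.zeros(pass_sample_idx.size, dtype=bool)]
    )
    flips = rng.random(rec_true_path.size) < config.annotation_error_rate
    annotated = rec_true_path ^ flips
    ann = _draw_annotations(rng, annotated)
    mutations = pd.DataFrame(
        {"sample_id": rec_sample, "gene": rec_gene, "variant_class": rec_vc}
    ).join(ann)
    mutations.index.name = "record_id"
    true_pathogenic = pd.Series(rec_true_path.astype(int), index=mutations.index, name="true_pathogenic")

    # CNV: amplified samples gain one random driver gene; everything else neutral
    amp_gene_choice = rng.integers(0, config.n_driver_genes, size=n)
    cnv_records = []
    for i, sid in enumerate(sample_ids):
        for g_i, gene in enumerate(driver_genes):
            cat = "amplified" if (amplified[i] and g_i == amp_gene_choice[i]) else "neutral"
            cnv_records.append((sid, gene, cat))
    cnv = pd.DataFrame(cnv_records, columns=["sample_id", "gene", "category"])

    # drug response: on-target drugs respond to activation, off-target pure noise
    n_on = int(round(config.on_target_fraction * config.n_drugs))
    drug_ids = [f"drug_{i + 1:03d}" for i in range(config.n_drugs)]
    on_target = drug_ids[:n_on]
    noise = rng.normal(0.0, config.response_noise_sd, size=(config.n_drugs, n))
    resp = noise.copy()
    resp[:n_on] -= config.drug_effect * level[np.newaxis, :]  # lower = more sensitive
    drug_response = pd.DataFrame(
        {
            "sample_id": np.tile(sample_ids.to_numpy(), config.n_drugs),
            "drug_id": np.repeat(drug_ids, n),
            "value": resp.ravel(),
            "metric_kind": config.metric_kind,
            "dataset_tag": "synthetic",
        }
    )

    sample_truth = pd.DataFrame(
        {
            "mutation": mutated.astype(int),
            "pathogenic": pathogenic.astype(int),
            "amplified": amplified.astype(int),
            "activation": active.astype(int),
            "activation_level": level,
            "cancer_type": cancer_types.to_numpy(),
        },
        index=sample_ids,
    )
    return SyntheticBundle(
        expression=expression,
        mutations=mutations,
        cnv=cnv,
        drug_response=drug_response,
        latent_activation=pd.Series(active.astype(int), index=sample_ids, name="activation"),
        true_pathogenic=true_pathogenic,
        pathway_definition=pathway,
        sample_truth=sample_truth,
        on_target_drugs=on_target,
        config=config,
    )


def generate_cohort(config: SyntheticConfig, prefix: str = "") -> SyntheticBundle:
    """Draw one cohort from the generative model.  Identical configs (same
    seed) give bit-identical bundles."""
    rng = np.random.default_rng([config.seed, 0])
    return _generate(config, rng, prefix)


def generate_paired_cohort(
    config: SyntheticConfig,
) -> tuple[SyntheticBundle, SyntheticBundle]:
    """Pre/post-treatment arms emulating paired clinical cohorts.

    The pre-treatment arm is an ordinary cohort draw.  The post-treatment arm
    is an independent draw from the same model in which each activated tumor
    is eliminated with probability ``treatment_selection_strength`` —
    treatment preferentially clears pathway-activated (sensitive) tumors, so
    the post arm's phenocopy-truth rate drops from p to
    (1-s)p / (1 - sp) in expectation.
    """
    s = config.treatment_selection_strength
    pre = _generate(config, np.random.default_rng([config.seed, 0]), "PRE_")
    post_full = _generate(config, np.random.default_rng([config.seed, 1]), "POST_")
    rng_sel = np.random.default_rng([config.seed, 2])
    active = post_full.latent_activation.to_numpy().astype(bool)
    eliminated = active & (rng_sel.random(active.size) < s)
    post = post_full.subset(post_full.samples[~eliminated])
    return pre, post
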