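"""Clinical-cohort analyses: pre/post-treatment phenocopy-rate shift and
responder-stratified response rates, plus CNV enrichment in
phenocopy-without-mutation samples.

Treatment preferentially eliminates pathway-activated (drug-sensitive)
tumors, so the phenocopy rate should drop from the pre-treatment to the
post-treatment (resistant) arm.
"""

from phenocopy import (
    SyntheticConfig,
    call_bundle,
    compare_cnv_rates,
    compare_phenocopy_rates,
    generate_cohort,
    generate_paired_cohort,
    mutation_labels,
    responder_stratified_rates,
    train_from_bundle,
)

signature, _ = train_from_bundle(
    generate_cohort(SyntheticConfig(seed=11)),
    grid=((2, 50), (2, 100), (3, 50), (3, 100)), folds=10, seed=0,
)

clinical_cfg = SyntheticConfig(
    seed=41, n_cancer_types=1, samples_per_type=60, alteration_rate_per_type=0.6,
    pathogenic_fraction=0.9, penetrance=0.9, treatment_selection_strength=0.6,
    n_drugs=1, on_target_fraction=1.0, drug_effect=2.0,
)
pre, post = generate_paired_cohort(clinical_cfg)
pre_calls = call_bundle(signature, pre)["call"]
post_calls = call_bundle(signature, post)["call"]

shift = compare_phenocopy_rates(pre_calls, post_calls)
print(f"phenocopy rate: pre-treatment {shift.rate_a:.1%} ({shift.n_a} samples) -> "
      f"post-treatment {shift.rate_b:.1%} ({shift.n_b} samples)")
print(f"two-proportion chi-square {shift.statistic:.2f}, p = {shift.p_value:.4f}")
print("a lower post-treatment rate is the expected selection signature: "
      "resistant tumors are depleted of phenocopies")

# response among phenocopy-positive vs -negative pre-treatment tumors
resp = (pre.latent_activation.to_numpy() == 1).astype(float)  # activation drives response here
strat = responder_stratified_rates(pre_calls.to_numpy(), resp)
print(f"\nresponse rate: phenocopy-positive {strat.rate_a:.1%} vs "
      f"phenocopy-negative {strat.rate_b:.1%} (Fisher p = {strat.p_value:.3g})")

# CNV mechanism: phenocopy-without-mutation tumors carry pathway CNV
cnv_cohort = generate_cohort(
    SyntheticConfig(seed=42, n_cancer_types=1, samples_per_type=1000,
                    alteration_rate_per_type=0.2, cnv_rate=0.2, penetrance=0.9)
)
cnv_calls = call_bundle(signature, cnv_cohort)["call"]
labels = mutation_labels(cnv_cohort)
cmp = compare_cnv_rates(cnv_calls, labels["any_mutation"], cnv_cohort.cnv,
                        cnv_cohort.pathway_definition)
print(f"\npathway CNV rate: phenocopy-without-mutation {cmp.rate_a:.1%} "
      f"vs all other samples {cmp.rate_b:.1%} (chi-square p = {cmp.p_value:.3g})")
print("the excess explains mechanistically why these samples mimic the "
      "mutant expression state without carrying the mutation")
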