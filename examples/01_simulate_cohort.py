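"""Simulate a pan-cancer training-style cohort and export it as TSV/GMT.

The generator plants a known causal chain — driver mutation or pathway
amplification -> latent pathway activation -> expression shift in signal
genes and sensitivity to on-target drugs — so every later pipeline stage can
be checked against ground truth.
"""

from pathlib import Path

from phenocopy import SyntheticConfig, generate_cohort
from phenocopy.io import write_bundle

config = SyntheticConfig(seed=1)
bundle = generate_cohort(config)
truth = bundle.sample_truth

print(f"cohort: {len(bundle.samples)} samples, "
      f"{bundle.expression.values.shape[0]} genes, "
      f"{bundle.drug_response['drug_id'].nunique()} drugs")
print(f"mutation rate        {truth['mutation'].mean():.3f}   (per-type rates {config.rates})")
print(f"pathogenic rate      {truth['pathogenic'].mean():.3f}   (pathogenic_fraction {config.pathogenic_fraction})")
print(f"amplification rate   {truth['amplified'].mean():.3f}   (cnv_rate {config.cnv_rate})")
print(f"activation rate      {truth['activation'].mean():.3f}   (penetrance {config.penetrance})")
phenocopy_only = ((truth["activation"] == 1) & (truth["mutation"] == 0)).mean()
print(f"phenocopy-without-mutation rate {phenocopy_only:.3f}  "
      "(these are the samples only an expression signature can find)")

out = write_bundle(bundle, Path("scratch") / "example_cohort")
print(f"written to {out}/ (expression.tsv, mutations.tsv, cnv.tsv, drug_response.tsv, pathway.gmt)")
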