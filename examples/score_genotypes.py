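"""Score a VCF against a SNP weight table and classify high/low risk.

Simulates a 5-individual cohort with the packaged synthetic 30-SNP panel,
writes it as a VCF, reads it back, and computes each individual's genetic
risk score: the sum of effect-allele dosages times log10 odds ratios,
divided by the total number of alleles counted.
"""

import tempfile
from pathlib import Path

import numpy as np

from t1dgrs import compute_grs, dosages_from_vcf
from t1dgrs.grs import scores_to_frame
from t1dgrs.simulate import SimulationConfig, simulate_control_genotypes, write_vcf

config = SimulationConfig(seed=7)
rng = np.random.default_rng(7)
genotypes = simulate_control_genotypes(config, n=5, rng=rng, prefix="child")

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "cohort.vcf"
    write_vcf(vcf, genotypes, config.weight_table)
    dosages = dosages_from_vcf(vcf, config.weight_table)

records = compute_grs(dosages, config.weight_table)
print(scores_to_frame(records, threshold=0.10).to_string(index=False))

# grs is a per-allele mean of log10 odds-ratio weights: higher scores mean a
# genotype more typical of type 1 diabetes.  'label' compares each score with
# the supplied threshold (here an arbitrary 0.10; a real analysis uses the
# 95th centile of a control reference).
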