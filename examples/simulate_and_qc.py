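"""Generate a small two-line dataset and push it through genotype QC.

Prints the QC report: how many SNPs each filter removed and what
survived.  The planted 1 % missingness exercises the call-rate,
missingness and imputation steps; the low-MAF column shows the
minor-allele-frequency filter in action.
"""

import numpy as np

from dompred import (
    SimConfig,
    allele_frequencies,
    filter_animals,
    filter_snps,
    impute_most_common,
    simulate_dataset,
)

cfg = SimConfig(
    n_snps=400,
    n_qtl=24,
    n_train_sows_per_line=300,
    n_boars_per_line=40,
    n_daughters_per_boar=20,
    missing_rate=0.01,
    seed=11,
)
ds = simulate_dataset(cfg)
sows = ds.sows["line1"]
sows.codes[:, 5] = 0  # plant a monomorphic SNP so the MAF filter fires

kept, report = filter_snps(sows)
print(f"SNPs in: {report.n_snps_in}")
print(f"  removed, call rate < 90 %   : {report.n_removed_call_rate}")
print(f"  removed, MAF < 1 %          : {report.n_removed_maf}")
print(f"  removed, > 2 % missing      : {report.n_removed_missing}")
print(f"  removed, HWE p < 1e-7       : {report.n_removed_hwe}")
print(f"SNPs out: {report.n_snps_out}")

kept, areport = filter_animals(kept, animal_missing_max=0.10)
print(f"animals removed (> 10 % missing): {areport.n_animals_removed}")

imputed = impute_most_common(kept)
print(f"missing codes after imputation: {(imputed.codes == -1).sum()}")
p = allele_frequencies(imputed).p
print(f"counted-allele frequency range after QC: {p.min():.3f} - {p.max():.3f}")
# Every surviving SNP has MAF >= 1 % and no missing genotypes, so the
# table is ready for model fitting.
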