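"""Validate predictors of crossbred performance on boar progeny means.

Trains MA and MAD on one line's sows, predicts the line's boars three
ways (MA GEBV, MAD GEBV, MAD GEBV-C), and validates each against the
mean phenotype of the boars' simulated crossbred daughters.  Accuracy
is the correlation divided by the average accuracy of an n-daughter
progeny mean, sqrt(n/(n+k)) with k=(4-h2)/h2; the bias slope should be
near 1 for unbiased predictions.
"""

from dompred import (
    BayesCConfig,
    SimConfig,
    allele_frequencies,
    build_designs,
    fit_bayesc,
    gebv_crossbred,
    gebv_ma,
    gebv_mad,
    prediction_accuracy,
    simulate_dataset,
)

cfg = SimConfig(
    n_snps=400,
    n_qtl=24,
    n_train_sows_per_line=1000,
    n_boars_per_line=150,
    n_daughters_per_boar=30,
    line_divergence=0.15,
    seed=6,
)
ds = simulate_dataset(cfg)
sows, boars = ds.sows["line1"], ds.boars["line1"]
y = ds.sow_phenotypes["line1"].values
designs = build_designs(sows)
own = allele_frequencies(sows)
opposite = allele_frequencies(ds.sows["line2"])
progeny = ds.progeny_means["line1"]

mcmc = dict(n_iter=3000, burn_in=600, thin=4)
fit_ma = fit_bayesc(y, designs, "MA", BayesCConfig(seed=1, **mcmc), snp_ids=sows.snp_ids)
fit_mad = fit_bayesc(y, designs, "MAD", BayesCConfig(seed=2, **mcmc), snp_ids=sows.snp_ids)

predictors = {
    "MA  GEBV  ": gebv_ma(boars, fit_ma, own),
    "MAD GEBV  ": gebv_mad(boars, fit_mad, own),
    "MAD GEBV-C": gebv_crossbred(boars, fit_mad, opposite),
}
print(f"validation on {boars.n_animals} boars x {cfg.n_daughters_per_boar} daughters")
print("predictor    accuracy (SE)     bias slope (SE)")
for name, bv in predictors.items():
    rep = prediction_accuracy(bv, progeny, h2=cfg.target_h2_a, n_boot=500, seed=0)
    print(f"{name}  {rep.accuracy:.3f} ({rep.accuracy_se:.3f})   "
          f"{rep.bias_slope:.2f} ({rep.bias_slope_se:.2f})")
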