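# dompred

Genomic prediction of **crossbred** performance from **purebred** training
data, with explicit dominance. The package implements the full analysis
pipeline for a two-line (e.g. Landrace x Yorkshire style) pig breeding
scheme: genotype I/O and quality control, BayesC estimation of additive and
dominance SNP effects, breeding values for purebred and crossbred
performance, genomic variance components by AI-REML, validation against
crossbred progeny means, and a synthetic two-line data generator so that
every stage is testable without proprietary animal data.

## The problem and the models

Pig selection happens in pure lines, but the commercial animal is a cross.
Dominance makes the genetic correlation between purebred and crossbred
performance less than 1, so a boar's best mate-line-specific merit depends
on the allele frequencies of the line it is mated to.

Two marker models are fitted to corrected phenotypes `y` of training sows:

```
MA  : y_i = mu + sum_j X_ij a_j + e_i
MAD : y_i = mu + sum_j X_ij a_j + sum_j Z_ij d_j + e_i
```

with `X_ij` in {0,1,2} counting copies of the counted allele, `Z_ij` the
heterozygosity indicator, and spike-and-slab (BayesC) priors on `a_j`, `d_j`.
From the posterior means, a boar's breeding value is the expected genotypic
value of its offspring under random mating; summed per-genotype terms use the
mate population's allele frequencies `p, q = 1-p`:

| genotype | contribution at one SNP              |
|----------|--------------------------------------|
| AA       | `p a + q d`                          |
| Aa       | `0.5(p-q) a + 0.5 d`                 |
| aa       | `-q a + p d`                         |

With own-line frequencies this is GEBV (purebred merit); with opposite-line
frequencies it is GEBV-C (crossbred merit). With `d = 0` the expression
collapses to `0.5 * sum_j X_ij a_j` minus a constant — so it correlates
perfectly with the familiar reduced form and regresses on it with slope 0.5,
an identity the acceptance script verifies.

Variance components use the breeding-model parameterisation: VanRaden's
`G = W_a W_a' / (2 sum p q)` and the dominance matrix
`D = W_d W_d' / (4 sum p^2 q^2)`, with `sigma2_a, sigma2_d, sigma2_e`
estimated by average-information REML. Validation accuracy is
`corr(GEBV, progeny mean) / mean(sqrt(n/(n+k)))`, `k = (4-h^2)/h^2`.

## Worked example

`examples/` contains one short script per capability. For instance:

```bash
python examples/crossbred_validation.py
```

trains MA and MAD on 1000 simulated sows (400 SNPs, heritability 0.10,
dominance variance 15 % of additive) and validates three predictors of the
same 150 boars against their crossbred daughters' mean phenotypes:

```
validation on 150 boars x 30 daughters
predictor    accuracy (SE)     bias slope (SE)
MA  GEBV    0.546 (0.104)   0.63 (0.14)
MAD GEBV    0.559 (0.107)   0.69 (0.14)
MAD GEBV-C  0.547 (0.108)   0.71 (0.15)
```

Accuracy is the progeny-mean-corrected correlation; a bias slope near 1
means the spread of the breeding values is neither over- nor under-stated.
In a single run of this size the three predictors differ by less than one
bootstrap SE; the systematic ordering (crossbred breeding values predict
crossbred daughters best) emerges when accuracies are averaged over seeds,
which is what the multi-seed acceptance test measures. Other examples cover
QC (`simulate_and_qc.py`), model comparison by DIC and likelihood ratio
(`fit_marker_effects.py`), purebred-vs-crossbred boar rankings
(`breeding_values.py`), and REML/GBLUP (`variance_components.py`).

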