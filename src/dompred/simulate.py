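"""Synthetic two-line pig breeding data with additive and dominance QTL.

The generator emulates the data structure of a two-line crossbreeding
scheme: two purebred lines whose allele frequencies have drifted apart,
training sows with own litter-size-like phenotypes, validation boars
without own records, and crossbred daughters produced by mating each
line's boars to dams of the opposite line.  Phenotypes follow the
genotypic model y = mu + X a + Z d + e at a set of QTL, with effects
rescaled so that the narrow-sense heritability and the
dominance-to-additive variance ratio hit configured targets against
line-1 frequencies under Hardy-Weinberg proportions.

Markers are simulated in linkage equilibrium.  This keeps every
analytic expectation exact (allele-substitution effects, true crossbred
breeding values) at the cost of realism: real SNP panels carry linkage
disequilibrium, which none of the implemented estimators require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .io_genotypes import MISSING, GenotypeTable, PhenotypeTable, SnpMeta
from .qc import AlleleFrequencySet


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic two-line scheme.

    Defaults describe the reference scenario: 5000 markers of which 300
    are QTL, 2000 training sows and 200 validation boars per line, 30
    crossbred daughters per boar, narrow-sense heritability 0.10 with
    dominance variance 15 % of additive variance, moderately diverged
    lines (drift parameter 0.15), and a litter-size-like mean of 15.
    """

    n_snps: int = 5000
    n_qtl: int = 300
    n_train_sows_per_line: int = 2000
    n_boars_per_line: int = 200
    n_daughters_per_boar: int = 30
    target_h2_a: float = 0.10
    dominance_ratio: float = 0.15
    line_divergence: float = 0.15
    mean_dominance_degree: float = 0.5
    dominance_degree_spread: float = 0.5
    missing_rate: float = 0.0
    mu: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_h2_a < 1:
            raise ValueError("target_h2_a must lie in (0, 1)")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        if not 0 <= self.line_divergence < 1:
            raise ValueError("line_divergence must lie in [0, 1)")
        for name in ("dominance_ratio", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TrueEffects:
    """Ground-truth QTL effects and the variance scaling they imply."""

    a: np.ndarray
    d: np.ndarray
    qtl_idx: np.ndarray
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    mu: float


@dataclass
class SyntheticDataset:
    """All pieces of one simulated two-line study."""

    sows: dict[str, GenotypeTable]
    sow_phenotypes: dict[str, PhenotypeTable]
    boars: dict[str, GenotypeTable]
    progeny_means: dict[str, PhenotypeTable]
    freqs: dict[str, AlleleFrequencySet]
    true_effects: TrueEffects
    true_bv_purebred: dict[str, np.ndarray]
    true_bv_crossbred: dict[str, np.ndarray]
    config: SimConfig = field(default=None)  # type: ignore[assignment]

    @property
    def lines(self) -> list[str]:
        return list(self.sows)


def _snp_panel(n_snps: int) -> list[SnpMeta]:
    return [SnpMeta(f"snp{j:06d}", "1", j + 1, "A", "B") for j in range(n_snps)]


def simulate_line_frequencies(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[AlleleFrequencySet, AlleleFrequencySet]:
    """Drifted per-line allele frequencies around shared ancestral values.

    Ancestral p0 ~ Uniform(0.05, 0.95); each line draws p from a Beta
    with mean p0 and variance F p0 (1 - p0), F = ``line_divergence``,
    then clamps to [0.01, 0.99].  E[(p1 - p2)^2] = 2 F p0 q0 per SNP.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    snp_ids = [s.snp_id for s in _snp_panel(config.n_snps)]
    p0 = rng.uniform(0.05, 0.95, size=config.n_snps)
    F = config.line_divergence
    if F == 0.0:
        return (
            AlleleFrequencySet("line1", snp_ids, p0.copy()),
            AlleleFrequencySet("line2", snp_ids, p0.copy()),
        )
    nu = (1.0 - F) / F
    alpha, beta = p0 * nu, (1.0 - p0) * nu
    out = []
    for label in ("line1", "line2"):
        p = np.clip(rng.beta(alpha, beta), 0.01, 0.99)
        out.append(AlleleFrequencySet(label, snp_ids, p))
    return out[0], out[1]


def simulate_genotypes(
    freqs: AlleleFrequencySet,
    n_animals: int,
    missing_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    line_label: Optional[str] = None,
    id_prefix: str = "an",
) -> GenotypeTable:
    """Binomial(2, p) genotypes per SNP (linkage equilibrium), optional missingness."""
    rng = np.random.default_rng(0) if rng is None else rng
    line_label = line_label or freqs.line_label
    codes = rng.binomial(2, freqs.p, size=(n_animals, freqs.p.size)).astype(np.int8)
    if missing_rate > 0.0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = MISSING
    snps = [
        SnpMeta(sid, "1", j + 1, "A", "B") for j, sid in enumerate(freqs.snp_ids)
    ]
    ids = [f"{id_prefix}{i:05d}" for i in range(n_animals)]
    return GenotypeTable(ids, [line_label] * n_animals, snps, codes)


def assign_qtl_effects(
    config: SimConfig,
    freqs_line1: AlleleFrequencySet,
    rng: Optional[np.random.Generator] = None,
) -> TrueEffects:
    """Draw QTL effects and rescale them to the variance targets.

    Raw additive effects are standard normal at ``n_qtl`` random SNPs;
    dominance effects are d = delta * |a| with degree of dominance
    delta ~ Normal(mean_dominance_degree, dominance_degree_spread).
    Both are rescaled so that, against line-1 frequencies under
    Hardy-Weinberg proportions, the additive (breeding-value) variance
    sum 2 p q alpha^2 (alpha = a + d(q - p)) equals 1 in simulation
    units with sigma2_d / sigma2_a = ``dominance_ratio``; the residual
    variance is then set from ``target_h2_a``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_snps
    qtl = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    a = np.zeros(m)
    d = np.zeros(m)
    a[qtl] = rng.normal(size=config.n_qtl)
    if config.dominance_ratio > 0:
        delta = rng.normal(
            config.mean_dominance_degree, config.dominance_degree_spread, size=config.n_qtl
        )
        d[qtl] = delta * np.abs(a[qtl])
        if not np.any(d):
            raise ValueError("dominance_ratio > 0 but all dominance degrees are zero")

    p = freqs_line1.p
    q = 1.0 - p
    twopq = 2.0 * p * q

    def sigma2_ad(c: float) -> tuple[float, float]:
        alpha = a + c * d * (q - p)
        s2a = float((twopq * alpha**2).sum())
        s2d = float(((twopq * c * d) ** 2).sum())
        return s2a, s2d

    if config.dominance_ratio > 0:
        def gap(c: float) -> float:
            s2a, s2d = sigma2_ad(c)
            return s2d - config.dominance_ratio * s2a

        c_hi = 1.0
        while gap(c_hi) < 0:
            c_hi *= 2.0
            if c_hi > 1e6:
                raise ValueError("cannot reach the requested dominance_ratio")
        c = float(optimize.brentq(gap, 0.0, c_hi, xtol=1e-12))
    else:
        c = 0.0
    d *= c
    s2a, s2d = float((twopq * (a + d * (q - p)) ** 2).sum()), float(
        ((twopq * d) ** 2).sum()
    )
    # common factor brings sigma2_a to 1 simulation unit
    scale = 1.0 / np.sqrt(s2a)
    a *= scale
    d *= scale
    s2a, s2d = 1.0, s2d * scale**2
    s2e = s2a / config.target_h2_a - s2a - s2d
    return TrueEffects(a=a, d=d, qtl_idx=qtl, sigma2_a=s2a, sigma2_d=s2d, sigma2_e=s2e, mu=config.mu)


def genotypic_values(table: GenotypeTable, effects: TrueEffects) -> np.ndarray:
    """True genotypic values X a + Z d (no mean, no residual)."""
    X = table.codes.astype(float)
    Z = (table.codes == 1).astype(float)
    return X @ effects.a + Z @ effects.d


def simulate_phenotypes(
    table: GenotypeTable,
    effects: TrueEffects,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> PhenotypeTable:
    """Own-performance phenotypes y = mu + X a + Z d + e."""
    if table.has_missing():
        raise ValueError("genotype table contains missing codes")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    y = effects.mu + genotypic_values(table, effects)
    y = y + rng.normal(scale=np.sqrt(effects.sigma2_e), size=table.n_animals)
    return PhenotypeTable(list(table.animal_ids), y)


def true_crossbred_value(
    boars: GenotypeTable, dam_freqs: AlleleFrequencySet, effects: TrueEffects
) -> np.ndarray:
    """Ground-truth crossbred breeding values.

    Expected offspring genotypic value (up to a constant) when each boar
    is mated at random to dams with the given allele frequencies,
    evaluated from the true effects with the per-genotype contribution
    table also used for estimated breeding values.
    """
    from .gebv import _evaluate

    return _evaluate(boars, dam_freqs.p, effects.a, effects.d)


def true_purebred_value(
    boars: GenotypeTable, own_freqs: AlleleFrequencySet, effects: TrueEffects
) -> np.ndarray:
    """Ground-truth purebred breeding values (own-line mate frequencies)."""
    from .gebv import _evaluate

    return _evaluate(boars, own_freqs.p, effects.a, effects.d)


def simulate_crossbred_progeny_means(
    boars: GenotypeTable,
    dam_freqs: AlleleFrequencySet,
    effects: TrueEffects,
    n_daughters: int,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> PhenotypeTable:
    """Mean daughter phenotype per boar from simulated crossbred daughters.

    Each daughter receives one paternal allele sampled from the boar's
    genotype and one maternal allele drawn Bernoulli(p) from the dam
    line's frequencies; her phenotype follows the genotypic model with a
    fresh residual.  The record stores the daughter count.
    """
    if boars.has_missing():
        raise ValueError("boars must be fully genotyped")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = boars.codes.shape
    means = np.empty(n)
    half = boars.codes.astype(float) / 2.0  # P(paternal allele is counted allele)
    for i in range(n):
        pat = rng.random((n_daughters, m)) < half[i]
        mat = rng.random((n_daughters, m)) < dam_freqs.p
        codes = pat.astype(np.int8) + mat.astype(np.int8)
        X = codes.astype(float)
        Z = (codes == 1).astype(float)
        g = X @ effects.a + Z @ effects.d
        y = effects.mu + g + rng.normal(scale=np.sqrt(effects.sigma2_e), size=n_daughters)
        means[i] = y.mean()
    return PhenotypeTable(
        list(boars.animal_ids), means, np.full(n, n_daughters, dtype=int)
    )


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run the full generator: frequencies, animals, phenotypes, progeny."""
    rng = np.random.default_rng(config.seed)
    f1, f2 = simulate_line_frequencies(config, rng)
    effects = assign_qtl_effects(config, f1, rng)

    sows, sow_phen, boars, progeny = {}, {}, {}, {}
    tbv_p, tbv_c = {}, {}
    freqs = {"line1": f1, "line2": f2}
    for line, own, opp in (("line1", f1, f2), ("line2", f2, f1)):
        sows[line] = simulate_genotypes(
            own,
            config.n_train_sows_per_line,
            config.missing_rate,
            rng,
            line_label=line,
            id_prefix=f"{line}_sow",
        )
        clean = sows[line]
        if config.missing_rate > 0:
            from .qc import impute_most_common

            clean = impute_most_common(sows[line])
        sow_phen[line] = simulate_phenotypes(clean, effects, config, rng)
        boars[line] = simulate_genotypes(
            own, config.n_boars_per_line, 0.0, rng, line_label=line, id_prefix=f"{line}_boar"
        )
        progeny[line] = simulate_crossbred_progeny_means(
            boars[line], opp, effects, config.n_daughters_per_boar, config, rng
        )
        tbv_p[line] = true_purebred_value(boars[line], own, effects)
        tbv_c[line] = true_crossbred_value(boars[line], opp, effects)

    return SyntheticDataset(
        sows=sows,
        sow_phenotypes=sow_phen,
        boars=boars,
        progeny_means=progeny,
        freqs=freqs,
        true_effects=effects,
        true_bv_purebred=tbv_p,
        true_bv_crossbred=tbv_c,
        config=config,
    )
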