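"""Breeding values for purebred and crossbred performance from marker effects.

A boar's genomic breeding value is the expected mean genotypic value of
its offspring.  Under random mating the expectation depends on the
allele frequencies of the mate population, so the same boar has a
purebred breeding value (own-line frequencies) and a crossbred breeding
value (opposite-line frequencies).  With additive SNP effects only, the
frequency dependence collapses to a per-SNP constant and the breeding
value reduces to the familiar sum of code x effect; with dominance
effects it does not, which is what makes a dedicated crossbred breeding
value informative.

Per-genotype contributions for SNP j with counted-allele frequency p
(q = 1 - p) in the mate population, additive effect a and dominance
effect d:

=========  =============================================
genotype   contribution
=========  =============================================
AA (2)     p*a + q*d
Aa (1)     0.5*p*a - 0.5*q*a + 0.5*q*d + 0.5*p*d
aa (0)     -q*a + p*d
=========  =============================================

With d = 0 this is the additive-only form; summed over SNPs it equals
0.5 * sum_j X_ij a_j minus a constant, so it correlates perfectly with
the reduced form and regresses on it with slope one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .bayesc import MarkerEffectPosterior
from .io_genotypes import MISSING, GenotypeTable
from .qc import AlleleFrequencySet


@dataclass
class BreedingValueSet:
    """Per-animal breeding values with their target population and model."""

    animal_ids: list[str]
    values: np.ndarray
    target: Literal["purebred", "crossbred"]
    model: str
    frequency_line: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.animal_ids):
            raise ValueError("one value per animal required")


def _check_alignment(
    table: GenotypeTable,
    effects: MarkerEffectPosterior,
    freqs: AlleleFrequencySet,
) -> None:
    if table.has_missing():
        raise ValueError("genotype table contains missing codes; impute first")
    if effects.a_hat.size != table.n_snps:
        raise ValueError(
            f"effects cover {effects.a_hat.size} SNPs but table has {table.n_snps}"
        )
    if effects.snp_ids is not None and effects.snp_ids != table.snp_ids:
        raise ValueError("SNP order of effects does not match the genotype table")
    if freqs.snp_ids != table.snp_ids:
        raise ValueError("SNP order of frequencies does not match the genotype table")


def _genotype_terms(
    p: np.ndarray, a: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Stack of per-genotype contributions, rows indexed by code 0/1/2."""
    q = 1.0 - p
    t_aa = -q * a + p * d
    t_het = 0.5 * p * a - 0.5 * q * a + 0.5 * q * d + 0.5 * p * d
    t_AA = p * a + q * d
    return np.stack([t_aa, t_het, t_AA])


def _evaluate(table: GenotypeTable, p: np.ndarray, a: np.ndarray, d: np.ndarray) -> np.ndarray:
    terms = _genotype_terms(p, a, d)
    codes = table.codes.astype(np.intp)
    return terms[codes, np.arange(table.n_snps)].sum(axis=1)


def gebv_ma(
    table: GenotypeTable,
    effects: MarkerEffectPosterior,
    freqs: AlleleFrequencySet,
) -> BreedingValueSet:
    """Purebred breeding values from additive effects (model MA form)."""
    _check_alignment(table, effects, freqs)
    values = _evaluate(table, freqs.p, effects.a_hat, np.zeros(table.n_snps))
    return BreedingValueSet(list(table.animal_ids), values, "purebred", "MA", freqs.line_label)


def gebv_mad(
    table: GenotypeTable,
    effects: MarkerEffectPosterior,
    freqs: AlleleFrequencySet,
) -> BreedingValueSet:
    """Purebred breeding values from additive plus dominance effects (MAD)."""
    if effects.d_hat is None:
        raise ValueError("MAD breeding values require dominance effects (d_hat)")
    _check_alignment(table, effects, freqs)
    values = _evaluate(table, freqs.p, effects.a_hat, effects.d_hat)
    return BreedingValueSet(list(table.animal_ids), values, "purebred", "MAD", freqs.line_label)


def gebv_crossbred(
    table: GenotypeTable,
    effects: MarkerEffectPosterior,
    opposite_freqs: AlleleFrequencySet,
    allow_same_line: bool = False,
) -> BreedingValueSet:
    """Crossbred breeding values: MAD form with opposite-line frequencies."""
    if effects.d_hat is None:
        raise ValueError("crossbred breeding values require dominance effects (d_hat)")
    if not allow_same_line and opposite_freqs.line_label in set(table.line_labels):
        raise ValueError(
            f"frequencies are from line {opposite_freqs.line_label!r}, which is the "
            "animals' own line; pass allow_same_line=True to override"
        )
    _check_alignment(table, effects, opposite_freqs)
    values = _evaluate(table, opposite_freqs.p, effects.a_hat, effects.d_hat)
    return BreedingValueSet(
        list(table.animal_ids), values, "crossbred", "MAD", opposite_freqs.line_label
    )


def reduced_form_check(
    table: GenotypeTable,
    effects: MarkerEffectPosterior,
    freqs: AlleleFrequencySet,
) -> tuple[float, float]:
    """Correlation and regression slope between the frequency-weighted
    additive breeding value and its reduced form sum_j X_ij a_j.

    The two differ only by a factor of one half and a constant, so the
    correlation is 1 and the least-squares slope of the former on the
    latter is 0.5.
    """
    _check_alignment(table, effects, freqs)
    full = _evaluate(table, freqs.p, effects.a_hat, np.zeros(table.n_snps))
    reduced = table.codes.astype(float) @ effects.a_hat
    if table.n_animals < 3:
        raise ValueError("need at least 3 animals")
    if np.ptp(reduced) == 0.0 or np.ptp(full) == 0.0:
        raise ValueError("breeding values are constant; correlation undefined")
    corr = float(np.corrcoef(reduced, full)[0, 1])
    xc = reduced - reduced.mean()
    slope = float(xc @ (full - full.mean()) / (xc @ xc))
    return corr, slope
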