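"""Validation of genomic predictions against crossbred progeny means.

A validation boar's record is the mean corrected phenotype of its n
crossbred daughters.  The correlation between breeding values and such
progeny means understates the accuracy of the breeding values because a
finite-daughter mean is itself an imperfect measure of the sire's
genetic merit: its accuracy is sqrt(n / (n + k)) with k = (4 - h^2)/h^2.
Dividing the raw correlation by the average progeny-mean accuracy over
boars gives the reported prediction accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gebv import BreedingValueSet
from .io_genotypes import PhenotypeTable


@dataclass
class ValidationReport:
    raw_correlation: float
    mean_progeny_accuracy: float
    accuracy: float
    accuracy_se: float
    bias_slope: float
    bias_slope_se: float
    n_boars: int


@dataclass
class CvPlan:
    """Seeded k-fold partition plan."""

    n_folds: int = 5
    seed: int = 0


def progeny_mean_accuracy(n, h2: float):
    """Accuracy sqrt(n/(n+k)) of an n-daughter progeny mean, k = (4 - h2)/h2."""
    if h2 <= 0 or h2 > 1:
        raise ValueError("heritability must lie in (0, 1]")
    n = np.asarray(n, dtype=float)
    if (n < 1).any():
        raise ValueError("daughter counts must be >= 1")
    k = (4.0 - h2) / h2
    out = np.sqrt(n / (n + k))
    return float(out) if out.ndim == 0 else out


def _align(gebv: BreedingValueSet, progeny: PhenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = {aid: i for i, aid in enumerate(progeny.animal_ids)}
    missing = [aid for aid in gebv.animal_ids if aid not in pos]
    if missing:
        raise ValueError(f"boars without progeny records: {missing[:5]}")
    idx = [pos[aid] for aid in gebv.animal_ids]
    return gebv.values, progeny.values[idx], progeny.n_daughters[idx]


def bias_regression(progeny: PhenotypeTable, gebv: BreedingValueSet) -> tuple[float, float]:
    """OLS slope (and its SE) of progeny means on breeding values.

    A slope of 1 means the spread of the breeding values is neither
    over- nor under-stated relative to realised progeny performance.
    """
    g, y, _ = _align(gebv, progeny)
    if g.size < 3:
        raise ValueError("need at least 3 boars")
    if np.ptp(g) == 0.0:
        raise ValueError("breeding values are constant; slope undefined")
    xc = g - g.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ (y - y.mean()) / sxx)
    resid = (y - y.mean()) - slope * xc
    dof = g.size - 2
    se = float(np.sqrt((resid @ resid) / dof / sxx))
    return slope, se


def prediction_accuracy(
    gebv: BreedingValueSet,
    progeny: PhenotypeTable,
    h2: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> ValidationReport:
    """Accuracy of breeding values against crossbred progeny means.

    accuracy = corr(GEBV, progeny mean) / mean_i sqrt(n_i/(n_i+k)).
    The SE is a seeded nonparametric bootstrap over boars.
    """
    g, y, nd = _align(gebv, progeny)
    if g.size < 3:
        raise ValueError("need at least 3 boars")
    if (nd < 1).any():
        raise ValueError("all progeny records need n_daughters >= 1")
    acc_n = progeny_mean_accuracy(nd, h2)
    raw = float(np.corrcoef(g, y)[0, 1])
    mean_acc = float(np.mean(acc_n))
    accuracy = raw / mean_acc

    rng = np.random.default_rng(seed)
    n = g.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        gb, yb = g[idx], y[idx]
        if np.ptp(gb) == 0.0 or np.ptp(yb) == 0.0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(gb, yb)[0, 1] / np.mean(acc_n[idx])
    acc_se = float(np.nanstd(boots, ddof=1))

    slope, slope_se = bias_regression(progeny, gebv)
    return ValidationReport(
        raw_correlation=raw,
        mean_progeny_accuracy=mean_acc,
        accuracy=accuracy,
        accuracy_se=acc_se,
        bias_slope=slope,
        bias_slope_se=slope_se,
        n_boars=n,
    )


def kfold_split(animal_ids: list[str], plan: CvPlan) -> np.ndarray:
    """Seeded random k-fold assignment; fold sizes differ by at most one."""
    n = len(animal_ids)
    if n < plan.n_folds:
        raise ValueError(f"{n} animals cannot be split into {plan.n_folds} folds")
    rng = np.random.default_rng(plan.seed)
    folds = np.arange(n) % plan.n_folds
    return folds[rng.permutation(n)]


def top_k_overlap(set_a: BreedingValueSet, set_b: BreedingValueSet, k: int = 50) -> int:
    """Number of animals in the top k of both rankings (ties by animal id)."""
    if set(set_a.animal_ids) != set(set_b.animal_ids):
        raise ValueError("breeding value sets cover different animals")
    n = len(set_a.animal_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} ranked animals")

    def top(s: BreedingValueSet) -> set[str]:
        order = sorted(zip(s.animal_ids, s.values), key=lambda t: (-t[1], t[0]))
        return {aid for aid, _ in order[:k]}

    return len(top(set_a) & top(set_b))
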