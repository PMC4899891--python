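"""SNP and animal quality control with most-common-genotype imputation.

Filters mirror routine genotype QC for SNP-chip data: SNP call rate,
minor allele frequency, per-SNP missingness, a Hardy-Weinberg
equilibrium chi-square test, and per-animal missingness.  All
frequency-based statistics are computed within each line, since allele
frequencies and genotype proportions differ between diverged lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_genotypes import MISSING, GenotypeTable


@dataclass
class AlleleFrequencySet:
    """Per-SNP frequency of the counted allele for one named line."""

    line_label: str
    snp_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != len(self.snp_ids):
            raise ValueError("frequency vector length does not match SNP ids")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p


@dataclass
class QcReport:
    """Counts and SNP/animal id lists for each filter, attribution in filter order."""

    n_snps_in: int = 0
    n_removed_call_rate: int = 0
    n_removed_maf: int = 0
    n_removed_missing: int = 0
    n_removed_hwe: int = 0
    n_animals_removed: int = 0
    n_snps_out: int = 0
    removed_call_rate: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_hwe: list[str] = field(default_factory=list)
    removed_animals: list[str] = field(default_factory=list)


def allele_frequencies(table: GenotypeTable, line: str | None = None) -> AlleleFrequencySet:
    """Counted-allele frequencies from genotype counts, ignoring missing calls.

    With ``line`` given, only animals of that line contribute; the
    returned set is labelled accordingly (or ``"all"``).
    """
    if line is None:
        codes = table.codes
        label = table.line_labels[0] if len(table.lines) == 1 else "all"
    else:
        rows = [i for i, lab in enumerate(table.line_labels) if lab == line]
        if not rows:
            raise ValueError(f"no animals with line label {line!r}")
        codes = table.codes[rows, :]
        label = line
    nonmiss = codes != MISSING
    n_called = nonmiss.sum(axis=0)
    if (n_called == 0).any():
        j = int(np.argmax(n_called == 0))
        raise ValueError(f"SNP {table.snps[j].snp_id}: no non-missing calls")
    counted = np.where(nonmiss, codes, 0).sum(axis=0)
    p = counted / (2.0 * n_called)
    return AlleleFrequencySet(label, table.snp_ids, p)


def hwe_chi2_p(n0: int, n1: int, n2: int) -> float:
    """One-df Pearson chi-square p-value for Hardy-Weinberg proportions.

    Expected counts are p^2, 2pq, q^2 with p estimated from the same
    genotype counts.  Monomorphic SNPs return 1.0 (no test possible).
    """
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("no genotype calls")
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or p == 1.0:
        return 1.0
    exp = np.array([q * q, 2 * p * q, p * p]) * n
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _per_line_rows(table: GenotypeTable) -> dict[str, np.ndarray]:
    labels = np.asarray(table.line_labels)
    return {line: np.flatnonzero(labels == line) for line in table.lines}


def filter_snps(
    table: GenotypeTable,
    call_rate_min: float = 0.90,
    maf_min: float = 0.01,
    missing_max: float = 0.02,
    hwe_p_min: float = 1e-7,
) -> tuple[GenotypeTable, QcReport]:
    """Remove SNPs failing call rate, MAF, missingness or HWE thresholds.

    Removal conditions are strict: call rate < ``call_rate_min``,
    MAF < ``maf_min``, missing fraction > ``missing_max``, HWE
    p < ``hwe_p_min``.  Call rate, missingness and HWE are assessed per
    line and a SNP is removed if any line fails; MAF must fail in every
    line for removal, so SNPs that are merely monomorphic in one line
    survive for a combined-line reference.  Each removed SNP is
    attributed to the first filter (in the order above) that rejects it.
    """
    if table.n_snps == 0 or table.n_animals == 0:
        raise ValueError("empty genotype table")
    rows_by_line = _per_line_rows(table)
    report = QcReport(n_snps_in=table.n_snps)
    keep: list[int] = []
    for j in range(table.n_snps):
        sid = table.snps[j].snp_id
        fail_cr = fail_miss = fail_hwe = False
        maf_fail_lines = 0
        for rows in rows_by_line.values():
            col = table.codes[rows, j]
            n_tot = col.size
            n_called = int((col != MISSING).sum())
            call_rate = n_called / n_tot
            miss_frac = 1.0 - call_rate
            if call_rate < call_rate_min:
                fail_cr = True
            if miss_frac > missing_max:
                fail_miss = True
            if n_called == 0:
                maf_fail_lines += 1
                continue
            n0 = int((col == 0).sum())
            n1 = int((col == 1).sum())
            n2 = int((col == 2).sum())
            p = (2 * n2 + n1) / (2 * n_called)
            if min(p, 1 - p) < maf_min:
                maf_fail_lines += 1
            if hwe_chi2_p(n0, n1, n2) < hwe_p_min:
                fail_hwe = True
        fail_maf = maf_fail_lines == len(rows_by_line)
        if fail_cr:
            report.removed_call_rate.append(sid)
        elif fail_maf:
            report.removed_maf.append(sid)
        elif fail_miss:
            report.removed_missing.append(sid)
        elif fail_hwe:
            report.removed_hwe.append(sid)
        else:
            keep.append(j)
    report.n_removed_call_rate = len(report.removed_call_rate)
    report.n_removed_maf = len(report.removed_maf)
    report.n_removed_missing = len(report.removed_missing)
    report.n_removed_hwe = len(report.removed_hwe)
    report.n_snps_out = len(keep)
    if not keep:
        raise ValueError("all SNPs removed by QC")
    return table.subset_snps(keep), report


def filter_animals(
    table: GenotypeTable, animal_missing_max: float = 0.10
) -> tuple[GenotypeTable, QcReport]:
    """Remove animals whose missing-genotype fraction exceeds the threshold."""
    if table.n_animals == 0:
        raise ValueError("empty genotype table")
    miss_frac = (table.codes == MISSING).mean(axis=1)
    keep = np.flatnonzero(miss_frac <= animal_missing_max)
    report = QcReport(
        n_snps_in=table.n_snps,
        n_snps_out=table.n_snps,
        removed_animals=[table.animal_ids[i] for i in np.flatnonzero(miss_frac > animal_missing_max)],
    )
    report.n_animals_removed = len(report.removed_animals)
    if keep.size == 0:
        raise ValueError("all animals removed by QC")
    return table.subset_animals(keep), report


def impute_most_common(table: GenotypeTable) -> GenotypeTable:
    """Replace missing codes by the modal genotype of the SNP within the line.

    Ties between modal codes are broken toward the lowest code so the
    operation is deterministic; a SNP with no called genotype within a
    line is an error.
    """
    out = table.copy()
    for line, rows in _per_line_rows(out).items():
        block = out.codes[rows, :]
        miss = block == MISSING
        if not miss.any():
            continue
        for j in np.flatnonzero(miss.any(axis=0)):
            col = block[:, j]
            called = col[col != MISSING]
            if called.size == 0:
                raise ValueError(
                    f"SNP {out.snps[j].snp_id}: all genotypes missing in line {line}"
                )
            counts = np.bincount(called, minlength=3)
            modal = int(np.argmax(counts))  # argmax takes lowest code on ties
            col[col == MISSING] = modal
            block[:, j] = col
        out.codes[np.ix_(rows, np.arange(out.n_snps))] = block
    return out
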