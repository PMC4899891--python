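"""Genotype and phenotype containers and their on-disk dialects.

Genotypes are held as additive codes counting copies of a per-SNP
*counted allele*: 0 (homozygous for the other allele), 1 (heterozygous),
2 (homozygous for the counted allele).  Missing genotypes use the
sentinel :data:`MISSING` and must be imputed before any modelling step.

Two text dialects are supported: whitespace-delimited PLINK ``.ped`` /
``.map`` pairs, and an additive-coded TSV with one row per animal.
Crossbred breeding values depend on comparing the *same* counted allele
against two lines' frequencies, so :func:`intersect_panels` harmonises
the counted-allele assignment across tables before any joint analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

MISSING: int = -1
"""Sentinel genotype code for a missing call."""

PLINK_MISSING_ALLELE = "0"


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one biallelic SNP.

    ``counted_allele`` is the allele whose copy number the genotype code
    counts; ``position`` is a 1-based base-pair coordinate carried as
    metadata only.
    """

    snp_id: str
    chromosome: str
    position: int
    counted_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"SNP {self.snp_id}: negative position {self.position}")
        if self.counted_allele == self.other_allele and self.counted_allele != PLINK_MISSING_ALLELE:
            raise ValueError(
                f"SNP {self.snp_id}: counted and other allele are both "
                f"{self.counted_allele!r}"
            )


@dataclass
class GenotypeTable:
    """Animals x SNPs additive genotype codes with per-animal line labels."""

    animal_ids: list[str]
    line_labels: list[str]
    snps: list[SnpMeta]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if n != len(self.animal_ids):
            raise ValueError(f"{len(self.animal_ids)} animal ids but {n} genotype rows")
        if n != len(self.line_labels):
            raise ValueError(f"{len(self.line_labels)} line labels but {n} genotype rows")
        if m != len(self.snps):
            raise ValueError(f"{len(self.snps)} SNP records but {m} genotype columns")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[bad[0], bad[1]]} for animal "
                f"{self.animal_ids[bad[0]]} at SNP {self.snps[bad[1]].snp_id}"
            )

    # -- basic introspection ------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.line_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    # -- subsetting ---------------------------------------------------------
    def subset_animals(self, index: Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(index, dtype=int)
        return GenotypeTable(
            [self.animal_ids[i] for i in idx],
            [self.line_labels[i] for i in idx],
            list(self.snps),
            self.codes[idx, :].copy(),
        )

    def subset_snps(self, index: Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(index, dtype=int)
        return GenotypeTable(
            list(self.animal_ids),
            list(self.line_labels),
            [self.snps[i] for i in idx],
            self.codes[:, idx].copy(),
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            list(self.animal_ids), list(self.line_labels), list(self.snps), self.codes.copy()
        )


@dataclass
class PhenotypeTable:
    """Per-animal corrected phenotypes.

    ``n_daughters`` is 0 for animals with an own record (training sows)
    and the daughter count for progeny-mean records (validation boars).
    """

    animal_ids: list[str]
    values: np.ndarray
    n_daughters: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_daughters is None:
            self.n_daughters = np.zeros(len(self.animal_ids), dtype=int)
        self.n_daughters = np.asarray(self.n_daughters, dtype=int)
        if len(self.animal_ids) != len(set(self.animal_ids)):
            raise ValueError("duplicate animal_id in phenotype table")
        if not (len(self.animal_ids) == self.values.size == self.n_daughters.size):
            raise ValueError("phenotype table columns have unequal lengths")
        if (self.n_daughters < 0).any():
            raise ValueError("n_daughters must be nonnegative")

    def __len__(self) -> int:
        return len(self.animal_ids)


# ---------------------------------------------------------------------------
# PLINK .ped/.map dialect
# ---------------------------------------------------------------------------

def read_plink(ped_path: str | Path, map_path: str | Path) -> GenotypeTable:
    """Read a whitespace-delimited PLINK ``.ped``/``.map`` pair.

    The family-ID column of the ``.ped`` is used as the line label.  The
    counted allele at each SNP is the alphabetically first allele
    observed in the file, so the coding is deterministic; ``0 0``
    genotypes become :data:`MISSING`.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snps_raw: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts[0], parts[1], parts[2], parts[3]
            snps_raw.append((snp_id, chrom, int(pos)))
    m = len(snps_raw)

    animal_ids: list[str] = []
    line_labels: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields for {m} SNPs, "
                    f"got {len(parts)}"
                )
            line_labels.append(parts[0])
            animal_ids.append(parts[1])
            pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            allele_rows.append(pairs)

    n = len(animal_ids)
    codes = np.full((n, m), MISSING, dtype=np.int8)
    snps: list[SnpMeta] = []
    for j, (snp_id, chrom, pos) in enumerate(snps_raw):
        observed = sorted(
            {a for row in allele_rows for a in row[j] if a != PLINK_MISSING_ALLELE}
        )
        if len(observed) > 2:
            raise ValueError(f"SNP {snp_id}: more than 2 alleles observed ({observed})")
        counted = observed[0] if observed else PLINK_MISSING_ALLELE
        other = observed[1] if len(observed) == 2 else PLINK_MISSING_ALLELE
        snps.append(SnpMeta(snp_id, chrom, pos, counted, other))
        for i in range(n):
            a1, a2 = allele_rows[i][j]
            if PLINK_MISSING_ALLELE in (a1, a2):
                continue
            codes[i, j] = (a1 == counted) + (a2 == counted)
    return GenotypeTable(animal_ids, line_labels, snps, codes)


def write_plink(table: GenotypeTable, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a table as a PLINK ``.ped``/``.map`` pair (missing -> ``0 0``)."""
    with open(map_path, "w") as fh:
        for s in table.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    with open(ped_path, "w") as fh:
        for i, (aid, lab) in enumerate(zip(table.animal_ids, table.line_labels)):
            fields = [lab, aid, "0", "0", "0", "-9"]
            for j, s in enumerate(table.snps):
                c = table.codes[i, j]
                if c == MISSING:
                    fields += [PLINK_MISSING_ALLELE, PLINK_MISSING_ALLELE]
                elif c == 2:
                    fields += [s.counted_allele, s.counted_allele]
                elif c == 1:
                    fields += [s.counted_allele, s.other_allele]
                else:
                    fields += [s.other_allele, s.other_allele]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Additive-coded TSV dialect
# ---------------------------------------------------------------------------

def read_additive_matrix(path: str | Path) -> GenotypeTable:
    """Read the additive TSV dialect: ``animal_id line <snp ids...>``, cells 0/1/2/NA.

    Allele labels are not part of this dialect; counted/other alleles are
    set to the placeholders ``A``/``B``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3 or header[0] != "animal_id" or header[1] != "line":
            raise ValueError(f"{path}:1: header must start with 'animal_id line'")
        snp_ids = header[2:]
        animal_ids, line_labels, rows = [], [], []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            animal_ids.append(parts[0])
            line_labels.append(parts[1])
            row = np.empty(len(snp_ids), dtype=np.int8)
            for j, cell in enumerate(parts[2:]):
                if cell == "NA":
                    row[j] = MISSING
                elif cell in ("0", "1", "2"):
                    row[j] = int(cell)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: invalid cell {cell!r} in column {snp_ids[j]}"
                    )
            rows.append(row)
    snps = [SnpMeta(sid, "0", 0, "A", "B") for sid in snp_ids]
    return GenotypeTable(animal_ids, line_labels, snps, np.array(rows, dtype=np.int8))


def write_additive_matrix(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tline\t" + "\t".join(table.snp_ids) + "\n")
        for i, (aid, lab) in enumerate(zip(table.animal_ids, table.line_labels)):
            cells = [
                "NA" if c == MISSING else str(int(c)) for c in table.codes[i, :]
            ]
            fh.write(f"{aid}\t{lab}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Phenotype TSV
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV with columns ``animal_id value n_daughters``."""
    path = Path(path)
    animal_ids, values, n_daughters = [], [], []
    with open(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["animal_id", "value", "n_daughters"]:
            raise ValueError(f"{path}:1: expected header 'animal_id value n_daughters'")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            animal_ids.append(parts[0])
            values.append(float(parts[1]))
            n_daughters.append(int(parts[2]))
    return PhenotypeTable(animal_ids, np.array(values), np.array(n_daughters))


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tvalue\tn_daughters\n")
        for aid, v, nd in zip(table.animal_ids, table.values, table.n_daughters):
            fh.write(f"{aid}\t{v:.10g}\t{int(nd)}\n")


# ---------------------------------------------------------------------------
# Panel intersection and allele harmonisation
# ---------------------------------------------------------------------------

def _flip_snp(table: GenotypeTable, j: int) -> None:
    """Swap counted/other allele of SNP j in place, flipping codes 0<->2."""
    s = table.snps[j]
    table.snps[j] = replace(s, counted_allele=s.other_allele, other_allele=s.counted_allele)
    col = table.codes[:, j]
    nonmiss = col != MISSING
    col[nonmiss] = 2 - col[nonmiss]


def intersect_panels(tables: Sequence[GenotypeTable]) -> list[GenotypeTable]:
    """Restrict tables to their shared SNPs with one consistent counted allele.

    The shared SNPs keep the order they have in the first table.  For
    each shared SNP the target counted allele is the alphabetically
    first allele among the counted alleles the tables assigned (missing
    placeholders ignored); tables whose counted allele differs have
    their codes flipped 0<->2.  Allele frequency content is untouched:
    the frequency of the new counted allele equals 1 minus the old one.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to intersect")
    shared_set = set(tables[1].snp_ids)
    for t in tables[2:]:
        shared_set &= set(t.snp_ids)
    shared = [sid for sid in tables[0].snp_ids if sid in shared_set]
    if not shared:
        raise ValueError("no SNPs shared across all tables")

    out: list[GenotypeTable] = []
    for t in tables:
        pos = {sid: j for j, sid in enumerate(t.snp_ids)}
        out.append(t.subset_snps([pos[sid] for sid in shared]))

    for j, sid in enumerate(shared):
        counted = [
            t.snps[j].counted_allele
            for t in out
            if t.snps[j].counted_allele != PLINK_MISSING_ALLELE
        ]
        observed = set()
        for t in out:
            s = t.snps[j]
            observed.update(a for a in (s.counted_allele, s.other_allele) if a != PLINK_MISSING_ALLELE)
        if len(observed) > 2:
            raise ValueError(f"SNP {sid}: incompatible alleles across tables ({sorted(observed)})")
        if not counted:
            continue
        target = min(counted)
        for t in out:
            s = t.snps[j]
            if s.counted_allele not in (target, PLINK_MISSING_ALLELE) :
                _flip_snp(t, j)
            elif s.counted_allele == PLINK_MISSING_ALLELE and len(observed) == 2:
                # fully missing column in this table: adopt the shared labels
                other = (observed - {target}).pop()
                t.snps[j] = replace(s, counted_allele=target, other_allele=other)
    return out
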