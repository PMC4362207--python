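"""Labeled-matrix containers and the tab-separated dialect used throughout.

All matrices are features x individuals (strains): one header row of strain
ids, one leading column of feature ids, decimal cells, ``NA`` (or empty) for
missing.  Genotypes additionally carry per-variant chromosome and physical
position and are coded 0/1 for the two parental alleles of a homozygous
recombinant inbred panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

MISSING_TOKENS = ("NA", "")

#: default parental-allele coding for BXD-style genotype files
DEFAULT_ALLELE_MAP: Mapping[str, float] = {"B": 0.0, "D": 1.0, "0": 0.0, "1": 1.0}


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files (duplicates, ragged rows, bad cells)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise MatrixFormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class LabeledMatrix:
    """A real-valued matrix with unique row and column identifiers.

    ``values`` is a float array; missing entries are NaN.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} col ids"
            )
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]

    def subset_rows(self, keep: Sequence[str]) -> "LabeledMatrix":
        idx = [self.row_ids.index(r) for r in keep]
        return LabeledMatrix(self.values[idx], [self.row_ids[i] for i in idx], list(self.col_ids))

    def subset_cols(self, keep: Sequence[str]) -> "LabeledMatrix":
        idx = [self.col_ids.index(c) for c in keep]
        return LabeledMatrix(self.values[:, idx], list(self.row_ids), [self.col_ids[i] for i in idx])


@dataclass
class VariantTable:
    """Biallelic genotypes (values 0, 1, or missing) with genomic coordinates.

    Variants are kept sorted by (chromosome, position_bp); the consecutive-run
    order used by the interval constraint of stage I is the row order here.
    """

    variant_ids: list[str]
    chromosome: list[str]
    position_bp: list[int]
    genotypes: LabeledMatrix

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        if not (len(self.chromosome) == len(self.position_bp) == n):
            raise ValueError("variant metadata lengths disagree")
        if self.genotypes.row_ids != list(self.variant_ids):
            raise ValueError("genotype row ids must equal variant_ids")
        if any(p <= 0 for p in self.position_bp):
            raise ValueError("position_bp must be positive (1-based)")
        vals = self.genotypes.values
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype value {vals[tuple(bad)]!r} at variant "
                f"{self.variant_ids[bad[0]]!r} is not 0/1/missing"
            )
        order = sorted(range(n), key=lambda i: (self.chromosome[i], self.position_bp[i]))
        if order != list(range(n)):
            self.variant_ids = [self.variant_ids[i] for i in order]
            self.chromosome = [self.chromosome[i] for i in order]
            self.position_bp = [self.position_bp[i] for i in order]
            self.genotypes = LabeledMatrix(
                self.genotypes.values[order], list(self.variant_ids), list(self.genotypes.col_ids)
            )
        for i in range(1, n):
            if self.chromosome[i] == self.chromosome[i - 1] and self.position_bp[i] <= self.position_bp[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on chromosome {self.chromosome[i]!r} "
                    f"near {self.variant_ids[i]!r}"
                )

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def subset_cols(self, keep: Sequence[str]) -> "VariantTable":
        return VariantTable(
            list(self.variant_ids), list(self.chromosome), list(self.position_bp), self.genotypes.subset_cols(keep)
        )


@dataclass
class AlignedDataset:
    """Genotype, expression, and trait matrices over one ordered strain list."""

    genotypes: VariantTable
    expression: LabeledMatrix
    traits: LabeledMatrix
    strains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strains:
            self.strains = list(self.expression.col_ids)
        for m in (self.genotypes.genotypes, self.expression, self.traits):
            if m.col_ids != self.strains:
                raise ValueError("all matrices must share the same ordered strain list")

    @property
    def n_strains(self) -> int:
        return len(self.strains)


def _parse_rows(path: Path, missing_tokens: Sequence[str]) -> tuple[list[str], list[str], np.ndarray]:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    _check_unique(col_ids, "column")
    row_ids: list[str] = []
    data = np.empty((len(lines) - 1, len(col_ids)), dtype=float)
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(col_ids) + 1:
            raise MatrixFormatError(
                f"{path}:{lineno}: expected {len(col_ids) + 1} fields, found {len(fields)}"
            )
        row_ids.append(fields[0])
        for j, cell in enumerate(fields[1:]):
            if cell in missing_tokens:
                data[lineno - 2, j] = np.nan
            else:
                try:
                    data[lineno - 2, j] = float(cell)
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {col_ids[j]!r}"
                    ) from None
    _check_unique(row_ids, "row")
    return row_ids, col_ids, data


def read_matrix_tsv(
    path: str | Path,
    rows_are_features: bool = True,
    missing_tokens: Sequence[str] = MISSING_TOKENS,
) -> LabeledMatrix:
    """Read a labeled TSV matrix (GeneNetwork-style export).

    With ``rows_are_features=False`` the file is transposed on read so that
    rows of the result are always features and columns are strains.
    """
    row_ids, col_ids, data = _parse_rows(Path(path), missing_tokens)
    if not rows_are_features:
        row_ids, col_ids, data = col_ids, row_ids, data.T
    return LabeledMatrix(data, row_ids, col_ids)


def write_matrix_tsv(m: LabeledMatrix, path: str | Path, precision: int = 12) -> None:
    """Write the TSV dialect back out; round-trips at ``precision`` significant digits."""
    fmt = f"%.{precision}g"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["id", *m.col_ids]) + "\n")
        for rid, row in zip(m.row_ids, m.values):
            cells = ["NA" if np.isnan(v) else fmt % v for v in row]
            fh.write("\t".join([rid, *cells]) + "\n")


def read_variant_tsv(
    path: str | Path,
    allele_map: Mapping[str, float] = DEFAULT_ALLELE_MAP,
) -> VariantTable:
    """Read a variant metadata TSV: variant_id, chromosome, position_bp, then strains.

    Allele tokens are mapped through ``allele_map``; heterozygous or unknown
    tokens become missing.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:3] != ["variant_id", "chromosome", "position_bp"]:
        raise MatrixFormatError(
            f"{path}: header must start with variant_id, chromosome, position_bp; got {header[:3]}"
        )
    strains = header[3:]
    _check_unique(strains, "strain")
    variant_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise MatrixFormatError(f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}")
        variant_ids.append(fields[0])
        chrom.append(fields[1])
        try:
            pos.append(int(fields[2]))
        except ValueError:
            raise MatrixFormatError(f"{path}:{lineno}: bad position_bp {fields[2]!r}") from None
        rows.append([allele_map.get(tok, np.nan) for tok in fields[3:]])
    _check_unique(variant_ids, "variant")
    geno = LabeledMatrix(np.array(rows, dtype=float), variant_ids, strains)
    return VariantTable(variant_ids, chrom, pos, geno)


def write_variant_tsv(vt: VariantTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["variant_id", "chromosome", "position_bp", *vt.genotypes.col_ids]) + "\n")
        for vid, c, p, row in zip(vt.variant_ids, vt.chromosome, vt.position_bp, vt.genotypes.values):
            cells = ["NA" if np.isnan(v) else "%d" % v for v in row]
            fh.write("\t".join([vid, c, str(p), *cells]) + "\n")
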