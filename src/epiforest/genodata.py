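"""Genotype matrices, phenotype labels, and vertical (column-wise) partitioning.

Genotypes are stored as small ordinal integers — the additive encoding maps a
bi-allelic genotype to its alternate-allele count (0/0 -> 0, 0/1 -> 1,
1/1 -> 2).  The matrix is held Fortran-ordered so that any single variant's
column is a contiguous, allocation-free view: tree induction is entirely
column-driven, and the column is the unit of data distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeDataError",
    "GenotypeMatrix",
    "PhenotypeVector",
    "ColumnBlock",
    "MISSING_AS_REF",
    "MISSING_AS_MODE",
    "read_vcf",
    "read_csv_matrix",
    "read_labels",
    "write_csv_matrix",
    "write_vcf",
    "write_labels",
    "partition",
    "reassemble",
]


class GenotypeDataError(ValueError):
    """Raised for malformed genotype or phenotype inputs."""


#: Missing genotypes are encoded as homozygous reference (0).
MISSING_AS_REF = "ref"
#: Missing genotypes are imputed with the per-variant modal genotype.
MISSING_AS_MODE = "mode"


@dataclass
class GenotypeMatrix:
    """Columnar store of ``n_samples x n_variants`` ordinal genotypes.

    Parameters
    ----------
    values
        Integer array of shape ``(n_samples, n_variants)`` with entries in
        ``{0, ..., n_levels - 1}``.  Converted to a Fortran-ordered ``int8``
        array so column access is a contiguous view.
    variant_ids, sample_ids
        Ordered, unique identifiers for columns and rows.
    n_levels
        Number of ordinal levels a genotype may take (3 for the additive
        bi-allelic encoding).
    """

    values: np.ndarray
    variant_ids: tuple
    sample_ids: tuple
    n_levels: int = 3

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise GenotypeDataError("genotype values must be a 2-D array")
        if not np.issubdtype(vals.dtype, np.integer):
            raise GenotypeDataError("genotype values must be integers")
        vals = np.asfortranarray(vals, dtype=np.int8)
        self.values = vals
        self.variant_ids = tuple(str(v) for v in self.variant_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        n_s, n_v = vals.shape
        if len(self.variant_ids) != n_v:
            raise GenotypeDataError(
                f"{len(self.variant_ids)} variant ids for {n_v} columns"
            )
        if len(self.sample_ids) != n_s:
            raise GenotypeDataError(
                f"{len(self.sample_ids)} sample ids for {n_s} rows"
            )
        if len(set(self.variant_ids)) != n_v:
            raise GenotypeDataError("duplicate variant ids")
        if len(set(self.sample_ids)) != n_s:
            raise GenotypeDataError("duplicate sample ids")
        if n_s == 0:
            raise GenotypeDataError("no samples")
        if n_v and (vals.min() < 0 or vals.max() >= self.n_levels):
            raise GenotypeDataError(
                f"genotypes must lie in 0..{self.n_levels - 1}"
            )
        self._variant_index: dict[str, int] = {
            v: j for j, v in enumerate(self.variant_ids)
        }

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> np.ndarray:
        """Contiguous view of variant ``j``'s genotype vector (no copy)."""
        return self.values[:, j]

    def variant_index(self, variant_id: str) -> int:
        return self._variant_index[variant_id]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.values),
            index=list(self.sample_ids),
            columns=list(self.variant_ids),
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, n_levels: int = 3) -> "GenotypeMatrix":
        return cls(
            values=frame.to_numpy(),
            variant_ids=tuple(frame.columns),
            sample_ids=tuple(frame.index),
            n_levels=n_levels,
        )


@dataclass
class PhenotypeVector:
    """Per-sample class labels, encoded as indices into ``class_names``."""

    labels: np.ndarray
    class_names: tuple
    sample_ids: tuple | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 1:
            raise GenotypeDataError("labels must be 1-D")
        self.labels = labels
        self.class_names = tuple(str(c) for c in self.class_names)
        k = len(self.class_names)
        if k == 0:
            raise GenotypeDataError("at least one class required")
        if labels.size and (labels.min() < 0 or labels.max() >= k):
            raise GenotypeDataError("label index out of range")
        if self.sample_ids is not None:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
            if len(self.sample_ids) != labels.size:
                raise GenotypeDataError("sample ids do not match label length")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def require_trainable(self) -> None:
        """Raise unless at least two classes are actually present."""
        if np.unique(self.labels).size < 2:
            raise GenotypeDataError(
                "training requires at least 2 distinct classes in the labels"
            )


@dataclass
class ColumnBlock:
    """A contiguous span ``[lo, hi)`` of variant columns owned by one worker.

    Blocks tile ``[0, n_variants)`` exactly once; membership of a global
    variant index is computable from the span alone, no lookup table needed.
    """

    block_index: int
    lo: int
    hi: int
    matrix: GenotypeMatrix = field(repr=False)

    @property
    def values(self) -> np.ndarray:
        """View (not copy) of the owned columns."""
        return self.matrix.values[:, self.lo : self.hi]

    @property
    def n_variants(self) -> int:
        return self.hi - self.lo

    def owns(self, variant_index: int) -> bool:
        return self.lo <= variant_index < self.hi


# ---------------------------------------------------------------------------
# readers / writers


def _resolve_missing(column: np.ndarray, missing: np.ndarray, policy: str) -> None:
    if not missing.any():
        return
    if policy == MISSING_AS_REF:
        column[missing] = 0
    elif policy == MISSING_AS_MODE:
        observed = column[~missing]
        if observed.size == 0:
            column[missing] = 0
        else:
            counts = np.bincount(observed, minlength=3)
            column[missing] = int(np.argmax(counts))  # ties -> smaller genotype
    else:
        raise GenotypeDataError(f"unknown missing-genotype policy: {policy!r}")


def read_vcf(path: str | Path, missing_policy: str = MISSING_AS_REF) -> GenotypeMatrix:
    """Load a VCF of bi-allelic records into the additive {0,1,2} encoding.

    GT fields map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; phase separators are
    ignored.  Variant ids are formed as ``chrom:pos:ref:alt``.  Multi-allelic
    records are rejected: split them upstream (e.g. ``bcftools norm -m-``)
    before loading.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = tuple(vcf.samples)
    if not sample_ids:
        raise GenotypeDataError("VCF has no samples")
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeDataError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}: split into "
                "bi-allelic records upstream (e.g. bcftools norm -m-) first"
            )
        # gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=missing/unknown
        g = rec.gt_types.astype(np.int8)
        if g.size != len(sample_ids):
            raise GenotypeDataError(
                f"malformed GT at record {rec.CHROM}:{rec.POS}"
            )
        _resolve_missing(g, g == 3, missing_policy)
        columns.append(g)
        variant_ids.append(f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}")
    if not columns:
        raise GenotypeDataError("VCF contains no variant records")
    values = np.asfortranarray(np.stack(columns, axis=1))
    return GenotypeMatrix(values, tuple(variant_ids), sample_ids)


def read_csv_matrix(path: str | Path, n_levels: int = 3) -> GenotypeMatrix:
    """Load a genotype CSV: header row of variant ids, first column sample ids.

    Cells must be integers in ``{0, ..., n_levels-1}``; ragged rows, missing
    or non-integer cells, and duplicate ids are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    if not header_line:
        raise GenotypeDataError(f"{path}: empty file")
    header = header_line.split(",")
    variant_ids = tuple(h.strip() for h in header[1:])
    if len(set(variant_ids)) != len(variant_ids):
        raise GenotypeDataError(f"{path}: duplicate variant id in header")
    try:
        frame = pd.read_csv(path, index_col=0, header=0)
    except pd.errors.ParserError as exc:
        raise GenotypeDataError(f"{path}: ragged or malformed rows: {exc}") from exc
    if frame.shape[0] == 0:
        raise GenotypeDataError(f"{path}: no samples")
    if frame.isna().to_numpy().any():
        raise GenotypeDataError(f"{path}: ragged rows or missing cells")
    vals = frame.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        try:
            fvals = vals.astype(float)
        except (ValueError, TypeError) as exc:
            raise GenotypeDataError(f"{path}: non-integer genotype cells") from exc
        if not np.all(fvals == np.round(fvals)):
            raise GenotypeDataError(f"{path}: non-integer genotype cells")
        vals = fvals.astype(np.int64)
    if vals.size and (vals.min() < 0 or vals.max() >= n_levels):
        raise GenotypeDataError(
            f"{path}: genotype values outside 0..{n_levels - 1}"
        )
    return GenotypeMatrix(
        vals, variant_ids, tuple(str(s) for s in frame.index), n_levels=n_levels
    )


def write_csv_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, index_label="sample")


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal bi-allelic VCF.

    Variant ids of the form ``chrom:pos:ref:alt`` are decomposed back into
    VCF fields; other ids are written on synthetic coordinates (chrom "1",
    consecutive positions, REF=A, ALT=G) with the id preserved in the ID
    column.
    """
    gt_strings = ("0/0", "0/1", "1/1")
    if matrix.n_levels != 3:
        raise GenotypeDataError("VCF output requires the {0,1,2} encoding")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(matrix.variant_ids):
            parts = vid.split(":")
            if len(parts) == 4 and parts[1].isdigit():
                chrom, pos, ref, alt = parts
                ident = "."
            else:
                chrom, pos, ref, alt = "1", str(j + 1), "A", "G"
                ident = vid
            gts = "\t".join(gt_strings[g] for g in matrix.column(j))
            fh.write(f"{chrom}\t{pos}\t{ident}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def read_labels(path: str | Path, samples: Sequence[str]) -> PhenotypeVector:
    """Read a two-column ``sample,label`` CSV and align it to ``samples``.

    Class names are the sorted distinct labels, mapped to ``0..K-1``.
    Samples in the file but not in ``samples`` are dropped with a warning;
    samples missing from the file are an error.
    """
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[1] < 2:
        raise GenotypeDataError(f"{path}: expected two columns (sample,label)")
    frame = frame.iloc[:, :2]
    frame.columns = ["sample", "label"]
    if frame["sample"].duplicated().any():
        raise GenotypeDataError(f"{path}: duplicate sample ids")
    mapping = dict(zip(frame["sample"], frame["label"]))
    samples = [str(s) for s in samples]
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise GenotypeDataError(
            f"{path}: no label for sample(s) {', '.join(missing[:5])}"
        )
    extra = set(mapping) - set(samples)
    if extra:
        logger.warning(
            "%s: dropping %d labelled sample(s) absent from the genotype data",
            path,
            len(extra),
        )
    raw = [mapping[s] for s in samples]
    class_names = tuple(sorted(set(raw)))
    index = {c: i for i, c in enumerate(class_names)}
    labels = np.array([index[r] for r in raw], dtype=np.int64)
    return PhenotypeVector(labels, class_names, sample_ids=tuple(samples))


def write_labels(phenotype: PhenotypeVector, path: str | Path) -> None:
    if phenotype.sample_ids is None:
        raise GenotypeDataError("phenotype has no sample ids to write")
    frame = pd.DataFrame(
        {
            "sample": list(phenotype.sample_ids),
            "label": [phenotype.class_names[i] for i in phenotype.labels],
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# partitioning


def partition(matrix: GenotypeMatrix, n_blocks: int) -> list[ColumnBlock]:
    """Split the variant axis into contiguous, near-equal column blocks.

    Block sizes differ by at most one, with the larger blocks first, so the
    layout is fully determined by ``(n_variants, n_blocks)``.
    """
    n_v = matrix.n_variants
    if not 1 <= n_blocks <= n_v:
        raise GenotypeDataError(
            f"n_blocks must be in 1..{n_v}, got {n_blocks}"
        )
    base, rem = divmod(n_v, n_blocks)
    blocks = []
    lo = 0
    for b in range(n_blocks):
        hi = lo + base + (1 if b < rem else 0)
        blocks.append(ColumnBlock(b, lo, hi, matrix))
        lo = hi
    return blocks


def reassemble(blocks: Sequence[ColumnBlock]) -> np.ndarray:
    """Concatenate blocks in order; equals the unpartitioned values exactly."""
    ordered = sorted(blocks, key=lambda b: b.block_index)
    return np.concatenate([np.asarray(b.values) for b in ordered], axis=1)
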