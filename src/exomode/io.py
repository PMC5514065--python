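"""Data model, matrix/annotation readers, filters, and normalization.

Exon-level expression matrices arrive as TSV with UCSC-style row ids
("chr1:100-200", 1-based inclusive as displayed); internally coordinates
are 0-based half-open.  Expression values are RPKM-like non-negative
reals.  Normalization follows the median-adjust-then-log convention:
each sample is divided by its median exon value (so the per-sample
median becomes 1) and then transformed ``x -> log2(1 + c * x)`` with a
scale constant ``c`` (1023 for deep cohorts, 127 for shallow ones), so
that the sample median maps exactly to ``log2(1 + c)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExonRecord",
    "ExonExpressionMatrix",
    "NormalizationConfig",
    "read_exon_matrix",
    "write_exon_matrix",
    "read_gtf_exons",
    "read_bed_exons",
    "map_exons_to_genes",
    "filter_unexpressed_exons",
    "filter_low_median_samples",
    "normalize_log",
    "read_sample_classes",
    "write_sample_classes",
]

_EXON_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class ExonRecord:
    """One exon: displayed id, genomic interval, and (optional) gene.

    ``start``/``end`` are 0-based half-open; the displayed ``exon_id`` is
    1-based inclusive, so ``chr1:100-200`` has ``start=99, end=200``.
    """

    exon_id: str
    chrom: str
    start: int
    end: int
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.exon_id}: start must be < end")

    @classmethod
    def from_id(cls, exon_id: str, gene_id: str | None = None) -> "ExonRecord":
        m = _EXON_ID_RE.match(exon_id)
        if m is None:
            raise ValueError(f"malformed exon id {exon_id!r} (expected 'chrom:start-end')")
        start1 = int(m.group("start"))
        end1 = int(m.group("end"))
        return cls(
            exon_id=exon_id,
            chrom=m.group("chrom"),
            start=start1 - 1,
            end=end1,
            gene_id=gene_id,
        )

    def format_id(self) -> str:
        """Round-trips: 0-based half-open back to 1-based inclusive display."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class ExonExpressionMatrix:
    """Exons x samples expression values plus coordinates and gene map.

    ``values`` is a DataFrame indexed by exon_id with sample columns;
    ``scale_state`` is ``"raw"`` (RPKM-like) or ``"normalized_log"``.
    """

    exons: tuple[ExonRecord, ...]
    values: pd.DataFrame
    scale_state: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_state not in ("raw", "normalized_log"):
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        ids = [e.exon_id for e in self.exons]
        if list(self.values.index) != ids:
            raise ValueError("exon order of records and values disagree")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")

    @property
    def exon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> pd.Series:
        return pd.Series(
            [e.gene_id for e in self.exons], index=self.values.index, name="gene_id"
        )

    def subset_exons(self, keep: Sequence[str]) -> "ExonExpressionMatrix":
        keep_set = set(keep)
        exons = tuple(e for e in self.exons if e.exon_id in keep_set)
        return ExonExpressionMatrix(
            exons=exons,
            values=self.values.loc[[e.exon_id for e in exons]],
            scale_state=self.scale_state,
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExonExpressionMatrix":
        return ExonExpressionMatrix(
            exons=self.exons, values=self.values[list(keep)], scale_state=self.scale_state
        )


@dataclass(frozen=True)
class NormalizationConfig:
    """Scale constant of the log transform: log2(1 + scale_constant * x)."""

    scale_constant: float = 1023.0

    def __post_init__(self) -> None:
        if not self.scale_constant > 0:
            raise ValueError("scale_constant must be positive")


def read_exon_matrix(path, id_column: str = "exon_id") -> ExonExpressionMatrix:
    """Read a TSV expression matrix (header: id column + sample ids).

    Rejects duplicate exon ids, negative values, and non-numeric cells
    (including the "." placeholder some tools emit).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if id_column not in df.columns:
        if df.columns[0] != id_column:
            raise ValueError(f"id column {id_column!r} not found in {path}")
    df = df.set_index(id_column)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate exon id {dup[0]!r} in {path}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at exon {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(f"missing value at exon {values.index[r]!r}, sample {values.columns[c]!r}")
    neg = values.to_numpy() < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ValueError(
            f"negative value {values.iat[r, c]} at exon {values.index[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    exons = tuple(ExonRecord.from_id(eid) for eid in values.index)
    return ExonExpressionMatrix(exons=exons, values=values.astype(float), scale_state="raw")


def write_exon_matrix(matrix: ExonExpressionMatrix, path) -> None:
    """Write back in the input dialect (TSV, id column 'exon_id')."""
    out = matrix.values.copy()
    out.index.name = "exon_id"
    out.to_csv(path, sep="\t")


def read_gtf_exons(path) -> pd.DataFrame:
    """Extract exon intervals + gene ids from a GTF2.2 file.

    Returns a DataFrame with columns chrom, start, end (0-based half-open),
    gene_id, strand.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("exon"):
        gene = feat.attributes.get("gene_id", [None])[0]
        if gene is None:
            continue
        # gffutils keeps GFF 1-based inclusive coordinates
        rows.append((feat.seqid, feat.start - 1, feat.end, gene, feat.strand or "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


def read_bed_exons(path) -> pd.DataFrame:
    """Read BED6+1 annotation (7th column = gene_id); BED is 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 7:
        raise ValueError("BED annotation needs 7 columns (BED6 + gene_id)")
    out = df.iloc[:, [0, 1, 2, 6]].copy()
    out.columns = ["chrom", "start", "end", "gene_id"]
    out["strand"] = df.iloc[:, 5] if df.shape[1] > 5 else "."
    out["chrom"] = out["chrom"].astype(str)
    return out


def read_annotation(path) -> pd.DataFrame:
    """Dispatch on extension: .gtf/.gff -> GTF parser, .bed -> BED parser."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gtf", ".gff", ".gff2"):
        return read_gtf_exons(path)
    if suffix == ".bed":
        return read_bed_exons(path)
    raise ValueError(f"unrecognized annotation format {suffix!r}")


def map_exons_to_genes(
    matrix: ExonExpressionMatrix, annotation: pd.DataFrame
) -> ExonExpressionMatrix:
    """Assign each exon to the overlapping annotated gene; drop unmapped exons.

    Ambiguity rule: the gene with maximal base-pair overlap wins; ties break
    lexicographically by gene_id.  Strand is ignored.  Raises if no exon can
    be mapped (almost always a coordinate-convention mismatch).
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in annotation.groupby("chrom"):
        t = IntervalTree()
        for start, end, gene in zip(grp["start"], grp["end"], grp["gene_id"]):
            if end > start:
                t.addi(int(start), int(end), str(gene))
        trees[str(chrom)] = t

    mapped: list[ExonRecord] = []
    for exon in matrix.exons:
        tree = trees.get(exon.chrom)
        if tree is None:
            continue
        best: tuple[int, str] | None = None
        for iv in tree.overlap(exon.start, exon.end):
            ov = min(exon.end, iv.end) - max(exon.start, iv.begin)
            if ov <= 0:
                continue
            cand = (ov, iv.data)
            if best is None or ov > best[0] or (ov == best[0] and iv.data < best[1]):
                best = cand
        if best is not None:
            mapped.append(replace(exon, gene_id=best[1]))
    if not mapped:
        raise ValueError(
            "no exon overlapped the annotation; check chromosome naming and "
            "coordinate conventions"
        )
    keep = [e.exon_id for e in mapped]
    return ExonExpressionMatrix(
        exons=tuple(mapped), values=matrix.values.loc[keep], scale_state=matrix.scale_state
    )


def filter_unexpressed_exons(matrix: ExonExpressionMatrix) -> ExonExpressionMatrix:
    """Drop exons with zero expression in every sample."""
    if matrix.scale_state != "raw":
        raise ValueError("unexpressed-exon filter operates on the raw matrix")
    mask = (matrix.values.to_numpy() > 0).any(axis=1)
    keep = [e.exon_id for e, m in zip(matrix.exons, mask) if m]
    return matrix.subset_exons(keep)


def filter_low_median_samples(
    matrix: ExonExpressionMatrix, mad_threshold: float = 3.0
) -> tuple[ExonExpressionMatrix, list[str]]:
    """Exclude samples whose median exon expression is unusually low.

    A sample is excluded when log2 of its median exon value lies more than
    ``mad_threshold`` scaled median-absolute-deviations below the cohort
    median of per-sample log-medians.  Samples whose median is 0 have
    log-median -inf and are always excluded (for finite thresholds).
    """
    if matrix.scale_state != "raw":
        raise ValueError("low-median filter operates on the raw matrix")
    n = len(matrix.samples)
    if n < 3:
        logger.warning("fewer than 3 samples: skipping low-median filtering")
        return matrix, []
    med = matrix.values.median(axis=0).to_numpy()
    with np.errstate(divide="ignore"):
        logmed = np.log2(med)
    center = float(np.median(logmed))
    mad = float(np.median(np.abs(logmed - center))) * 1.4826
    cutoff = center - mad_threshold * mad
    if mad == 0.0:
        drop = ~np.isfinite(logmed) if np.isfinite(cutoff) else np.zeros(n, bool)
    else:
        drop = logmed < cutoff
    excluded = [s for s, d in zip(matrix.samples, drop) if d]
    kept = [s for s in matrix.samples if s not in set(excluded)]
    return matrix.subset_samples(kept), excluded


def normalize_log(
    matrix: ExonExpressionMatrix, config: NormalizationConfig | None = None
) -> ExonExpressionMatrix:
    """Median-adjust each sample and apply the log2(1 + c*x) transform.

    Each sample column is divided by its own median over retained exons
    (removing per-sample depth/systematic error; the adjusted median is 1),
    then mapped through ``x -> log2(1 + scale_constant * x)``.  A sample
    median at zero is an error: filter unexpressed exons and low-median
    samples first.
    """
    if matrix.scale_state != "raw":
        raise ValueError("matrix is already normalized")
    config = config or NormalizationConfig()
    med = matrix.values.median(axis=0)
    zero = med[med <= 0]
    if len(zero):
        raise ValueError(
            f"sample {zero.index[0]!r} has non-positive median expression; "
            "filter unexpressed exons / low-median samples first"
        )
    adjusted = matrix.values / med
    # quantize to 9 significant digits: ulp-level rounding differences from
    # per-sample rescaling otherwise leak into downstream KDE decisions
    arr = adjusted.to_numpy()
    pos = arr > 0
    exp = np.floor(np.log10(arr[pos]))
    scale = np.power(10.0, 8.0 - exp)
    arr[pos] = np.round(arr[pos] * scale) / scale
    transformed = np.log2(1.0 + config.scale_constant * pd.DataFrame(
        arr, index=adjusted.index, columns=adjusted.columns
    ))
    return ExonExpressionMatrix(
        exons=matrix.exons, values=transformed, scale_state="normalized_log"
    )


def write_annotation_bed(matrix: ExonExpressionMatrix, path) -> None:
    """Write the matrix's own exon->gene map as BED6+1 annotation."""
    with open(path, "w") as fh:
        for e in matrix.exons:
            gene = e.gene_id if e.gene_id is not None else "."
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.exon_id}\t0\t.\t{gene}\n")


def read_sample_classes(path) -> pd.DataFrame:
    """Read a sample metadata / class TSV (sample_id plus marker or class columns)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("sample table must have a 'sample_id' column")
    return df.set_index("sample_id")


def write_sample_classes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="sample_id")
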