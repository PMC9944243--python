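"""Readers, writers and the internal data model.

Every matrix entering the pipeline is wrapped in a :class:`NamedMatrix`
(features x cells with unique names); genomic features use 0-based half-open
coordinates internally.  GTF input (1-based, inclusive) is converted on read
by :func:`gtf_to_internal`, BED is native.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MODALITIES = ("rna", "protein", "atac_peak", "velocity", "gas")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class NamedMatrix:
    """A features x cells matrix with unique row/column names.

    ``values`` is kept dense (float64).  Count modalities (rna, protein,
    atac_peak) must be non-negative; velocity may carry any sign.
    """

    values: np.ndarray
    row_names: list[str]
    col_names: list[str]
    modality: str = "rna"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_names = list(self.row_names)
        self.col_names = list(self.col_names)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.ndim != 2:
            raise FormatError("values must be 2-dimensional")
        if self.values.shape != (len(self.row_names), len(self.col_names)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_names)} row names / {len(self.col_names)} col names"
            )
        for kind, names in (("row", self.row_names), ("column", self.col_names)):
            if len(set(names)) != len(names):
                dupes = [n for n in set(names) if names.count(n) > 1][:3]
                raise FormatError(f"duplicate {kind} name(s): {dupes}")
        if self.modality in ("rna", "protein", "atac_peak") and np.any(self.values < 0):
            raise FormatError(f"{self.modality} matrix must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.row_names)}

    def col_index(self) -> dict[str, int]:
        return {n: j for j, n in enumerate(self.col_names)}

    def subset(self, rows: Sequence[int] | None = None,
               cols: Sequence[int] | None = None) -> "NamedMatrix":
        r = np.arange(self.shape[0]) if rows is None else np.asarray(rows)
        c = np.arange(self.shape[1]) if cols is None else np.asarray(cols)
        return NamedMatrix(
            self.values[np.ix_(r, c)],
            [self.row_names[i] for i in r],
            [self.col_names[j] for j in c],
            self.modality,
        )


@dataclass
class GenomicInterval:
    """0-based half-open interval, optionally named and scored."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneAnnotation:
    """A gene with a TSS and merged exon spans (internal coordinates)."""

    gene_id: str
    chrom: str
    tss: int
    exons: list[GenomicInterval] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = merge_intervals(self.exons)
        if self.exon_length() <= 0:
            raise FormatError(f"gene {self.gene_id} has zero exon length")

    def exon_length(self) -> int:
        return sum(e.length() for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Transcript body: first exon start to last exon end."""
        return self.exons[0].start, self.exons[-1].end


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals on the same chromosome, sorted by start."""
    ivs = sorted(ivs, key=lambda e: (e.chrom, e.start, e.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def gtf_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert GTF 1-based inclusive coordinates to 0-based half-open."""
    if start_1based < 1 or end_1based < start_1based:
        raise FormatError(f"bad GTF coordinates {start_1based}..{end_1based}")
    return start_1based - 1, end_1based


# ---------------------------------------------------------------------------
# readers


def _read_names(path: str | Path) -> list[str]:
    with open(path) as fh:
        names = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return names


def read_mtx_triplet(matrix_path: str | Path, row_names_path: str | Path,
                     col_names_path: str | Path, modality: str = "rna") -> NamedMatrix:
    """Read a MatrixMarket coordinate matrix plus row/column name files."""
    mat = scipy.io.mmread(str(matrix_path))
    if sp.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    rows = _read_names(row_names_path)
    cols = _read_names(col_names_path)
    if mat.shape != (len(rows), len(cols)):
        raise FormatError(
            f"matrix is {mat.shape} but {len(rows)} row names and "
            f"{len(cols)} column names were supplied"
        )
    return NamedMatrix(mat, rows, cols, modality)


def read_dense_tsv(path: str | Path, modality: str = "rna") -> NamedMatrix:
    """Dense TSV with a header row of cell names and first column of features."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return NamedMatrix(df.to_numpy(dtype=float),
                       [str(x) for x in df.index],
                       [str(x) for x in df.columns], modality)


def write_dense_tsv(m: NamedMatrix, path: str | Path) -> None:
    pd.DataFrame(m.values, index=m.row_names, columns=m.col_names).to_csv(
        path, sep="\t", float_format="%.6g")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED5(+): tab-separated, 0-based half-open, score in column 5."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = f[3] if len(f) > 3 else ""
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            try:
                out.append(GenomicInterval(f[0], start, end, name, score))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name or iv.score is not None:
                fields.append(iv.name or ".")
            if iv.score is not None:
                fields.append(f"{iv.score:g}")
            fh.write("\t".join(fields) + "\n")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Parse a gene/exon GTF into :class:`GeneAnnotation` records.

    TSS is the 5' end of the merged exon span (+ strand: first exon start,
    - strand: last exon end).  Genes without exon features are dropped with
    a warning.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}
    seen_genes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 GTF columns")
            chrom, _, feature, start, end, _, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            attrs = dict(_ATTR_RE.findall(f[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene" and gid not in strands:
                seen_genes.append(gid)
                strands[gid] = strand
                chroms[gid] = chrom
            elif feature == "exon":
                s0, e0 = gtf_to_internal(int(start), int(end))
                exons.setdefault(gid, []).append(GenomicInterval(chrom, s0, e0))
                if gid not in strands:
                    seen_genes.append(gid)
                    strands[gid] = strand
                    chroms[gid] = chrom
    out: list[GeneAnnotation] = []
    for gid in seen_genes:
        if gid not in exons:
            warnings.warn(f"gene {gid} has no exon features; dropped")
            continue
        merged = merge_intervals(exons[gid])
        strand = strands[gid]
        tss = merged[0].start if strand == "+" else merged[-1].end
        out.append(GeneAnnotation(gid, chroms[gid], tss, merged, strand))
    return out


_PEAK_RE = re.compile(r"^(.*?)[:\-]_?(\d+)[\-_](\d+)$")


def parse_peak_name(name: str) -> GenomicInterval:
    """Parse 'chr1:100-200' or 'chr1-100-200' peak identifiers."""
    m = _PEAK_RE.match(name)
    if m is None:
        raise FormatError(f"cannot parse peak name {name!r}")
    return GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3)), name)


# ---------------------------------------------------------------------------
# writers


def write_edge_list(edges: Iterable[tuple], path: str | Path,
                    header: Sequence[str] = ("source", "target", "weight")) -> None:
    """TSV edge list, lexicographic row order, >=6 significant digits."""
    rows = []
    for e in edges:
        e = list(e)
        if len(e) < len(header):
            e += [""] * (len(header) - len(e))
        rows.append(e)
    rows.sort(key=lambda r: tuple(str(x) for x in r))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(
                f"{x:.8g}" if isinstance(x, float) else str(x) for x in r) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append((str(row.iloc[0]), str(row.iloc[1]), float(row.iloc[2])))
    return out


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    items = sorted(labels.items())
    with open(path, "w") as fh:
        fh.write("barcode\tcluster\n")
        for k, v in items:
            fh.write(f"{k}\t{v}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(b): int(c) for b, c in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_mtx(m: NamedMatrix, prefix: str | Path) -> None:
    """Write a NamedMatrix as <prefix>.mtx / .rows.txt / .cols.txt."""
    prefix = str(prefix)
    scipy.io.mmwrite(prefix + ".mtx", sp.coo_matrix(m.values))
    for suffix, names in ((".rows.txt", m.row_names), (".cols.txt", m.col_names)):
        with open(prefix + suffix, "w") as fh:
            fh.write("\n".join(names) + "\n")
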