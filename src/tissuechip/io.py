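"""Readers and writers for the on-disk formats the pipeline touches.

Formats: ENCODE narrowPeak (BED6+4, column 9 = -log10 q), BED6+ with an
optional -log10 q in column 7, GFF3 gene annotation (converted to 0-based
half-open on read), a simple 1-based closed TSV gene table, chrom.sizes,
plain-text gene lists, GMT term maps, and BED read tracks where each
record contributes its 5' position.
"""

from __future__ import annotations

import math
import os
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils.iterators

from .model import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
)

__all__ = [
    "read_narrowpeak",
    "write_narrowpeak",
    "read_genes",
    "write_gff3",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "gmt_to_gene_terms",
    "read_read_track",
    "write_read_track",
    "write_bed",
]

_NARROWPEAK_EXTS = {".narrowpeak", ".np"}
_BED_EXTS = {".bed", ".bed6", ".bedgraph"}


def _infer_dialect(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in _NARROWPEAK_EXTS:
        return "narrowpeak"
    if ext in _BED_EXTS:
        return "bed"
    raise ValueError(
        f"cannot infer peak dialect from extension {ext!r} of {path}; "
        "pass dialect='narrowpeak' or 'bed'"
    )


def _parse_key(path: Path, factor: str | None, tissue: str | None) -> tuple[str, str]:
    if factor is not None and tissue is not None:
        return factor, tissue
    stem = path.stem
    if "@" in stem:
        f, t = stem.split("@", 1)
        return factor or f, tissue or t
    return factor or stem, tissue or ""


def read_narrowpeak(
    path: str | os.PathLike,
    q_threshold: float | None = 0.001,
    dialect: str | None = None,
    factor: str | None = None,
    tissue: str | None = None,
) -> PeakSet:
    """Read a peak file, keeping peaks with q <= q_threshold (inclusive).

    narrowPeak stores -log10(q) in column 9 (-1 meaning unavailable); the
    BED6+ dialect optionally stores -log10(q) in column 7. Peaks without a
    q-value are dropped when a threshold is in force. Pass
    ``q_threshold=None`` to keep everything.
    """
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in ("narrowpeak", "bed"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    factor, tissue = _parse_key(path, factor, tissue)

    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            try:
                peak = _parse_peak_line(cols, dialect)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if q_threshold is not None:
                if peak.qvalue is None or peak.qvalue > q_threshold:
                    continue
            peaks.append(peak)
    return PeakSet(factor=factor, tissue=tissue, peaks=peaks)


def _parse_peak_line(cols: Sequence[str], dialect: str) -> Peak:
    if len(cols) < 3:
        raise ValueError(f"expected >= 3 columns, got {len(cols)}")
    if dialect == "narrowpeak" and len(cols) < 10:
        raise ValueError(f"narrowPeak needs 10 columns, got {len(cols)}")
    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
    if end <= start:
        raise ValueError(f"end {end} <= start {start}")
    interval = GenomicInterval(chrom, start, end)
    name = cols[3] if len(cols) > 3 else "."
    score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else None
    strand = cols[5] if len(cols) > 5 else "."
    signal = pvalue = qvalue = None
    summit = None
    extra: tuple[str, ...] = ()
    if dialect == "narrowpeak":
        signal = float(cols[6]) if cols[6] != "." else None
        pvalue = float(cols[7]) if float(cols[7]) >= 0 else None
        neglog_q = float(cols[8])
        qvalue = 10.0 ** (-neglog_q) if neglog_q >= 0 else None
        summit = int(cols[9]) if int(cols[9]) >= 0 else None
        extra = tuple(cols[10:])
    else:
        if len(cols) > 6:
            neglog_q = float(cols[6])
            qvalue = 10.0 ** (-neglog_q) if neglog_q >= 0 else None
        extra = tuple(cols[7:])
    return Peak(
        interval=interval,
        name=name,
        score=score,
        strand=strand,
        signal=signal,
        pvalue=pvalue,
        qvalue=qvalue,
        summit=summit,
        extra=extra,
    )


def write_narrowpeak(peakset: PeakSet, path: str | os.PathLike) -> None:
    """Write a PeakSet as ENCODE narrowPeak.

    -log10 q-values are written with 6 significant digits (round-trip
    stable to that precision); missing p/q/summit become -1, preserving
    narrowPeak conventions. Extra columns round-trip opaquely.
    """
    with open(path, "w") as fh:
        for p in peakset:
            neglog_q = -1.0 if p.qvalue is None else -math.log10(p.qvalue)
            cols = [
                p.interval.chrom,
                str(p.interval.start),
                str(p.interval.end),
                p.name,
                "0" if p.score is None else f"{p.score:g}",
                p.strand,
                "0" if p.signal is None else f"{p.signal:g}",
                "-1" if p.pvalue is None else f"{p.pvalue:.6g}",
                f"{neglog_q:.6g}",
                "-1" if p.summit is None else str(p.summit),
                *p.extra,
            ]
            fh.write("\t".join(cols) + "\n")


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | os.PathLike,
    names: Iterable[str] | None = None,
) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# gene annotation

_SEQREGION_RE = re.compile(r"^##sequence-region\s+(\S+)\s+(\d+)\s+(\d+)")

_DEFAULT_X_NAMES = {"x", "chrx"}


def read_genes(
    path: str | os.PathLike,
    chrom_sizes: str | os.PathLike | Mapping[str, int] | None = None,
    x_chromosomes: Iterable[str] | None = None,
) -> GenomeAnnotation:
    """Read gene models from GFF3 or a TSV gene table.

    GFF3 is 1-based closed and converted to 0-based half-open; the TSV
    dialect (extension .tsv/.txt) has columns gene_id, chrom, strand,
    start, end (1-based closed, header line required). Chromosome lengths
    come from ##sequence-region directives or a chrom.sizes sidecar.
    Chromosomes named X/chrX (any case) are flagged as the X unless
    ``x_chromosomes`` overrides.
    """
    path = Path(path)
    sizes: dict[str, int] = {}
    if isinstance(chrom_sizes, Mapping):
        sizes.update(chrom_sizes)
    elif chrom_sizes is not None:
        sizes.update(read_chrom_sizes(chrom_sizes))

    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _read_gff3_genes(path, sizes)
    else:
        genes = _read_tsv_genes(path)
    if not sizes:
        raise ValueError(
            f"{path}: chromosome lengths unknown; provide ##sequence-region "
            "directives or a chrom.sizes file"
        )
    if x_chromosomes is None:
        x_chromosomes = [c for c in sizes if c.lower() in _DEFAULT_X_NAMES]
    return GenomeAnnotation(sizes, genes, x_chromosomes=x_chromosomes)


def _read_gff3_genes(path: Path, sizes: dict[str, int]) -> list[GeneModel]:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _SEQREGION_RE.match(line)
            if m:
                sizes.setdefault(m.group(1), int(m.group(3)))
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gene_id = feat.attributes.get("ID", feat.attributes.get("gene_id", [None]))[0]
        if gene_id is None:
            raise ValueError(f"{path}: gene feature without ID at {feat.seqid}:{feat.start}")
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{path}: gene {gene_id}: strand must be + or -")
        span = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand, span))
    return genes


def _read_tsv_genes(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "chrom", "strand", "start", "end"]
        idx = {}
        for col in required:
            if col not in header:
                raise ValueError(f"{path}: missing column {col!r}")
            idx[col] = header.index(col)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            gene_id = cols[idx["gene_id"]]
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene_id!r} (line {lineno})")
            seen.add(gene_id)
            chrom = cols[idx["chrom"]]
            strand = cols[idx["strand"]]
            start1 = int(cols[idx["start"]])
            end1 = int(cols[idx["end"]])
            span = GenomicInterval(chrom, start1 - 1, end1)
            genes.append(GeneModel(gene_id, chrom, strand, span))
    return genes


def write_gff3(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write gene models as minimal GFF3 with ##sequence-region directives."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(
            annotation.genes.values(), key=lambda g: (g.chrom, g.span.start)
        ):
            fh.write(
                f"{g.chrom}\ttissuechip\tgene\t{g.span.start + 1}\t{g.span.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed line {lineno}")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# gene lists and term maps

def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Plain text, one gene id per line; '#' comments and blanks ignored."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.append(entry)
    return genes


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """GMT: term, description, then member genes, tab separated."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            terms[cols[0]] = {g for g in cols[2:] if g}
    return terms


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, term, *sorted(genes)]) + "\n")


def gmt_to_gene_terms(terms: Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    """Invert a term -> genes map into gene -> terms."""
    gene_terms: dict[str, set[str]] = {}
    for term, genes in terms.items():
        for g in genes:
            gene_terms.setdefault(g, set()).add(term)
    return gene_terms


# ---------------------------------------------------------------------------
# read tracks

def read_read_track(path: str | os.PathLike, label: str | None = None):
    """Read a BED read track as 5' positions.

    The 5' position is the interval start for + strand (or strandless)
    records and end - 1 for - strand records.
    """
    from .concordance import ReadTrack  # local import avoids a cycle

    path = Path(path)
    reads: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ValueError(f"{path}: malformed line {lineno}")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            strand = cols[5] if len(cols) > 5 else "+"
            pos = end - 1 if strand == "-" else start
            reads.append((chrom, pos))
    return ReadTrack(label=label or path.stem, reads=reads)


def write_read_track(track, path: str | os.PathLike, read_length: int = 1) -> None:
    with open(path, "w") as fh:
        for chrom, pos in track.iter_reads():
            fh.write(f"{chrom}\t{pos}\t{pos + read_length}\tread\t0\t+\n")
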