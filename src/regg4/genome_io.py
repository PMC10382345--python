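"""Input/output for genomes, gene annotation, SNPs and intervals.

All coordinates are 0-based half-open internally.  Conversions from
1-based sources (VCF, the two-column SNP TSV) happen here and only here,
so downstream modules never see mixed conventions.  A SNP at position
``p`` overlaps an interval ``[s, e)`` iff ``s <= p < e``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
BIOTYPES = ("protein_coding", "lncRNA", "other")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded/named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to what promoter extraction needs: TSS, strand, biotype."""

    gene_id: str
    chrom: str
    tss: int  # 0-based position of the transcription start
    strand: str
    biotype: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")


@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    pos: int  # 0-based
    id: str | None = None
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative SNP position {self.pos} on {self.chrom}")
        if self.ref is not None and self.alt is not None and self.ref == self.alt:
            raise ValueError(f"SNP at {self.chrom}:{self.pos}: ref equals alt")


@dataclass(frozen=True)
class Promoter:
    """A prom500 window: the ``window`` nt immediately upstream of a TSS."""

    interval: GenomicInterval
    gene_id: str
    biotype: str
    clipped: bool = False


def chrom_sizes(genome: Mapping[str, str]) -> dict[str, int]:
    return {c: len(s) for c, s in genome.items()}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into ``{chrom: uppercase sequence}``.

    Duplicate headers are an error; IUPAC ambiguity codes are preserved.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    if n == 0 and path.stat().st_size > 0:
        raise ValueError(f"no FASTA records parsed from non-empty file {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6.  BED is natively 0-based half-open; no shift applied."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (name '.', score 0 when absent); round-trips with read_bed."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_snps(path: str | Path, dialect: str = "vcf") -> list[SNPRecord]:
    """Read SNPs from a VCF (1-based) or a chrom/pos TSV (1-based).

    Non-SNP VCF records (indels, multi-nucleotide, symbolic alleles) are
    skipped; the skip count is logged.  Positions are returned 0-based.
    """
    if dialect == "vcf":
        return _read_snps_vcf(path)
    if dialect == "tsv":
        return _read_snps_tsv(path)
    raise ValueError(f"unknown SNP dialect {dialect!r}")


def _read_snps_vcf(path: str | Path) -> list[SNPRecord]:
    snps: list[SNPRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = rec.ref or ""
            alts = rec.alts or ()
            if len(ref) != 1 or not alts or any(
                len(a) != 1 or a.startswith("<") for a in alts
            ):
                skipped += 1
                continue
            snps.append(
                SNPRecord(
                    chrom=rec.chrom,
                    pos=rec.start,  # pysam .start is already 0-based
                    id=rec.id,
                    ref=ref,
                    alt=alts[0],
                )
            )
    if skipped:
        log.info("read_snps(%s): skipped %d non-SNP records", path, skipped)
    return snps


def _read_snps_tsv(path: str | Path) -> list[SNPRecord]:
    snps: list[SNPRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>pos")
            pos1 = int(fields[1])
            if pos1 < 1:
                raise ValueError(f"{path}:{lineno}: non-positive position {pos1}")
            snp_id = fields[2] if len(fields) > 2 and fields[2] != "." else None
            ref = fields[3] if len(fields) > 3 else None
            alt = fields[4] if len(fields) > 4 else None
            snps.append(SNPRecord(fields[0], pos1 - 1, snp_id, ref, alt))
    return snps


def write_snps_tsv(snps: Iterable[SNPRecord], path: str | Path) -> None:
    """Write the 1-based TSV dialect; round-trips with read_snps(..., 'tsv')."""
    with open(path, "w") as fh:
        for s in snps:
            fh.write(
                "\t".join(
                    [s.chrom, str(s.pos + 1), s.id or ".", s.ref or "", s.alt or ""]
                ).rstrip("\t")
                + "\n"
            )


def write_snps_vcf(
    snps: Iterable[SNPRecord], sizes: Mapping[str, int], path: str | Path
) -> None:
    """Write a minimal but header-compliant VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in sizes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.id or '.'}\t{s.ref or 'N'}"
                f"\t{s.alt or 'N'}\t.\t.\t.\n"
            )


GENE_COLUMNS = ("gene_id", "chrom", "tss", "strand", "biotype", "name")


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read the 6-column gene TSV (header required, TSS 0-based)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in GENE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"gene TSV {path} missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                chrom=row.chrom,
                tss=int(row.tss),
                strand=row.strand,
                biotype=row.biotype,
                name=str(getattr(row, "name", "") or ""),
            )
        )
    return genes


def write_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.biotype}\t{g.name}\n"
            )


def derive_prom500(
    genes: Sequence[GeneRecord],
    genome: Mapping[str, str] | Mapping[str, int],
    window: int = 500,
) -> list[Promoter]:
    """Derive promoter windows: the ``window`` nt upstream of each TSS.

    For a + strand gene the window is ``[max(0, tss-window), tss)``; for a
    - strand gene ``[tss+1, min(L, tss+window+1))``.  Windows clipped at a
    chromosome edge are retained and flagged so density denominators can
    use their true lengths; windows that clip to zero length are dropped
    with a log message.
    """
    sizes = {
        c: (v if isinstance(v, int) else len(v)) for c, v in genome.items()
    }
    promoters: list[Promoter] = []
    for g in genes:
        if g.chrom not in sizes:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        L = sizes[g.chrom]
        if not 0 <= g.tss < L:
            raise ValueError(
                f"gene {g.gene_id}: TSS {g.tss} outside {g.chrom} (length {L})"
            )
        if g.strand == "+":
            start, end = max(0, g.tss - window), g.tss
        else:
            start, end = g.tss + 1, min(L, g.tss + window + 1)
        if start >= end:
            log.warning("gene %s: promoter window empty at chromosome edge", g.gene_id)
            continue
        promoters.append(
            Promoter(
                interval=GenomicInterval(g.chrom, start, end, g.strand, g.gene_id),
                gene_id=g.gene_id,
                biotype=g.biotype,
                clipped=(end - start) < window,
            )
        )
    return promoters
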