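"""Genome, annotation and variant I/O with one internal coordinate convention.

Everything inside the package is 0-based, half-open, on the reference
(plus) strand.  The two 1-based formats the pipeline touches — VCF
(1-based positions) and GFF3 (1-based closed intervals) — are converted
at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pyfaidx
import pyranges
import pysam
from cyvcf2 import VCF

log = logging.getLogger("aidmap")

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

SNPKey = tuple[str, int, str, str]  # (contig, pos, ref, alt)


@dataclass(frozen=True, slots=True)
class SNPRecord:
    """One biallelic single-nucleotide substitution call.

    ``pos`` is 0-based.  ``frequency`` is the alternate-allele read
    fraction; it is ``None`` (unknown) when no depth information exists,
    never silently 0.  After replicate consensus, ``rep_freqs`` carries
    the per-replicate frequencies used for reproducibility statistics.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    ref_depth: int | None = None
    alt_depth: int | None = None
    rep_freqs: tuple[float | None, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a single-base substitution: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.contig}:{self.pos}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")

    @property
    def key(self) -> SNPKey:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def total_depth(self) -> int | None:
        if self.ref_depth is None or self.alt_depth is None:
            return None
        return self.ref_depth + self.alt_depth

    @property
    def frequency(self) -> float | None:
        total = self.total_depth
        if total is None or total == 0:
            return None
        return self.alt_depth / total

    def with_rep_freqs(self, freqs: Iterable[float | None]) -> "SNPRecord":
        return replace(self, rep_freqs=tuple(freqs))


class SNPSet:
    """An identity-keyed collection of SNP records for one sample or stage.

    Membership is by the identity key (contig, pos, ref, alt) only;
    depths and frequencies never enter the comparison.  Iteration is in
    (contig, pos, ref, alt) order.
    """

    def __init__(self, records: Iterable[SNPRecord] = (), label: str = "") -> None:
        self.label = label
        self._records: dict[SNPKey, SNPRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SNPRecord) -> None:
        if rec.key in self._records:
            raise ValueError(f"duplicate SNP identity {rec.key} in set {self.label!r}")
        self._records[rec.key] = rec

    def get(self, key: SNPKey) -> SNPRecord:
        return self._records[key]

    def keys(self) -> set[SNPKey]:
        return set(self._records)

    def __contains__(self, item: SNPRecord | SNPKey) -> bool:
        key = item.key if isinstance(item, SNPRecord) else item
        return key in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SNPRecord]:
        return iter(sorted(self._records.values(), key=lambda r: r.key))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SNPSet):
            return NotImplemented
        return self._records.keys() == other._records.keys()

    def __repr__(self) -> str:
        return f"SNPSet(label={self.label!r}, n={len(self)})"


@dataclass(frozen=True, slots=True)
class GeneFeature:
    """A gene body on a contig; ``start``/``end`` 0-based half-open."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty gene interval for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} has no defined strand")

    @property
    def tss(self) -> int:
        """Position of the 5' end (transcription start side)."""
        return self.start if self.strand == "+" else self.end - 1


class GenomeModel:
    """Contig sequences plus gene features and derived intergenic intervals."""

    def __init__(self, contigs: Mapping[str, str], genes: Iterable[GeneFeature] = ()):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name} contains non-ACGTN bases: {sorted(bad)}")
            self.contigs[name] = seq
        self.genes: list[GeneFeature] = sorted(genes, key=lambda g: (g.contig, g.start, g.end))
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig}")
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(f"gene {g.gene_id} extends past end of {g.contig}")

    def genes_on(self, contig: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.contig == contig]

    @property
    def intergenic(self) -> dict[str, list[tuple[int, int]]]:
        """Per contig, the maximal intervals not covered by any gene body."""
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, seq in self.contigs.items():
            length = len(seq)
            gaps: list[tuple[int, int]] = []
            cursor = 0
            for g in self.genes_on(contig):  # sorted by start
                if g.start > cursor:
                    gaps.append((cursor, g.start))
                cursor = max(cursor, g.end)
            if cursor < length:
                gaps.append((cursor, length))
            out[contig] = gaps
        return out

    def set_sequence(self, contig: str, seq: str) -> None:
        seq = seq.upper()
        if len(seq) != len(self.contigs[contig]):
            raise ValueError("replacement sequence changes contig length")
        self.contigs[contig] = seq


@dataclass(frozen=True, slots=True)
class FlankWindow:
    """A reference-strand window centered on a SNP, for motif input."""

    seq: str
    truncated: bool
    start: int  # 0-based start of the window on the contig
    center_offset: int  # index of the SNP base within seq


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, label: str | None = None,
             split_multiallelic: bool = False) -> SNPSet:
    """Read a VCF into an :class:`SNPSet` of biallelic substitutions.

    Positions shift from 1-based VCF to internal 0-based.  Allele depths
    are taken from the first sample's FORMAT/AD field; records without
    usable depths keep ``frequency`` unknown.  Indels and MNVs are
    dropped.  Multiallelic rows are split into one record per alternate
    allele when ``split_multiallelic`` is true, otherwise skipped (both
    choices are logged).
    """
    path = Path(path)
    snps = SNPSet(label=label or path.stem)
    n_skipped_type = n_skipped_multi = 0
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    try:
        for var in vcf:
            alts = var.ALT
            if len(alts) > 1:
                if not split_multiallelic:
                    n_skipped_multi += 1
                    continue
            elif len(alts) == 0:
                n_skipped_type += 1
                continue
            ad = None
            try:
                fmt = var.format("AD")
            except Exception:
                fmt = None
            if fmt is not None and len(fmt) > 0:
                ad = fmt[0]
            for alt_idx, alt in enumerate(alts):
                if len(var.REF) != 1 or len(alt) != 1 or alt not in "ACGT":
                    n_skipped_type += 1
                    continue
                ref_depth = alt_depth = None
                if ad is not None and len(ad) > alt_idx + 1:
                    rd, qd = int(ad[0]), int(ad[alt_idx + 1])
                    if rd >= 0 and qd >= 0:  # cyvcf2 encodes missing as negative
                        ref_depth, alt_depth = rd, qd
                snps.add(SNPRecord(contig=var.CHROM, pos=var.POS - 1, ref=var.REF,
                                   alt=alt, ref_depth=ref_depth, alt_depth=alt_depth))
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed record in VCF {path}: {exc}") from exc
    if n_skipped_type:
        log.info("%s: skipped %d non-SNP records", path.name, n_skipped_type)
    if n_skipped_multi:
        log.info("%s: skipped %d multiallelic records (split_multiallelic=False)",
                 path.name, n_skipped_multi)
    return snps


def write_vcf(snps: SNPSet, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> Path:
    """Write an :class:`SNPSet` as a sorted single-sample VCF 4.2 file.

    Internal 0-based positions become 1-based POS; depths go to
    FORMAT/AD.  ``read_vcf(write_vcf(s))`` reproduces ``s`` exactly.
    """
    path = Path(path)
    if contig_lengths is None:
        contig_lengths = {}
        for rec in snps:
            contig_lengths[rec.contig] = max(contig_lengths.get(rec.contig, 0), rec.pos + 1)
    header = pysam.VariantHeader()
    for contig, length in sorted(contig_lengths.items()):
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths for the ref and alt alleles")
    sample = snps.label or "sample"
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in snps:  # already key-sorted: contig then position
            row = out.new_record(contig=rec.contig, start=rec.pos,
                                 alleles=(rec.ref, rec.alt))
            if rec.ref_depth is not None and rec.alt_depth is not None:
                row.samples[sample]["AD"] = (rec.ref_depth, rec.alt_depth)
            out.write(row)
    return path


# ---------------------------------------------------------------------------
# FASTA / annotation
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Contig id → uppercase sequence."""
    fa = pyfaidx.Fasta(str(path), rebuild=True)
    out = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    return out


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def read_annotation(path: str | Path, format: str | None = None,
                    feature_types: tuple[str, ...] = ("gene",)) -> list[GeneFeature]:
    """Read gene features from GFF3 or 6-column BED.

    GFF3's 1-based closed intervals and BED's 0-based half-open ones are
    both normalized to the internal 0-based half-open convention (the
    GFF3 shift is done by the reader library).  A feature without a
    defined strand is rejected.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bed" if suffix == ".bed" else "gff3"
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")

    genes: list[GeneFeature] = []
    if format == "gff3":
        df = pyranges.read_gff3(str(path)).df
        if "Feature" in df.columns:
            df = df[df["Feature"].isin(feature_types)]
        for i, row in enumerate(df.itertuples(index=False)):
            strand = getattr(row, "Strand", ".")
            if strand not in ("+", "-"):
                raise ParseError(f"{path.name}: feature without strand at "
                                 f"{row.Chromosome}:{row.Start}-{row.End}")
            gid = getattr(row, "ID", None) or getattr(row, "Name", None) or f"gene{i + 1}"
            genes.append(GeneFeature(gene_id=str(gid), contig=str(row.Chromosome),
                                     start=int(row.Start), end=int(row.End),
                                     strand=strand))
    else:
        df = pyranges.read_bed(str(path)).df
        if "Strand" not in df.columns:
            raise ParseError(f"{path.name}: BED lacks a strand column (need 6 columns)")
        for i, row in enumerate(df.itertuples(index=False)):
            strand = str(row.Strand)
            if strand not in ("+", "-"):
                raise ParseError(f"{path.name}: feature without strand at "
                                 f"{row.Chromosome}:{row.Start}-{row.End}")
            gid = str(getattr(row, "Name", "") or f"gene{i + 1}")
            genes.append(GeneFeature(gene_id=gid, contig=str(row.Chromosome),
                                     start=int(row.Start), end=int(row.End),
                                     strand=strand))
    return genes


def write_gff3(genes: Iterable[GeneFeature], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            fh.write(f"{g.contig}\taidmap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_id}\n")
    return path


# ---------------------------------------------------------------------------
# Flank extraction (motif-discovery input)
# ---------------------------------------------------------------------------

def extract_flanks(snp: SNPRecord, genome: GenomeModel, flank: int = 100) -> FlankWindow:
    """Reference-strand sequence of ``2*flank + 1`` bp centered on a SNP.

    The default window is 100 bp either side of the site (201 bp in
    total), the input size used for motif discovery.  Near contig ends
    the window is truncated rather than padded, and flagged as such.
    """
    if snp.contig not in genome.contigs:
        raise ValueError(f"unknown contig {snp.contig}")
    seq = genome.contigs[snp.contig]
    if not 0 <= snp.pos < len(seq):
        raise ValueError(f"position {snp.pos} outside contig {snp.contig} "
                         f"(length {len(seq)})")
    start = max(0, snp.pos - flank)
    end = min(len(seq), snp.pos + flank + 1)
    window = seq[start:end]
    if window[snp.pos - start] != snp.ref:
        log.warning("reference mismatch at %s:%d: genome has %s, SNP says %s",
                    snp.contig, snp.pos, window[snp.pos - start], snp.ref)
    return FlankWindow(seq=window, truncated=(end - start) < 2 * flank + 1,
                       start=start, center_offset=snp.pos - start)


def write_flank_fasta(snps: Iterable[SNPRecord], genome: GenomeModel,
                      path: str | Path, flank: int = 100) -> Path:
    """Write flank windows as FASTA with ``><contig>:<pos1>:<ref>><alt>`` headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for snp in snps:
            win = extract_flanks(snp, genome, flank=flank)
            header = f"{snp.contig}:{snp.pos + 1}:{snp.ref}>{snp.alt}"
            if win.truncated:
                header += " truncated"
            fh.write(f">{header}\n{win.seq}\n")
    return path
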