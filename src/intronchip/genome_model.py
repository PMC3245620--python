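"""Gene models, probe records and annotation I/O.

Coordinates are 1-based, fully closed intervals everywhere (GFF3
convention): a 25-bp probe starting at position 100 covers 100..124 and
its midpoint — the 13th base — sits at 112.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pyfaidx

logger = logging.getLogger(__name__)

PROBE_LENGTH = 25
#: 0-based offset of a 25-mer's midpoint (its 13th base).
MIDPOINT_OFFSET = 12


class AnnotationError(ValueError):
    """Raised when an annotation fails validation."""


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ORF span plus ordered exon structure.

    ``exons`` are 1-based closed intervals in genomic coordinate order.
    Introns are derived as the maximal gaps between consecutive exons.
    The ORF span runs from the first exon start to the last exon end;
    UTRs are not modelled, so promoter/terminator windows anchor on the
    ORF boundaries.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene has no exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end < start:
                raise AnnotationError(f"{self.gene_id}: exon ({start},{end}) has end < start")
            if prev_end is not None and start <= prev_end:
                raise AnnotationError(
                    f"{self.gene_id}: exons overlap or are unsorted near position {start}"
                )
            if prev_end is not None and start == prev_end + 1:
                raise AnnotationError(
                    f"{self.gene_id}: zero-length intron between adjacent exons at {prev_end}"
                )
            prev_end = end

    @property
    def orf_start(self) -> int:
        return self.exons[0][0]

    @property
    def orf_end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced(self) -> bool:
        return len(self.exons) >= 2

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns_genomic(self) -> list[tuple[int, int]]:
        """Introns in genomic coordinate order."""
        return derive_introns_genomic(self)

    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'→3' along the direction of transcription."""
        return list(self.exons) if self.strand == "+" else list(self.exons[::-1])

    def introns_tx_order(self) -> list[tuple[int, int]]:
        """Introns ordered 5'→3' along the direction of transcription."""
        introns = self.introns_genomic()
        return introns if self.strand == "+" else introns[::-1]


def derive_introns_genomic(gene: GeneModel) -> list[tuple[int, int]]:
    """Maximal gaps between consecutive exons, in genomic order.

    A single-exon gene yields an empty list.  Intron *indices* in
    transcription order are obtained via :meth:`GeneModel.introns_tx_order`;
    for minus-strand genes that order is the reverse of the genomic one.
    """
    out = []
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        out.append((e1 + 1, s2 - 1))
    return out


@dataclass(frozen=True)
class ProbeRecord:
    """One 25-bp tiling-array probe at a fixed genomic position."""

    probe_id: str
    chrom: str
    start: int
    length: int = PROBE_LENGTH
    gc_fraction: float | None = None

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def midpoint(self) -> int:
        """Genomic position of the probe's 13th base."""
        return self.start + MIDPOINT_OFFSET


@dataclass
class GenomeAnnotation:
    """All gene models of a genome plus chromosome lengths."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes.values():
            self._check_bounds(g)

    def _check_bounds(self, gene: GeneModel) -> None:
        if gene.chrom not in self.chrom_lengths:
            raise AnnotationError(f"{gene.gene_id}: unknown chromosome {gene.chrom!r}")
        L = self.chrom_lengths[gene.chrom]
        if gene.orf_start < 1 or gene.orf_end > L:
            raise AnnotationError(
                f"{gene.gene_id}: coordinates ({gene.orf_start},{gene.orf_end}) "
                f"exceed chromosome {gene.chrom} length {L}"
            )

    def add(self, gene: GeneModel) -> None:
        self._check_bounds(gene)
        self.genes[gene.gene_id] = gene

    def spliced_genes(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.spliced]

    def unspliced_genes(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if not g.spliced]

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self.genes == other.genes and self.chrom_lengths == other.chrom_lengths


def read_annotation(path: str | Path, chrom_lengths: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Read gene/exon features from a GFF3 file into a :class:`GenomeAnnotation`.

    Chromosome lengths are taken from ``##sequence-region`` pragmas unless
    supplied explicitly.  Genes without exon children are rejected.
    """
    path = Path(path)
    lengths: dict[str, int] = dict(chrom_lengths or {})
    if not lengths:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        lengths[parts[1]] = int(parts[3])
                elif not line.startswith("#"):
                    break
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise AnnotationError(f"failed to parse GFF3 {path}: {exc}") from exc

    ann = GenomeAnnotation(chrom_lengths=lengths)
    for gf in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gf.id, featuretype="exon")
        )
        if not exons:
            raise AnnotationError(f"gene {gf.id} has no exon children")
        gene = GeneModel(gene_id=gf.id, chrom=gf.seqid, strand=gf.strand, exons=tuple(exons))
        if gene.chrom not in ann.chrom_lengths:
            # tolerate missing pragma: infer a length covering the gene
            ann.chrom_lengths[gene.chrom] = gene.orf_end
        ann.add(gene)
    return ann


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write a :class:`GenomeAnnotation` as GFF3 (gene + exon features)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_lengths[chrom]}\n")
        for gid in sorted(ann.genes):
            g = ann.genes[gid]
            fh.write(
                f"{g.chrom}\tintronchip\tgene\t{g.orf_start}\t{g.orf_end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tintronchip\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={gid}.exon{i};Parent={gid}\n"
                )


def read_probe_layout(path: str | Path) -> list[ProbeRecord]:
    """Read a probe layout TSV with header ``probe_id  chrom  start``."""
    probes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["probe_id", "chrom", "start"]:
            raise ValueError(f"probe layout header must be probe_id/chrom/start, got {header}")
        for line in fh:
            pid, chrom, start = line.rstrip("\n").split("\t")[:3]
            probes.append(ProbeRecord(probe_id=pid, chrom=chrom, start=int(start)))
    return probes


def write_probe_layout(probes: Iterable[ProbeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchrom\tstart\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.chrom}\t{p.start}\n")


def gc_fraction_of_sequence(seq: str) -> float:
    """Fraction of G/C bases (case-insensitive); ambiguous bases count as non-GC."""
    s = seq.upper()
    n_amb = sum(1 for c in s if c not in "ACGT")
    if n_amb:
        warnings.warn(f"{n_amb} ambiguous base(s) counted as non-GC", stacklevel=2)
    gc = s.count("G") + s.count("C")
    return gc / len(s)


def compute_probe_gc(probe: ProbeRecord, genome: pyfaidx.Fasta | Mapping[str, str]) -> float:
    """GC fraction of a probe's 25-bp sequence from the genome."""
    if isinstance(genome, pyfaidx.Fasta):
        seq = str(genome[probe.chrom][probe.start - 1 : probe.end])
    else:
        seq = genome[probe.chrom][probe.start - 1 : probe.end]
    if len(seq) != probe.length:
        raise ValueError(
            f"probe {probe.probe_id} interval ({probe.start},{probe.end}) "
            f"outside sequence bounds of {probe.chrom}"
        )
    return gc_fraction_of_sequence(seq)
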