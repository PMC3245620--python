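"""Probe-to-feature assignment.

Two distinct assignment rules operate side by side, mirroring the two
uses the analysis makes of probes:

* **Bulk classification** (:func:`classify_probe`): a probe counts as an
  intron or exon probe only if its entire 25-bp body lies within that
  feature; probes straddling a boundary are unassigned.  For unspliced
  genes the test is full containment within the ORF.
* **Metagene binning** (:func:`assign_probe_to_gene_bins`): a probe is
  placed by the position of its midpoint (13th base) alone, into the
  promoter window (400 bp 5' of the ORF in the direction of
  transcription), the terminator window (400 bp 3'), an exon, an intron,
  or — for unspliced genes — the ORF, and then into one of the region's
  equal-size bins.

Bins are numbered 1..n in the direction of transcription, so bin 1 is
always 5'-most regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomeAnnotation, ProbeRecord

REGION_PROMOTER = "promoter"
REGION_TERMINATOR = "terminator"
REGION_ORF = "orf"
REGION_EXON = "exon"
REGION_INTRON = "intron"

KLASS_INTRON = "intron_probe"
KLASS_EXON = "exon_probe"
KLASS_ORF_UNSPLICED = "orf_probe_unspliced"
KLASS_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BinScheme:
    """Bin counts of the average-gene layout.

    Defaults: 400-bp flanks in ten 40-bp bins; 20 bins across an
    unspliced ORF; 20 per exon and 10 per intron of spliced genes.
    """

    flank_bp: int = 400
    n_flank_bins: int = 10
    n_orf_bins: int = 20
    n_exon_bins: int = 20
    n_intron_bins: int = 10

    def __post_init__(self) -> None:
        if self.flank_bp % self.n_flank_bins != 0:
            raise ValueError("flank_bp must be divisible by n_flank_bins")
        for n in (self.n_flank_bins, self.n_orf_bins, self.n_exon_bins, self.n_intron_bins):
            if n < 1:
                raise ValueError("bin counts must be >= 1")


@dataclass(frozen=True)
class ProbeClass:
    """Bulk classification of one probe within one gene."""

    probe_id: str
    gene_id: str
    klass: str
    feature_index: int | None = None  # transcription-order ordinal, 1-based


@dataclass(frozen=True)
class BinAssignment:
    """Metagene placement of one probe within one gene."""

    region: str
    feature_index: int | None  # for exon/intron regions
    bin: int  # 1..n_bins, transcription order


def bin_of_midpoint(midpoint_offset: int, region_length: int, n_bins: int) -> int:
    """Proportional bin of a 0-based offset within a region.

    bin = floor(offset * n_bins / length) + 1.  Bins partition the region
    into contiguous segments whose sizes differ by at most 1 bp; regions
    shorter than ``n_bins`` leave some bins empty of positions.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not (0 <= midpoint_offset < region_length):
        raise ValueError(
            f"offset {midpoint_offset} outside region of length {region_length}"
        )
    return (midpoint_offset * n_bins) // region_length + 1


def classify_probe(probe: ProbeRecord, gene: GeneModel) -> ProbeClass:
    """Full-containment classification of a probe against one gene."""
    if probe.chrom != gene.chrom:
        return ProbeClass(probe.probe_id, gene.gene_id, KLASS_UNASSIGNED)
    s, e = probe.start, probe.end
    if not gene.spliced:
        if gene.orf_start <= s and e <= gene.orf_end:
            return ProbeClass(probe.probe_id, gene.gene_id, KLASS_ORF_UNSPLICED)
        return ProbeClass(probe.probe_id, gene.gene_id, KLASS_UNASSIGNED)
    for idx, (fs, fe) in enumerate(gene.exons_tx_order(), start=1):
        if fs <= s and e <= fe:
            return ProbeClass(probe.probe_id, gene.gene_id, KLASS_EXON, idx)
    for idx, (fs, fe) in enumerate(gene.introns_tx_order(), start=1):
        if fs <= s and e <= fe:
            return ProbeClass(probe.probe_id, gene.gene_id, KLASS_INTRON, idx)
    return ProbeClass(probe.probe_id, gene.gene_id, KLASS_UNASSIGNED)


def assign_probe_to_gene_bins(probe: ProbeRecord, gene: GeneModel,
                              scheme: BinScheme) -> BinAssignment | None:
    """Place a probe midpoint into one (region, bin) of a gene, or None.

    Flank windows keep their offsets anchored at the ORF edge even where
    the window runs past a chromosome end (clipping removes positions
    but does not shift the anchor).
    """
    if probe.chrom != gene.chrom:
        return None
    m = probe.midpoint
    fwd = gene.strand == "+"
    # flank windows (400 bp, transcription-direction offsets)
    if fwd:
        prom_lo, prom_hi = gene.orf_start - scheme.flank_bp, gene.orf_start - 1
        term_lo, term_hi = gene.orf_end + 1, gene.orf_end + scheme.flank_bp
        prom_off = m - prom_lo
        term_off = m - term_lo
    else:
        prom_lo, prom_hi = gene.orf_end + 1, gene.orf_end + scheme.flank_bp
        term_lo, term_hi = gene.orf_start - scheme.flank_bp, gene.orf_start - 1
        prom_off = prom_hi - m
        term_off = term_hi - m
    if prom_lo <= m <= prom_hi:
        b = bin_of_midpoint(prom_off, scheme.flank_bp, scheme.n_flank_bins)
        return BinAssignment(REGION_PROMOTER, None, b)
    if term_lo <= m <= term_hi:
        b = bin_of_midpoint(term_off, scheme.flank_bp, scheme.n_flank_bins)
        return BinAssignment(REGION_TERMINATOR, None, b)
    if not (gene.orf_start <= m <= gene.orf_end):
        return None
    if not gene.spliced:
        (fs, fe) = gene.exons[0]
        off = m - fs if fwd else fe - m
        b = bin_of_midpoint(off, fe - fs + 1, scheme.n_orf_bins)
        return BinAssignment(REGION_ORF, None, b)
    for idx, (fs, fe) in enumerate(gene.exons_tx_order(), start=1):
        if fs <= m <= fe:
            off = m - fs if fwd else fe - m
            b = bin_of_midpoint(off, fe - fs + 1, scheme.n_exon_bins)
            return BinAssignment(REGION_EXON, idx, b)
    for idx, (fs, fe) in enumerate(gene.introns_tx_order(), start=1):
        if fs <= m <= fe:
            off = m - fs if fwd else fe - m
            b = bin_of_midpoint(off, fe - fs + 1, scheme.n_intron_bins)
            return BinAssignment(REGION_INTRON, idx, b)
    return None  # unreachable: exons+introns tile the ORF span


class ProbeIndex:
    """Sorted per-chromosome probe lookup for window queries."""

    def __init__(self, probes: Sequence[ProbeRecord]):
        self.by_chrom: dict[str, tuple[np.ndarray, list[ProbeRecord]]] = {}
        grouped: dict[str, list[ProbeRecord]] = {}
        for p in probes:
            grouped.setdefault(p.chrom, []).append(p)
        for chrom, ps in grouped.items():
            ps.sort(key=lambda p: p.midpoint)
            mids = np.array([p.midpoint for p in ps], dtype=np.int64)
            self.by_chrom[chrom] = (mids, ps)

    def midpoints_in(self, chrom: str, lo: int, hi: int) -> list[ProbeRecord]:
        """Probes whose midpoint lies in [lo, hi]."""
        if chrom not in self.by_chrom:
            return []
        mids, ps = self.by_chrom[chrom]
        i = int(np.searchsorted(mids, lo, side="left"))
        j = int(np.searchsorted(mids, hi, side="right"))
        return ps[i:j]


@dataclass
class AssignmentTables:
    """Full probe bookkeeping for one annotation/probe layout.

    ``bins``: one row per (probe, gene) midpoint placement — columns
    probe_id, gene_id, spliced, n_exons, region, feature_index, bin.
    ``classes``: one row per (probe, gene) full-containment class with
    klass != unassigned — columns probe_id, gene_id, klass, feature_index.
    ``outside_probe_ids``: probes placed in no (region, bin) of any gene.
    """

    bins: pd.DataFrame
    classes: pd.DataFrame
    outside_probe_ids: pd.Index = field(repr=False)


def assign_probes(annotation: GenomeAnnotation, probes: Sequence[ProbeRecord],
                  scheme: BinScheme) -> AssignmentTables:
    """Compute both assignment tables over all genes.

    Overlapping genes are handled independently: a probe may be placed
    within each gene that covers it.
    """
    index = ProbeIndex(probes)
    bin_rows = []
    class_rows = []
    assigned: set[str] = set()
    for gene in annotation.genes.values():
        lo = gene.orf_start - scheme.flank_bp
        hi = gene.orf_end + scheme.flank_bp
        for probe in index.midpoints_in(gene.chrom, lo, hi):
            asn = assign_probe_to_gene_bins(probe, gene, scheme)
            if asn is not None:
                bin_rows.append((probe.probe_id, gene.gene_id, gene.spliced,
                                 gene.n_exons, asn.region, asn.feature_index, asn.bin))
                assigned.add(probe.probe_id)
            klass = classify_probe(probe, gene)
            if klass.klass != KLASS_UNASSIGNED:
                class_rows.append((probe.probe_id, gene.gene_id, klass.klass,
                                   klass.feature_index))
    bins = pd.DataFrame(
        bin_rows, columns=["probe_id", "gene_id", "spliced", "n_exons",
                           "region", "feature_index", "bin"],
    )
    classes = pd.DataFrame(
        class_rows, columns=["probe_id", "gene_id", "klass", "feature_index"],
    )
    outside = pd.Index([p.probe_id for p in probes if p.probe_id not in assigned],
                       name="probe_id")
    return AssignmentTables(bins=bins, classes=classes, outside_probe_ids=outside)


def write_assignment_tsv(tables: AssignmentTables, path) -> None:
    """Export ``probe_id  gene_id  region  bin  klass`` per midpoint placement."""
    klass_map = {
        (r.probe_id, r.gene_id): r.klass for r in tables.classes.itertuples()
    }
    df = tables.bins.copy()
    df["klass"] = [
        klass_map.get((r.probe_id, r.gene_id), KLASS_UNASSIGNED)
        for r in df.itertuples()
    ]
    df[["probe_id", "gene_id", "region", "bin", "klass"]].to_csv(path, sep="\t", index=False)
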