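"""Average-gene (metagene) profile construction.

Two composite layouts are produced:

* ``unspliced_40``: promoter (10 bins) + ORF (20) + terminator (10).
* ``spliced_70``: seven 10-bin segments — promoter, the first exons'
  5' halves, the 3' halves of every exon upstream of an intron, all
  introns, the 5' halves of every exon downstream of an intron, the
  last exons' 3' halves, terminator.  This composite averages every
  exon-intron-exon junction of every gene; the half-exon construction
  guarantees no probe is counted twice within one composite segment
  (a probe sits in exactly one 20-bin exon position, which maps to at
  most one junction role).

Bin means average over *probes* directly (each plotted point is the
mean of all probes whose midpoint fell in that bin over all genes in
the set), not over per-gene means.  Empty bins carry count 0 and a NaN
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import (
    AssignmentTables,
    BinScheme,
    REGION_EXON,
    REGION_INTRON,
    REGION_ORF,
    REGION_PROMOTER,
    REGION_TERMINATOR,
    assign_probes,
)
from .genome_model import GeneModel, GenomeAnnotation, ProbeRecord
from .normalize import EnrichmentTrack

LAYOUT_UNSPLICED = "unspliced_40"
LAYOUT_SPLICED = "spliced_70"

SEGMENTS_UNSPLICED: list[tuple[str, int]] = [
    (REGION_PROMOTER, 10), (REGION_ORF, 20), (REGION_TERMINATOR, 10)]
SEGMENTS_SPLICED: list[tuple[str, int]] = [
    (REGION_PROMOTER, 10), ("exon_first", 10), ("exon_up", 10), (REGION_INTRON, 10),
    ("exon_down", 10), ("exon_last", 10), (REGION_TERMINATOR, 10)]


@dataclass
class MetageneProfile:
    """Ordered, region-labelled bin vector of averaged signal."""

    layout: str
    track_name: str
    gene_set_label: str
    bins: pd.DataFrame  # columns: segment, bin, mean, count

    @property
    def means(self) -> np.ndarray:
        return self.bins["mean"].to_numpy()

    @property
    def counts(self) -> np.ndarray:
        return self.bins["count"].to_numpy()

    def segment_means(self, segment: str) -> pd.Series:
        sub = self.bins[self.bins["segment"] == segment]
        return pd.Series(sub["mean"].to_numpy(), index=sub["bin"].to_numpy())


def composite_segment(region: str, feature_index: int | None, bin: int,
                      n_exons: int) -> tuple[str, int] | None:
    """Map one per-gene (region, feature ordinal, bin) to a spliced-layout
    composite (segment, bin), or None if the position serves no role.

    Exon bins 1-10 are the exon's 5' half, 11-20 its 3' half; roles:
    first exon 5' half, upstream-of-intron 3' halves, downstream-of-
    intron 5' halves, last exon 3' half.  Each (ordinal, bin) maps to at
    most one role.
    """
    if region in (REGION_PROMOTER, REGION_TERMINATOR):
        return (region, bin)
    if region == REGION_INTRON:
        return (REGION_INTRON, bin)
    if region == REGION_EXON:
        k = feature_index
        if bin <= 10:
            if k == 1:
                return ("exon_first", bin)
            return ("exon_down", bin)  # exon k>=2 is downstream of intron k-1
        if k == n_exons:
            return ("exon_last", bin - 10)
        return ("exon_up", bin - 10)  # exon k<=n-1 is upstream of intron k
    return None


def _empty_frame(segments: list[tuple[str, int]]) -> pd.DataFrame:
    rows = [(seg, b) for seg, n in segments for b in range(1, n + 1)]
    df = pd.DataFrame(rows, columns=["segment", "bin"])
    df["mean"] = np.nan
    df["count"] = 0
    return df


def _accumulate(df: pd.DataFrame, keys: pd.DataFrame, values: np.ndarray) -> pd.DataFrame:
    """Fill mean/count of the layout frame from (segment, bin, value) rows."""
    agg = (
        pd.DataFrame({"segment": keys["segment"], "bin": keys["bin"], "value": values})
        .groupby(["segment", "bin"], sort=False)["value"]
        .agg(["mean", "count"])
    )
    out = df.set_index(["segment", "bin"])
    out.loc[agg.index, "mean"] = agg["mean"]
    out.loc[agg.index, "count"] = agg["count"].astype(int)
    return out.reset_index()


def _bins_with_values(bins: pd.DataFrame, track: EnrichmentTrack) -> pd.DataFrame:
    df = bins.copy()
    df["value"] = track.values.reindex(df["probe_id"]).to_numpy()
    return df.dropna(subset=["value"])


def profile_from_bins(bins: pd.DataFrame, track: EnrichmentTrack, layout: str,
                      gene_set_label: str = "all") -> MetageneProfile:
    """Build a profile from a precomputed midpoint-assignment table.

    ``bins`` must be restricted to genes of the layout's splice status.
    """
    df = _bins_with_values(bins, track)
    if layout == LAYOUT_UNSPLICED:
        frame = _empty_frame(SEGMENTS_UNSPLICED)
        keys = df[["region", "bin"]].rename(columns={"region": "segment"})
        frame = _accumulate(frame, keys, df["value"].to_numpy())
    elif layout == LAYOUT_SPLICED:
        frame = _empty_frame(SEGMENTS_SPLICED)
        seg_bins = [
            composite_segment(r.region, r.feature_index, r.bin, r.n_exons)
            for r in df.itertuples()
        ]
        keep = [i for i, sb in enumerate(seg_bins) if sb is not None]
        keys = pd.DataFrame(
            [seg_bins[i] for i in keep], columns=["segment", "bin"], index=df.index[keep]
        )
        frame = _accumulate(frame, keys, df["value"].to_numpy()[keep])
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return MetageneProfile(layout=layout, track_name=track.name,
                           gene_set_label=gene_set_label, bins=frame)


def _profile(genes: list[GeneModel], track: EnrichmentTrack,
             probes: list[ProbeRecord], scheme: BinScheme, layout: str,
             gene_set_label: str) -> MetageneProfile:
    if not genes:
        raise ValueError("empty gene set")
    chrom_lengths: dict[str, int] = {}
    for g in genes:
        chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0),
                                     g.orf_end + scheme.flank_bp)
    ann = GenomeAnnotation(genes={g.gene_id: g for g in genes},
                           chrom_lengths=chrom_lengths)
    tables = assign_probes(ann, probes, scheme)
    return profile_from_bins(tables.bins, track, layout, gene_set_label)


def build_unspliced_profile(genes, track: EnrichmentTrack, probes, scheme: BinScheme,
                            gene_set_label: str = "all") -> MetageneProfile:
    """40-bin average-gene profile over a set of single-exon genes."""
    genes = list(genes)
    if any(g.spliced for g in genes):
        raise ValueError("build_unspliced_profile requires unspliced genes only")
    return _profile(genes, track, list(probes), scheme, LAYOUT_UNSPLICED, gene_set_label)


def build_spliced_profile(genes, track: EnrichmentTrack, probes, scheme: BinScheme,
                          gene_set_label: str = "all") -> MetageneProfile:
    """70-bin junction-composite profile over a set of spliced genes."""
    genes = list(genes)
    if any(not g.spliced for g in genes):
        raise ValueError("build_spliced_profile requires spliced genes only")
    return _profile(genes, track, list(probes), scheme, LAYOUT_SPLICED, gene_set_label)


@dataclass(frozen=True)
class BackgroundEstimate:
    """Signal level of probes outside every binned region."""

    mean_outside: float
    trimmed_mean_outside: float
    n_outside: int
    n_removed: int


def trim_count(n_outside: int, fraction: float = 0.10) -> int:
    """Number of top-signal probes removed for the trimmed background:
    the ceiling of ``fraction`` × n (152,253 outside probes → 15,226)."""
    return math.ceil(fraction * n_outside)


def estimate_background(track: EnrichmentTrack, tables: AssignmentTables,
                        trim_fraction: float = 0.10) -> BackgroundEstimate:
    """Mean signal of probes assigned to no (region, bin) of any gene,
    plus a trimmed mean with the top ``trim_fraction`` of probes by
    signal removed (they absorb unannotated transcribed regions)."""
    values = track.values.reindex(tables.outside_probe_ids).dropna().to_numpy()
    n = values.size
    if n == 0:
        raise ValueError("no probes outside binned regions")
    k = trim_count(n, trim_fraction)
    kept = np.sort(values)[: n - k] if k else np.sort(values)
    return BackgroundEstimate(
        mean_outside=float(values.mean()),
        trimmed_mean_outside=float(kept.mean()),
        n_outside=n,
        n_removed=k,
    )


def write_profile_tsv(profiles, path) -> None:
    """Write profiles as ``layout  gene_set_label  track  region  bin  mean  count``."""
    rows = []
    for p in profiles:
        for r in p.bins.itertuples():
            rows.append((p.layout, p.gene_set_label, p.track_name,
                         r.segment, r.bin, r.mean, r.count))
    pd.DataFrame(
        rows, columns=["layout", "gene_set_label", "track", "region", "bin", "mean", "count"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
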