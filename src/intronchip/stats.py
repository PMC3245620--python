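"""Bulk intron/exon comparisons and the Welch two-sample t-test.

The Welch (unequal-variance) t statistic and its Welch–Satterthwaite
degrees of freedom are computed from the standard definitions::

    t  = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
    df = (s_a^2/n_a + s_b^2/n_b)^2
         / ( (s_a^2/n_a)^2/(n_a-1) + (s_b^2/n_b)^2/(n_b-1) )

with the two-sided p-value from the t distribution.  P-values are
reported with a display floor of 2.2e-16 (the conventional printed
floor) while the exact value is retained internally.

All tests here are two-sided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .assign import AssignmentTables, KLASS_EXON, KLASS_INTRON
from .genome_model import GeneModel, GenomeAnnotation
from .metagene import composite_segment
from .normalize import EnrichmentTrack
from .stratify import ExpressionBinTable

logger = logging.getLogger(__name__)

P_DISPLAY_FLOOR = 2.2e-16


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False  # both variances zero with unequal means

    @property
    def p_display(self) -> float:
        """p floored at 2.2e-16 for reporting."""
        return max(self.p, P_DISPLAY_FLOOR)

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p, "p_display": self.p_display,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "n_a": self.n_a, "n_b": self.n_b,
        }


def welch_t_test(a, b) -> WelchResult:
    """Welch two-sample t-test of ``a`` vs ``b`` (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError(f"need >= 2 values per group (got {n_a}, {n_b})")
    # exact handling of constant groups: summation rounding would otherwise
    # turn a zero variance into ~eps^2 and the t statistic into noise
    if np.all(a == a[0]):
        m_a, v_a = float(a[0]), 0.0
    else:
        m_a, v_a = a.mean(), a.var(ddof=1)
    if np.all(b == b[0]):
        m_b, v_b = float(b[0]), 0.0
    else:
        m_b, v_b = b.mean(), b.var(ddof=1)
    if v_a == 0.0 and v_b == 0.0:
        if m_a == m_b:
            return WelchResult(0.0, float(n_a + n_b - 2), 1.0, m_a, m_b, n_a, n_b)
        logger.warning("welch_t_test: both variances zero with unequal means")
        t = math.inf if m_a > m_b else -math.inf
        return WelchResult(t, float(min(n_a, n_b) - 1), float(np.nextafter(0.0, 1.0)),
                           m_a, m_b, n_a, n_b, degenerate=True)
    se2_a = v_a / n_a
    se2_b = v_b / n_b
    t = (m_a - m_b) / math.sqrt(se2_a + se2_b)
    df = (se2_a + se2_b) ** 2 / (
        se2_a ** 2 / (n_a - 1) + se2_b ** 2 / (n_b - 1)
    )
    p = float(2.0 * t_dist.sf(abs(t), df))
    p = min(max(p, float(np.nextafter(0.0, 1.0))), 1.0)
    return WelchResult(float(t), float(df), p, float(m_a), float(m_b), n_a, n_b)


def quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation of order statistics."""
    q1, q2, q3 = np.percentile(np.asarray(values, float), [25, 50, 75])
    return float(q1), float(q2), float(q3)


def _class_values(track: EnrichmentTrack, classes: pd.DataFrame, klass: str,
                  gene_ids=None, feature_sel=None) -> np.ndarray:
    sel = classes["klass"] == klass
    if gene_ids is not None:
        sel &= classes["gene_id"].isin(gene_ids)
    if feature_sel is not None:
        sel &= feature_sel(classes)
    pids = classes.loc[sel, "probe_id"].drop_duplicates()
    return track.values.reindex(pids).dropna().to_numpy()


@dataclass(frozen=True)
class BulkResult:
    """Bulk intron-vs-exon contrast; group a = intron, group b = exon."""

    welch: WelchResult
    exon_median: float


def bulk_intron_exon_test(track: EnrichmentTrack, classes: pd.DataFrame,
                          gene_ids=None) -> BulkResult:
    """Welch test of all intron-probe values vs all exon-probe values."""
    intron = _class_values(track, classes, KLASS_INTRON, gene_ids)
    exon = _class_values(track, classes, KLASS_EXON, gene_ids)
    if intron.size < 2 or exon.size < 2:
        raise ValueError(
            f"need >= 2 probes per class (got {intron.size} intron, {exon.size} exon)"
        )
    return BulkResult(welch=welch_t_test(intron, exon),
                      exon_median=float(np.median(exon)))


@dataclass(frozen=True)
class PositionContrast:
    ordinal: int
    welch: WelchResult  # intron k (a) vs exon k (b)
    exon_quartiles: tuple[float, float, float]
    intron_quartiles: tuple[float, float, float]


def position_wise_tests(track: EnrichmentTrack, classes: pd.DataFrame,
                        max_ordinal: int) -> list[PositionContrast]:
    """Per position k: Welch test of intron-k probes vs exon-k probes.

    Ordinals with fewer than 2 probes in either member are skipped with
    a logged warning.
    """
    out = []
    for k in range(1, max_ordinal + 1):
        sel_k = lambda df, k=k: df["feature_index"] == k
        intron = _class_values(track, classes, KLASS_INTRON, feature_sel=sel_k)
        exon = _class_values(track, classes, KLASS_EXON, feature_sel=sel_k)
        if intron.size < 2 or exon.size < 2:
            logger.warning("position %d: too few probes (%d intron, %d exon); skipped",
                           k, intron.size, exon.size)
            continue
        out.append(PositionContrast(
            ordinal=k,
            welch=welch_t_test(intron, exon),
            exon_quartiles=quartiles(exon),
            intron_quartiles=quartiles(intron),
        ))
    return out


@dataclass(frozen=True)
class DecileContrast:
    """Intron-vs-exon contrast within one expression decile.

    Ratios are log2-scale differences (exon mean − intron mean): track
    values are already log2 enrichments, so the ratio of occupancies is
    the difference of means.
    """

    decile: int
    track: str
    mean_intron: float
    mean_up_exon: float
    mean_down_exon: float
    ratio_up: float
    ratio_down: float
    p: float
    p_display: float
    n_intron: int
    n_exon: int


def _junction_role_probes(bins: pd.DataFrame, gene_ids, role: str) -> pd.Index:
    sub = bins[(bins["gene_id"].isin(gene_ids)) & (bins["region"] == "exon")]
    keep = []
    for r in sub.itertuples():
        sb = composite_segment(r.region, r.feature_index, r.bin, r.n_exons)
        if sb is not None and sb[0] == role:
            keep.append(r.probe_id)
    return pd.Index(keep).drop_duplicates()


def decile_contrasts(track: EnrichmentTrack, tables: AssignmentTables,
                     bins: ExpressionBinTable, annotation: GenomeAnnotation,
                     exon_mode: str = "junction",
                     ratio_scale: str = "log_mean_diff") -> list[DecileContrast]:
    """Per decile: intron mean, junction-adjacent exon means, log2 ratios
    and the Welch p of intron vs pooled exon probes (spliced genes only).

    ``exon_mode``: "junction" restricts the up/down exon means to the
    exon halves adjacent to an intron (composite segments exon_up /
    exon_down); "whole" uses all probes of exons that have a downstream
    (upstream) intron.  ``ratio_scale``: "log_mean_diff" (default)
    reports differences of mean log2 signals; "log_of_linear_means"
    reports log2 of the ratio of linearized means.
    """
    classes = tables.classes
    out = []
    for d in range(1, bins.n_groups + 1):
        gids = bins.decile_gene_ids(d, spliced=True)
        if not gids:
            raise ValueError(f"decile {d} has no spliced genes")
        intron = _class_values(track, classes, KLASS_INTRON, gids)
        exon = _class_values(track, classes, KLASS_EXON, gids)
        if intron.size < 2 or exon.size < 2:
            raise ValueError(
                f"decile {d}: need >= 2 intron and exon probes "
                f"(got {intron.size}, {exon.size})"
            )
        if exon_mode == "junction":
            up_ids = _junction_role_probes(tables.bins, gids, "exon_up")
            down_ids = _junction_role_probes(tables.bins, gids, "exon_down")
            up = track.values.reindex(up_ids).dropna().to_numpy()
            down = track.values.reindex(down_ids).dropna().to_numpy()
        elif exon_mode == "whole":
            n_exons = {g: annotation.genes[g].n_exons for g in gids}
            up = _class_values(
                track, classes, KLASS_EXON, gids,
                feature_sel=lambda df: df["feature_index"] < df["gene_id"].map(n_exons))
            down = _class_values(
                track, classes, KLASS_EXON, gids,
                feature_sel=lambda df: df["feature_index"] > 1)
        else:
            raise ValueError(f"unknown exon_mode {exon_mode!r}")

        def _mean(x: np.ndarray) -> float:
            return float(x.mean()) if x.size else float("nan")

        if ratio_scale == "log_mean_diff":
            mi, mu, md = _mean(intron), _mean(up), _mean(down)
            ratio_up, ratio_down = mu - mi, md - mi
        elif ratio_scale == "log_of_linear_means":
            mi = float(np.log2(np.mean(2.0 ** intron)))
            mu = float(np.log2(np.mean(2.0 ** up)))
            md = float(np.log2(np.mean(2.0 ** down)))
            ratio_up, ratio_down = mu - mi, md - mi
        else:
            raise ValueError(f"unknown ratio_scale {ratio_scale!r}")
        w = welch_t_test(intron, exon)
        out.append(DecileContrast(
            decile=d, track=track.name, mean_intron=mi, mean_up_exon=mu,
            mean_down_exon=md, ratio_up=ratio_up, ratio_down=ratio_down,
            p=w.p, p_display=w.p_display, n_intron=intron.size, n_exon=exon.size,
        ))
    return out


def gc_boundary_test(genes, genome) -> WelchResult:
    """Welch test of GC content at intron 5' vs 3' ends (25-bp windows).

    For every intron of length >= 25 bp, the GC fraction of the first
    and last 25 bases in the direction of transcription is computed
    (GC content is strand-symmetric, so genomic-strand sequence
    suffices).  Shorter introns are skipped with a logged count.
    """
    from .genome_model import gc_fraction_of_sequence

    five, three = [], []
    n_skipped = 0
    for gene in genes:
        if not gene.spliced:
            continue
        for (s, e) in gene.introns_tx_order():
            if e - s + 1 < 25:
                n_skipped += 1
                continue
            if isinstance(genome, dict):
                seq = genome[gene.chrom]
            else:
                seq = str(genome[gene.chrom][:])
            left = seq[s - 1 : s + 24]
            right = seq[e - 25 : e]
            if gene.strand == "+":
                five.append(gc_fraction_of_sequence(left))
                three.append(gc_fraction_of_sequence(right))
            else:
                five.append(gc_fraction_of_sequence(right))
                three.append(gc_fraction_of_sequence(left))
    if n_skipped:
        logger.info("gc_boundary_test: skipped %d intron(s) shorter than 25 bp", n_skipped)
    if len(five) < 2:
        raise ValueError(f"need >= 2 introns of length >= 25 bp (got {len(five)})")
    return welch_t_test(five, three)


def contrasts_to_frame(contrasts: list[DecileContrast]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contrasts])
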