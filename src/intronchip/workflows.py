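"""One-call analyses over a generated study, shared by the numbered
analysis drivers and the reproduction script."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .assign import AssignmentTables, BinScheme, assign_probes
from .genome_model import GenomeAnnotation, ProbeRecord
from .metagene import (
    BackgroundEstimate,
    LAYOUT_SPLICED,
    MetageneProfile,
    estimate_background,
    profile_from_bins,
)
from .normalize import EnrichmentTrack, subtract_input
from .pipeline import build_tracks
from .stats import (
    BulkResult,
    DecileContrast,
    WelchResult,
    bulk_intron_exon_test,
    decile_contrasts,
    gc_boundary_test,
)
from .stratify import ExpressionBinTable, filter_and_rank
from .synthetic_data import (
    Amplitudes,
    GroundTruth,
    SimConfig,
    generate_genome,
    generate_signals,
)


@dataclass
class StudyAnalysis:
    """Everything the end-to-end analysis measures on one study."""

    config: SimConfig
    annotation: GenomeAnnotation
    sequences: dict[str, str]
    probes: list[ProbeRecord]
    truth: GroundTruth
    tracks: dict[str, EnrichmentTrack]
    tables: AssignmentTables
    expression_bins: ExpressionBinTable
    bulk_polII: BulkResult
    contrasts: list[DecileContrast]
    ratio_decile_spearman: float
    spliced_profiles: dict[str, MetageneProfile]
    faire_h3_profile_pearson: float
    background: BackgroundEstimate
    gc_boundary: WelchResult


def analyze_study(config: SimConfig, scheme: BinScheme | None = None) -> StudyAnalysis:
    """Generate a study under ``config`` and run the full analysis on it."""
    scheme = scheme or BinScheme()
    annotation, sequences, probes = generate_genome(config)
    arrays, expr, truth = generate_signals(config, annotation, sequences, probes)
    tracks = build_tracks(arrays)
    tables = assign_probes(annotation, probes, scheme)
    bins = filter_and_rank(expr, annotation, n_groups=config.n_expression_groups)

    bulk = bulk_intron_exon_test(tracks["polII"], tables.classes)
    contrasts = decile_contrasts(tracks["polII"], tables, bins, annotation)
    rho = float(spearmanr([c.decile for c in contrasts],
                          [c.ratio_up for c in contrasts]).statistic)

    spliced_bins = tables.bins[tables.bins["spliced"]]
    profiles = {
        name: profile_from_bins(spliced_bins, tracks[name], LAYOUT_SPLICED, "all")
        for name in ("polII", "h3", "k36_norm", "faire")
    }
    mask = (profiles["faire"].bins["count"] > 0) & (profiles["h3"].bins["count"] > 0)
    pearson = float(np.corrcoef(
        profiles["faire"].bins.loc[mask, "mean"],
        profiles["h3"].bins.loc[mask, "mean"])[0, 1])

    background = estimate_background(tracks["polII"], tables)
    gc = gc_boundary_test(annotation.genes.values(), sequences)

    return StudyAnalysis(
        config=config, annotation=annotation, sequences=sequences, probes=probes,
        truth=truth, tracks=tracks, tables=tables, expression_bins=bins,
        bulk_polII=bulk, contrasts=contrasts, ratio_decile_spearman=rho,
        spliced_profiles=profiles, faire_h3_profile_pearson=pearson,
        background=background, gc_boundary=gc,
    )


def null_calibration_pvalues(n_seeds: int = 200, base_seed: int = 0,
                             n_genes: int = 60) -> list[float]:
    """Bulk intron-vs-exon Welch p-values under the null (all planted
    amplitudes zero) over independent signal draws on one fixed genome.

    The genome layout is held fixed (it carries no signal under the null)
    while each seed draws fresh array noise, which is what the p-value
    distribution is about.
    """
    base_cfg = SimConfig(seed=base_seed, n_genes=n_genes, n_chroms=1,
                         amplitudes=Amplitudes.null())
    annotation, sequences, probes = generate_genome(base_cfg)
    tables = assign_probes(annotation, probes, BinScheme())
    pvals = []
    for i in range(n_seeds):
        cfg = replace(base_cfg, seed=base_seed + 1000 + i)
        arrays, _, _ = generate_signals(cfg, annotation, sequences, probes)
        track = subtract_input(arrays["polII_ip"], arrays["input"])
        pvals.append(bulk_intron_exon_test(track, tables.classes).welch.p)
    return pvals


def promoter_peak_bin(profile: MetageneProfile) -> int:
    """Bin ordinal (1..10) of the maximum mean within the promoter segment."""
    seg = profile.segment_means("promoter").dropna()
    return int(seg.idxmax())


def intron_peak_bin(profile: MetageneProfile) -> int:
    """Bin ordinal (1..10) of the maximum mean within the intron segment."""
    seg = profile.segment_means("intron").dropna()
    return int(seg.idxmax())
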