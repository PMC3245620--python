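"""Shared fixtures: toy gene models and a small synthetic study bundle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from intronchip.assign import BinScheme
from intronchip.genome_model import GeneModel, GenomeAnnotation, ProbeRecord
from intronchip.normalize import EnrichmentTrack
from intronchip.synthetic_data import SimConfig, generate_genome, generate_signals


@pytest.fixture
def scheme() -> BinScheme:
    return BinScheme()


@pytest.fixture
def gene_plus() -> GeneModel:
    """Spliced plus-strand gene: exons (1001,1400),(1501,1700),(1801,2000)."""
    return GeneModel("gplus", "chrT", "+", ((1001, 1400), (1501, 1700), (1801, 2000)))


@pytest.fixture
def gene_minus() -> GeneModel:
    """Spliced minus-strand gene with the same genomic exon structure."""
    return GeneModel("gminus", "chrT", "-", ((1001, 1400), (1501, 1700), (1801, 2000)))


@pytest.fixture
def gene_unspliced() -> GeneModel:
    return GeneModel("gsingle", "chrT", "+", ((1001, 2000),))


def random_gene(rng: np.random.Generator, gene_id: str, chrom: str = "chrR",
                max_exons: int = 4) -> GeneModel:
    """Small random gene for oracle comparisons (exons 30-200 bp, introns 26-90 bp)."""
    n_exons = int(rng.integers(1, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(500, 2000))
    exons = []
    for i in range(n_exons):
        length = int(rng.integers(30, 201))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(26, 91))
    return GeneModel(gene_id, chrom, strand, tuple(exons))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_genes=60, n_chroms=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Generated-in-memory small study: (config, annotation, sequences, probes,
    arrays, expression table, ground truth)."""
    ann, seqs, probes = generate_genome(small_config)
    arrays, expr, truth = generate_signals(small_config, ann, seqs, probes)
    return small_config, ann, seqs, probes, arrays, expr, truth


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory, small_config):
    from intronchip.synthetic_data import write_fixture_bundle

    d = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_config, d)
    return d


def constant_track(probes, value: float, name: str = "const") -> EnrichmentTrack:
    return EnrichmentTrack(
        name=name,
        values=pd.Series(value, index=pd.Index([p.probe_id for p in probes],
                                               name="probe_id"), dtype=float),
    )


def probes_covering(genes, chrom: str, step: int = 7, flank: int = 450) -> list[ProbeRecord]:
    """Dense probe tiling across the span of a set of genes plus flanks."""
    lo = min(g.orf_start for g in genes) - flank
    hi = max(g.orf_end for g in genes) + flank
    lo = max(lo, 1)
    return [
        ProbeRecord(f"{chrom}_p{s:06d}", chrom, s)
        for s in range(lo, hi - 24, step)
    ]


def annotation_for(genes, flank: int = 600) -> GenomeAnnotation:
    lengths: dict[str, int] = {}
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.orf_end + flank)
    return GenomeAnnotation(genes={g.gene_id: g for g in genes}, chrom_lengths=lengths)
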