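"""Average-gene profile construction, junction composition, background."""

import numpy as np
import pandas as pd
import pytest

from intronchip.genome_model import GeneModel, ProbeRecord
from intronchip.metagene import (
    LAYOUT_SPLICED,
    LAYOUT_UNSPLICED,
    build_spliced_profile,
    build_unspliced_profile,
    estimate_background,
    profile_from_bins,
    trim_count,
)
from intronchip.normalize import EnrichmentTrack
from intronchip.assign import assign_probes

from conftest import annotation_for, constant_track, probes_covering, random_gene
from test_assign import oracle_gene_bins


def oracle_spliced_composite(gene: GeneModel, region: str, feature_index, bin: int):
    """Junction-role mapping re-derived by enumerating every
    exon-intron-exon junction of the gene plus the two end roles."""
    n = gene.n_exons
    roles = []
    for j in range(1, n):  # junction j: exon j -- intron j -- exon j+1
        roles.append(("exon", j, range(11, 21), "exon_up", -10))
        roles.append(("intron", j, range(1, 11), "intron", 0))
        roles.append(("exon", j + 1, range(1, 11), "exon_down", 0))
    roles.append(("exon", 1, range(1, 11), "exon_first", 0))
    roles.append(("exon", n, range(11, 21), "exon_last", -10))
    if region in ("promoter", "terminator"):
        return [(region, bin)]
    hits = []
    for r_region, r_idx, r_bins, seg, shift in roles:
        if region == r_region and feature_index == r_idx and bin in r_bins:
            hits.append((seg, bin + shift))
    return hits


def dense_values(probes, rng):
    return pd.Series(rng.normal(size=len(probes)),
                     index=pd.Index([p.probe_id for p in probes], name="probe_id"))


class TestUnsplicedProfile:
    def test_constant_track(self, scheme):
        genes = [GeneModel("g1", "c", "+", ((1001, 1800),)),
                 GeneModel("g2", "c", "-", ((3001, 4200),))]
        probes = probes_covering(genes, "c")
        profile = build_unspliced_profile(genes, constant_track(probes, 1.7), probes, scheme)
        nonempty = profile.bins[profile.bins["count"] > 0]
        assert len(nonempty) > 30
        assert np.allclose(nonempty["mean"], 1.7)
        empty = profile.bins[profile.bins["count"] == 0]
        assert empty["mean"].isna().all()

    def test_single_probe_lands_in_one_bin(self, scheme):
        gene = GeneModel("g", "c", "+", ((1001, 2000),))
        # promoter window 601-1000; bin 3 covers offsets 80-119 -> positions 681-720
        probe = ProbeRecord("p", "c", 688)  # midpoint 700, offset 99
        track = EnrichmentTrack("t", pd.Series({"p": 1.7}))
        profile = build_unspliced_profile([gene], track, [probe], scheme)
        hit = profile.bins[profile.bins["count"] > 0]
        assert len(hit) == 1
        row = hit.iloc[0]
        assert (row["segment"], row["bin"], row["mean"], row["count"]) == ("promoter", 3, 1.7, 1)

    def test_rejects_empty_or_spliced_input(self, scheme):
        with pytest.raises(ValueError):
            build_unspliced_profile([], constant_track([], 0.0), [], scheme)
        spliced = GeneModel("g", "c", "+", ((1, 100), (151, 300)))
        with pytest.raises(ValueError):
            build_unspliced_profile([spliced], constant_track([], 0.0), [], scheme)


class TestSplicedProfile:
    def _random_study(self, seed, n_genes=6):
        rng = np.random.default_rng(seed)
        genes = []
        pos = 600
        for i in range(n_genes):
            g = random_gene(rng, f"g{i}")
            shift = pos - g.orf_start
            genes.append(GeneModel(g.gene_id, "c", g.strand,
                                   tuple((s + shift, e + shift) for s, e in g.exons)))
            pos = genes[-1].orf_end + 900
        genes = [g for g in genes if g.spliced]
        probes = probes_covering(genes, "c", step=6)
        track = EnrichmentTrack("t", dense_values(probes, rng))
        return genes, probes, track

    def test_constant_track(self, scheme):
        genes, probes, _ = self._random_study(3)
        profile = build_spliced_profile(genes, constant_track(probes, -0.4), probes, scheme)
        nonempty = profile.bins[profile.bins["count"] > 0]
        assert np.allclose(nonempty["mean"], -0.4)

    def test_bin_means_match_exhaustive_triple_oracle(self, scheme):
        """Every (gene, probe, composite bin) triple enumerated explicitly."""
        for seed in (5, 6, 7):
            genes, probes, track = self._random_study(seed)
            profile = build_spliced_profile(genes, track, probes, scheme)
            sums: dict = {}
            counts: dict = {}
            for g in genes:
                for p in probes:
                    asn = oracle_gene_bins(p, g, scheme)
                    if asn is None:
                        continue
                    for seg_bin in oracle_spliced_composite(g, *asn):
                        sums[seg_bin] = sums.get(seg_bin, 0.0) + track.values[p.probe_id]
                        counts[seg_bin] = counts.get(seg_bin, 0) + 1
            for row in profile.bins.itertuples():
                key = (row.segment, row.bin)
                assert row.count == counts.get(key, 0)
                if row.count:
                    assert row.mean == pytest.approx(sums[key] / counts[key], abs=1e-12)

    def test_no_double_counting_in_composite_segments(self, scheme):
        """Contribution matrix: each probe contributes at most once per
        composite segment within one gene, including multi-intron genes
        where middle exons serve two junction roles."""
        gene = GeneModel("g", "c", "+", ((1001, 1300), (1401, 1700), (1801, 2100)))
        probes = probes_covering([gene], "c", step=4)
        for p in probes:
            asn = oracle_gene_bins(p, gene, scheme)
            if asn is None:
                continue
            contributions = oracle_spliced_composite(gene, *asn)
            segments = [seg for seg, _ in contributions]
            assert len(segments) == len(set(segments))
        # middle exon serves both roles across its two halves
        mid_up = oracle_spliced_composite(gene, "exon", 2, 15)
        mid_down = oracle_spliced_composite(gene, "exon", 2, 5)
        assert mid_up == [("exon_up", 5)] and mid_down == [("exon_down", 5)]

    def test_strand_symmetry(self, scheme):
        """A signal mirror-symmetric about the gene center, sampled at every
        position, yields identical transcription-order profiles for plus-
        and minus-strand copies of the same exon structure (the exon
        structure here is itself mirror-symmetric)."""
        plus = GeneModel("gp", "c", "+", ((2001, 2400), (2501, 2900)))
        minus = GeneModel("gm", "c", "-", ((2001, 2400), (2501, 2900)))
        probes = probes_covering([plus], "c", step=1)
        mid = (plus.orf_start + plus.orf_end) / 2
        values = pd.Series(
            [abs(p.midpoint - mid) / 100.0 for p in probes],
            index=pd.Index([p.probe_id for p in probes], name="probe_id"),
        )
        track = EnrichmentTrack("sym", values)
        prof_p = build_spliced_profile([plus], track, probes, scheme)
        prof_m = build_spliced_profile([minus], track, probes, scheme)
        merged = prof_p.bins.merge(prof_m.bins, on=["segment", "bin"],
                                   suffixes=("_p", "_m"))
        assert (merged["count_p"] == merged["count_m"]).all()
        both = merged["count_p"] > 0
        assert np.allclose(merged.loc[both, "mean_p"],
                           merged.loc[both, "mean_m"], atol=1e-9)


class TestWeightedRecombination:
    def test_pooled_equals_count_weighted_parts(self, scheme):
        rng = np.random.default_rng(21)
        genes = []
        pos = 700
        for i in range(8):
            g = random_gene(rng, f"g{i}")
            shift = pos - g.orf_start
            genes.append(GeneModel(g.gene_id, "c", g.strand,
                                   tuple((s + shift, e + shift) for s, e in g.exons)))
            pos = genes[-1].orf_end + 900
        spliced = [g for g in genes if g.spliced]
        probes = probes_covering(genes, "c", step=5)
        track = EnrichmentTrack("t", dense_values(probes, rng))
        pooled = build_spliced_profile(spliced, track, probes, scheme)
        half = len(spliced) // 2
        parts = [build_spliced_profile(s, track, probes, scheme)
                 for s in (spliced[:half], spliced[half:])]
        for i in range(len(pooled.bins)):
            n = sum(p.bins["count"].iloc[i] for p in parts)
            assert n == pooled.bins["count"].iloc[i]
            if n == 0:
                continue
            weighted = sum(
                p.bins["count"].iloc[i] * p.bins["mean"].iloc[i]
                for p in parts if p.bins["count"].iloc[i] > 0
            ) / n
            assert abs(weighted - pooled.bins["mean"].iloc[i]) < 1e-9


class TestBackground:
    def test_trim_count_arithmetic(self):
        assert trim_count(152_253) == 15_226
        assert trim_count(10) == 1
        assert trim_count(91) == 10  # ceiling, not floor

    def test_constant_outside_signal(self, scheme):
        gene = GeneModel("g", "c", "+", ((1001, 2000),))
        ann = annotation_for([gene], flank=3000)
        probes = probes_covering([gene], "c", step=10, flank=2000)
        tables = assign_probes(ann, probes, scheme)
        assert len(tables.outside_probe_ids) > 0
        track = constant_track(probes, 0.33)
        bg = estimate_background(track, tables)
        assert bg.mean_outside == pytest.approx(0.33)
        assert bg.trimmed_mean_outside == pytest.approx(0.33)
        assert bg.n_removed == trim_count(bg.n_outside)

    def test_trimmed_mean_never_exceeds_mean(self, scheme):
        gene = GeneModel("g", "c", "+", ((1001, 2000),))
        ann = annotation_for([gene], flank=3000)
        probes = probes_covering([gene], "c", step=10, flank=2000)
        tables = assign_probes(ann, probes, scheme)
        rng = np.random.default_rng(5)
        for _ in range(20):
            track = EnrichmentTrack("t", dense_values(probes, rng))
            bg = estimate_background(track, tables)
            assert bg.trimmed_mean_outside <= bg.mean_outside + 1e-12
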