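"""Welch t-test and the intron/exon contrast machinery."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from intronchip.assign import BinScheme, assign_probes
from intronchip.genome_model import GeneModel
from intronchip.normalize import EnrichmentTrack
from intronchip.stats import (
    P_DISPLAY_FLOOR,
    bulk_intron_exon_test,
    decile_contrasts,
    gc_boundary_test,
    position_wise_tests,
    quartiles,
    welch_t_test,
)
from intronchip.stratify import filter_and_rank

from conftest import annotation_for, probes_covering
from test_stratify import expr_frame, make_annotation


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_independent_reference(self):
        """Fixed vectors against scipy's independent Welch implementation."""
        cases = [
            ([1, 2, 3, 4], [3, 4, 5, 6]),
            ([0.1, 0.9, 0.4, 0.6, 0.2], [1.0, 1.2, 0.8]),
            (np.random.default_rng(0).normal(size=40),
             np.random.default_rng(1).normal(1.0, 2.0, size=25)),
        ]
        for a, b in cases:
            res = welch_t_test(a, b)
            ref = scipy.stats.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert res.df == pytest.approx(ref.df, abs=1e-10)

    def test_equal_n_equal_variance_df_is_pooled(self):
        """With n_a = n_b and equal sample variances, the Welch df reduces
        to the pooled n_a + n_b - 2 exactly."""
        a = [1.0, 2.0, 3.0, 4.0]
        b = [11.0, 12.0, 13.0, 14.0]
        res = welch_t_test(a, b)
        assert res.df == pytest.approx(len(a) + len(b) - 2, abs=1e-12)

    def test_df_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(0, 3, size=rng.integers(2, 30))
            res = welch_t_test(a, b)
            assert min(len(a) - 1, len(b) - 1) - 1e-9 <= res.df <= len(a) + len(b) - 2 + 1e-9
            assert 0 < res.p <= 1

    def test_antisymmetry_and_invariances(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=15)
        b = rng.normal(1, 2, size=12)
        fwd = welch_t_test(a, b)
        rev = welch_t_test(b, a)
        assert fwd.t == pytest.approx(-rev.t, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)
        assert fwd.df == pytest.approx(rev.df, abs=1e-12)
        shift = welch_t_test(a + 5.0, b + 5.0)
        scale = welch_t_test(a * 3.0, b * 3.0)
        assert shift.t == pytest.approx(fwd.t, rel=1e-9)
        assert scale.t == pytest.approx(fwd.t, rel=1e-9)

    def test_degenerate_zero_variance_unequal_means(self):
        res = welch_t_test([1.0, 1.0], [2.0, 2.0])
        assert res.degenerate and res.p_display == P_DISPLAY_FLOOR

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_p_display_floor(self):
        rng = np.random.default_rng(2)
        res = welch_t_test(rng.normal(0, 0.01, 500), rng.normal(10, 0.01, 500))
        assert res.p < P_DISPLAY_FLOOR < 1e-15
        assert res.p_display == P_DISPLAY_FLOOR


class TestQuartiles:
    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=37)
        q1, q2, q3 = quartiles(values)
        s = np.sort(values)

        def oracle(q):
            h = q * (len(s) - 1)
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert q1 == pytest.approx(oracle(0.25), abs=1e-12)
        assert q2 == pytest.approx(oracle(0.50), abs=1e-12)
        assert q3 == pytest.approx(oracle(0.75), abs=1e-12)


def _classes_frame(intron_ids, exon_ids, gene_id="g", ordinal=1):
    rows = [(p, gene_id, "intron_probe", ordinal) for p in intron_ids]
    rows += [(p, gene_id, "exon_probe", ordinal) for p in exon_ids]
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "klass", "feature_index"])


def _track(values: dict[str, float]) -> EnrichmentTrack:
    return EnrichmentTrack("polII", pd.Series(values, dtype=float))


class TestBulkTest:
    def test_known_planted_effect(self):
        rng = np.random.default_rng(7)
        n = 1000
        intron_ids = [f"i{k}" for k in range(n)]
        exon_ids = [f"e{k}" for k in range(n)]
        vals = {p: 1.0 + rng.normal(0, 0.1) for p in intron_ids}
        vals.update({p: 0.0 + rng.normal(0, 0.1) for p in exon_ids})
        res = bulk_intron_exon_test(_track(vals), _classes_frame(intron_ids, exon_ids))
        assert res.welch.mean_a - res.welch.mean_b == pytest.approx(1.0, abs=0.02)
        assert res.welch.p < 1e-100
        assert res.welch.p_display == P_DISPLAY_FLOOR
        assert res.exon_median == pytest.approx(0.0, abs=0.02)

    def test_identical_groups_give_p_one(self):
        vals = {"i1": 0.5, "i2": 0.5, "e1": 0.5, "e2": 0.5}
        res = bulk_intron_exon_test(_track(vals), _classes_frame(["i1", "i2"], ["e1", "e2"]))
        assert res.welch.t == 0.0 and res.welch.p == 1.0

    def test_null_p_values_are_uniform(self):
        """Type-I calibration at small scale: both groups from one
        distribution, KS uniformity over 300 seeded repetitions."""
        pvals = []
        rng = np.random.default_rng(99)
        for _ in range(300):
            a = rng.normal(size=30)
            b = rng.normal(size=45)
            pvals.append(welch_t_test(a, b).p)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_insufficient_probes(self):
        with pytest.raises(ValueError):
            bulk_intron_exon_test(_track({"i1": 1.0, "e1": 0.0, "e2": 0.1}),
                                  _classes_frame(["i1"], ["e1", "e2"]))


class TestPositionWise:
    def test_uniform_elevation_significant_everywhere(self):
        rng = np.random.default_rng(15)
        rows = []
        vals = {}
        for k in (1, 2):
            for j in range(60):
                pid = f"i{k}_{j}"
                rows.append((pid, "g", "intron_probe", k))
                vals[pid] = 0.8 + rng.normal(0, 0.2)
            for j in range(80):
                pid = f"e{k}_{j}"
                rows.append((pid, "g", "exon_probe", k))
                vals[pid] = 0.0 + rng.normal(0, 0.2)
        classes = pd.DataFrame(rows, columns=["probe_id", "gene_id", "klass", "feature_index"])
        results = position_wise_tests(_track(vals), classes, max_ordinal=2)
        assert [r.ordinal for r in results] == [1, 2]
        assert all(r.welch.p < 1e-10 for r in results)
        for r in results:
            assert r.intron_quartiles[1] > r.exon_quartiles[1]

    def test_sparse_ordinal_skipped(self, caplog):
        vals = {"i1": 1.0, "i2": 1.2, "e1": 0.0, "e2": 0.1, "i3": 5.0, "e3": 4.0}
        rows = [("i1", "g", "intron_probe", 1), ("i2", "g", "intron_probe", 1),
                ("e1", "g", "exon_probe", 1), ("e2", "g", "exon_probe", 1),
                ("i3", "g", "intron_probe", 2), ("e3", "g", "exon_probe", 2)]
        classes = pd.DataFrame(rows, columns=["probe_id", "gene_id", "klass", "feature_index"])
        results = position_wise_tests(_track(vals), classes, max_ordinal=2)
        assert [r.ordinal for r in results] == [1]


class TestDecileContrasts:
    def _study(self, seed=23, amplitude_of=None):
        """Three-decile toy study with an optional per-decile intron shift."""
        ann = make_annotation(12, 10)
        genes = list(ann.genes.values())
        probes = probes_covering(genes, "c", step=6)
        rng = np.random.default_rng(seed)
        vals = {g.gene_id: float(v) for g, v in
                zip(genes, rng.uniform(2, 500, size=len(genes)))}
        bins = filter_and_rank(expr_frame(vals), ann, n_groups=3)
        scheme = BinScheme()
        tables = assign_probes(ann, probes, scheme)
        decile_of = dict(zip(bins.table["gene_id"], bins.table["decile"]))
        track_vals = {}
        intron_probe_gene = dict(zip(tables.classes["probe_id"],
                                     tables.classes["gene_id"]))
        intron_ids = set(tables.classes.loc[
            tables.classes["klass"] == "intron_probe", "probe_id"])
        for p in probes:
            base = rng.normal(0, 0.05)
            if amplitude_of and p.probe_id in intron_ids:
                d = decile_of.get(intron_probe_gene[p.probe_id])
                if pd.notna(d):
                    base += amplitude_of(int(d))
            track_vals[p.probe_id] = base
        return ann, tables, bins, _track(track_vals)

    def test_constant_track_gives_zero_ratios(self, scheme):
        ann, tables, bins, _ = self._study()
        const = EnrichmentTrack("polII", pd.Series(
            0.7, index=pd.Index(sorted({r for r in tables.bins["probe_id"]}))))
        out = decile_contrasts(const, tables, bins, ann)
        for c in out:
            assert c.ratio_up == pytest.approx(0.0, abs=1e-12)
            assert c.ratio_down == pytest.approx(0.0, abs=1e-12)
            assert c.p == 1.0

    def test_ratio_identity(self):
        ann, tables, bins, track = self._study()
        for c in decile_contrasts(track, tables, bins, ann):
            assert c.ratio_up == pytest.approx(c.mean_up_exon - c.mean_intron, abs=1e-12)
            assert c.ratio_down == pytest.approx(c.mean_down_exon - c.mean_intron, abs=1e-12)

    def test_programmed_amplitude_recovered_in_order(self):
        """Intron elevation growing as expression falls is recovered as an
        exon-minus-intron ratio that decreases with the decile index."""
        ann, tables, bins, track = self._study(
            seed=29, amplitude_of=lambda d: 0.4 * d)
        out = decile_contrasts(track, tables, bins, ann)
        ratios = [c.ratio_up for c in out]
        assert ratios[0] > ratios[1] > ratios[2]
        rho = scipy.stats.spearmanr([c.decile for c in out], ratios).statistic
        assert rho == -1.0

    def test_whole_exon_mode_and_ratio_scale_switches(self):
        ann, tables, bins, track = self._study(seed=31)
        default = decile_contrasts(track, tables, bins, ann)
        whole = decile_contrasts(track, tables, bins, ann, exon_mode="whole")
        linear = decile_contrasts(track, tables, bins, ann,
                                  ratio_scale="log_of_linear_means")
        assert len(default) == len(whole) == len(linear) == 3
        with pytest.raises(ValueError):
            decile_contrasts(track, tables, bins, ann, exon_mode="nope")


class TestGCBoundary:
    def _genome_with_introns(self, gc_3prime_boost=0.0, n_genes=40, seed=3):
        rng = np.random.default_rng(seed)
        genes, seq_parts, chrom_seq = [], [], []
        pos = 1
        seq = []

        def bases(n, gc):
            return rng.choice(list("ACGT"), size=n,
                              p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

        for i in range(n_genes):
            gap, e1, il, e2 = 80, 120, 70, 120
            seq.extend(bases(gap, 0.4))
            start = pos + gap
            intron_start = start + e1
            seq.extend(bases(e1, 0.4))
            seq.extend(bases(il - 25, 0.4))
            seq.extend(bases(25, min(0.4 + gc_3prime_boost, 0.95)))
            seq.extend(bases(e2, 0.4))
            genes.append(GeneModel(
                f"g{i}", "c", "+",
                ((start, intron_start - 1), (intron_start + il, intron_start + il + e2 - 1)),
            ))
            pos = intron_start + il + e2
        genome = {"c": "".join(map(str, seq))}
        return genes, genome

    def test_uniform_composition_not_significant(self):
        genes, genome = self._genome_with_introns(0.0)
        res = gc_boundary_test(genes, genome)
        assert res.p > 0.01  # no planted difference

    def test_planted_3prime_gc_enrichment_detected(self):
        genes, genome = self._genome_with_introns(0.45)
        res = gc_boundary_test(genes, genome)
        assert res.p < 1e-6
        assert res.mean_b > res.mean_a  # 3' windows are GC-richer

    def test_single_qualifying_intron_is_error(self):
        genes, genome = self._genome_with_introns(0.0, n_genes=1)
        with pytest.raises(ValueError):
            gc_boundary_test(genes, genome)
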