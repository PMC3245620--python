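"""Synthetic tiling-array study generator.

Produces a toy genome (FASTA + GFF3), a 25-bp probe layout tiling it at
a fixed step, a per-gene expression table, and raw log2 signal arrays
for every experiment (Pol II IP, input, histone H3 IP, H3K36me3 IP,
FAIRE, genomic DNA), with the statistical structure the downstream
analysis assumes:

* Pol II: Gaussian enrichment peaks at the promoter and terminator, a
  body level proportional to log2 expression, and a linear within-intron
  ramp rising to the intron 3' end whose amplitude grows as expression
  falls (largest in the lowest expression decile).
* Histone H3: flat baseline with dips at promoter/terminator windows and
  at every exon-intron junction, and a mild expression-dependent body
  depletion.
* H3K36me3: the H3 latent plus an expression-proportional body term,
  reduced inside introns.
* FAIRE: the negative of the H3 latent (nucleosome-depleted DNA is
  recovered), measured with the same GC hybridization bias as the
  genomic-DNA reference arrays.
* A shared per-locus input latent (smooth random profile plus GC bias)
  enters every IP array and every input array, so input subtraction
  recovers the IP-specific latent in expectation.

Probe values are the mean latent over the probe's 25 bp plus Gaussian
log2-scale noise, independent per replicate.  Everything is a pure
function of (config, seed): two runs are byte-identical.

Expression deciles used for amplitude programming are computed with the
stratify module's own ranking rule, so generator and analysis agree on
what "decile d" means; undetectable genes (expression < 1) are
programmed with the lowest-decile amplitude.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assign import BinScheme, KLASS_EXON, KLASS_INTRON, assign_probes
from .genome_model import (
    GeneModel,
    GenomeAnnotation,
    ProbeRecord,
    write_annotation,
    write_probe_layout,
)
from .normalize import EnrichmentTrack, SignalArray, write_signal_tsv
from .stratify import filter_and_rank

PROBE_LEN = 25


@dataclass(frozen=True)
class Amplitudes:
    """Log2-scale effect sizes of the planted signal structure."""

    promoter_peak: float = 1.2
    terminator_peak: float = 0.8
    body_per_expression: float = 0.15  # per log2 expression unit
    intron_ramp_base: float = 0.25
    intron_ramp_expression_slope: float = 0.12  # per decile below the top
    h3_baseline: float = 0.0
    h3_dip_depth: float = 0.6
    h3_body_per_expression: float = 0.04
    k36_per_expression: float = 0.12
    k36_intron_drop: float = 0.5
    gc_bias_slope: float = 1.0

    @classmethod
    def null(cls) -> "Amplitudes":
        """All planted effects zero (type-I calibration configuration)."""
        return cls(**{f: 0.0 for f in cls.__dataclass_fields__})


@dataclass(frozen=True)
class SimConfig:
    """Study-scale and effect-size configuration.

    Defaults emulate the study's conditions at desk scale: two
    chromosomes with ~150 genes each, half of them spliced with 1-3
    short introns (40-120 bp; real fission yeast introns are typically
    under 100 bp), 25-bp probes every 20 bp (~35k probes), log-normal
    expression with ~9% of genes below the detection threshold of 1,
    duplicate ChIP/input arrays and triplicate FAIRE/gDNA arrays.
    """

    seed: int = 0
    n_chroms: int = 2
    n_genes: int = 300
    frac_spliced: float = 0.5
    introns_per_gene: tuple[int, int] = (1, 3)
    intron_len: tuple[int, int] = (40, 120)
    exon_len: tuple[int, int] = (150, 700)
    intergenic_len: tuple[int, int] = (400, 1200)
    probe_step: int = 20
    expression_meanlog: float = 3.0   # natural-log parameters of the
    expression_sdlog: float = 2.2     # linear-scale expression signal
    expression_rep_noise: float = 0.05
    amplitudes: Amplitudes = field(default_factory=Amplitudes)
    noise_sd: float = 0.2
    n_replicates: tuple[tuple[str, int], ...] = (
        ("polII_ip", 2), ("input", 2), ("h3_ip", 2), ("k36_ip", 2),
        ("faire", 3), ("gdna", 3),
    )
    n_expression_groups: int = 10

    def __post_init__(self) -> None:
        for name in ("introns_per_gene", "intron_len", "exon_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if hi < lo or lo < (0 if name == "introns_per_gene" else 1):
                raise ValueError(f"degenerate range for {name}: ({lo},{hi})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.probe_step < 1:
            raise ValueError("probe_step must be >= 1")

    def replicate_counts(self) -> dict[str, int]:
        return dict(self.n_replicates)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_replicates"] = [list(x) for x in self.n_replicates]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "amplitudes" in d and isinstance(d["amplitudes"], dict):
            d["amplitudes"] = Amplitudes(**d["amplitudes"])
        for name in ("introns_per_gene", "intron_len", "exon_len", "intergenic_len"):
            if name in d:
                d[name] = tuple(d[name])
        if "n_replicates" in d:
            d["n_replicates"] = tuple((k, int(v)) for k, v in d["n_replicates"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    genes: pd.DataFrame  # gene_id, expression, spliced, decile, intron_amplitude
    latent_probe_means: dict[str, pd.Series]  # track -> noiseless probe values
    intron_exon_latent_diff: dict[int, float]  # decile -> latent Pol II diff


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def generate_genome(config: SimConfig) -> tuple[GenomeAnnotation, dict[str, str], list[ProbeRecord]]:
    """Place genes left to right with sampled intergenic gaps; tile probes."""
    rng = _rng(config.seed, 0)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    ann = GenomeAnnotation()
    sequences: dict[str, str] = {}
    probes: list[ProbeRecord] = []
    gene_no = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 1 + int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        genes: list[GeneModel] = []
        for _ in range(per_chrom[ci]):
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            spliced = rng.random() < config.frac_spliced
            n_introns = (
                int(rng.integers(config.introns_per_gene[0], config.introns_per_gene[1] + 1))
                if spliced and config.introns_per_gene[1] >= 1 else 0
            )
            n_exons = n_introns + 1
            exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, size=n_exons)
            intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, size=n_introns)
            exons = []
            p = pos
            for i in range(n_exons):
                exons.append((p, p + int(exon_lens[i]) - 1))
                p += int(exon_lens[i])
                if i < n_introns:
                    p += int(intron_lens[i])
            genes.append(GeneModel(
                gene_id=f"SPSYN{gene_no:04d}", chrom=chrom, strand=strand,
                exons=tuple(exons),
            ))
            pos = p - 1 + int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        chrom_len = pos + 500
        ann.chrom_lengths[chrom] = chrom_len
        for g in genes:
            ann.add(g)
        # S. pombe-like base composition (~36% GC)
        bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_len,
                           p=[0.32, 0.18, 0.18, 0.32])
        seq = bases.tobytes().decode("ascii")
        sequences[chrom] = seq
        is_gc = np.frombuffer(seq.encode(), dtype="S1")
        is_gc = ((is_gc == b"G") | (is_gc == b"C")).astype(np.float64)
        gc_cum = np.concatenate([[0.0], np.cumsum(is_gc)])
        for start in range(1, chrom_len - PROBE_LEN + 2, config.probe_step):
            end = start + PROBE_LEN - 1
            gc = (gc_cum[end] - gc_cum[start - 1]) / PROBE_LEN
            probes.append(ProbeRecord(
                probe_id=f"{chrom}_P{start:07d}", chrom=chrom, start=start,
                gc_fraction=float(gc),
            ))
    return ann, sequences, probes


def _add_gaussian(arr: np.ndarray, center0: int, amp: float, sd: float) -> None:
    """Add a Gaussian bump (0-based center) in place, clipped to bounds."""
    if amp == 0.0:
        return
    half = int(4 * sd)
    lo = max(0, center0 - half)
    hi = min(arr.size, center0 + half + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi) - center0
    arr[lo:hi] += amp * np.exp(-0.5 * (x / sd) ** 2)


def _sample_expression(config: SimConfig, gene_ids: list[str]) -> pd.DataFrame:
    rng = _rng(config.seed, 1)
    latent = np.exp(rng.normal(config.expression_meanlog, config.expression_sdlog,
                               size=len(gene_ids)))
    reps = {}
    for r in range(2):
        noise = rng.normal(0.0, config.expression_rep_noise, size=len(gene_ids))
        reps[f"rep{r + 1}"] = latent * np.exp(noise)
    df = pd.DataFrame({"gene_id": gene_ids, **reps})
    df.attrs["latent"] = latent
    return df


def _amplitude_for_decile(amp: Amplitudes, decile: int | None, n_groups: int) -> float:
    """Within-intron ramp amplitude: largest for the lowest-expressed genes.

    Undetectable genes (no decile) take the lowest-decile amplitude.
    """
    d = n_groups if decile is None else decile
    return amp.intron_ramp_base + amp.intron_ramp_expression_slope * (d - 1)


def generate_signals(config: SimConfig, annotation: GenomeAnnotation,
                     sequences: dict[str, str], probes: list[ProbeRecord],
                     ) -> tuple[dict[str, list[SignalArray]], pd.DataFrame, GroundTruth]:
    """Build latent per-base tracks, average over probes, add noise."""
    amp = config.amplitudes
    gene_ids = sorted(annotation.genes)
    expr = _sample_expression(config, gene_ids)
    bins = filter_and_rank(expr[["gene_id", "rep1", "rep2"]], annotation,
                           n_groups=config.n_expression_groups)
    decile_of = dict(zip(bins.table["gene_id"],
                         [None if pd.isna(d) else int(d) for d in bins.table["decile"]]))
    expr_of = dict(zip(bins.table["gene_id"], bins.table["expression"]))

    flank_sd = 120.0
    junction_sd = 20.0

    latent: dict[str, dict[str, np.ndarray]] = {}
    for chrom, seq in sequences.items():
        L = len(seq)
        latent[chrom] = {
            "polII": np.zeros(L),
            "h3": np.full(L, amp.h3_baseline),
            "k36_extra": np.zeros(L),  # added to H3 latent later
        }

    gt_rows = []
    for gid in gene_ids:
        g = annotation.genes[gid]
        tr = latent[g.chrom]
        log2e = max(np.log2(max(expr_of[gid], 1e-12)), 0.0)
        d = decile_of[gid]
        ramp_amp = _amplitude_for_decile(amp, d, config.n_expression_groups) if g.spliced else 0.0
        start0, end0 = g.orf_start - 1, g.orf_end - 1  # 0-based
        tss0, tes0 = (start0, end0) if g.strand == "+" else (end0, start0)
        _add_gaussian(tr["polII"], tss0, amp.promoter_peak, flank_sd)
        _add_gaussian(tr["polII"], tes0, amp.terminator_peak, flank_sd)
        tr["polII"][start0 : end0 + 1] += amp.body_per_expression * log2e
        _add_gaussian(tr["h3"], tss0, -amp.h3_dip_depth, flank_sd)
        _add_gaussian(tr["h3"], tes0, -amp.h3_dip_depth, flank_sd)
        tr["h3"][start0 : end0 + 1] -= amp.h3_body_per_expression * log2e
        tr["k36_extra"][start0 : end0 + 1] += amp.k36_per_expression * log2e
        for (s, e) in g.introns_genomic():
            s0, e0 = s - 1, e - 1
            n = e0 - s0 + 1
            ramp = np.linspace(0.0, ramp_amp, n)
            if g.strand == "-":
                ramp = ramp[::-1]  # 3' end of the intron is the genomic start
            tr["polII"][s0 : e0 + 1] += ramp
            _add_gaussian(tr["h3"], s0, -0.6 * amp.h3_dip_depth, junction_sd)
            _add_gaussian(tr["h3"], e0, -0.6 * amp.h3_dip_depth, junction_sd)
            tr["k36_extra"][s0 : e0 + 1] -= amp.k36_intron_drop
        gt_rows.append((gid, expr_of[gid], g.spliced, d, ramp_amp if g.spliced else np.nan))

    # shared per-locus input latent: smooth random profile (500-bp knots)
    rng_in = _rng(config.seed, 2)
    input_base: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        L = len(seq)
        n_knots = max(L // 500 + 2, 2)
        knots = rng_in.normal(0.0, 0.3, size=n_knots)
        x = np.linspace(0, L - 1, n_knots)
        input_base[chrom] = np.interp(np.arange(L), x, knots)

    def probe_means(track: dict[str, np.ndarray]) -> pd.Series:
        cums = {c: np.concatenate([[0.0], np.cumsum(a)]) for c, a in track.items()}
        vals = np.empty(len(probes))
        for i, p in enumerate(probes):
            cs = cums[p.chrom]
            vals[i] = (cs[p.end] - cs[p.start - 1]) / PROBE_LEN
        return pd.Series(vals, index=pd.Index([p.probe_id for p in probes], name="probe_id"))

    polII_m = probe_means({c: latent[c]["polII"] for c in latent})
    h3_m = probe_means({c: latent[c]["h3"] for c in latent})
    k36_m = h3_m + probe_means({c: latent[c]["k36_extra"] for c in latent})
    faire_m = -h3_m
    input_m = probe_means(input_base)
    gc = pd.Series([p.gc_fraction for p in probes], index=polII_m.index, dtype=float)
    gdna_m = amp.gc_bias_slope * gc
    input_m = input_m + gdna_m  # GC bias is shared by every hybridization

    rng_noise = _rng(config.seed, 3)
    counts = config.replicate_counts()
    ip_latent = {"polII_ip": polII_m, "h3_ip": h3_m, "k36_ip": k36_m}

    def make_arrays(experiment: str, base: pd.Series) -> list[SignalArray]:
        out = []
        for r in range(counts.get(experiment, 0)):
            noise = rng_noise.normal(0.0, config.noise_sd, size=len(base))
            out.append(SignalArray(
                experiment=experiment, replicate_id=f"rep{r + 1}",
                values=base + noise,
            ))
        return out

    arrays: dict[str, list[SignalArray]] = {}
    for exp, base in ip_latent.items():
        arrays[exp] = make_arrays(exp, base + input_m)
    arrays["input"] = make_arrays("input", input_m)
    arrays["faire"] = make_arrays("faire", faire_m + gdna_m)
    arrays["gdna"] = make_arrays("gdna", gdna_m)

    gt_genes = pd.DataFrame(
        gt_rows, columns=["gene_id", "expression", "spliced", "decile", "intron_amplitude"],
    )
    truth = GroundTruth(
        genes=gt_genes,
        latent_probe_means={
            "polII": polII_m, "h3": h3_m, "k36": k36_m, "faire": faire_m,
            "input": input_m, "gdna": gdna_m,
        },
        intron_exon_latent_diff=_latent_decile_diff(
            annotation, probes, polII_m, bins),
    )
    return arrays, expr[["gene_id", "rep1", "rep2"]], truth


def _latent_decile_diff(annotation, probes, polII_m, bins) -> dict[int, float]:
    """Latent (noiseless) intron-minus-exon Pol II difference per decile."""
    tables = assign_probes(annotation, probes, BinScheme())
    track = EnrichmentTrack(name="polII_latent", values=polII_m)
    out: dict[int, float] = {}
    classes = tables.classes
    for d in range(1, bins.n_groups + 1):
        gids = bins.decile_gene_ids(d, spliced=True)
        sel_i = (classes["klass"] == KLASS_INTRON) & classes["gene_id"].isin(gids)
        sel_e = (classes["klass"] == KLASS_EXON) & classes["gene_id"].isin(gids)
        iv = track.values.reindex(classes.loc[sel_i, "probe_id"].drop_duplicates())
        ev = track.values.reindex(classes.loc[sel_e, "probe_id"].drop_duplicates())
        if len(iv) and len(ev):
            out[d] = float(iv.mean() - ev.mean())
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fixture_bundle(config: SimConfig, output_dir) -> dict:
    """Generate and write the complete study bundle; return the manifest."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "signals").mkdir(exist_ok=True)

    annotation, sequences, probes = generate_genome(config)
    arrays, expr, truth = generate_signals(config, annotation, sequences, probes)

    write_fasta(sequences, outdir / "genome.fa")
    write_annotation(annotation, outdir / "annotation.gff3")
    write_probe_layout(probes, outdir / "probes.tsv")
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False, float_format="%.6g")

    signal_files: dict[str, list[dict]] = {}
    for exp, reps in arrays.items():
        signal_files[exp] = []
        for arr in reps:
            fname = f"signals/{exp}_{arr.replicate_id}.tsv"
            write_signal_tsv(arr, outdir / fname)
            signal_files[exp].append({"replicate_id": arr.replicate_id, "path": fname})

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "annotation": "annotation.gff3",
        "genome": "genome.fa",
        "probes": "probes.tsv",
        "expression": "expression.tsv",
        "signals": signal_files,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    gt = {
        "genes": truth.genes.replace({np.nan: None}).to_dict(orient="records"),
        "intron_exon_latent_diff": {str(k): v for k, v in
                                    truth.intron_exon_latent_diff.items()},
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, default=float)
    return manifest
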