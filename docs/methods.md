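# Methods

`intronchip` reimplements, as a tested pipeline, a genome-wide analysis of
RNA polymerase II (Pol II) occupancy, histone H3, H3K36me3 and FAIRE
signals across gene features in fission yeast, measured on 25-bp tiling
arrays.  The pipeline is exercised end to end on synthetic data whose
planted structure mirrors the phenomena the analysis is designed to
detect; this note documents the model, the procedure, the defaults, and
what the synthetic data does and does not show.

## Coordinates and probe model

All external formats and domain types use 1-based, fully closed genomic
intervals (the GFF3 convention).  A probe is a fixed 25-mer; its midpoint
is its 13th base, i.e. genomic position `start + 12`.  The ORF span of a
gene runs from its first exon start to its last exon end; UTRs are not
modelled, so the 400-bp promoter and terminator windows anchor directly
on the ORF boundaries.  Introns are the maximal gaps between consecutive
exons; genes with zero-length introns or overlapping exons are rejected
at load time.  Overlapping genes are permitted, and a probe is assigned
independently within each gene that covers it.

## Normalization

All normalization is subtraction on the log2 scale, probe-local, with no
quantile or between-array scale adjustment:

* ChIP enrichment = log2(IP) − log2(input) per replicate pair, then the
  arithmetic mean over biological replicates.
* H3K36me3 is additionally corrected for nucleosome density by
  subtracting the histone H3 enrichment probe-wise.
* FAIRE = mean log2 FAIRE signal − mean log2 signal of the genomic-DNA
  hybridizations, which removes GC-dependent hybridization bias (for
  FAIRE the replicate means are taken before the subtraction; for ChIP
  the subtraction precedes averaging — with equal replicate counts the
  two orders coincide).

A probe missing (NA) in any contributing array is dropped from the
output track with the count logged; silent imputation would bias the
bulk intron/exon comparisons.  No replicate rescaling is applied before
averaging.

## Probe assignment — two distinct rules

1. **Bulk classification**: a probe is an intron (exon) probe only if
   all 25 bases lie within that intron (exon) of a spliced gene; for
   unspliced genes the test is containment within the ORF.  Probes
   straddling a boundary are unassigned.  These classes feed all Welch
   contrasts.
2. **Metagene binning**: a probe is placed by its midpoint alone into
   the promoter window, terminator window, an exon, an intron, or the
   ORF, then into one of that region's bins by the proportional rule
   `bin = floor(offset × n_bins / length) + 1`, with the offset measured
   in the direction of transcription so bin 1 is always 5'-most.  A
   probe whose midpoint is inside a region is binned even if its body
   straddles the region edge — the full-containment rule belongs to the
   bulk classification only.

For region lengths not divisible by the bin count, the proportional rule
yields bin sizes differing by at most 1 bp; regions shorter than their
bin count leave some bins with no positions, which surface as count-0
bins with a null mean.  Flank windows that run past a chromosome end are
clipped, but their offsets stay anchored at the ORF edge.

## Average-gene (metagene) profiles

Bin counts: 400-bp flanks in ten 40-bp bins; 20 bins across an unspliced
ORF; 20 bins per exon and 10 per intron of spliced genes.  Two composite
layouts are built:

* **Unspliced, 40 bins**: promoter(10) + ORF(20) + terminator(10).
* **Spliced, 70 bins**: promoter(10) + first-exon 5' halves(10) +
  upstream-exon 3' halves(10) + introns(10) + downstream-exon 5'
  halves(10) + last-exon 3' halves(10) + terminator(10).

The spliced composite averages every exon–intron–exon junction of every
gene: each exon's bins 1–10 are its 5' half and bins 11–20 its 3' half,
and each half serves exactly one junction role (first exon, upstream of
an intron, downstream of an intron, last exon).  Because every probe
occupies exactly one exon bin, it contributes at most once per composite
segment — the no-double-counting guarantee that the tests audit with an
explicit contribution matrix.  The seven-segment composite length is a
structural reconstruction from the junction rule plus the first/last
exon flank rule; see README.

Bin means average over probes directly, not over per-gene means, so a
pooled profile is exactly the probe-count-weighted combination of any
partition of its gene set (asserted to 1e-9).

**Background**: the mean signal of probes assigned to no (region, bin)
of any gene, plus a trimmed mean with the ceiling of 10% of the
highest-signal outside probes removed (they absorb unannotated
transcribed regions; 152,253 outside probes → 15,226 removed).  The
ceiling rule is inferred from that worked ratio; floor would give the
same count there but can differ for other totals.

## Expression stratification

Linear-scale array expression below 1 counts as undetectable and is
excluded.  Replicate expression columns are averaged on the linear scale
before filtering.  Detected genes are split into spliced and unspliced
partitions, ranked in descending expression (ties broken by gene id —
deterministic and seed-free), and sliced into 10 contiguous groups;
remainder genes go to the highest-expression groups, as a plain slice of
the sorted list gives.  Decile 1 is the most highly expressed 10%.
Decile membership is invariant under any strictly increasing transform
of the expression values.

## Statistics

The Welch two-sample t statistic and Welch–Satterthwaite degrees of
freedom are computed from the standard definitions, with the two-sided
p-value from the t distribution.  Groups whose values are all identical
get an exactly zero variance (summation rounding would otherwise turn a
constant group into a spurious signal).  If both variances are zero:
equal means give t = 0, p = 1; unequal means set a degenerate flag with
the p floored.  Reported p-values carry a display floor of 2.2e-16, the
conventional printed floor; the exact value is retained internally.
All tests are two-sided, and no multiple-testing correction is applied.

Per expression decile, the contrast reports the mean intron signal, the
mean signal of junction-adjacent exon halves upstream and downstream of
introns, and log2-scale ratios.  Since track values are already log2
enrichments, the occupancy ratio is implemented as the difference of
mean log2 signals (exon mean − intron mean); `ratio_scale=
"log_of_linear_means"` switches to log2 of the ratio of linearized
means, and `exon_mode="whole"` uses whole exons instead of
junction-adjacent halves.  The defaults are the difference form and the
junction-adjacent halves, the simplest reading consistent with
log2-scale axes and with the junction composite.

The GC control computes the GC fraction of the first and last 25 bases
(transcription direction) of every intron of length ≥ 25 bp and Welch-
tests the two sets; GC content is strand-symmetric, so genomic-strand
sequence suffices.

## Synthetic data generator

The generator emits a toy genome, probe layout, expression table and all
raw signal arrays directly on the log2 scale (the analysis operates
entirely in log2; no read-count layer is simulated).  Defaults: 2
chromosomes, 300 genes, half spliced with 1–3 introns of 40–120 bp
(fission yeast introns are typically under 100 bp), exons 150–700 bp,
probes every 20 bp (~27k probes), log-normal expression with ~5–10% of
genes below the detection threshold, duplicate ChIP/input and triplicate
FAIRE/gDNA arrays, and log2 noise sd 0.2 per array — a desk-scale study
that runs in seconds.

Planted structure (per-base latent means, averaged over each probe's
25 bp):

* Pol II: Gaussian peaks (sd 120 bp) at the ORF start (amplitude 1.2)
  and end (0.8); a body level of 0.15 per log2 expression unit; and a
  linear within-intron ramp rising to the intron 3' end with amplitude
  `0.25 + 0.12 × (decile − 1)` — largest in the lowest-expressed decile,
  matching the direction of the expression dependence the analysis must
  recover.  Undetectable genes take the lowest-decile amplitude.
* H3: flat baseline with Gaussian dips (depth 0.6, sd 120 bp) at the
  ORF ends, narrower dips (0.36, sd 20 bp) at every exon–intron
  junction, and a mild expression-dependent body depletion (0.04 per
  log2 unit).
* H3K36me3: the H3 latent plus 0.12 per log2 expression unit across the
  body, minus 0.5 inside introns.
* FAIRE: the negative of the H3 latent, measured with the same GC bias
  term as the gDNA reference arrays (slope 1.0 per GC fraction).
* A shared per-locus input latent (smooth 500-bp-knot profile plus the
  GC term) enters every IP and input array, so input subtraction
  recovers the IP-specific latent in expectation.

Amplitude programming uses the stratify module's own decile rule on the
sampled expression values, keeping generator and analysis definitions
aligned.  Everything is a pure function of (config, seed): two runs are
byte-identical, and a recorded config hash changes iff any field does.

**What the synthetic data does not emulate**: probe cross-hybridization,
array spatial artifacts, sequence-composition effects beyond a linear GC
term, UTRs and alternative transcripts, antisense transcription, and the
irregular probe spacing of a real array.  Passing tests therefore
demonstrate that the *procedure* recovers known structure under its own
assumptions — not that those effect sizes hold on real arrays.

## Numerical and design choices

* Problem sizes: the default study (300 genes, ~27k probes) runs the
  full analysis in about a second; the null calibration re-draws array
  noise 200 times on a fixed 60-gene null genome, which is equivalent
  for the p-value distribution (the genome carries no signal under the
  null) and keeps the check fast.
* Empty bins report count 0 and a null mean; nothing is interpolated.
* Probes missing from a track (NA propagation) are simply absent from
  bin means and contrasts.
* The trim count uses the ceiling rule (see background above).
* Degenerate inputs: empty gene sets, deciles without probes, fewer
  than two probes per test group, and introns shorter than 25 bp in the
  GC control all raise or are skipped with logged counts, never silently
  imputed.

## Known limitations

* Promoter windows of one gene may lie inside a neighbouring gene's ORF;
  such probes are retained (fixed 400-bp windows are applied
  unconditionally).
* The 70-bin spliced composite is a reconstruction of the junction rule;
  other composite arrangements consistent with the same averaging exist.
* The generator's smooth input latent is a convenience model of shared
  hybridization structure, not a mechanistic one.
* Real-array headline values (e.g. absolute p-values on hundreds of
  thousands of probes) are scale-dependent and are not reproduced at
  desk scale; the tests check directions, calibration and exact
  arithmetic instead.
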