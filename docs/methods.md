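# Methods

This note documents the models, estimators and numerical choices behind
`ocratlas`, and what the synthetic-data generator does and does not emulate.

## Coordinate and interval conventions

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted at the I/O boundary (1-based closed on disk) and round-trips
exactly. `merge` joins overlapping *and book-ended* intervals at `gap=0`.
Interval sets can be bound to a chromosome-sizes map, in which case every
record is validated against it. The TSS is the strand-aware 5′ end
(`start` for +, `end − 1` for −); signed peak–TSS distances are reported as
`TSS − centre`, sign-flipped for − strand genes, so positive always means
the peak lies upstream. Nearest-TSS ties are broken by the
lexicographically smaller gene id — an arbitrary but deterministic rule.

## Peak annotation and relative enrichment

Peaks are classified by the position of their **centre** with the priority
Promoter > 5′ UTR > 3′ UTR > Exon > Intron > Downstream (≤300 bp past the
3′ end) > Distal Intergenic. Centre-based assignment keeps the classes
exhaustive and mutually exclusive, so class percentages sum to 100. The
promoter window is two-sided around the TSS, binned at ≤1 kb / 1–2 kb /
2–3 kb (exposed as `promoter_bins`); "promoters" in aggregate is their sum.

Relative enrichment compares observed class counts to the mean over
`n_shuffles` width-preserving uniform relocations (default 5000). A
shuffled interval picks its chromosome with probability proportional to
`size − width + 1` and its start uniformly over the valid range, so
placement is uniform over all valid genome positions; a `same_chrom` flag
restricts relocation to the source chromosome. Because every shuffled
region is classified, Σ expected = Σ observed = peak count exactly. The
empirical p-value uses the +1 finite-sample correction and is one-sided in
the direction of the observed deviation; it can never be 0, and its
resolution is `1/(n_shuffles+1)`.

Peak-width statistics per class use one-way ANOVA plus pairwise Welch
t-tests with BH correction at 0.05, summarized as a compact letter display
(insert-and-absorb algorithm; classes sharing a letter are not
distinguishable). Classes with fewer than two peaks are excluded and
flagged.

## Simple peak caller

The internal caller exists so the synthetic end-to-end path does not depend
on an external tool; real narrowPeak files are accepted everywhere a
PeakSet is consumed. Cut sites (both fragment ends) are piled per base;
150 bp windows every 50 bp are tested against
`Poisson(max(genome mean, 10 kb local mean) × window)` at `p_cut = 1e-5`;
significant windows are merged and the summit is the leftmost maximum of
the per-base pileup. This is a deliberately minimal detector: no model for
duplicate fragments, no multiple-testing control, no shifted/smoothed
pileup. Its false-positive behaviour on uniform background is
Poisson-bounded (the discrete tail makes it conservative).

## Differential accessibility

Consensus peaks per group are the merged union intervals supported (≥1 bp
overlap) by peaks from at least `min_samples = 2` distinct samples.
Consensus intervals across groups are merged and re-centred to
`[summit − 200, summit + 200)`, where the summit is the maximum of the
cut-site pileup pooled over all samples (leftmost on ties; the choice of
pooled signal is a documented design decision — per-sample summits can
disagree and the pooled pileup is the maximum-likelihood location under
shared signal). Windows at chromosome edges are clipped and flagged.
Overlapping redefined windows are **not** re-merged: they are counted as
distinct features, which keeps the feature count stable across runs.

Counting is of Tn5 cut sites: each fragment contributes its two end
positions, and an end in `[start, end)` counts once, so a fragment fully
inside a peak contributes 2. A `mode="fragments"` option counts overlapping
fragments instead (the convention of read-count-based screens).

Size factors are DESeq2-style median-of-ratios over features positive in
all samples (positive-subset fallback with a warning). Dispersion
(variance `μ + αμ²`) is estimated by method-of-moments per feature within
groups, pooled with `n_g − 1` weights and truncated at zero; the final
per-feature α is the least-squares trend `α(μ) = a₀ + a₁/μ` evaluated at
the feature's mean (`shrink_weight = 1`). With three replicates per group
the raw per-feature moment estimate is extremely noisy and plugging it into
a Wald test inflates the false-positive rate well above nominal; because
the generator (and most bulk ATAC data at this depth) has dispersion that
varies smoothly with the mean, the trend value is the stable choice.
`shrink_weight < 1` blends the raw estimate back in (log-scale geometric
interpolation) for data with genuinely heterogeneous dispersion; `shrink=False`
returns the raw estimates. Measured on 5000 null NB features (α = 0.1, mean
100, 3 vs 3), the trend estimator gives a Wald FPR of ~0.05 with uniform
p-values, the raw estimator ~0.12.

The test itself fits one NB mean per group with a log link and size-factor
offsets: the group mean `q_g` solves `Σ_s (y_s − s_s q)/(1 + α s_s q) = 0`
(Newton iteration on `log q`, vectorized across features; information
floor 1e-12, step clipped to ±5). The Wald statistic is
`(log q_test − log q_ref)/SE` with `SE² = 1/I_test + 1/I_ref` from the
Fisher information `I_g = Σ_s μ_s/(1 + αμ_s)`. Features with all-zero
counts are excluded (`call = ns`, p = NaN). When exactly one group is
all-zero the MLE sits on the boundary; 0.5 is added to both normalized
group means for the reported fold change and its SE, which keeps the
estimate finite and the p-value conservative. BH q across tested features;
calls at `|log2FC| ≥ 0.58` and `q ≤ 0.05` (a `use_raw_p` switch thresholds
the raw p instead, mirroring screens that filter on unadjusted p).

## Expression integration

`FPKM = count × 10⁹ / (exon_length × mapped_total)` with mapped totals
defaulting to column sums; the quantity is invariant to jointly scaling
counts and totals. Quintile thresholds are the 20/40/60/80th percentiles
(linear interpolation); values tying a threshold go to the lower group, so
zero-FPKM genes stay in "lower"; an all-equal input degenerates to a single
group with a warning.

Metagene profiles bin cut-site density (cuts/bp, scaled to cuts per
million) over fixed 50 bp flank bins (±3 kb) and a gene body scaled to 100
bins; − strand genes are reversed so the left edge is always upstream.
Genes shorter than 100 bp are skipped and counted. The argmax of the
profile is a noisy location estimator: with ~50 genes per quintile group
and the default generator the maximum is flat within roughly ±150 bp of the
TSS, so argmax positions jitter by up to ~±200 bp between runs.

Quadrant classification takes one promoter OCR per gene — smallest q, then
largest |log2FC|, then nearest TSS — and assigns one of four quadrants by
the fold-change sign pair, but only to genes significant on both axes
(ATAC `|log2FC| ≥ 0.58, q ≤ 0.05`; RNA `|log2FC| ≥ 1, q ≤ 0.05`). The four
counts partition the dual-significant genes.

ORA is the one-sided hypergeometric upper tail `P(X ≥ k)` for a list of
size n against a set of size K in a universe of size N, sets filtered to
5 ≤ K ≤ 2000, BH across sets. It replaces database-backed GO/KEGG calls:
term databases are version-dependent and out of scope; any GMT file works.

## Motifs and TF network

PWMs are `log2(((c + p)/(Σc + 4p))/b)` with pseudocount `p = 0.8` and
uniform background `b = 0.25`. Scanning is exhaustive over both strands
(reverse-complement = reversed rows and columns of the matrix); `N` bases
contribute 0 bits; the default threshold is 80% of the maximum attainable
score. Enrichment is a one-sided Fisher exact test on per-sequence
presence/absence in foreground (differential OCRs) vs background
(non-differential OCRs), BH-corrected and ranked; this deterministic
replacement for model-based motif enrichment is exactly testable against
the hypergeometric distribution. The TF network connects the top-k enriched
motifs by the Jaccard similarity of their target-region sets (edges at
weight ≥ `min_jaccard`, no self-edges); node attributes carry enrichment q
and expression log2FC (0 with a `rna_missing` flag when the TF is absent
from the expression table). Shared-target Jaccard stands in for external
protein-interaction databases, which are out of scope.

## Synthetic-data generator

The generator emulates a two-group (elevated "CY" vs reference "Y"),
three-replicate bulk ATAC + mRNA study at desk scale. Defaults (all in
`SynthConfig`):

- **Genome**: 2 chromosomes × 2 Mb, i.i.d. uniform ACGT. 250 non-overlapping
  genes (1.5–4 kb, ≥200 bp apart, random strand, 2–4 exons, 5′/3′ UTRs of
  ≤100/150 bp carved from the terminal exons). Uniform base composition
  keeps the PWM null analytic; there is no GC structure, no repeats, no
  assembly gaps.
- **Peak landscape**: 480 peaks, width ~N(500, 100²) floored at 200 bp,
  relative accessibility weight ~ lognormal(0, 0.5). Half the peaks
  (`frac_promoter_peaks = 0.5`) are placed one-per-gene with centre offset
  ~N(0, 300²) truncated at ±800 bp from the TSS — TSS-concentrated, because
  the accessibility maximum of real promoters sits at the TSS; the rest are
  uniform. 120 peaks carry a planted log2FC of ±1 (half each, elevated
  group), i.e. `n_differential/n_peaks = 25%` differential, symmetric by
  default (`diff_up_frac`).
- **Fragments**: 100k per sample, 20% uniform background. Per-peak counts
  are NB with mean ∝ weight (×2^lfc in the elevated group) and shared
  dispersion α = 0.1; midpoints ~N(centre, width/4); insert lengths a
  two-Gaussian mixture — nucleosome-free 75 ± 20 bp (65%) and
  mono-nucleosome 200 ± 30 bp (35%) — floored at 20 bp. Fragments are the
  simulated unit (no reads, no sequencing errors, no duplicates, no Tn5
  sequence bias).
- **Expression**: per-gene log2 mean = N(log2 100, 1) + coupling × z(promoter
  openness) with `expr_coupling = 1`, where openness is the summed weight
  of peaks centred within 1 kb of the TSS. 60 DE genes get an extra ±1
  log2 shift in the elevated group; 70% of them (`de_couple_frac`) are
  drawn sign-matched from genes whose promoter peak is itself
  differential, so accessibility and expression changes co-occur the way
  the integrated analysis expects. Counts are NB (same α) scaled by exon
  length, so FPKM recovers the planted level.
- **Motifs**: the consensus of the bundled synthetic 12-bp PFM `SYN0001.1`
  (file `data/toy_motifs.pfm`, with two decoy motifs) is written at a
  uniform offset, random strand, into 60% of the opened differential peaks
  (`motif_plant_rate`). A 12-bp near-one-hot motif has an expected random
  perfect-hit count ≪ 1 over the whole peak set at the 80% threshold, so
  recovery is unambiguous.

Every stage draws from an independent `SeedSequence([seed, stage, ...])`
substream, so any stage is reproducible in isolation and the whole study is
byte-deterministic per seed.

**What passing tests do and do not show.** Recovery on this generator
demonstrates that the inference chain is implemented correctly and
calibrated under its own assumptions (NB counts, width-stationary peaks,
uniform background, no GC/Tn5 bias, no batch structure). It does not
demonstrate robustness to the violations real ATAC data exhibits —
GC-dependent accessibility, duplicate structure, copy-number variation,
mappability holes — nor does it reproduce any specific published percentage
or peak count, which depend on the underlying data.

## Problem sizes used in the shipped checks

The test suite runs the generator at two scales: a small configuration
(2 × 400 kb, 60 genes, 120 peaks, 30k fragments/sample) for unit-level
checks, and the default configuration above for whole-method checks. The
oracle-equivalence suites use ≥500 random instances per operation; null
calibration uses 5000 NB features and the shuffle null 500 peaks × 1000
shuffles; `scripts/acceptance.py` uses the default configuration with 1000
shuffles. These sizes give every statistical assertion comfortable power
while keeping the full suite under a minute of CPU.
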