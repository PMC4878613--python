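# Methods

This note documents the models, numerical choices and limitations behind
`polysomeloc`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The measurement model

A polysome-profiling experiment pools sucrose-gradient fractions into three
cytoplasmic samples — free/monosomal (`free`), light polysomal (`light`,
2–6 ribosomes), heavy polysomal (`heavy`, >6) — plus a total cytoplasmic
input (`input`). Equal RNA masses from each pool are hybridized, so the
hybridized concentration of transcript *t* in sample *s* is its pool
concentration divided by the pool's relative starting mass, the
**mass factor** m_s. Probe intensity follows a power law with a hard noise
floor:

    I = max(floor, gain · C_hyb^slope · 10^ε),   ε ~ N(0, σ²)

with σ the lognormal intensity noise on the log10 scale. Spike-in RNAs are
added at hybridization at known concentrations, identical across samples,
and share the noise model but not the mass factors. The floor is what bends
the low end of the spike intensity–concentration series away from
linearity and motivates a detection threshold.

## Calibration

Per sample, probe-level spike observations are collapsed to a median
intensity per spike level and log10 intensity is regressed on log10
concentration. The detection threshold is found by scanning levels from low
to high concentration: the lowest remaining level is dropped while it
deviates from a regression over the remaining levels by more than
`deviation_tolerance`-fold (default 2-fold on the linear scale; the
experiment itself defines the threshold only as the intensity where signal
to concentration "deviates from unity", so the tolerance is configurable).
The iterative form matters: with several floored levels a single global fit
is tilted by the bend and misplaces the cutoff. The returned
slope/intercept/r are fit on the levels strictly above the threshold, so
refitting on the points above the returned threshold is a fixed point.
Calibration fails when fewer than 3 levels survive, or fewer than 5 levels
exist at all.

Concentrations invert the fit: log10 C = (log10 I − b)/a + log10 m_s for
intensities above the threshold, absent otherwise. Monotonicity in
intensity is inherited from a > 0.

### Background correction

The background step subtracts the per-sample minimum intensity and adds a
positive offset — a monotone, order- and difference-preserving transform
with strictly positive output. The synthetic noise model is multiplicative
with a floor and has no additive background term, so the orchestrated run
applies this step only when a background offset is configured; applying an
additive correction to data without additive background would bend the
log–log spike line and sacrifice the exactness of noise-free recovery for
no benefit. On real array data (which does have additive background) the
step belongs at the head of the chain.

### Between-array normalization

Cyclic loess on spike probes only: for each sample pair, a loess curve of
the log-intensity difference against the mean is fitted on spikes and
applied to all probes, half to each sample, cycling over pairs three times
(lowess `frac=0.7` over 8 spike levels). Non-spike probes are moved by the
spike curves, never by their own values, which preserves genuine biological
differences between samples. Identical samples are a fixed point; a global
scale distortion is removed exactly; curves are extrapolated as constants
beyond the spike intensity range.

### Aggregation

A transcript is detected in a sample when strictly more than half of its
probes clear the threshold (a single-probe target needs its one probe);
its value is the mean log10 concentration of the detected probes. Probeset
variance is computed over the unthresholded log10 conversions of all the
target's probes — the detected/undetected cut would otherwise censor the
very disagreement the filter is looking for. Within each sample,
`floor(q·n)` of the n detected targets with the highest variance are
excluded (q = 0.05 by default); `floor` matches "the top 5% of 100 is
exactly 5" and excludes nobody from very small panels. Variance-excluded
values are treated as undetected by everything downstream.

## Classification and occupancy

Detected transcripts are classified into the cytoplasmic fraction of
maximal linear concentration. Ties break toward the lighter fraction
(free < light < heavy) — the conservative direction with respect to
claiming ribosome association. Transcripts detected in no cytoplasmic
fraction are nuclear-specific when nuclear RNA-seq shows mean RPKM > 0 with
IDR < 0.1 (a boolean detection column is accepted where IDR is
unavailable), else not present. Polysomal occupancy
O = (C_L + C_H)/(C_F + C_L + C_H) uses linear concentrations with
undetected fractions contributing zero; it is undefined (flagged) when all
three are zero. The per-fraction log share log10 C_f − log10 ΣC is the
quantity regressed against normalized CAGE signal; its three exponentials
sum to one by construction.

## Catalog filtering

The positional filter discards a gene when any transcript (a) overlaps a
same-strand pseudogene, (b) overlaps a same-strand protein-coding exon, or
(c) lies within 5 kb, same strand, of a protein-coding transcript or
pseudogene. "Within 5 kb" is measured span-to-span with the gap ≤ 5000 bp
inclusive and overlap counting as within — the most conservative reading;
interval-tree queries are widened by one base because half-open trees treat
touching intervals as disjoint while a gap of exactly 5000 must count.
Chromosomes absent from the reference annotation cannot be tested; their
transcripts are retained and logged once, aggregated.

The coding vote flags a transcript when any of four external scores crosses
its cutoff: PhyloCSF strictly > 95, CPAT ≥ 0.364, CPC ≥ 1, or ≥ 1 exonic
same-strand peptide hit. CPAT/CPC are applied inclusively because their
sources state a "threshold"/"cutoff" without strictness, while the
PhyloCSF rule is quoted as strictly greater. Missing evidence counts as
noncoding (scores of −∞, zero hits) and is logged — the alternative
silently inflates the potential-coding set. A single flagged transcript
makes the whole gene potential protein-coding.

## Sequence features

The ORF catalog scans all six frames (reverse frames on the reverse
complement, with offsets in reverse-complement coordinates). Start codon is
AUG only; stops are UAA/UAG/UGA; codons containing N are neither. Per stop
codon exactly one ORF is kept — the 5′-most in-frame start with no
intervening stop, i.e. the longest. The pseudo-5′UTR is the offset of the
5′-most **forward**-frame ORF start: although the catalog is six-frame, a
ribosome reads the transcript 5′→3′, so antisense frames cannot define a
leader. Total ORF coverage maps reverse-frame intervals back to forward
coordinates before taking the union.

Conservation means weight every covered base equally across intervals;
bases missing from the score track are skipped and counted, never imputed.
Promoters are fixed strand-aware windows around the TSS (default −1000 to
+500 nt) and transcripts sharing an identical window collapse to a single
record.

## Transposable elements

Coverage is the unioned repeat overlap of the transcript's **exonic**
intervals divided by mature transcript length — the quantity is per mature
transcript, and the arrays probe mature transcripts, so intronic overlap
would dilute it. A repeat spanning two exons counts as one insertion;
repeat strand is recorded but both orientations count. Class summaries use
one transcript per gene (most exons; ties to the lexicographically smallest
id) to avoid isoform-rich genes dominating the means. Presence enrichment
is the upper-tail hypergeometric test; coverage differences use the
two-sided Wilcoxon rank-sum (exact where SciPy can be, asymptotic with
ties).

## qPCR

Stability: technical replicates are averaged first; per biological
replicate ΔCt = Ct_target − Ct_GAPDH, ΔΔCt = ΔCt(6 h) − ΔCt(0 h),
FC = 2^−ΔΔCt, and the reported value is FC_treated/FC_control — invariant
to any per-replicate Ct offset. Significance is a one-sample one-sided
t-test of mean log2(ratio) > 0: ratios are ratio-distributed, so the log
scale is the defensible one, and the one-sample form matches the
normalize-to-control design. Zero-spread inputs return the exact boundary
values (p = 0.5 at ratio 1).

Pool percentages: amount_p = 2^−(Ct_target − mean(Ct_Dap, Ct_Thr)); the
arithmetic mean of the two spike Cts is the geometric mean of their
amounts, a standard multi-reference combination. Percentages over
FM/LP/HP sum to 100 by construction and are invariant to per-pool Ct
shifts.

## Cross-evidence statistics

The translation index is log10(peptide/mRNA) with peptide expression
aggregated to gene level and records at or below 0.5 (log10) excluded.
CAGE normalization divides tag counts in the TSS ± 100 nt window by the
transcript's cytoplasmic expression; counts rather than a binary presence
flag are used because the downstream regression needs variance in the
predictor. Capping–occupancy relationships are ordinary least squares per
fraction with the two-sided p for slope = 0. Cytoplasmic/nuclear ratios
are log2 over transcripts present in both compartments; absent records are
skipped and counted. Tissue CV is sd/mean over tissues (undefined for
all-zero rows); detection breadth is the fraction of tissues with
RPKM > 0.

## The synthetic experiment

Defaults describe one study: 300 lncRNA genes (up to 3 isoforms each) and
60 single-isoform protein-coding genes, 4 probes per transcript, an
8-level ten-fold spike ladder with 4 probes per level, intensity noise
σ = 0.1 on log10, gain 100, mass factors free:light:heavy:input =
5:2:1:8. Localization classes are drawn per gene (10% free cytoplasmic,
20% light, 2% heavy, 28% nuclear-specific, 40% not present — detected
cytoplasmic lncRNAs are a small minority of any catalog); the maximal
fraction concentration is lognormal (mean 2.5, sd 0.7 in log10 units) and
the other two fractions sit 2–8-fold below it, so true classes are
separated but not trivially so. Coding genes skew heavy
(25/45/30 free/light/heavy), as actively translated mRNAs do.

Planted features: every sequence carries a first ORF at a class-dependent
exponential pseudo-5′UTR offset (mean 90 nt for polysomal, 30 nt for free
cytoplasmic) with all upstream AUGs erased, so the planted offset **is**
the pseudo-5′UTR by construction; ERVL-MaLR insertions occur at rate 0.4
in free cytoplasmic vs 0.2 elsewhere (Alu 0.35 and L1 0.25 everywhere);
capping probability is 0.85 for polysomal vs 0.35 for free transcripts and
capped transcripts emit ~15× more CAGE tags; a planted 5% of lncRNA genes
sit within 5 kb of a coding gene and another ~5% of transcripts carry one
coding-evidence score over its cutoff. Stability time courses use a 4 h
base half-life (Ct rises one cycle per half-life under transcription
block) with the stalling drug doubling the half-life of planted
"stabilized" genes; qPCR noise is 0.1 cycles.

All child generators derive deterministically from one master seed
(`SeedSequence(seed, spawn_key)`), so every output file is byte-identical
across runs at a fixed seed.

### What the generator does not emulate

Sequences are uniform-random nucleotides apart from the planted ORFs: no
codon structure, conservation, GC skew or repeat-derived sequence, so
passing recovery tests validates the *quantification and statistics*, not
feature extraction on realistic sequence composition. There is no
probe-level cross-hybridization, no spatial array artifact, no partial
floor (probes are either clean or exactly clamped), and fraction
concentrations are drawn independently across transcripts rather than from
a co-regulated covariance structure. Real-data effect sizes will differ;
the planted effects only establish that each statistic detects its target
at realistic n and noise.

## Problem sizes and tolerances

Recovery checks run at the sizes where their claims are meaningful while
staying fast: noise-free calibration on 50 genes (errors at machine
precision, asserted below 1e−6), floored-noisy calibration on 150 genes
(RMSE below 0.1 log10 units), classification recovery on 2000
single-isoform transcripts at σ = 0.1 and 2-fold separation (≥ 90%
correct), TE contrast at ~200 transcripts per class, ORF oracle agreement
on 500 random 300-nt sequences, hypergeometric exactness by full
enumeration up to N = 12. The orchestrated demo runs in a few seconds on
one CPU.

## Known limitations

- The loess normalization assumes the spike ladder spans the intensity
  range of interest; probes far outside it receive a constant (edge)
  correction.
- The background correction estimates additive background as the
  per-sample minimum; on panels where no probe is background-only this
  overcorrects slightly.
- Probeset variance uses unthresholded conversions, which near the floor
  compresses variance (floored probes convert to identical values); the
  per-sample quantile cut is unaffected by monotone compression but the
  absolute variances are not comparable across samples.
- IDR values are consumed, never computed; replicate-consistency modeling
  is out of scope.
- The positional filter tests spans, not TSS/TES distances; a transcript
  whose span is distant but whose promoter is close to a coding gene is
  retained.
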