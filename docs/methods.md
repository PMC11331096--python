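# Methods

This note documents the models and procedures implemented in
`m6apipe`, the design choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate frames and window scores

All analyses run in the spliced coordinate frame of one transcript per
gene — the isoform with the greatest spliced exon length, ties broken
by the lexicographically smallest transcript id; transcripts without
CDS features, or whose CDS length is not a multiple of 3, are excluded
with a warning. Internally coordinates are 0-based half-open; GFF3 is
converted from 1-based inclusive on read, BED output is 0-based
half-open. The CDS is taken to include the stop codon.

A window grid starts at 0 and advances by `step`; each window spans
`window_length` nt and the grid stops at the first window reaching the
transcript end. That final window is truncated but kept at least
`step` long (a shorter tail is absorbed into the preceding window), so
grids always tile the transcript and consecutive starts differ by
exactly `step`.

Window normalization is `(count + pseudocount) / median(count +
pseudocount)`; the pseudocount defaults to 1 and the median of an even
number of windows is the mean of the two central order statistics. The
peak-over-median score (POM) of a window is this normalized IP
coverage — i.e. coverage measured against the library median, which
is 1 after normalization. The peak-over-input score (POI) is the ratio
of normalized IP to normalized input coverage; the normalizing medians
make POI invariant to library depth (exactly so in the limit of a
vanishing, depth-scaled pseudocount — a property the tests check).

## m⁶A peak calling

Defaults: 100-nt windows, 50-nt step, POM > 3, POI > 3, support in
≥ 2 of 3 replicates, all strict inequalities.

*Candidate regions.* Significant windows that are consecutive on the
grid (hence overlapping or abutting) merge into one region; a
non-significant window splits regions. Candidate regions from all
replicates are unified by interval overlap, and the unified region's
POI — mean IP norm over the windows intersecting the region divided by
the mean input norm over the same windows — is evaluated in every
replicate, which keeps the 2-of-3 rule well-posed on a single region
set.

*Which median?* The POM gate needs a reference median, and both
natural choices fail on a predictable subset of transcripts. With the
global library median, a transcript expressed a few-fold above the
library median has *all* windows POM-significant: the whole transcript
condenses into one region whose average POI is diluted toward the
background IP efficiency and the site is lost; conversely, lowly
expressed transcripts never reach POM > 3 however strong the
enrichment. With the per-transcript median the situation reverses: on
short transcripts a peak spans most windows and inflates the
transcript's own median. The default `pom_mode="union"` therefore
gates a window as a candidate when it clears the threshold under
*either* median — reading POM as "enriched on an absolute scale or
relative to the transcript's own background" — while POI is always
computed on the library-median normalization (the scale cancels in the
ratio). Both single-median modes remain selectable.

*Condition specificity.* A putative site of condition A is A-specific
iff no grid window overlapping it also overlaps a putative site of
condition B; otherwise it is shared. The rule is symmetric under
swapping conditions (tested).

## FA-CLIP binding-site calling

Defaults: 30-nt windows at a 10-nt step, 90th-percentile control
floor, Z > 2.576, FDR < 0.05, two replicates intersected.

*Sensitivity floor.* Pooled POI scores of the non-specific (YFP-like)
control IP libraries, each ratioed against the positionally matching
input library; the floor is their 90th percentile under the
linear-interpolation percentile convention (so the 90th percentile of
{1..10} is 9.1). Windows below the floor are removed. Disabling the
floor can only add passing windows (a monotone gate, tested); this
holds because the Z-statistics are computed on all windows, not only
floor-survivors.

*Z-scores.* Significance of a window's POI is judged within its own
transcript. The plain mean/sd Z-score on linear POI
(`transcript_zscores`, kept and tested against hand values) has two
failure modes that the caller avoids by default. First, ratio noise is
multiplicative and right-skewed, so Z-scores are taken on log(POI).
Second, the bound windows themselves contaminate the per-transcript
mean and standard deviation: a 50-nt footprint on a 500-nt transcript
spans ~9 of 46 windows and caps the achievable Z below the 2.576
threshold regardless of enrichment strength. The default therefore
standardizes against a robust background estimate — the median and
1.4826·MAD of the transcript's window scores — which tolerates the
bound minority while remaining calibrated (≈ N(0,1) scores) on
unbound transcripts. Transcripts with fewer than three windows are
skipped; zero-scale transcripts yield z = 0 everywhere.

*Region support.* Passing windows are condensed as in the m⁶A caller,
but a region must contain at least two consecutive significant
windows: at a 10-nt step a real footprint always spans several
80-95%-overlapping windows, so an isolated significant window is
treated as noise. Sites must pass independently in each replicate and
the reported interval is the intersection across replicates.

*Empirical FDR.* The entire calling procedure (floor, Z, condensation,
replicate intersection) is re-run with IP and input inverted —
input/IP ratios, floor recomputed on inverted control ratios — and the
FDR is the ratio of inverted to forward call counts, attached globally
to the run; all forward calls are kept iff FDR < 0.05. The ratio is
taken at the level of final site calls ("calling peaks with the
samples inverted"); a window-level variant is available
(`fdr_level="window"`). With zero forward calls the FDR is defined as
0 when the inverted run is also empty, else 1.

*Window length.* Only the 10-nt step is dictated by the assay
description; the window length is an open choice. 30 nt — comparable
to an RNase-protected protein footprint — maximizes the contrast
between a bound window and the transcript background; windows much
wider than the footprint dilute the bound signal across many windows
and, on short transcripts, make the per-transcript Z-gate unreachable.

## Metagene segments and motif enrichment

Peak centre = midpoint of the region interval. Segments: 5′ leader,
start codon ± 50 nt, CDS, stop codon ± 50 nt, 3′ UTR; the codon
segments take precedence over the plain split, and stop beats start
when both match on a very short CDS. Segment fractions always sum to 1
(empty peak sets yield an all-zero report).

Motif enrichment counts overlapping IUPAC-expanded matches (e.g.
RRACH with R = A/G, H = A/C/U) in peak sequences against a randomized
background: by default each peak sequence is permuted (exact
mononucleotide preservation); alternatively length-matched segments
are resampled from transcript positions. The empirical p-value uses
the add-one rule, `p = (1 + #{null ≥ observed}) / (1 + N)`, and is
therefore bounded below by `1/(N+1)`.

Flanking k-mer enrichment examines the ±150 nt around peaks (clipped
at transcript ends) against dinucleotide-preserving shuffles of the
same flanks, implemented as a random Eulerian walk on the
dinucleotide transition graph with a rejection-sampled arborescence
toward the terminal symbol — exact dinucleotide multiset preservation
is asserted in the tests. Dinucleotide (rather than mononucleotide)
preservation is used here because k-mer counts are sensitive to
first-order composition.

## mRNA decay model

The normalized abundance of a transcript after transcriptional
shut-off is

    m(t) = exp(−(α/β)(1 − e^(−βt)))  for β > 0,
    m(t) = e^(−αt)                   for β = 0,

continuous in β at 0 (implemented via expm1; the tests check the
β → 0 limit and monotonicity). α is the initial decay rate and β the
decay-of-decay rate, both min⁻¹.

*Candidate models.* For G genotypes fitted jointly under one
treatment: {α shared, β=0}, {α per genotype, β=0}, {α shared,
β shared}, {α per genotype, β shared}, {α per genotype, β per
genotype} — a tractable subset capturing genotype effects on either
parameter; with one genotype this collapses to {β=0, β free}.

*Fitting and selection.* Gaussian residuals on the normalized-abundance
scale with a single σ² per fit; maximizing the likelihood gives
σ̂² = RSS/n and −2lnL = n(ln 2πσ̂² + 1). AICc = −2lnL + 2k +
2k(k+1)/(n−k−1) with k counting all free parameters including σ²; the
lowest AICc wins and ties break toward fewer parameters. Optimization
is bounded L-BFGS-B on (log α, β) with α ∈ [10⁻⁵, 1], β ∈ [0, 1],
five starts spread around a log-linear initial estimate, and a 10⁻⁹
objective tolerance.

*Reporting and filters.* Half-life is reported as t½ = ln 2/α (an
exact identity in the output, asserted), with the model-based time to
half abundance — which differs when β > 0, and is infinite when the
curve plateaus above ½ — emitted alongside. Fits pass the quality
filter iff σ² < 0.0625 and every genotype's t½ < 720 min, strict
inequalities.

*Normalization and identifiability.* Size factors use the
median-of-ratios estimator (factor_j = median over genes, nonzero in
all libraries, of count/geometric-mean; validated against DESeq2's
`estimateSizeFactorsForMatrix` in the tests). In a decay time course,
however, *every* transcript decays, so a global exponential trend
trades off exactly against all αs (for β = 0 models, sf_j → sf_j·e^(−c·t_j),
α_g → α_g − c leaves the likelihood unchanged): size factors estimated
on all genes absorb the median decay profile and α recovery collapses.
Real decay assays anchor normalization on stable references, so the
synthetic time courses carry stable spike-in rows and
`fit_decay_cohort` computes the median-of-ratios factors on those
control genes (the analogue of DESeq2's `controlGenes`); any id list
can be supplied for real data, or normalization can fall back to all
genes. Per-genotype normalized observations are scaled by the
genotype's mean normalized count at t = 0, so m(0) ≈ 1 matches the
model's normalization; transcripts with a zero t = 0 mean are skipped.

## Translation efficiency and inducibility

Replicate TE = (normalized polysome + pseudocount) / (normalized
input + pseudocount), pseudocount 1 by default (0 for exact
arithmetic), input and polysome libraries paired by replicate number;
the reported TE is the arithmetic mean over replicates (geometric mean
available). TE is invariant to library depth scaling — exact at
pseudocount 0, approximate otherwise; both are tested.

The induction test substitutes a documented simple test for a full
shrinkage-based differential-expression fit: Welch's t on
log2(normalized count + 1), elf18 vs mock input libraries (≥ 2
replicates each), Benjamini–Hochberg adjustment across transcripts.
An externally computed differential-expression table
(transcript_id, log2FC, padj) can be imported in its place.
Inducible iff fold-change > 1.5 and adjusted p < 0.05, both strict.
With three replicates and overdispersed counts this test is
conservative — in the integration benchmark only ~a third of truly
4-fold-induced transcripts are called — which costs power, never
type-I control (the null benchmark measures ~0% false calls).

## Statistical layer

The Mann–Whitney implementation reports U of the first group. For
small samples (both ≤ 20 and ≤ 200 000 combinations) the exact null
distribution of U is enumerated over all rank assignments with
midranks under ties, and the two-sided p doubles the smaller tail,
capped at 1 — stated explicitly because two-sided conventions differ.
Larger samples use the normal approximation with tie-corrected
variance and no continuity correction (matching the reference
implementation in scipy without continuity, tested). The difference
of medians is reported as an effect size. Exhaustive agreement with a
brute-force enumerator is asserted for all group sizes ≤ 7, and
label-shuffled p-values are checked for uniformity.

Subgroups: a transcript is a *target* when it carries ≥ 1 putative
m⁶A site and ≥ 1 CLIP site, a *control* when it has neither, and
unlabeled otherwise; inducibility is an independent axis. The
stability/TE scatter pairs log2 half-life change with log2 TE change
for inducible transcripts and reports quadrant counts, with
incomplete transcripts excluded and counted.

## Synthetic data: what it emulates, and what it does not

Expression levels are log-normal (median ≈ 1 relative units, σ = 1);
counts are negative-binomial with dispersion 0.05 (Poisson available
for oracle tests); the IP background efficiency for unmodified RNA is
λ_bg = 0.5 (the IP depletes unmodified fragments); control IP
libraries track the input (γ = 1). Planted peaks are 150 nt for the
m⁶A scenario (fragment-scale) and 50 nt for CLIP (footprint-scale),
centred on an exact instance of the consensus motif written into the
sequence, with a stop-codon bias of 0.8 by default. Decay truth draws
half-lives log-uniform on [30, 480] min with β = 0 unless specified;
polysome truth spans TE ∈ [0.25, 4]; decay libraries carry 50 stable
spike-in rows; library size factors are uniform on [0.5, 2] so the
normalization stage genuinely matters. All generators are
deterministic under a fixed seed and truth tables round-trip through
TSV.

The generator does not emulate: read-level artefacts (mapping bias,
duplication), fragment-level coverage autocorrelation within windows,
5′–3′ coverage bias, isoform mixtures, crosslink-induced truncations,
or partial/graded methylation stoichiometry. Benchmarks passing on
this generator therefore demonstrate the correctness and calibration
of the statistical machinery under the stated noise model — not
performance on real libraries, where window counts are more
correlated and backgrounds less exchangeable.

Benchmark problem sizes (200 transcripts per peak-calling run, 200
null CLIP runs at 40 transcripts, 500 decay transcripts, 500-gene
induction nulls, 300 + 300 integration cohort) were chosen so the full
validation suite runs in a couple of minutes on one CPU while keeping
Monte-Carlo error well below the margins being asserted.

## Known limitations

* The m⁶A caller reports region-level sites; it does not refine to
  single-nucleotide resolution or use the motif to sharpen peaks.
* The global empirical FDR is all-or-nothing per run: a run at
  FDR ≥ 0.05 discards every call rather than ranking them.
* The decay model assumes homoscedastic Gaussian residuals on the
  normalized scale; heavy-tailed outliers can distort σ² and hence the
  quality filter.
* The induction test is conservative at small replicate numbers (see
  above); importing an external differential-expression table is the
  recommended route for real data.
* Joint decay fitting enumerates a fixed five-model family; the full
  set-partition enumeration of α-groupings across ≥ 3 genotypes is not
  implemented.
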