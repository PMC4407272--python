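# Methods

## Scope and data model

`chromare` analyses nucleosome-resolution occupancy of a chromatin
remodeller and co-binding transcription factors around regulatory
elements and transcription start sites. All coordinates are 0-based
half-open; BED and bedGraph are consumed natively in that convention and
any 1-based dialect must be converted at the boundary. Coverage is held
dense at 1-bp resolution — the package targets desk-scale genomes (a few
megabases) where a dense float vector is simpler and faster than interval
trees, and the contract that matters (random access, non-negativity) is
independent of layout. A peak's *summit* is the 1-bp position of maximal
signal; where a summit column is absent the interval midpoint is used,
since the anchor rule must still be total.

## Synthetic data generator

The generator emulates the statistical structure of MNase ChIP-seq
occupancy that the downstream analysis assumes; its defaults are the
study conditions, not tuning knobs.

**Element architectures.** Each planted element is one of: `flat` (no
signal), `single` (one remodeller nucleosome), `tf_only` (TF summit
only), `paired` (two remodeller nucleosomes at centre ± d/2 with d drawn
uniformly from 450–800 bp, the separation regime of paired
remodeller-bound nucleosomes at active elements), `tf_between_pair` (TF
summits strictly inside the pair — the MARE architecture), and `tss`
(−1/+1 nucleosomes at stranded offsets centred at −200 and +72 bp with
20 bp Gaussian jitter, plus Pol II 40 bp upstream of the +1 nucleosome,
matching the promoter-paused configuration). Elements are placed
uniformly per chromosome (weighted by usable length) with a minimum
spacing of 3 kb and 3 kb end margins, by the exact order-statistics
construction (uniform draws in the gap-reduced span), so placement is
uniform over all feasible configurations.

**Signal shapes.** Nucleosome bumps are Gaussian with sd 40 bp (a
147-bp MNase footprint), TF and Pol II bumps sd 25 bp; default peak
amplitude 10 (arbitrary density units), acetylation and Pol II 8.
Background noise is per-bp Poisson, default rate 0.05 × the nucleosome
amplitude. Where a fixture specifies a signal-to-noise ratio, SNR is
defined as peak amplitude / Poisson rate (so SNR 5 means rate 2 at
amplitude 10). Knockdown is modelled as multiplicative loss (default
factor 0.1) of the configured factor's bumps at a flagged subset of
elements (exactly round(fraction × n) per class); the Poisson background
is independent per factor and condition.

**Sequence and motifs.** Background sequence is i.i.d. with composition
A/C/G/T = 0.30/0.20/0.20/0.30 (human-like GC ≈ 40%). Motif embedding
writes the PWM consensus at exactly round(p × n) eligible elements on a
random strand; the built-in `ebox_pwm()` (consensus TCACGTGA) is a
synthetic E-box-style matrix for a bHLH factor like MITF, constructed in
code, not taken from a motif database. Consensus (rather than
PWM-sampled) instances make planted counts exactly recoverable by string
search, which the tests exploit.

**Genes.** Differential-expression genes live in 90-kb slots on a
dedicated gene chromosome, one gene per slot at the slot centre. A
configured fraction per status gets a planted occupied site within
±9.5 kb of its TSS, a second fraction in the 10.5–29.5-kb band, and the
remainder are decoys with no element in their slot; with 90-kb slots the
nearest possible foreign element is ≥ 50 kb away, so ±10-kb and ±30-kb
window membership is exact by construction. Default linked fractions are
0.34/0.47 (down-regulated), 0.12/0.18 (up-regulated) and 0.10/0.15
(unchanged) at ±10/±30 kb, the overlap regime the pipeline is meant to
recover. TSS-class elements carry their own genes but are excluded from
the DEG table so the per-status fractions stay exact.

**What the generator does not emulate:** read-level sampling and
fragment-size effects, mappability and GC bias, copy-number variation,
correlated (non-Poisson) background, nucleosome fuzziness/phasing
beyond Gaussian width, and enhancer–promoter looping. Passing tests
therefore demonstrate correctness of the computations under the stated
generative model, not robustness to every artefact of real ChIP-seq.

## Signal matrices and meta-profiles

`compute_matrix` averages per-bp density in fixed-width bins over
[−flank, +flank) around each anchor; means rather than sums keep values
invariant to bin size. Bases beyond chromosome ends contribute zero.
Minus-strand anchors are column-reversed so upstream is always left; the
anchor base itself falls in the first downstream bin (offset 0 belongs
to the + side, consistent with the half-open convention). Defaults are
flank 1000 bp / bin 10 bp for element anchors and flank 2000 bp for TSS
anchors, resolving 450–800-bp pair separations and the −370…+440-bp TSS
range with ample bins. Normalisation modes (`none`, `per_row_max`,
`library_size`) are explicit substitutes for the undocumented internal
scaling of heatmap tools; none is applied by default.

## Profile clustering

`ProfileKMeans` clusters concatenated row vectors from one or more
row-aligned matrices with Euclidean k-means (k-means++ initialisation,
best of 10 restarts, ≤ 300 iterations, fixed seed, via scikit-learn).
Rows are z-scored per row by default so partitions reflect profile shape
rather than amplitude; all-zero (zero-variance) rows are left as zeros.
Clusters are relabelled in descending mean original-scale signal, ties
broken by original label index, making labels stable in meaning across
seeds. k is user-chosen (default 6; typical figures use 4–8).
For accuracy against planted classes the tests use Hungarian matching on
the confusion matrix (`match_labels` / `label_agreement`).

## Paired-peak calling

Profiles are smoothed with a Gaussian (sd 25 bp, converted to bins);
strict local maxima with topographic prominence ≥ 0.2 × the smoothed
global maximum are summits (both parameters exposed). Prominence is
relative, so calls are invariant to positive rescaling; plateaus resolve
to their leftmost bin, which means a profile and its mirror can differ
by one bin exactly on plateau ties. Summit offsets are reported at bin
centres. Classification: 0 summits → none, 1 → single, ≥ 2 → paired on
the *two highest* summits (the stronger/weaker pair), with remaining
summits kept as shoulders; the two-highest rule is preferred over
two-outermost because secondary density shoulders are explicitly not the
flanking nucleosomes. For TSS profiles, summits at offset < 0 are
−1-nucleosome candidates and ≥ 0 are +1 candidates (offset 0 counts as
downstream); the highest summit per side is reported. Separation
summaries (histogram, median, IQR) are provided both per site and on
cluster centroids/meta-profiles, since the separation regime can be read
at either level.

With smoothing sd 25 bp and nucleosome sd 40 bp, two equal bumps ≥
272 bp apart remain bimodal (separation ≫ 2 × the effective 47-bp
width), so both the 450–800-bp pairs and the −200/+72 TSS pair are
resolvable; quantisation limits separation accuracy to ±1 bin per side
(±2 bins on d).

## Co-occupancy, MAREs, differential occupancy, annotation

Co-occupancy is summit-to-summit: site A is co-occupied by factor B iff
some B summit lies within max_dist (default 250 bp, an NDR-scale
distance; inclusive threshold; nearest summit, equidistant ties to the
leftmost). Combination codes list present factors in caller order;
exact code tallies are the analogue of combinatorial heatmap cluster
sizes. A site is a MARE iff its remodeller profile is paired, at least
one member TF is present and *every* member TF summit lies strictly
inside (p1, p2) — open interval, a TF at a flank summit is not
"between" — and acetylation lies within 150 bp of both flank summits
(the `both` rule; `either` is available since single-flank marking is a
plausible reading). Acetyl matching uses per-nucleosome acetyl records.

Differential occupancy is a descriptive symmetric threshold on
log2((s2 + ε)/(s1 + ε)) of mean window signal per site (default
threshold 1, i.e. two-fold), with ε defaulting to 1% of the reference
matrix's mean signal; it is deliberately not a significance test, since
the underlying comparison is cluster/threshold-based. Because knockdown
loss multiplies bumps but not background, loss detection is computed on
windows dominated by the bump (e.g. ±150 bp around single-nucleosome
summits), where a 0.1 loss factor at SNR 5 yields log2 ratios near
−1.2.

Gene annotation is strand-independent distance from summit to TSS with a
half-open window: associated iff tss − w ≤ summit < tss + w (so +w is
excluded, −w included). Annotation measures to summits, not interval
edges, consistent with the summit-centric pipeline. Overlap fractions
report |annotated ∩ status| / |status| per regulation status, with
undefined (not 0) fractions for empty classes, plus pairwise Venn
counts for two DEG tables.

## Motif Z-score

Windows of 200 bp (configurable) around site summits are scanned on both
strands with PWM log-odds scores in bits against a 0-order background
estimated from the supplied genome (N excluded). Scores live on an
integer lattice: per-position log-odds are rounded to 1/1000 bit at
scorer construction, and scanning, thresholds and p-values all use those
integers. The p-value of a score is the exact tail probability that a
background-generated L-mer reaches it, computed by dynamic programming
(per-position convolution of the integer score distribution) — exact for
lattice scores; the only approximation versus unrounded log-odds is the
per-position rounding, bounded by L × 0.0005 bits. A hit is a window
whose p-value is ≤ the threshold (default 1e-4); windows containing N
are skipped. The reverse strand is scanned with the reverse-complement
matrix and its own background distribution (identical to the forward one
for complement-symmetric backgrounds).

The observed statistic x counts total occurrences by default ("number of
motif occurrences" read literally); counting regions-with-≥1-hit is
exposed as an alternative. The null repeats the identical scan on N
(default 100) independent draws of random regions matched one-to-one in
length to the observed windows, uniform over chromosomes weighted by
length; draws may overlap each other and the observed sites, as no
exclusion is part of the procedure (an exclusion flag is not provided;
filtering sites beforehand is the caller's responsibility). Then
z = (x − µ)/σ with µ, σ the mean and standard deviation of the null
counts. σ uses the population denominator N, treating the draws as the
null distribution itself (ddof is switchable); σ = 0 yields an explicit
undefined flag rather than ±∞.

Calibration checks scan a *fresh* independent random site draw as the
observed set (scanning the null draws themselves would make mean z = 0
and sd = 1 identities under the population-σ convention). Those checks
use p-threshold 1e-3 so that ~O(10–40) hits per draw are expected and
the null counts are near-normal; at the 1e-4 default, counts are small
and z is visibly discrete. Because all motifs share one observed draw
and one set of null draws, their z values are weakly correlated; the
across-motif mean of z therefore fluctuates somewhat more than
1/sqrt(#motifs).

## Problem sizes and numerical choices

Simulated studies use 2 × 1 Mb genomes with 100–500 elements (500 for
separation recovery, 200 for TSS and differential fixtures, 84 for the
seven-class combinatorial fixture), 100 null draws, and 50-motif panels;
these sizes give stable recovery statistics in seconds per stage.
Deterministic behaviour under a fixed seed is part of the contract at
every stage: child RNG streams are derived from the config seed and a
stable label (CRC32 of "noise:FACTOR:CONDITION", etc.), so adding one
factor's track never perturbs another's. Writers emit sorted,
fixed-format text so equal inputs give byte-identical outputs.

## Known limitations

- Dense tracks and in-memory genomes cap practical genome size at tens
  of megabases; no bigWig/BAM support by design.
- The p-value DP assumes a 0-order background; higher-order models are
  out of scope.
- Differential calls have no error model; they are threshold
  descriptions of planted multiplicative loss.
- Paired-peak calls on very short separations (< ~150 bp) merge under
  the default smoothing; the method targets the 450–800-bp regime.
- The combination table is exact-match on factor subsets; soft or
  graded membership is not modelled.
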