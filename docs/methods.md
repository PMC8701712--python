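# Methods

## Coordinates and annotation

All internal coordinates are 1-based with closed intervals; position 1 is
the 35S transcription start site (TSS) and `+` is the 35S transcription
direction.  Three anchored frames are interconvertible by affine shifts:
the canonical TSS frame, signed offsets from the mature 25S rRNA 3′ end
(canonical 6648), and signed offsets from the TSS of the downstream repeat
(canonical `repeat_length + 1`).

The packaged annotation fixes only the landmarks whose offsets are well
characterised: the primary terminator T1 at canonical 6739 (+91 from the
25S end), the Rnt1 stem-loop cleavage sites at +14/+15 and +49/+50, the
20-bp A/T-rich tract ending at T1, and the putative promoter-proximal
terminator Tp at −215 from the downstream TSS.  The repeat length
(9100 nt) and the remaining coordinates (T2, the RFB, the 5S gene, spacer
boundaries, Reb1/Nsi1 sites) are plausible editable defaults flagged
`approximate`; nothing in the analysis depends on their exact values, and
a BED6 override replaces any of them.  On disk BED is 0-based half-open;
repeat length and anchors are carried in `#` header comments so the BED
round trip is exact.

## Occupancy profiles

A profile is the per-position count of retained 5′ read ends.  In the
standard Pol I NET-seq chemistry the sequenced cDNA aligns antisense to
the 35S direction, so the default strand policy keeps reverse-strand
primary alignments and takes the rightmost aligned base as the 5′ end;
`sense` and `both` policies cover other library designs.  Unmapped,
secondary and supplementary records are always excluded.  No duplicate
collapsing is performed: at rDNA coverage depths, identical 5′ ends are
expected biological signal, not PCR artefacts that could be recognised as
such without UMIs.

Each replicate is normalized by its own 35S-body sum (positions 1..T1);
positions beyond T1 are scaled by the same factor but excluded from the
normalizing sum, so IGS signal is expressed relative to the 35S output of
the same library.  Re-normalizing is rejected rather than silently
repeated.  The per-strain track is the per-position **median** of the
normalized replicates (a sum aggregate is available); the median is robust
to a single outlier replicate, which is the failure mode triplicate
designs guard against.  A median of normalized tracks does not itself sum
exactly to one over the 35S body; it stays on the normalized scale and is
used as-is.

## Reproducibility

Replicate agreement is the pairwise Spearman rank correlation over the
35S body (default region 1..T1), with average ranks for ties.  Positions
at zero in both replicates are retained — they are genuine observations
that carry tied ranks — and a constant track has no defined ranking, so
such pairs are reported NaN rather than guessed.  Rank correlation is
invariant to normalization, so raw and normalized tracks give identical
coefficients.

## Differential occupancy

At each position a two-sample t-test compares the normalized replicate
values of the two strains; the default is the pooled-variance Student
test (Welch optional), two-sided, with calls at raw p < 0.05.  Raw
p-values are the deliberate default — the analysis is descriptive,
flagging single-nucleotide positions for inspection — with
Benjamini–Hochberg adjustment available when controlling FDR matters.
Positions with zero pooled variance are `untestable` even when the group
means differ: with no within-group variation the statistic is undefined,
and calling such positions would amount to asserting significance from
n = 1 effective observations.  The default analysis region is the 35S
body; terminator analyses use the full repeat.

The 300-nt moving average is centred with truncated windows at the edges
(no padding), so edge values are means over fewer positions rather than
biased toward zero.

Under the generator's null (two strains drawn from one truth at depth
10⁶, three replicates each) the fraction of testable positions called
significant at α = 0.05 sits inside the 99% binomial envelope of 0.05 —
at ~110 expected counts per position the normal approximation behind the
t-test is adequate — and an injected 3-fold block is called `up` at
essentially every position.

## Sequence context and difference logos

The top 2.5% occupied positions of a region (floor of q·|region|; ties at
the threshold broken by ascending coordinate, so selection is
deterministic and rank-invariant) are treated as last-incorporated-
nucleotide (LNT) positions.  Around each, the RNA-sense template symbols
over offsets −8..+4 are tallied (offset 0 = LNT; negative offsets lie in
the RNA:DNA hybrid, which spans roughly 8–9 bp; positive offsets are
untranscribed).  Windows that run off the template, or that contain
non-ACGT symbols, are skipped and counted.

Two context matrices are compared column-wise by Jensen–Shannon
divergence with base-2 logarithms (bounded by 1 bit, symmetric, zero only
for identical distributions) on pseudocounted probabilities (1 per symbol
per column).  The divergence is split into per-symbol contributions
proportional to |p_B − p_A|, signed positive when the symbol is enriched
in the second matrix; absolute contributions sum to the column height.

Column significance uses a permutation test: strain labels are reassigned
over the pooled context sequences (pool sorted first, so results are
independent of input order and symmetric under group swap), each column
rescored with the same statistic, and p = (1 + #{perm ≥ obs}) /
(1 + n_perm) with 1000 permutations by default.  Because a logo window
asks about 13 columns at once, offsets are *called* significant after
Holm step-down correction at the 5% family-wise level; raw per-column
p-values are also reported.  With 1000 permutations the smallest
attainable p (≈ 0.001) still clears the Holm threshold, while uniform
null columns essentially never do.

## Termination

Occupancy at steady state is flux × dwell time.  Assuming locally
constant elongation rate (constant dwell) on the two sides of a
terminator, the ratio of mean occupancy downstream vs upstream estimates
the read-through fraction; efficiency is 1 − ratio clipped to [0, 1].
Windows default to 100 nt on each side separated from the terminator by a
10-nt gap, so the pre-termination pause peak does not inflate the
upstream mean.  A zero upstream mean leaves the index undefined and is
reported explicitly.  The constant-dwell assumption is the method's main
approximation: strong sequence-dependent dwell variation inside a
flanking window biases the ratio (visible in the worked example, where
the recovered efficiency differs from the generative setting by ~0.1);
on uniform-dwell simulations the estimate is within ±0.01 of truth at
depth 10⁶ across efficiencies 0.5–0.99.

Pause/arrest clusters are positions exceeding a robust local background —
rolling median and MAD over a 500-nt window (whole-region fallback, with
a warning, when the region is smaller) — by z > 4 MAD-scaled deviations
*and* at least 1.5-fold.  The fold floor matters at depth: on a deep
track the MAD is small relative to the mean, and replicate
overdispersion alone can push tiny relative excursions past any pure
z-threshold.  Outlier positions within 5 nt merge into one cluster; each
cluster reports its maximum position as the peak, a MAD-z enrichment
score, and the peak's distance upstream of the downstream 35S TSS (the
frame in which the promoter-proximal pause site is conventionally
quoted).  Detection operates on the median replicate track, as in the
pipeline; on uniform-dwell null medians (three replicates) the default
thresholds produce no clusters in ≥ 95% of simulations, while injected
pauses of ≥ 5-fold are recovered within ±2 nt.

## Synthetic data generator

The generator is the testing ground truth, not a fit to real data.  Per
position, the expected weight is

    w_i = exp(Σ_{o ∈ hybrid window} β[template[i+o]]) · pause_fold(i) · S_i

with `S_i = Π (1 − e_T)` over terminators upstream of `i` (memoryless
survival; a Pol III roadblock at the 5S gene is representable as a
terminator-like entry).  Counts per replicate are gamma-Poisson
(negative binomial) around `depth · library_factor · w_i / Σw`;
dispersion 0 recovers Poisson.  Defaults: depth 10⁶ reads per replicate
(the scale of a deep NET-seq library over the rDNA), three replicates,
dispersion 0.01 (mild biological overdispersion), unit library factors,
GC fraction 0.4 for random templates (near the yeast genome average),
and dwell coefficients A +0.3, T +0.2, G −0.2, C −0.3 summed over offsets
−8..0 — an A/T dwell preference giving tracks the multi-order-of-
magnitude dynamic range real occupancy shows (replicate Spearman ρ ≈ 0.96
at full depth).  Pause motifs are written into the shared template ending
at the pause position, so context analyses can recover them at offsets
−len+1..0.

What the generator does **not** emulate: polymerase collisions and
backtracking, 5′→3′ exonuclease (torpedo) kinetics, Pol III occupancy of
the 5S gene, mappability artefacts, and PCR duplication.  Passing
recovery tests therefore shows the statistics are correct under the
stated model, not that real libraries satisfy the model.

Recovery-oriented validations (terminator efficiency, pause position,
motif detection, t-test calibration) use uniform-dwell truths
(`sequence_coefficients={}`): they test each estimator under its own
assumptions, with the dwell-variation bias documented above and exercised
separately in the worked example.

Toy alignments are single-end 30-nt reverse-strand SAM records whose 5′
end sits at the counted position (shortened near the template start), so
counting the emitted file reproduces the simulated profile exactly.

## Numerical and design notes

- Normalization tolerance: the 35S-body sum after normalization is 1
  within 1e-9 (float64 summation error over ~6700 terms is ≪ that).
- Moving-average and dwell-weight windows use cumulative sums; the
  window-1 moving average short-circuits to the identity.
- All simulation randomness flows through one `numpy` generator seeded
  from the truth's seed, with strains and replicates drawn in sorted
  order — outputs are bit-reproducible.
- Problem sizes in the test suite (depth 10⁶, 10 null simulations for
  calibration, 100 seeds for the null-cluster check, 1000 permutations)
  keep the full suite under half a minute on one core while leaving the
  binomial/permutation resolution the checks need.
- The pipeline writes every stage output as TSV/bedGraph/BED plus a JSON
  manifest echoing the configuration, package version and seed; a stage
  failure aborts with the stage name and leaves the manifest marked.

## Known limitations

- The read-through index is an operationalization; no standard numeric
  definition exists.  It is scale-invariant and comparable across strains
  but biased where dwell varies strongly within a flanking window.
- Efficiencies at tandem terminators are estimated marginally per
  terminator; no joint deconvolution of T1/T2/Tp survival is attempted.
- The default annotation's `approximate` coordinates are placeholders;
  analyses quoting T2/5S/RFB positions on real data should supply a
  reference-matched BED.
- Single-repeat mapping collapses the ~150–200 genomic rDNA copies onto
  one consensus; copy-to-copy variation is invisible.
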