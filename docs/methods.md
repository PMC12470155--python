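# Methods

`dnascape` analyzes how dinucleotide composition and DNA repeats shape the
landscape of structural DNA properties (Roll, Twist, Slide, stiffness,
persistence length, ...) around functional genomic annotations (genes,
promoters, enhancers, TF/CTCF binding sites, TAD borders).  This note
documents the models, the conventions behind every numerical choice, and
what the synthetic-genome tests do and do not demonstrate.

## Binned maps

All quantities live on fixed-resolution per-chromosome bins (default
1000 bp; every analysis accepts any resolution).  Dinucleotides are counted
overlapping on the forward strand; the pair spanning positions (i, i+1) is
assigned to the bin containing i.  Under this convention the pair bridging
two bins belongs to the left bin, every genomic pair is counted exactly
once, and an interior N-free bin holds exactly `resolution` pairs — which
makes the zero-order identity `sum_XY E[n_XY] = L` exact (see below).  N
bases break pairs and runs; bins with less than 50% valid bases are flagged
invalid (NaN), mirroring the 50% masking rule of the profile aggregation.
Complement dinucleotide classes (AA/TT, ...) are summed only at reporting
time (`group_complements`): the property models are defined per ordered
dinucleotide, and strand symmetry is a presentation choice.

## Tandem repeats

A tandem repeat is a maximal perfect head-to-tail run of a 1–6 bp unit,
qualifying iff its total length is at least `max(4, 2 * unit)` — at least
two complete units and at least 4 bp.  Runs are reported at their smallest
period (a homopolymer is never also a dimer repeat), and rotational phases
form one class, labelled by the lexicographically smallest rotation
(`(AC)n` covers ACAC... and CACA...).  Reverse-complement classes are kept
separate at detection and merged only as a reporting option.  Overlaps
between runs of different periods are resolved greedily — longest run
first, leftmost then smallest period on ties — with later candidates
trimmed to uncovered bases and re-checked, so no base is counted twice.
The detector is validated exhaustively against a brute-force (start, unit)
scanner.  Repeat *content* per bin is base coverage (bp of the bin inside
repeats of a class); degenerate repeats with mismatches or indels are out
of scope (that is annotation-tool territory).

## Property models

A property model is a vector of 16 values, one per dinucleotide step.  The
bundled table (`data/dinucleotide_properties.tsv`) is a small synthetic
fixture of named models with literature-typical magnitudes and correct
strand symmetry (helical parameters symmetric under reverse complement,
Tilt/Shift antisymmetric); real studies should load their own table in the
same TSV layout.  A model applied to a bin yields either the sum
`sum_XY m_XY n_XY` (`sum` mode) or that sum divided by the bin's total pair
count (`mean` mode, the default): the phrase "summing the products" leaves
the normalization open, and the mean makes bins with different valid
lengths comparable, so profiles remain intensive.  `sum` mode is retained
for exact count-style totals and is used wherever exact additivity matters
(influence decomposition).

## Null models

Two nested references isolate what composition alone explains:

* **Zero-order (dinucleotide) reference.**  `E[n_XY] = n_X n_Y / L` per
  bin, from the bin's own nucleotide counts.  This is the expectation under
  a zero-order Markov model — i.i.d. redraws from the bin's empirical
  composition.  It is *not* the permutation expectation: shuffling a fixed
  bin without replacement depresses homotypic pairs by exactly `n_X / L`
  (the hypergeometric correction `n_X(n_X-1)/L`), a small but measurable
  difference at 10^4 replicates.  The validation oracle therefore redraws
  i.i.d., and draws each randomized bin with its bridging base so the bin
  carries exactly L pairs, matching the counting convention; the closed-form
  expectations are then exactly unbiased.
* **First-order (tandem-repeat) reference.**
  `E[n_XY, n>=2] = n_XY^2 n_YX / (n_X n_Y)` per bin, from the bin's own
  dinucleotide counts.  Monte-Carlo simulation under first-order Markov
  chains pins down what this formula estimates: the expected number of
  *start positions* of the 4-mer XYXY (overlapping occurrences of at least
  two units).  The homopolymer case degenerates to `n_XX^3 / n_X^2` and is
  validated the same way.  The comparison must evaluate the formula at mean
  counts; the per-replicate plug-in carries an O(1) ratio bias.
* **Uniform reference.**  Genome-wide valid-fraction-weighted mean and SD
  of a track over valid bins.

## Environment profiles

For each anchor the surrounding track values are collected per signed
distance from the anchor's reference point (interval midpoint by default;
start/end modes are provided for long features such as genes).  The
interiors of annotations — including the anchors themselves — are masked:
a bin overlapped by annotation intervals loses that fraction of its
weight, and bins more than 50% masked are discarded.  This is what removes
the clustering bias (e.g. promoters sitting next to genes).  Remaining
bins are weighted by their unmasked fraction; per distance, a weighted
mean and variance are pooled over anchors using reliability weights with
the standard frequency-weight correction, and the profile's standard error
is `sqrt(weighted variance / total weight)`.  Profiles are not
strand-flipped (regulatory annotations are strandless here).

When several tracks are profiled together (`profile_tracks`) a bin
contributes only if it is valid in *every* track, so all profiles share
identical weights.  Any linear combination of tracks then profiles to the
same linear combination of profiles exactly — the property the influence
decomposition is built on.

## Peak calling

The far-distance baseline pools the weighted mean and SD of all profile
bins beyond a minimum distance (default 800 kbp; the profile default
half-width of 1 Mbp comfortably exceeds it), assuming anchors have no
influence there.  From distance zero, the deviation is tested with
`z = (mean(d) - baseline) / sqrt(SE(d)^2 + SE_baseline^2)`; detection
requires |z| > 2 at the center (the threshold is configurable; no
multiple-testing correction is applied, raw sigmas are reported).  The
peak expands outward until the first bin that is not significantly
deviated in the apex's direction (a gap-tolerance option can bridge
isolated non-significant bins; default strict).  Height is the maximal
absolute deviation over the significant span; width is the span bounds;
the height uncertainty is the SE at the apex bin.

A peak can be scored against the same peak called on a reference profile:
`sigma_rel = (h_emp - h_ref) / sqrt(u_emp^2 + u_ref^2)` with signed
heights, an undetected peak contributing height 0 with its center-bin SE.
Scored against the zero-order reference this cancels peaks that are pure
composition (G+C) gradients, which is verified on synthetic genomes whose
anchor flanks carry only a nucleotide-frequency gradient.

## Map correlation

Pearson correlation between two genome-wide maps is estimated by
bootstrap: R repetitions of K jointly valid bin positions drawn uniformly
genome-wide *with replacement* (defaults R = K = 50), giving a mean and SD
over repetitions.  The null independently permutes the bin positions of
each map (alignment destroyed, marginals kept) and repeats the procedure;
significance is the difference of means over the quadrature sum of the two
SDs.  Zero-variance samples are redrawn (bounded retries).  Known
limitation: the scheme ignores spatial autocorrelation between bins, so
its SD understates the error for strongly autocorrelated maps; a block
bootstrap would be the remedy and is deliberately not the default.

## Influence decomposition

Because the property track is linear in the 16 dinucleotide count tracks,
profiling property and counts with shared weights makes the peak height
decompose exactly: `c_XY = m_XY (f_XY(apex) - f_XY(baseline))` sums over
XY to the signed height (machine precision in `sum` mode; in `mean` mode
the features are fractions of the bin's total pair count — a shared
denominator — so additivity again holds exactly and the reported residual
row is a numerical check, not a model term).  Restricting counts to bases
inside repeat intervals (both bases of a pair must lie in the interval;
per-base precedence transposon > tandem repeat > outside, fixed and
documented) partitions each c_XY into repeat-class contributions plus an
"outside" remainder, conserving counts exactly.  Relative influences are
reported under two normalizations, column-labelled: by the sum of absolute
dinucleotide contributions (keeps opposing influences visible; repeat
rows share the same denominator so they are comparable with dinucleotide
rows on one scale, and can exceed 100% when partitions oppose each other)
and by the signed peak height.

## Synthetic genomes

The generator replaces multi-GB genome downloads with ground-truth test
material.  It emulates: i.i.d. or first-order Markov background
composition; tandem-repeat arrays and transposon-like insertions of fixed
consensus composition (an Alu-like G+C/AG-rich and an L1-like A+T-rich
consensus are bundled), placed uniformly or biased toward anchor flanks,
overwriting the sequence so coordinates never shift; and anchors whose
flanks are resampled from a local first-order chain realizing a programmed
dinucleotide enrichment profile (triangular or flat decay over a support
W).  A rank-1 enrichment (per-nucleotide factors) degenerates to i.i.d.
sampling — a pure composition gradient, the adversarial case for the
zero-order reference.  The truth record stores anchor/repeat coordinates
and the *realized* chain expectation of the flank dinucleotide profile
(the marginal evolved through the per-offset transition matrices), which
is exact for the sampler — downstream recovery is tested against it, not
against the nominal enrichment factor.  Anchor windows are placed by exact
uniform sampling over the remaining feasible positions, so placement fails
only when the requested packing genuinely does not fit.  All randomness
derives from one master seed via per-operation streams (CRC32 of the
operation name as spawn key), making every artifact byte-reproducible and
stages independently regenerable.

What the generator does *not* emulate: transposon phylogenies and age
structure, CpG islands, mutation processes, chromatin-state-dependent
annotation densities, and real genomes' long-range composition structure.
Passing tests therefore demonstrate the correctness and calibration of the
machinery, not biological conclusions about real genomes.

## Scaled study conditions

The defaults mirror the megabase-scale design (resolution 1000 bp, profile
half-width 1 Mbp, baseline beyond 800 kbp, bootstrap 50 x 50).  The test
suite and the acceptance script run the same machinery at toy scale as the
package's own reference conditions: resolution 200 bp, anchor-flank
support 2–5 kbp, half-width 40 kbp, baseline beyond 25 kbp, genomes of
0.4–1.6 Mbp with 30–80 anchors.  These sizes were chosen once for adequate
statistical power (detection z of 4–7 for the programmed effects) and are
not tuned per test.

## Known limitations

* Peak detection is anchored at distance zero; off-center or multi-modal
  structure is summarized only through the central peak.
* The bootstrap correlation ignores autocorrelation (above).
* Whether the original analyses counted TR occurrences or base coverage
  per bin is not documented; base coverage is used here and the choice is
  isolated behind `tandem_repeat_intervals`/`coverage_track` for
  sensitivity analysis.
* The bundled property table is a fixture; conclusions about specific
  properties require a real model database in the same layout.
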