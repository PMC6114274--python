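# Methods

## Problem setting and model

cladescan annotates protein domains on short amino-acid reads/ORFs.  A
hit of model *M* on read *r* is summarised by two coordinates: the
bit-score *b* (log-odds of the match under the profile vs a background
model) and the mean-bit-score *b/ℓ*, where ℓ = ali_end − ali_start + 1
is the hit length on the read.  Short true fragments have small *b* but
high *b/ℓ*; random matches have both small.  The per-domain acceptance
region — the "two-dimensional gathering threshold" — is the set of
points whose posterior probability of being a true positive, under a
discrete naive-Bayes model fitted to labelled training points in this
plane, exceeds a cut (default 0.9), intersected with
{b > b_min}, where b_min is the smallest bit-score among the negative
training points.  The floor matters because the retained negatives are
deliberately the most significant ones, which sit at the boundary of
the positive region.

Each domain carries one sequence-consensus model (SCM) and any number of
clade-centered models (CCMs).  Two spaces are fitted per domain — one
for the SCM, one pooling all CCM points — because the two model classes
produce scores on different scales.  Model libraries are supplied as a
TSV manifest; the package never builds clade libraries itself.

## Training-set construction

Positives: for each (degapped) SEED sequence of length *len*, terminal
fragment ladders with maximum M = min(0.30·len, 100 aa), step
L = 1 (len < 15), 5 (15–75) or 10 (> 75) aa, lengths n·L for n = 1…N
with N = ⌈M/L⌉, from both ends.  For len > 270 aa, ten internal
fragments: start uniform over the region not covered by the ladders,
raw length ~ Normal(50, 25) rounded, clipped to [1, available span].
Internal fragments may overlap one another (disjointness is not
enforced).  Each fragment is scanned against the domain's models; the
best hit per model class yields one training point, and points are
deduplicated by exact (b, b/ℓ).

Negatives: decoys are screened against the domain's models and only the
matched ones become training points.  Three generators, in order:

1. permutation of the sequence's non-overlapping 2-mers (an odd trailing
   residue stays in place),
2. reversal,
3. an order-3 Markov chain whose 4-tuple emission is
   (n·W + 1) / (160000 + N·W) with n the tuple count over all SEED
   sequences, N = Σn, and W ≥ 1 a weight that sharpens the SEED bias
   when SEEDs are small.  This form sums to 1 exactly and makes W
   effective: the odds of an observed tuple against an unobserved one
   are n·W + 1.  (The variant that multiplies the whole pseudo-counted
   numerator by W is a no-op after normalisation, which would defeat
   the weight-calibration loop, so it is not used.)  Sampling is
   stationary: the first three residues from the marginal 3-prefix
   distribution of the emission, then next-residue conditionals.  This
   "global 4-mer" reading is one interpretation of position-dependent
   sampling; a position-specific variant would need per-position counts
   the SEED sizes here cannot support.

Acceptance of a decoy: a positive bit-score for the SCM; for CCMs, a
calibrated bit-score threshold standing in for "E-value < 1" — the 99th
percentile of best scores on uniform-random sequences of the model's
length (the built-in scanner has no E-value theory; the percentile makes
CCM acceptance deliberately easier than SCM acceptance, matching the
relative permissiveness of the two rules).  A decoy accepted by several
CCMs contributes one point (best score), mirroring the one-hit-per-region
logic of the first selection filter.

The generation target is negatives ≥ ⌈0.5·n_pos⌉ per model class
(`plan_negative_generation`; the Markov stage is budgeted as
deficit / expected-acceptance-rate, defaults 5·10⁻⁴ per decoy for SCMs
and 5·10⁻³ for CCMs, the midpoints of the 1–10 per 10,000 / per 1,000
acceptance bands).  In `build_training_set` the Markov stage runs in
batches and stops as soon as the balance is reached, with a hard cap
(default 2,000 decoys per domain) that keeps threshold training on a
20-domain library under a minute on one CPU; the built-in scanner
accepts decoys far more often than the external engines the default
rates describe, so the cap does not bind in practice.  Finally
`select_negatives` deduplicates exact (b, b/ℓ) points and keeps the
n_pos points farthest (Euclidean) from the origin.

The adaptive weight calibration (`calibrate_markov_weight`) increments
W from 10 until a 10,000-decoy batch yields 1–10 SCM-accepted decoys,
and errors out at max_W reporting the last rate.

## The discrete naive-Bayes space

Each axis is discretized by supervised MDL partitioning (Fayyad–Irani:
recursive best-entropy binary splits, accepted while
gain > (log₂(n−1) + log₂(3^k−2) − kE + k₁E₁ + k₂E₂)/n); if no split is
accepted the axis falls back to 20 equal-width bins over the observed
range (a constant axis to a single cut).  The two open-ended boundary
bins guarantee the posterior is defined everywhere.  Bin counts get
Laplace smoothing (α = 1, configurable), priors are empirical, and

P(+|b, m) ∝ P(+) · P(bin(b)|+) · P(bin(m)|+).

Degenerate inputs: a single-class training set is an error (the domain
is reported unlearnable); ties in bin assignment use left-closed bins
(value ≤ cut falls left).  Note the α = 1 smoothing means posteriors are
only asymptotically invariant under duplication of the training set;
at realistic training sizes (≥ ~50 points/class) the effect is < 0.05.

## Hit selection

1. **Same-domain dedup** — per model class and domain, greedy by
   descending bit-score (ties: longer hit, then model_id); a hit is
   dropped when its overlap with a retained hit covers ≥ 85% of *both*
   lengths.  Distinct occurrences of one domain on a read survive.
2. **Gathering threshold** — strict inequalities on both criteria:
   b > b_min and posterior > threshold (0.9 default; 0.85 variant).
3. **Ranking resolution** — ranking score = posterior × identity/100.
   The posterior serves as the [0,1] significance of the bit-score: it
   is monotone in score within the acceptance region and already
   computed; no separate significance map is introduced.  Greedy
   retention in rank order (ties: bit-score, then model_id); a hit
   sharing ≥ 10 read positions with a retained hit is discarded.

Identity is computed against the model consensus over aligned columns,
excluding columns where either side is X or `*` (empty denominator → 0).
For hits parsed from HMMER domtblout without read sequences the identity
defaults to 100 (a neutral constant — ranking then reduces to the
posterior).

`combine_annotations` implements primary-plus-secondary merging: all
primary annotations verbatim, secondary ones only for reads the primary
tool left without any hit.

## Built-in scanner

The test/desk backend is an ungapped PSSM: per-column probabilities
(count + pseudocount)/(rows + 20·pseudocount), uniform 1/20 background,
log-odds in bits.  Every placement of the model over the read with ≥ 8
aligned columns (terminal overhangs allowed) is scored as the sum of
column log-odds; placements with positive score are reported after
suppression of placements within one column shift of a higher-scoring
eligible placement.  `*` and X contribute zero bits and never count as
matches.  It performs no gapped alignment and has no E-value theory —
real searches should be imported through the domtblout / PSI-BLAST
parsers.

## Synthetic data

`default_fixture` emulates the target regime: 20 families of length
80–300 aa; SEED rows at 15% substitution from a uniform-random
consensus; 3 clade variants per family drifted at 35% (divergent enough
that the clade's own model out-scores the consensus model on its
fragments) each with a 4-row sub-SEED at 10%; 2,000 reads of 60 aa
(≈180 bp ORFs), half carrying a planted fragment of 25–55 aa at 5%
substitution noise inside uniform-random background.  Background is
uniform over the 20 residues by design, matching the scanner's
background model so bit-scores are calibrated.

What passing on this fixture does *not* show: robustness to real
sequencing-error profiles (indels, homopolymer errors), biased amino
acid composition, gapped divergence, overlapping/multi-domain
architectures beyond two domains, or the behaviour of real pHMM/PSSM
engines — those enter only through the file parsers.

## Problem sizes and determinism

All randomness flows through explicit `numpy.random.Generator` seeds;
repeated runs are byte-identical.  Default analysis sizes (20 families /
2,000 reads; 2,000-decoy Markov cap; 200-sequence CCM calibration in
training, 1,000 available) were chosen so a full train-plus-annotate
cycle completes in about a minute on a single CPU while keeping every
per-domain training set in the hundreds of points — ample for a
two-axis discrete classifier.

## Known limitations

- The CCM "E-value < 1" surrogate is a per-model empirical percentile;
  it is not an E-value and is only used with the built-in scanner.
- Whole translated frames are annotated; frames are not split at stop
  codons into sub-ORFs (stops score as background and depress b/ℓ
  instead).
- Clade libraries are consumed, not constructed; no model-redundancy
  clustering.
- Functional profiling counts flat GO classes; no GO-DAG traversal.
- Read-level evaluation ignores coordinates (domain presence per read);
  the planted-truth tables carry coordinates should a coordinate-aware
  mode be added.
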