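# Methods

## Model and definitions

Sequences are promoter-sized DNA fragments over {A,C,G,T,N}; coordinates
are 0-based half-open internally and 1-based closed in GFF3 output.  A
*feature type* is anything that places located occurrences (instances) on
sequences: a PWM above its threshold, a built-in detector, or an imported
prediction track.  For a set S of N sequences:

- feature coverage `C^S_φ`: distinct sequences carrying ≥ 1 instance,
  divided by N.  The formal "maximal matching" reading of coverage
  collapses to this count for single features because two instances on
  the same sequence never contribute twice.
- feature frequency `F^S_φ`: instance count divided by Σ|sᵢ|.
- module Φ = {φ₁,…,φ_k} (a *set* of feature types — mutation operators
  exchange/add/delete single members, which forces set semantics; repeated
  members are not supported).  Module coverage counts sequences carrying
  all members.
- support sequence: the shortest interval containing one complete
  instance of every member, computed by an anchor sweep over instance
  starts (for each anchor, each member contributes its earliest-ending
  instance starting at or after the anchor).  Ties in length resolve to
  the smallest start, so the leftmost minimal support is canonical and
  overlap computations are deterministic.
- module overlap: Σ over sequences of the bp intersection of two modules'
  supports.  Supports on different sequences contribute zero.  Strand is
  ignored throughout module construction: an instance occupies its
  interval regardless of orientation.

## PWM scoring and discriminative thresholds

PWMs are log-odds (base 2) matrices from position frequency matrices with
a background-distributed pseudocount of total mass 1:
`w[b,j] = log2((n[b,j] + q_b) / ((N_j + 1)·q_b))`, background `q`
estimated from the union of the positive and negative sets (uniform
fallback).  Window scores are min-max normalized to [0,1], so the
consensus word scores exactly 1 and "threshold minus 5%" is an absolute
0.05 step.  Windows containing N never count as hits.  Both strands are
scanned by default (prokaryotic promoters); reverse-strand hits are
reported in forward coordinates.

Threshold optimization evaluates every *attained* normalized window score
(no grid), keeps candidates satisfying `C⁺ ≥ 0.75`, `C⁻ ≤ 0.5`,
`F⁺/F⁻ ≥ 2` (strict mode: `C⁻ ≤ 0.25`), and selects the candidate
maximizing `C⁺/C⁻`, breaking ties toward the stricter threshold.  A PWM
with no qualifying candidate is excluded.  When `C⁻ = 0` the ratio uses
the half-count `1/(2N⁻)` — one imagined hit in a doubled negative set —
which keeps fitness finite and comparable instead of letting a single
zero dominate the search.

## Built-in detectors

- **Compositional regions**: windows of `min_len` (default 100 bp, step
  1) classified against three-sigma bounds derived from the per-sequence
  GC of the positive set (mean ± 3·sample SD; the pooled-bp variant is
  available for comparison); touching same-class windows merge into
  maximal regions (merge gap configurable, default 0).
- **Poly-A tracts**: 8-mers within Hamming distance 1 of A₈; raw windows
  by default, maximal merged tracts as an option; (T)₈ scanning behind a
  flag (strand convention of the source data decides).
- **Repeats**: exact maximal direct and inverted repeats by
  seed-and-extend (arm ≥ 10 bp, spacer ≤ 500 bp by default), arms trimmed
  to non-overlap for tandem/palindromic matches, classified GC-rich
  (≥ 0.75), GC-poor (≤ 0.25) or neutral.  This is a self-contained
  detector; repeat tracks from external programs can equally be imported.
- **Imported tracks** (TSS, SIDD, de novo motif hits): BED (0-based
  half-open) or GFF3 (1-based closed, feature id in the source column).
  SIDD values are never computed here — when an imported SIDD track has
  scores, their dispersion is reported descriptively, not used as a
  detector.
- Detector and imported features can be screened through the same
  boundary-condition interface as PWMs (`screen_feature`), with
  configurable bounds; non-motif features are not screened by default,
  matching practice where a TSS track enters the analysis on judgment.

## Genetic algorithm

Initial population: all feature pairs, fitness-sorted, truncated to
`population_size` (200).  Parent choice is fitness-proportional.
Operators and default probabilities: exchange 0.4, add 0.2, delete 0.2,
merge 0.2 (merge partners fitness-weighted); results respect
1 ≤ k ≤ `max_features` (6); impossible operators are resampled.
Truncation is purely elitist over distinct feature sets.  Population
ordering breaks fitness ties by fewer members, then lexicographic ids —
a parsimony preference that makes the smallest of otherwise equivalent
modules the canonical representative.

Every `selection_interval` mutations the top `pool_size` (20) modules
form the candidate pool and the K-subset minimizing total pairwise
support overlap on the positive set is selected exactly (subset
enumeration with memoized pairwise overlaps, pools ≤ 25) or by greedy
forward selection with single-swap refinement beyond that.  Subset ties
break toward higher summed fitness, then lexicographic feature ids.
Convergence: the selected K-set unchanged for `convergence_rounds`
consecutive selections; `max_rounds` caps the loop.

Production settings follow the published procedure (10⁶ mutations per
selection, 100 unchanged rounds).  The desk profile `GaConfig.scaled()`
(10³ mutations per selection, 10 unchanged rounds, ≤ 200 rounds) is what
the test suite, the CLI default and the acceptance script use; at 23–32
feature types on 13 + 115 sequences a run converges in seconds because
module evaluation reduces to boolean row-ANDs over precomputed
feature-by-sequence presence matrices.

Module p-values are a pragmatic binomial tail: P(X ≥ n⁺) with N⁺ trials
and per-sequence success probability equal to the module's presence rate
on the random set (half-count corrected when zero).  They are reported
for orientation only and play no role in the search — ranking hypotheses
by significance is deliberately *not* the selection principle; the
overlap criterion is.

The multi-run driver concatenates R independent runs (R×K modules),
removes exact duplicates automatically, and emits Jaccard similarity
matrices over feature sets and over support intervals.  Grouping merely
*similar* modules by OR-logic remains a human judgment and is out of
scope.

## Synthetic benchmark

`simulate.generate_sets` emulates a promoter-trap library: fragment
lengths Normal(640, 232²) truncated (by resampling) at 100 bp; i.i.d.
bases at per-set GC (positives 0.488, negatives 0.532); a planted module
of three well-conserved 14-bp motifs placed in order within a 150 bp
span (one slot per member) in 80% of positives; 20 decoy 8-mer types
embedded twice per sequence in every set; and — the deliberate hard part
— 30% of negatives carry a *partial* module (a random 2-subset of the
planted motifs, co-located, never all three).  Partial negatives mirror
inactive fragments lacking one essential component and give every proper
subset of the planted set a measurably worse C⁺/C⁻ than the full module;
without them the benchmark could not distinguish the exact planted set
from its subsets.  Planted occurrences are sampled per column from the
PFM *conditioned* on a normalized PWM score ≥ 0.85: sites vary, so
threshold optimization is non-trivial, but are always plausible binding
words rather than the degenerate tail of unconditional column sampling.

What the generator does **not** emulate: dinucleotide/genomic background
structure (an i.i.d. null, with a Markov-1 option for harder nulls),
positional preferences relative to a TSS, overlapping or nested true
modules, and any expression readout.  Passing the recovery benchmark
therefore shows that the pipeline's machinery — threshold optimization,
relaxation, scanning, fitness and overlap-minimal selection — composes
correctly under realistic sizes and confounders; it does not certify
performance on genomic background or on datasets whose negatives are
free of partial modules.

`simulate.fragment_genome` tiles a genome into fragments with the same
length distribution; fragments reconstruct the genome exactly, and the
promoter-trap convention of dropping a trailing fragment shorter than
100 bp is an option (`min_keep`) rather than the default.

## Numerical choices

- Score comparisons use an absolute epsilon of 1e-9 on normalized scores
  so "≥ threshold" is robust to float noise; candidate thresholds are the
  attained scores themselves.
- Coverage counts are exact set computations; fitness ties are therefore
  exact ties and the deterministic tie-breaks above decide.
- All randomness flows through a single `numpy` Generator per component,
  seeded from the run configuration; identical seeds give byte-identical
  FASTA, searches and reports.  Multi-run and multi-seed drivers derive
  child seeds via `SeedSequence`.

## Known limitations

- The exact-repeat detector finds exact arms only; degenerate repeats
  need an external tool and track import.
- The overlap-minimal K-selection intrinsically favors low-coverage,
  small-support candidates among near-ties; the pool is fitness-gated
  (top 20) precisely so that weak but disjoint modules cannot displace
  strong ones.
- The binomial module p-value treats sequences as exchangeable Bernoulli
  trials and ignores length variation; it is a descriptive column, not an
  inferential claim.
- With fewer than K sufficiently distinct candidates the selection
  returns the whole pool and flags it rather than fabricating diversity.
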