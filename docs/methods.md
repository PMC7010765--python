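# Methods

This note documents the models and procedures implemented in `songseq`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limitations of validating the analysis on
synthetic song.

## Song representation

A corpus is one bird's set of song bouts; a bout is a non-empty ordered
sequence of syllable events. A syllable is a symbolic label (labelling
itself — segmenting and categorizing syllables from audio — is outside
the package's scope), optionally annotated with the silent gap preceding
it within the bout (ms) and a vector of named acoustic features.
`<START>` and `<END>` are reserved tokens; `<END>` marks bout
termination in transition tables. Formats are plain text: bout files
(one bout per line, whitespace-separated labels, UTF-8, case-sensitive),
gap/feature CSVs keyed by 0-based bout index and within-bout position
(the first syllable of a bout has no within-bout gap by convention), and
grammar JSON.

## Sequence statistics

**Prevalence.** An element's count divided by the total count of
elements of its class in that bird's song, pooled over bouts.

**Transition tables.** First-order (or fixed higher-order context)
counts of the next element after each context, counting each adjacent
within-bout pair once; the final element of every bout contributes an
`<END>` count. Probabilities are computed either over all continuations
including `<END>` (diagnostics) or renormalized over syllable
transitions only — the default, since a bout termination is not a
syllable transition. The same convention is applied at pairwise and
branch-point levels for consistency; terminations immediately following
a branch point are excluded from its probabilities and entropy.

**Transition entropy.** `H = Σ −pᵢ log₂ pᵢ` in bits over a context's
transition distribution; zero-probability entries contribute 0;
`0 ≤ H ≤ log₂ k` with equality at 0 iff one transition is certain.
Input distributions must sum to 1 within 1e-9.

**Repeat number.** The mean length of maximal consecutive runs of a
syllable across bouts; always ≥ 1.

**Split-half reliability.** Bouts (the unit of recording) are randomly
partitioned into halves differing in size by at most one; transition
probabilities at the requested contexts are estimated per half and the
squared Pearson correlation is taken over the union of transitions
observed in either half (absent → 0). Contexts absent from both halves
are excluded with a warning.

## Structure discovery

Motifs are recovered by greedy agglomeration on the first-order
transition graph. Maximal runs of a single label are first collapsed to
a repeat unit (a label that ever repeats is treated as a repeat
syllable). Two adjacent units `u → v` merge into a chunk when the
forward probability p(v follows u), the backward probability
p(u precedes v), and the pair count all clear thresholds
(`chain_threshold` default 0.75; `min_count` default 5), iterating to a
fixed point with chunks as units; the most frequent eligible pair is
merged first, ties broken lexicographically, and self-merges are not
allowed. Both directions are required so that a syllable shared by two
motifs (e.g. `c` in both `abcd` and `cefg`) does not chain across motif
boundaries. Denominators include all occurrences of a unit (bout-final
and bout-initial ones included), so boundary effects dilute rather than
hide variable transitions. Chunks of ≥ 2 positions and standalone
repeat units are reported as motifs; `min_count` also gates final
scoring so rare incidental chunks are not motifs. Motif relative
prevalences are computed over the returned motif inventory and sum
to 1.

Branch points: each motif occurrence's immediately following syllable
(the first syllable of the next segment under greedy longest-match
segmentation) is tallied, bout terminations excluded. A motif whose
dominant continuation reaches the stereotypy threshold (default 0.95,
*inclusive*) is a stereotyped continuation; all others are branch
points, carrying their transition distribution, entropy, dominant
transition (ties broken lexicographically) and observation count. A
motif that is always bout-final is classified stereotyped-to-`<END>`
with a warning.

## Tutor–pupil comparison

**Repertoire.** With a shared label space (or an injective pupil→tutor
label map), syllable types partition into retained (both birds),
dropped (tutor only) and novel (pupil only); percentages are relative
to the tutor's and pupil's repertoire sizes respectively.

**Motifs.** A tutor motif's best pupil match maximizes the shared
fraction — the length of the longest common subsequence (LCS) divided
by the *tutor* motif length — with ties broken by pupil-motif
prevalence, then lexicographically; matching is one-to-one greedy by
shared fraction. Status is `matched` (identical), `modified` (shared
fraction ≥ 0.5, inclusive) or `dropped`. The tutor-denominator reading
of the retention rule was adopted; both the threshold and the
denominator are configurable.

**Edit scoring.** For a modified motif the LCS is the order-preserving
backbone (on ties the pupil side is advanced first, binding matches to
the earliest tutor syllables). Unmatched tutor syllables are deletions,
positioned by their slot in the tutor motif (first = beginning, last =
end, else middle); unmatched pupil syllables are additions, positioned
relative to the backbone (before the first match = beginning, after the
last = end, else middle). This is the only position convention
consistent with all the canonical worked cases (`abcd→rtbcd`,
`abcd→abcef`, `abcd→abq`, `abc→rabc`, `abcd→abd`). A shuffled pair
(e.g. `rtg` vs `etr`) scores as a paired addition + deletion. Both
counting conventions are provided: per syllable, and per instance
(a block of same-position additions in one motif counts once).

**Positional chance model.** Under the null that an edit lands on any
slot with equal probability, a motif of length L offers deletion slots
(1 beginning, L−2 middle, 1 end) and insertion slots (1, L−1, 1).
Slots are pooled over the tutor's motif-length multiset and normalized.
Expected counts are `n_edits × probs`, reported unrounded (presentation
rounding only in reports). Observed counts are tested with the
likelihood-ratio statistic `G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ)` (0·ln 0 ≡ 0) against
the chi-square upper tail with k−1 = 2 degrees of freedom. Note the
statistic is reported as computed; G-statistics quoted elsewhere for
the same printed observed/expected counts are not always reproducible
from those counts, and no attempt is made to match them.

**Branch points.** A tutor branch point is `dropped_sequence` if its
sequence motif was dropped; `dropped_stereotyped_in_pupil` if the
pupil follows the retained sequence with a ≥ 95% transition (recording
whether that transition is the tutor's dominant one — the
"regularization" case); otherwise `retained`, with transitions
partitioned into retained/dropped/novel and copying fidelity measured
by the total deviation in transition probability:
`100 × Σ_union |p_tutor − p_pupil|`, a scaled L1 distance ranging from
0% (perfect copy) to 200% (disjoint supports).

**Acoustic features.** Feature distributions are pooled across syllable
types within a bird (no classification step). Distances are univariate
Bhattacharyya per feature — Gaussian closed form
`D = ¼(μ₁−μ₂)²/(σ₁²+σ₂²) + ½ ln[(σ₁²+σ₂²)/(2σ₁σ₂)]` by default, with a
shared-range histogram variant (`method="histogram"`) for the mixture-
shaped pooled distributions, where the Gaussian summary loses most of
its discriminative power — plus the mean across features. The
representative token of a syllable type is the rendition nearest the
z-scored feature centroid (zero-variance features contribute z = 0;
ties go to the lowest index).

## The synthetic song model

The generator stands in for recorded song; its defaults are the study
conditions the analysis is validated under.

A **grammar** is a motif-level first-order Markov model: 3–6 motifs of
2–7 syllables (one repeat motif by default, geometric run length with
mean drawn from 2–5), a branch matrix over next motifs plus `<END>`,
per-label Gaussian feature models for five acoustic features (mean
frequency, duration, spectrotemporal entropy, amplitude entropy,
spectral entropy), and lognormal gap models with between-motif gaps
(median 60 ms) longer than within-motif gaps (median 10 ms). Branch
rows offer 2–4 successors (a permutation cycle keeps every motif
reachable); row draws are Dirichlet blended 20% with uniform so rare
transitions stay observable, and are redrawn until no
termination-excluded entry reaches `max_branch_prob` (default 0.95 —
every motif a branch point; configurable lower, or a
`stereotyped_fraction` of rows can be made ≥ 95% dominant). The
per-row termination probability is mean motif length divided by the
target bout length (default 55 syllables), giving geometrically
distributed bout lengths of realistic mean; a 200-syllable cap guards
against absorbing chains and ends bouts only at motif boundaries.
Observable branch transitions are the first syllables of successor
motifs; labels are unique across motifs in sampled tutors, so these
are identifiable.

**Pupil derivation.** Retention is logistic in log tutor prevalence,
centered per level: an element of prevalence q is kept with probability
sigmoid(intercept + slope·(ln q − mean ln q)), so the intercept sets
the overall retention rate (default 0.5 ≈ 62%, in the range observed
for repertoire and motif retention) and the slope (default 1.5) the
prevalence dependence. Motifs are retained first; retained rows then
keep each transition to a retained motif by the same rule (the
dominant one always survives, so no row empties), and kept rows are
resampled from a Dirichlet with concentration κ (default 60) times the
tutor probabilities — infinite κ copies exactly. Each retained
multi-syllable motif is edited with probability `edit_rate`
(default 0.6, matching the observed ~60% of retained motifs modified):
an addition (probability 0.54) at a position drawn from
`addition_position_bias` (default 0.55/0.10/0.35, the observed
beginning-heavy pattern) or a deletion at a uniform slot. Added labels
are novel with probability `novel_syllable_rate` (default 0.3),
otherwise borrowed from another retained motif — so pupil motifs can
share labels, as real modified motifs do. Length bounds are respected:
length-7 motifs only receive deletions, length-2 motifs only additions.
A subset of dropped motifs is replaced by novel motifs; novel
successors enter resampled rows with a small pseudo-weight (0.05·κ).
Retained labels inherit the tutor's feature model with mean drift of
`feature_jitter` (default 0.1) SD. The derivation returns a
ground-truth edit log recording the *injected* edits (so recovering
them with the edit scorer is an independent check), the
retained/dropped/novel sets at all levels, and the pupil's rows;
replaying the log onto the tutor reconstructs the pupil's structure
exactly. Parameter sets under which no motif survives raise a
degenerate-pupil error.

**What the generator does not emulate.** Human labelling noise and
rater disagreement; gradual developmental change (pupil song is
sampled from a crystallized grammar); acoustic waveforms; gap-duration
dependence of learning (gaps are sampled but do not influence the
derivation); higher-order sequence dependencies. Tests passing on this
model therefore demonstrate correctness of the statistics and the
internal consistency of the pipeline, not robustness to labelling
error in real recordings.

## Validation design and problem sizes

Tests validate estimators against independent oracles: brute-force
recounts for transition tables, explicit slot enumeration for the
chance model, hand-evaluated closed forms for entropy, the G statistic
and the Bhattacharyya distance, and generative ground truth for the
pipeline. Sizes were chosen so estimates are sharp while the full
suite runs in well under a minute per stochastic property:

- Estimator consistency and structure recovery use 500-bout corpora
  (~27,000 syllables, comparable to a generously sampled bird) over 50
  seeded grammars. Recovery grammars cap between-motif probabilities
  at 0.6 so the generative values sit clear of the 0.75 chaining
  threshold — with probabilities at the threshold itself, recovery is
  undefined by construction.
- G-test type-I calibration uses 10,000 vectorized multinomial draws
  at N = 29; the observed rejection rate is accepted within
  [0.04, 0.065], the slack of the chi-square approximation at small N.
- Learning-model recovery uses 100 replicates, each one tutor with
  three pupils pooled — mirroring a breeding study where several sons
  learn from one father, and the statistical pooling of pupils within
  tutor. Single-pupil replicates are dominated by whole-motif
  retention noise (a 3-motif bird yields 1–2 comparable transitions).
- Split-half reliability is anchored to a fixed, explicitly specified
  four-motif grammar containing a strongly dominant (91%) branch
  transition next to rare alternatives — the regime in which the
  estimate's reliability is informative. Sixty bouts match a typical
  recording session.

## Known limitations

- Motif discovery is threshold-based chaining, not probabilistic
  grammar induction; motifs that overlap on shared syllables with
  near-threshold stereotypy may chain or split depending on sampling.
- The branch-point unit is the discovered motif; a motif inventory
  that differs between tutor and pupil (e.g. due to chaining
  differences at default grammar settings) propagates into branch-point
  comparison as dropped/novel structure.
- The Gaussian Bhattacharyya distance summarizes pooled mixtures by
  their first two moments; use the histogram variant when distribution
  shape matters.
- Gap durations are carried through to the predictor table
  (`predictors.csv`) for external mixed-model fitting; the package
  deliberately does not fit mixed-effects models itself.
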