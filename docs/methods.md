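# Methods

This note documents the models and procedures implemented in `trpscan`, the
defaults that matter, what the synthetic generator does and does not
emulate, and the design choices taken where the design was genuinely open.

## Profile models and scoring

A profile is a linear sequence of match states with per-column emission
distributions over the 20 amino acids, flanked by insert and delete states.
Match columns are alignment columns with ≤50% gap occupancy.  Emissions use
a single background-mixture pseudocount,

    p(a) = (count(a) + w · bg(a)) / (n_observed + w),

with weight `w = 2.0` effective counts and a uniform background by default.
Dirichlet-mixture priors are deliberately avoided: the single-weight scheme
is closed-form and lets tests verify emissions by hand counting.
Transitions are counted from each row's observed match/insert/delete state
path and smoothed the same way (uniform 1/3 pseudo-distribution).

The reported score is the best **local Viterbi log-odds in bits**: the path
may enter and leave the model at any match state at zero cost, insert
emissions equal the background (inserted residues cost only their
transitions), and the envelope is the residue span of the optimal path.
Viterbi rather than forward scoring was chosen because it is deterministic,
sufficient for competitive ranking, and exactly checkable against
exhaustive path enumeration (the test suite does this for models of ≤3
columns).  Scores are therefore *not* comparable to HMMER forward bit
scores, and no glocal or posterior-decoding modes exist.

**E-values.**  Each model is calibrated by scoring `n ≥ 100` (default 200)
random background sequences (default length `max(100, 2L)`) and fitting a
Gumbel law by the method of moments: `λ = π/(sd·√6)`,
`μ = mean − γ_Euler/λ`.  Then `E(S) = N · exp(−λ(S − μ))` for a database of
`N` sequences, clipped below at 0.  For strong hits the exponential
underflows to exactly 0.0; the classifier therefore breaks E-value ties on
bit score.  Method of moments rather than maximum likelihood keeps the fit
closed-form and test-friendly; at the stringent thresholds used here
(1e-10 … 1e-25) the tail approximation is orders of magnitude away from any
decision boundary.

**Iterative search** starts from a single-sequence profile of the query,
scans the database, includes hits with `E` strictly below the inclusion
threshold (default 1e-20, default five iterations), realigns the included
sequences to the model via Viterbi traceback (match/delete columns only;
inserts are dropped) and rebuilds.  The query is always a member.

**Transmembrane seeds.**  Kyte–Doolittle hydropathy with window 19 and
threshold 1.6; runs of ≥6 consecutive qualifying windows form a helix, and
the seed region spans from the first helix start minus a flank to the last
helix end plus a flank, clipped to the sequence.  This hydropathy predictor
is a deliberately simple stand-in for dedicated TM-topology HMMs; it is
only used to cut seed regions, where helix boundaries a few residues off
are harmless.  The flank defaults to 20 residues, with 25 available as an
option (both conventions appear in practice for this analysis; they are
exposed, not reconciled).

## Subfamily detection

Agglomerative clustering from singletons under an encoding cost, per
cluster:

    cost(C) = Σ_match-columns −ln L(residues | pseudocounted column profile)
            + penalty_scale · (20−1) · L · ½ · ln |C|.

The cheapest merge (smallest Δ total cost; ties broken on the
lexicographically smallest label pair) is taken at every step until one
cluster remains, and the partition returned is the trajectory state with
minimum total cost.  This cost replaces Dirichlet-mixture MDL encodings
used by classical subfamily-detection tools with a closed-form statistic
that an exhaustive partition search can verify at small n (the tests do so
at n = 8).

`penalty_scale` defaults to 0.05.  At full strength the BIC-style penalty
dominates the pseudocounted likelihood at desk-scale cluster sizes and, in
particular, costs nothing for singleton clusters (ln 1 = 0), which makes
the all-singleton partition the trajectory optimum.  Down-weighted, the
likelihood term drives merging — near-identical sequences merge at negative
Δ, cross-subfamily merges cost sharply positive Δ at the default
divergences — and the penalty only breaks near-ties.  Clusters holding ≥5%
of sequences (`min_fraction = 0.05`) are "major" subfamilies; the 5%
default separates the six planted families from decoy dust in the synthetic
regime.

Each selected cluster becomes one calibrated profile; the pooled alignment
of *all* rows becomes the "unspecific" model, the analogue of a generic
ion-transport profile that matches every subfamily.

## Classification

Scanning emits a hit when `E < threshold` (strict) and model coverage
`cols_matched / consensus_length ≥ coverage_threshold`; coverage is
measured on the model, not the protein, so N-terminally truncated proteins
with an intact channel core still pass.  Two named threshold profiles
exist: `census` (`E < 1e-25`, coverage ≥ 0.80) and `genome` (`E < 1e-10`,
no coverage filter); both are exposed rather than reconciled because they
serve different scan types.  The verdict is the subfamily of the smallest
E-value (ties: larger bit score, then model name); a best hit to the
unspecific model yields "excluded", no hits "unclassified".  Benchmarking
reports per-family sensitivity (fraction of family-f records with verdict
f) and selectivity (fraction of verdict-f records truly f), macro-averaged;
families without records report absent metrics, not zero.

## Redundancy clustering

Pairwise identity is computed from a global alignment (match +1, mismatch
−1, gap open −10, gap extend −1; Biopython's `PairwiseAligner`):
`100 · matches / columns`, where columns inside a terminal gap run of
either sequence are excluded from the denominator (length-difference
tolerant).  The sequence pair is ordered canonically before aligning so
tie-broken alternative alignments cannot break symmetry.  Greedy
first-match clustering processes sequences in decreasing length (ties by
id); a sequence joins the first centroid with identity strictly above the
threshold (default 80%), else founds a cluster.  Every output is audited:
members > threshold to their centroid, centroid pairs ≤ threshold.  No
k-mer prefilter — input sizes here are desk-scale.

## Repeat annotation

Unit hits are extracted by repeated best-local-hit scanning: after each
hit, the interior of its envelope (minus a 10%-of-unit-length margin at
each edge) is masked and the scan repeats until the best score falls below
the per-unit threshold.  The default threshold is the 99th percentile of
the model's calibrated random-score Gumbel.  Candidates covering <80% of
the unit model never count — this, not post-hoc subtraction, encodes the
convention of always reporting the lower repeat number when a trailing
partial unit makes the count ambiguous by one.  Greedy tiling (decreasing
score, ≤10% overlap) finalises the accepted set; the 10% tolerance exists
because tandem units abut tightly and forbidding all overlap undercounts at
noisy boundaries.  Domain arrangements are token sequences (ANK…, CHANNEL)
compared by Levenshtein distance.  TRP-N-like verdicts with fewer than 27
accepted units are flagged as fragmented gene models; the flag is scoped to
that family only.

## Specificity analysis

Per-column conservation follows the 10-property physico-chemical table
(hydrophobic, polar, small, tiny, aliphatic, aromatic, positive, negative,
charged, proline): 11 for a gap-free single-residue column, otherwise the
count of properties whose status — possessed by all residues or by none —
is uniform.  A gap carries no properties, so it breaks every all-have
status but leaves none-have statuses checkable; all-gap columns score
absent.

The group-contrast statistic is `mR(c) = D_between(c) − D_within(c)` over
all sequence pairs, with gaps as a 21st symbol, so `mR ∈ [−1, 1]`.  This
all-pairs form replaces the nearest-neighbour weighting of the original
multi-Relief method: it is deterministic, equals exhaustive pair
enumeration (tested), and behaves identically in the two-group,
well-separated regime targeted here.  Significance comes from shuffling the
push/pull labels (default 1000 permutations, seeded):
`z = (mR_obs − mean_perm)/sd_perm`, one-sided, keeping sites with `z > 3`
strictly; zero-spread columns get no z and are never significant.  No
multiple-testing correction is applied — a deliberate match to the simple
z-filter this analysis style uses; the false-site rate under pure noise is
covered by a dedicated test.  Significant sites are then filtered to
completely disjunct ones (push and pull residue sets share nothing; gaps
participate as symbols).  Query rows are always excluded from the group
statistics; at each disjunct site a query votes push/pull/neither (gap ⇒
neither), and the overall call is push or pull only when every site agrees,
otherwise ambiguous — conservative by construction.

## Synthetic study conditions

The generator emulates the statistical regime of the real analysis: six
subfamilies (default 30 members each) derived from one 200-residue
ancestral channel core, subfamily consensuses at per-site substitution
divergence 0.7 from the ancestor, members at 0.05 from their consensus;
TRP-N-like members carry 28 tandem copies of a 33-residue ankyrin unit
(TRP-A-like: 8) mutated at 0.10 per site; 60 uniform-background decoys of
length 150–600.  The push/pull preset plants 17 completely disjunct columns
in a 300-column alignment of 8+8 group sequences and 4 query rows at 10%
background noise, with queries copying a pull residue at every planted
site.  Divergence defaults are set so the planted structure is clearly
recoverable (within-subfamily identity ≈ 90%, between-subfamily ≈ 10–30%);
no claim is made that they match the divergence statistics of real TRP
subfamilies.

The mutation model is substitution-only (uniform over the 19 alternatives),
with no indels inside the channel core, so planted alignments stay
column-addressable; indels enter only through the fragmentation operation,
which removes whole N-terminal units.  Passing tests therefore demonstrate
correctness of the algorithms under a clean, well-separated regime — they
do not demonstrate robustness to alignment error, compositional bias,
repeat-boundary frame shifts or the long-tailed divergence structure of
real superfamilies.

Problem sizes throughout (180-member superfamilies, 300-column alignments,
200-sequence clustering inputs, 1000 permutations) are the package's
desk-scale defaults; they keep every stage exact and auditable while
preserving the decision structure of the full-scale analysis.

## Numerical notes

- All coordinates are 1-based inclusive in memory and in reports; BED-like
  outputs and the disjunct-site JSON use 0-based (half-open) coordinates
  and say so in their headers.
- One top-level seed derives all stage seeds (fixed offsets, kept below
  2³¹); identical config + seed reproduces byte-identical artifacts.
- Merge ties in clustering and E-value ties in classification have
  deterministic, documented tie-breaks (lexicographic label pair; bit score
  then model name).
- Degenerate inputs fail loudly: empty alignments, all-gap columns,
  uncalibrated models, zero-variance calibration samples and ragged
  alignments raise typed errors naming the offender; "no TM region" is a
  None return, distinct from an error.
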