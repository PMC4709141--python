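# Methods

## The annotation problem

A heavy-chain B cell receptor (BCR) sequence is assembled by VDJ
recombination: one germline V, D, and J gene are chosen, their junctional
ends are trimmed by exonuclease deletion, and the trimmed segments are
joined with non-templated N-insertions at the V–D and D–J boundaries.  The
rearranged gene then accumulates point substitutions through somatic
hypermutation (SHM).  Annotation means reconstructing, for an observed
read, the origin of every base: which germline alleles were used, how much
was trimmed from each end, what the N-regions are, and hence what the naive
(unmutated ancestor) sequence was.

## Model

Each germline position of each allele is a hidden Markov model state that
emits its germline base with probability `1 − p` and each other base with
`p/3`, where `p` is the per-allele per-position mutation frequency.  The
model is deliberately non-parametric: instead of a parametric family (e.g.
negative binomial) for trimming lengths and a shared mutation process, every
allele carries its own categorical distribution per deletion type and its
own per-position `p`, all estimated from the data set being annotated.

* 5' deletions appear as the start-state transition (entry) distribution;
  3' deletions as transitions to the end state.  Entry probabilities equal
  the (tiered) 5'-deletion table restricted to feasible positions; exit
  probabilities are stored in hazard form — `P(exit after i | arrival)` =
  `P(del = n−1−i) / P(del ≤ n−1−i)` — which telescopes so the unconditional
  exit mass reproduces the table regardless of entry point.
* 5' V and 3' J "deletions" double as read-length truncation and are
  counted and modeled exactly like junctional deletions.
* N-regions are four insert states (nominal base A/C/G/T) attached to the
  left of every D and J model.  Insert emissions follow the same
  `1 − p̄` / `p̄/3` rule with `p̄` the overall mean mutation frequency, so
  the naive base of each N-position is inferred, and clonal reads can vote
  on it.  The insert block is entered with the empirical `P(length > 0)`;
  once inside, the self/cross transition probability is `1 − 1/m⁺` with
  `m⁺` the mean positive insertion length, giving a geometric length
  distribution whose conditional mean matches the data.  (A geometric is
  forced by the Markov property; empirical N-length distributions are close
  to geometric anyway.)
* Allele usage probabilities `q_g` are the observed allele frequencies,
  applied independently per segment.

## Factorization

Rather than one monolithic HMM over all alleles, inference runs per-allele
HMMs and combines them over the boundary partition `(l_V, l_D)` — the
number of read bases assigned to the V region and to the VD-insert + D
region:

    P(x) = Σ_{l_V, l_D} Π_{R ∈ {V,D,J}} Σ_{g ∈ R} q_g Σ_{π ∈ g} P_R(x, π)

This is exact (a path cannot cross between alleles), and the test suite
verifies forward and Viterbi agreement with an explicitly stitched
monolithic model to 1e-8 log units.  Implementation details: one forward
(or max) table per V allele yields `P_V` for every `l_V` simultaneously;
D tables are batched across all `l_V` start offsets as a single tensor
recursion; J scores for all start positions come from one backward (suffix)
pass per allele.  All dynamic programming is in log space with a stable
log-sum-exp.  Viterbi ties are broken toward the lexicographically smallest
state-name sequence, and allele ties by IMGT name order, so output is
deterministic.

A `k`-tuple of clonally related reads is annotated by the same machinery
with multi-emissions: one hidden path emits all `k` sequences, so the
per-column emission term is the product over reads.  `k = 1` reduces
exactly to the classical algorithms.  The ambiguity code N emits with
probability one everywhere.

## Smith–Waterman preprocessing

A local-alignment pass (biopython's `PairwiseAligner`; match +5, mismatch
−4, gap open −50, gap extend −2, all configurable) ranks candidate alleles,
produces a provisional annotation to seed parameter estimation, and bounds
the `(l_V, l_D)` search to the best boundaries ±5 (`kbound_fuzz`).  Local
alignments extend across junction bases through occasional mismatches, so
alignment ends are trimmed back to their running-score maximum under a
harsher mismatch penalty (10) before boundaries are read off; without this
the provisional insert lengths are biased short by about one base.  Reads
whose bounds admit no partition consistent with the deletion supports are
retried once with exhaustive bounds; only reads with no acceptable V or J
match at all are recorded as failures.  Alignment gaps are flagged as
candidate indel mutations (the HMM does not model indels); a flagged read
can be annotated with and without the reversed indel.

## Parameter estimation

Counts are tallied from annotations (unique sequences are the counting
unit), converted to normalized tables, and refined by Viterbi training:
Smith–Waterman provisional annotations seed the first parameter set, HMMs
built from it re-annotate the same reads, and the counts are re-estimated.
One refinement round is the default; the suite checks that a second round
moves the deletion tables by a weighted-mean total variation below 0.05.

Sparse alleles use tiered aggregation: if an allele has fewer than
`min_obs` (default 20) observations, counts are pooled over its allelic
variants, then its IMGT gene family, then the whole segment, stopping at
the narrowest tier that reaches `min_obs`.  Pooling is by summing counts
with per-position mutation tables aligned on germline index.  Unobserved
deletion lengths keep probability zero — categorical fidelity is the point
and tiering is the only sparsity remedy — but mutation probabilities are
clamped to `[1e-3, 0.5]` before use as emissions, since an exact 0 or 1
would make an emission degenerate.  N-region base content is estimated
globally per boundary.

Bootstrap uncertainties partition the unique sequences into ten disjoint
subsets, estimate parameters per subset, and report twice the across-subset
standard deviation: clonal expansion means unique sequences overstate the
number of independent rearrangements, and positing two-member clones halves
the effective sample size.

## Simulator

The simulator shares no inference code (the test suite asserts its module
imports neither the engine nor the annotator).  An event is drawn either
from an explicit joint categorical table over all rearrangement values —
which preserves every correlation between them — or from a parameter set
with tables treated as independent (infeasible deletion combinations are
rejected and redrawn).  The naive sequence is trimmed V + VD insert +
trimmed D + DJ insert + trimmed J, with insert bases drawn from the
empirical nucleotide distribution.

Each naive sequence diversifies down a birth–death lineage tree (dendropy;
speciation 1.0, extinction 0.5) conditioned on the leaf count, with branch
lengths rescaled so the root height equals a draw from a small discrete
height table.  Substitutions are Jukes–Cantor-style per position with
site-specific relative rates (per-position frequency normalized to mean one
within each segment) and per-segment rate scalings (V 0.98, D 1.8, J 0.87 —
D mutates fastest); N-regions mutate at the cross-segment average.  Per
branch of length `t`, a site with rate `r` changes with probability
`3/4 (1 − exp(−4/3 r t))`, the target uniform over the three other bases.
Scaling a segment's tree height is algebraically identical to scaling its
site rates, which is how it is implemented.  No indel SHM, no sequencing
error, and no unequal substitution-target preferences are simulated.

## Built-in study conditions

The default synthetic germline set is deterministic (fixed internal seed)
and scaled down relative to the real IGH locus so simulated reads are
~120–160 nt: 8 V alleles (~75 nt), 6 D (~16 nt), 3 J (~40 nt), with allelic
variants a few SNPs apart and a realistic family/gene/allele hierarchy.
The sequences are random — they carry no homology to real IMGT entries.
The companion "true" parameter set uses multi-modal categorical deletion
tables (support 0–6; 5' V and 3' J truncations 0–3), insertion lengths 0–10
with mean ≈ 4, and lognormal per-position rates (σ = 0.9, so the central
80% of positions span about an order of magnitude, as repertoire data
show).  The tree-height table is calibrated so reads average ≈ 5% mutated
positions — a typical human memory-compartment load — and the 2× multiplier
reproduces the harder "doubled mutation" benchmark (≈ 10%).

Standard benchmark sizes used by the tests and the acceptance script:
2,000 events × 5 leaves for parameter recovery, 1,000 × 5 at doubled
mutation for the k = 1 vs k = 5 comparison and the failure rate, 200
single-leaf events at zero mutation for the identity check.  These sizes
give per-allele observation counts in the 10²–10³ range, comparable per
allele to what the scaled-down locus supports.

## Known limitations

* Viterbi (MAP) annotation systematically absorbs N-region bases that
  chance-match the adjacent germline into the germline segment: a matching
  germline emission is free while an insert base costs `−log` base
  frequency plus the geometric length penalty, and only the categorical
  deletion priors push back.  Measured on the built-in conditions this
  shortens inferred inserts by ~0.2–0.4 bases on average even when
  annotating with the true parameters, inflates apparent mutation rates at
  the few germline positions adjacent to each junction, and at zero
  mutation leaves ~1/4 of events with a strictly more probable alternative
  annotation than the truth.  Summing over annotations (forward) rather
  than maximizing would remove the bias but is not what annotation reports.
* Per-position mutation profiles of the short, fast-mutating D segment are
  only weakly identified: reads whose D carries mutations are preferentially
  re-assigned (different boundaries or allele), censoring high-rate D
  positions downward.
* The geometric insert-length model cannot represent the multi-modality of
  true N-length distributions; it matches `P(0)` and the conditional mean
  only.
* Clonal families must be given; the package does not infer them.  Light
  chains, TCRs, palindromic N-additions, tandem D segments, and
  platform-specific sequencing error are out of scope.
* Passing tests on the synthetic conditions demonstrate correctness of the
  machinery and the qualitative claims (multi-sequence benefit, tiered
  robustness, zero failure rate); they do not certify accuracy numbers on
  real repertoires, whose germline sets are far larger and whose mutation
  process is context-dependent in ways per-position frequencies absorb only
  partially.
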