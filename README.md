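# vdjhmm

HMM-based annotation and simulation of B cell receptor (BCR) heavy-chain
VDJ rearrangements, with data-driven categorical parameter distributions
fitted on the fly.

## The problem

A heavy-chain BCR gene is assembled by VDJ recombination — a germline V, D,
and J gene are chosen, their junctional ends are trimmed by exonuclease
deletion, and the pieces are joined with non-templated N-insertions — and
then diversified by somatic hypermutation.  Annotating a repertoire read
means deciding, for every base, whether it came from a specific germline
allele (and which position of it) or from an N-region, despite mutation
blurring the junctions.  This package is for immunologists and method
developers who need per-read annotations (gene calls, deletion lengths,
N-regions, naive ancestor sequences) from large repertoire sequencing data
sets, plus a ground-truth simulator to validate them.

## The model

Every germline position of every allele is an HMM state emitting its
germline base with probability 1 − p and each other base with p/3, where p
is that allele's per-position mutation frequency.  Transitions encode the
rearrangement: entry distributions are 5'-deletion length tables, end-state
transitions are 3'-deletion tables, and four per-base insert states on the
left of each D and J model represent the N-regions.  All of these are
parameter-rich categorical distributions estimated from the data set being
annotated (seeded by Smith–Waterman, refined by Viterbi training), with
tiered aggregation — allele → allelic variants → IMGT gene family → whole
segment — standing in when an allele has fewer than N ≈ 20 observations.

Inference is factorized: for a read x of length L,

    P(x) = Σ_{l_V, l_D} Π_{R∈{V,D,J}} Σ_{g∈R} q_g Σ_{π∈g} P_R(x, π)

where (l_V, l_D) partitions the read into V, VD-insert + D, and DJ-insert +
J regions, q_g is allele usage, and the inner sums run over paths within a
single allele's small HMM — exactly equal to one monolithic HMM over all
alleles, but orders of magnitude fewer states per dynamic program.  Viterbi
(argmax) gives the maximum-likelihood annotation; the forward sum gives the
total probability of the read under the rearrangement model.  A clonal
family of k reads can be annotated jointly (a multi-HMM: one hidden path
emits all k sequences), which averages out private mutations — including
inside N-regions.

See `docs/methods.md` for the full model description and known limitations.

## Worked example

Simulate a truth-annotated sample from the built-in scaled-down germline
set, fit parameters, annotate, and score:

```python
from vdjhmm import (
    SimulatorConfig, annotate_batch, benchmark, simulate_sample,
    synthetic_germline_set, example_parameter_set, viterbi_train,
)

germline = synthetic_germline_set()
true_params = example_parameter_set(germline)
events, reads, truth = simulate_sample(
    true_params, germline,
    SimulatorConfig(n_events=100, leaves_per_event=5), rng=1,
)
params, _ = viterbi_train(reads, germline, rounds=1)
annotations, failures = annotate_batch(reads, germline, params)
print(f"{len(annotations)} reads annotated, {len(failures)} failures")
first = annotations[0]
print(f"{first.query_ids[0]}: V={first.v_allele} D={first.d_allele} "
      f"J={first.j_allele} vd={first.vd_insertion!r} dj={first.dj_insertion!r} "
      f"mutations={len(first.mutated_positions[0])}")
report = benchmark(annotations, truth)
print(report.summary().to_string(index=False))
```

Output:

```
500 reads annotated, 0 failures
ev0-L0: V=IGHV2-5*01 D=IGHD4-17*02 J=IGHJ4*01 vd='A' dj='CATAA' mutations=2
            metric  fraction     n  correct   ci_low  ci_high
         V_correct     1.000 500.0    500.0 0.994991 1.000000
         D_correct     0.972 500.0    486.0 0.954706 0.983864
         J_correct     1.000 500.0    500.0 0.994991 1.000000
    failed_correct     0.000 500.0      0.0 0.000000 0.005009
mean_naive_hamming     1.150   NaN      NaN      NaN      NaN
```

Reading this: every one of the 500 simulated reads was annotated; V and J
gene calls (allele ignored) are all correct, 97.2% of the short D calls are
correct, and the reconstructed naive (unmutated ancestor) sequences differ
from the truth by 1.15 bases on average — errors concentrate in the
junctions, where N-bases that happen to match adjacent germline are
genuinely ambiguous.  The `ci_*` columns are binomial 95% intervals under
the Jeffreys prior.  Passing `groupings=[list(t.query_ids) for t in truth]`
to `annotate_batch` switches to joint clonal-family (k = 5) annotation,
which roughly halves the mean naive Hamming distance.

## Command line

```
vdjhmm simulate --n-events 200 --n-leaves 5 --seed 1 --outdir sim/
vdjhmm cache-parameters --infname sim/reads.fasta --parameter-dir params/
vdjhmm annotate --infname sim/reads.fasta --parameter-dir params/ \
                --outfname annotations.csv
vdjhmm validate --annotations annotations.csv --truth sim/truth.csv \
                --report report.csv
```

`--germline-dir` points any subcommand at a directory of `ighv/ighd/ighj`
FASTA files with IMGT-style headers; without it the built-in synthetic set
is used.

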