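"""Benchmark metrics: annotation output versus simulated truth.

The headline number is the per-segment fraction of reads whose gene call is
correct regardless of allele, with binomial 95% confidence intervals under
the Jeffreys prior (equal-tailed Beta(s + 1/2, n - s + 1/2) quantiles).
Finer-grained comparisons use the Hamming distance between inferred and
true naive sequences and signed (inferred - true) differences for each
deletion length, each insertion length, and the per-read mutation
frequency.

Failed reads count in the denominator as incorrect for the gene-call
fractions; they are excluded from the Hamming/difference histograms and
reported separately as a failure fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import DELETION_TYPES, Annotation
from .germline import parse_allele_name

__all__ = [
    "BenchmarkReport",
    "jeffreys_interval",
    "gene_call_fractions",
    "naive_hamming",
    "parameter_diffs",
    "accuracy_vs_mutation",
    "benchmark",
]


def jeffreys_interval(successes: int, n: int, level: float = 0.95):
    """Equal-tailed binomial interval under the Jeffreys prior."""
    if n <= 0:
        raise ValueError("n must be positive")
    a, b = successes + 0.5, n - successes + 0.5
    # boundary convention: the interval always contains the point estimate
    lo = 0.0 if successes == 0 else stats.beta.ppf((1 - level) / 2, a, b)
    hi = 1.0 if successes == n else stats.beta.ppf(1 - (1 - level) / 2, a, b)
    return float(lo), float(hi)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def _gene(allele: str) -> str:
    return parse_allele_name(allele).gene


def _pair_by_read(
    annotations: list[Annotation], truth: list[Annotation]
) -> dict[str, tuple[Annotation, Annotation]]:
    """Map read id -> (inferred annotation, truth annotation)."""
    truth_by_id = {}
    for t in truth:
        for rid in t.query_ids:
            truth_by_id[rid] = t
    pairs = {}
    for a in annotations:
        for rid in a.query_ids:
            if rid not in truth_by_id:
                raise KeyError(f"no truth row for read {rid!r}")
            pairs[rid] = (a, truth_by_id[rid])
    return pairs


def _all_truth_ids(truth: list[Annotation]) -> list[str]:
    return [rid for t in truth for rid in t.query_ids]


def gene_call_fractions(
    annotations: list[Annotation], truth: list[Annotation]
) -> dict[str, dict]:
    """Per-segment correct-gene fraction, allele suffix ignored.

    The denominator is every read in the truth set, so reads with no
    annotation (failures) count as incorrect.
    """
    all_ids = _all_truth_ids(truth)
    n = len(all_ids)
    if n == 0:
        raise ValueError("empty truth set")
    pairs = _pair_by_read(annotations, truth)
    out = {}
    for segment, attr in (("V", "v_allele"), ("D", "d_allele"), ("J", "j_allele")):
        correct = sum(
            1
            for rid in all_ids
            if rid in pairs
            and _gene(getattr(pairs[rid][0], attr))
            == _gene(getattr(pairs[rid][1], attr))
        )
        lo, hi = jeffreys_interval(correct, n)
        out[segment] = {
            "fraction": correct / n,
            "n": n,
            "correct": correct,
            "ci_low": lo,
            "ci_high": hi,
        }
    failed = n - len(pairs)
    lo, hi = jeffreys_interval(failed, n)
    out["failed"] = {
        "fraction": failed / n, "n": n, "correct": failed,
        "ci_low": lo, "ci_high": hi,
    }
    return out


def naive_hamming(
    annotations: list[Annotation], truth: list[Annotation]
) -> pd.DataFrame:
    """Per-read Hamming distance between inferred and true naive sequences.

    Returns a tidy frame with both the raw distance and the
    length-normalized one.
    """
    pairs = _pair_by_read(annotations, truth)
    rows = []
    for rid, (inferred, true) in pairs.items():
        d = hamming(inferred.naive_seq, true.naive_seq)
        rows.append(
            {
                "read_id": rid,
                "hamming": d,
                "hamming_normalized": d / len(true.naive_seq),
            }
        )
    return pd.DataFrame(rows, columns=["read_id", "hamming", "hamming_normalized"])


def parameter_diffs(
    annotations: list[Annotation], truth: list[Annotation]
) -> pd.DataFrame:
    """Signed (inferred - true) differences per read.

    Lengths give integer differences; the per-read mutation frequency
    (Hamming(read, naive) / L, with each side's own naive) gives a real
    difference.
    """
    pairs = _pair_by_read(annotations, truth)
    rows = []
    for rid, (inf, true) in pairs.items():
        row = {"read_id": rid}
        for dtype in DELETION_TYPES:
            row[dtype] = inf.deletion(dtype) - true.deletion(dtype)
        row["vd_insert_len"] = len(inf.vd_insertion) - len(true.vd_insertion)
        row["dj_insert_len"] = len(inf.dj_insertion) - len(true.dj_insertion)
        i_inf = inf.query_ids.index(rid)
        i_true = true.query_ids.index(rid)
        row["mutation_freq"] = (
            inf.mutation_freqs()[i_inf] - true.mutation_freqs()[i_true]
        )
        rows.append(row)
    return pd.DataFrame(rows)


def accuracy_vs_mutation(
    annotations: list[Annotation],
    truth: list[Annotation],
    bins: np.ndarray | list[float],
) -> pd.DataFrame:
    """Correct-gene fractions binned by true per-read mutation frequency.

    Empty bins are reported as absent (dropped), not as zero.
    """
    bins = np.asarray(bins, dtype=float)
    pairs = _pair_by_read(annotations, truth)
    all_ids = _all_truth_ids(truth)
    truth_by_id = {rid: t for t in truth for rid in t.query_ids}
    freqs = {
        rid: truth_by_id[rid].mutation_freqs()[
            truth_by_id[rid].query_ids.index(rid)
        ]
        for rid in all_ids
    }
    rows = []
    for b in range(len(bins) - 1):
        lo, hi = bins[b], bins[b + 1]
        last = b == len(bins) - 2
        ids = [
            rid
            for rid in all_ids
            if lo <= freqs[rid] < hi or (last and freqs[rid] == hi)
        ]
        if not ids:
            continue
        for segment, attr in (
            ("V", "v_allele"), ("D", "d_allele"), ("J", "j_allele")
        ):
            correct = sum(
                1
                for rid in ids
                if rid in pairs
                and _gene(getattr(pairs[rid][0], attr))
                == _gene(getattr(pairs[rid][1], attr))
            )
            ci_lo, ci_hi = jeffreys_interval(correct, len(ids))
            rows.append(
                {
                    "bin_low": lo,
                    "bin_high": hi,
                    "segment": segment,
                    "fraction": correct / len(ids),
                    "n": len(ids),
                    "ci_low": ci_lo,
                    "ci_high": ci_hi,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BenchmarkReport:
    """Everything the benchmark computes, plus the raw per-read table."""

    gene_fractions: dict
    hamming: pd.DataFrame
    diffs: pd.DataFrame
    by_mutation: pd.DataFrame
    failure_fraction: float
    per_read: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> pd.DataFrame:
        rows = []
        for segment, stats_ in self.gene_fractions.items():
            rows.append({"metric": f"{segment}_correct", **stats_})
        rows.append(
            {"metric": "mean_naive_hamming",
             "fraction": float(self.hamming["hamming"].mean())
             if len(self.hamming) else float("nan")}
        )
        return pd.DataFrame(rows)


def benchmark(
    annotations: list[Annotation],
    truth: list[Annotation],
    mutation_bins: list[float] | None = None,
) -> BenchmarkReport:
    fractions = gene_call_fractions(annotations, truth)
    ham = naive_hamming(annotations, truth)
    diffs = parameter_diffs(annotations, truth)
    if mutation_bins is None:
        mutation_bins = [0.0, 0.05, 0.1, 0.15, 0.2, 0.3, 1.0]
    by_mut = accuracy_vs_mutation(annotations, truth, mutation_bins)
    pairs = _pair_by_read(annotations, truth)
    per_read_rows = []
    for t in truth:
        for rid in t.query_ids:
            inf = pairs.get(rid, (None, None))[0]
            per_read_rows.append(
                {
                    "read_id": rid,
                    "failed": inf is None,
                    "true_v": t.v_allele,
                    "true_d": t.d_allele,
                    "true_j": t.j_allele,
                    "called_v": inf.v_allele if inf else "",
                    "called_d": inf.d_allele if inf else "",
                    "called_j": inf.j_allele if inf else "",
                }
            )
    return BenchmarkReport(
        gene_fractions=fractions,
        hamming=ham,
        diffs=diffs,
        by_mutation=by_mut,
        failure_fraction=fractions["failed"]["fraction"],
        per_read=pd.DataFrame(per_read_rows),
    )
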