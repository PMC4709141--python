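"""Non-parametric model parameters estimated on the fly from annotations.

The model is deliberately parameter-rich: every allele gets its own
categorical distribution for each exonuclease-deletion length, its own
per-position mutation frequency, and its own usage probability q_g; the two
N-region boundaries get empirical length and nucleotide-content tables.
Nothing is assumed unimodal or shared across alleles a priori.

Sparse alleles are handled by tiered aggregation: if an allele is seen fewer
than ``min_obs`` times, counts are pooled over its allelic variants (same
gene), then over its IMGT gene family, then over the whole segment, stopping
at the narrowest tier that reaches ``min_obs`` observations.

Estimation is seeded from Smith-Waterman provisional annotations and refined
by Viterbi training: build HMMs from the current parameters, re-annotate the
same reads, re-count.  One refinement round is the default; more change
little.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import DELETION_TYPES, Annotation, germline_position_map
from .germline import GermlineSet, parse_allele_name

__all__ = [
    "CountTables",
    "ParameterSet",
    "TIERS",
    "MUTATION_P_MIN",
    "MUTATION_P_MAX",
    "count_events",
    "tiered_counts",
    "build_parameter_set",
    "viterbi_train",
    "bootstrap_uncertainty",
]

TIERS = ("allele", "gene", "family", "segment")
BOUNDARIES = ("vd", "dj")

# emission clamps: an exact 0 or 1 mutation probability would make the
# corresponding emission degenerate
MUTATION_P_MIN = 1e-3
MUTATION_P_MAX = 0.5

_SEGMENT_DTYPES = {
    "V": ("v_5p", "v_3p"),
    "D": ("d_5p", "d_3p"),
    "J": ("j_5p", "j_3p"),
}


@dataclass
class CountTables:
    """Raw event tallies, the sufficient statistics for the model."""

    allele_counts: Counter = field(default_factory=Counter)
    # (allele, deletion type) -> length -> count
    deletions: dict = field(default_factory=lambda: defaultdict(Counter))
    # boundary -> insertion length -> count
    insertion_lengths: dict = field(default_factory=lambda: defaultdict(Counter))
    # boundary -> nucleotide -> count
    insertion_bases: dict = field(default_factory=lambda: defaultdict(Counter))
    # allele -> germline position -> [mutated, total]
    mutation: dict = field(
        default_factory=lambda: defaultdict(lambda: defaultdict(lambda: [0, 0]))
    )

    def n_annotations(self) -> int:
        return sum(self.allele_counts[a] for a in self.allele_counts) // 3


def count_events(
    annotations: list[Annotation], germline: GermlineSet
) -> CountTables:
    """Tally every annotation once into the count tables.

    Mutated/total per germline position are tallied only at positions
    actually covered by the read(s); each of an annotation's k reads
    contributes one observation per covered position.
    """
    tables = CountTables()
    for ann in annotations:
        for allele in (ann.v_allele, ann.d_allele, ann.j_allele):
            if allele not in germline:
                raise KeyError(f"annotation references unknown allele {allele!r}")
        tables.allele_counts[ann.v_allele] += 1
        tables.allele_counts[ann.d_allele] += 1
        tables.allele_counts[ann.j_allele] += 1
        for dtype in DELETION_TYPES:
            allele = {
                "v": ann.v_allele, "d": ann.d_allele, "j": ann.j_allele
            }[dtype[0]]
            tables.deletions[(allele, dtype)][ann.deletion(dtype)] += 1
        for boundary, ins in (("vd", ann.vd_insertion), ("dj", ann.dj_insertion)):
            tables.insertion_lengths[boundary][len(ins)] += 1
            for base in ins:
                tables.insertion_bases[boundary][base] += 1
        mutated_sets = [set(m) for m in ann.mutated_positions]
        pos_map = germline_position_map(ann, germline)
        for segment, allele in (
            ("V", ann.v_allele), ("D", ann.d_allele), ("J", ann.j_allele)
        ):
            mut_table = tables.mutation[allele]
            for read_pos, germ_pos in pos_map[segment]:
                cell = mut_table[germ_pos]
                cell[1] += len(mutated_sets)
                cell[0] += sum(read_pos in s for s in mutated_sets)
    return tables


@dataclass
class AggregatedCounts:
    """Counts pooled over one tier's member alleles."""

    n_obs: int
    members: list[str]
    deletions: dict  # dtype -> Counter
    mutation: dict  # germline position -> (mutated, total)


def _tier_members(germline: GermlineSet, allele: str, tier: str) -> list[str]:
    name = parse_allele_name(allele)
    out = []
    for other in germline.segment_alleles(name.segment):
        o = parse_allele_name(other)
        if tier == "allele" and other != allele:
            continue
        if tier == "gene" and o.gene != name.gene:
            continue
        if tier == "family" and o.family != name.family:
            continue
        out.append(other)
    return out


def tiered_counts(
    counts: CountTables,
    germline: GermlineSet,
    allele: str,
    min_obs: int = 20,
) -> tuple[AggregatedCounts, str]:
    """Pool counts at the narrowest tier reaching ``min_obs`` observations.

    Tiers widen from the allele itself, to all alleles of its gene, to its
    IMGT family, to the whole segment (which always exists as a fallback).
    Per-position mutation counts are aligned by germline position index.
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    segment = parse_allele_name(allele).segment
    chosen = None
    for tier in TIERS:
        members = _tier_members(germline, allele, tier)
        n_obs = sum(counts.allele_counts.get(m, 0) for m in members)
        chosen = (tier, members, n_obs)
        if n_obs >= min_obs:
            break
    tier, members, n_obs = chosen
    deletions: dict[str, Counter] = {
        dtype: Counter() for dtype in _SEGMENT_DTYPES[segment]
    }
    mutation: dict[int, tuple[int, int]] = defaultdict(lambda: (0, 0))
    for member in members:
        for dtype in _SEGMENT_DTYPES[segment]:
            deletions[dtype].update(counts.deletions.get((member, dtype), {}))
        for pos, (mut, tot) in counts.mutation.get(member, {}).items():
            m0, t0 = mutation[pos]
            mutation[pos] = (m0 + mut, t0 + tot)
    return AggregatedCounts(n_obs, members, deletions, dict(mutation)), tier


@dataclass
class ParameterSet:
    """Everything needed to build the per-allele HMMs and the simulator."""

    # segment -> allele -> usage probability (sums to 1 per segment)
    q_g: dict[str, dict[str, float]]
    # (allele, dtype) -> length -> probability
    deletion_dists: dict
    # boundary -> length -> probability (categorical; used by the simulator)
    insertion_length_dists: dict
    # boundary -> mean length (drives the geometric insert states)
    insertion_mean_len: dict
    # boundary -> base -> probability
    insertion_base_freqs: dict
    # allele -> germline position -> mutation probability (clamped)
    mutation_freq: dict
    overall_mutation_mean: float
    # (allele, "deletions"|"mutation") -> tier used
    tiers: dict = field(default_factory=dict)

    def mutation_p(self, allele: str, pos: int) -> float:
        return self.mutation_freq.get(allele, {}).get(
            pos, _clamp(self.overall_mutation_mean)
        )

    def validate(self) -> None:
        for segment, table in self.q_g.items():
            tot = sum(table.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"q_g for segment {segment} sums to {tot}")
        for key, dist in self.deletion_dists.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"deletion dist {key} sums to {tot}")
        for boundary in BOUNDARIES:
            for table in (
                self.insertion_length_dists[boundary],
                self.insertion_base_freqs[boundary],
            ):
                tot = sum(table.values())
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(f"{boundary} insertion table sums to {tot}")
        for allele, per_pos in self.mutation_freq.items():
            for pos, p in per_pos.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"mutation p={p} at ({allele}, {pos})")

    # -- serialization: a directory of CSV tables, one per distribution family

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {"segment": seg, "allele": a, "prob": p}
                for seg, table in self.q_g.items()
                for a, p in sorted(table.items())
            ]
        ).to_csv(out_dir / "allele_usage.csv", index=False)
        pd.DataFrame(
            [
                {"allele": a, "deletion_type": dt, "length": l, "prob": p}
                for (a, dt), dist in sorted(self.deletion_dists.items())
                for l, p in sorted(dist.items())
            ]
        ).to_csv(out_dir / "deletion_lengths.csv", index=False)
        pd.DataFrame(
            [
                {"boundary": b, "length": l, "prob": p}
                for b, dist in sorted(self.insertion_length_dists.items())
                for l, p in sorted(dist.items())
            ]
        ).to_csv(out_dir / "insertion_lengths.csv", index=False)
        pd.DataFrame(
            [
                {"boundary": b, "base": base, "prob": p}
                for b, freqs in sorted(self.insertion_base_freqs.items())
                for base, p in sorted(freqs.items())
            ]
        ).to_csv(out_dir / "insertion_bases.csv", index=False)
        pd.DataFrame(
            [
                {"allele": a, "position": pos, "prob": p}
                for a, per_pos in sorted(self.mutation_freq.items())
                for pos, p in sorted(per_pos.items())
            ]
        ).to_csv(out_dir / "mutation_freqs.csv", index=False)
        meta = {
            "overall_mutation_mean": self.overall_mutation_mean,
            "insertion_mean_len": self.insertion_mean_len,
            "tiers": {f"{a}|{kind}": t for (a, kind), t in self.tiers.items()},
        }
        (out_dir / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ParameterSet":
        in_dir = Path(in_dir)
        q_g: dict[str, dict[str, float]] = defaultdict(dict)
        for row in pd.read_csv(in_dir / "allele_usage.csv").itertuples():
            q_g[row.segment][row.allele] = float(row.prob)
        deletion_dists: dict = defaultdict(dict)
        for row in pd.read_csv(in_dir / "deletion_lengths.csv").itertuples():
            deletion_dists[(row.allele, row.deletion_type)][int(row.length)] = float(
                row.prob
            )
        ins_len: dict = defaultdict(dict)
        for row in pd.read_csv(in_dir / "insertion_lengths.csv").itertuples():
            ins_len[row.boundary][int(row.length)] = float(row.prob)
        ins_base: dict = defaultdict(dict)
        for row in pd.read_csv(in_dir / "insertion_bases.csv").itertuples():
            ins_base[row.boundary][row.base] = float(row.prob)
        mutation: dict = defaultdict(dict)
        for row in pd.read_csv(in_dir / "mutation_freqs.csv").itertuples():
            mutation[row.allele][int(row.position)] = float(row.prob)
        meta = json.loads((in_dir / "meta.json").read_text())
        tiers = {}
        for key, tier in meta["tiers"].items():
            allele, kind = key.split("|")
            tiers[(allele, kind)] = tier
        return cls(
            q_g=dict(q_g),
            deletion_dists=dict(deletion_dists),
            insertion_length_dists=dict(ins_len),
            insertion_mean_len={
                k: float(v) for k, v in meta["insertion_mean_len"].items()
            },
            insertion_base_freqs=dict(ins_base),
            mutation_freq=dict(mutation),
            overall_mutation_mean=float(meta["overall_mutation_mean"]),
            tiers=tiers,
        )


def _clamp(p: float) -> float:
    return min(MUTATION_P_MAX, max(MUTATION_P_MIN, p))


def _normalize(counter) -> dict:
    total = sum(counter.values())
    return {k: v / total for k, v in sorted(counter.items())}


def build_parameter_set(
    counts: CountTables,
    germline: GermlineSet,
    min_obs: int = 20,
) -> ParameterSet:
    """Turn count tables into normalized model parameters.

    Deletion lengths never observed (after tiering) keep probability zero:
    categorical fidelity is the point, and tiering is the only sparsity
    remedy.  Mutation probabilities are clamped to
    [``MUTATION_P_MIN``, ``MUTATION_P_MAX``] before use as emissions.
    N-region base content is estimated globally per boundary.
    """
    q_g: dict[str, dict[str, float]] = {}
    for segment in ("V", "D", "J"):
        alleles = germline.segment_alleles(segment)
        total = sum(counts.allele_counts.get(a, 0) for a in alleles)
        if total == 0:
            raise ValueError(f"no observations for segment {segment}")
        q_g[segment] = {
            a: counts.allele_counts.get(a, 0) / total for a in alleles
        }

    mut_tot = sum(
        mut for table in counts.mutation.values() for mut, _ in table.values()
    )
    cov_tot = sum(
        tot for table in counts.mutation.values() for _, tot in table.values()
    )
    overall_mean = mut_tot / cov_tot if cov_tot else 0.0

    deletion_dists: dict = {}
    mutation_freq: dict = {}
    tiers: dict = {}
    for segment in ("V", "D", "J"):
        for allele in germline.segment_alleles(segment):
            agg, tier = tiered_counts(counts, germline, allele, min_obs)
            tiers[(allele, "deletions")] = tier
            tiers[(allele, "mutation")] = tier
            for dtype in _SEGMENT_DTYPES[segment]:
                counter = agg.deletions[dtype]
                if not counter:
                    counter = Counter({0: 1})
                deletion_dists[(allele, dtype)] = _normalize(counter)
            per_pos = {}
            for pos in range(len(germline.seq(allele))):
                mut, tot = agg.mutation.get(pos, (0, 0))
                per_pos[pos] = _clamp(mut / tot if tot else overall_mean)
            mutation_freq[allele] = per_pos

    insertion_length_dists = {}
    insertion_mean_len = {}
    insertion_base_freqs = {}
    for boundary in BOUNDARIES:
        lengths = counts.insertion_lengths.get(boundary, Counter())
        if not lengths:
            lengths = Counter({0: 1})
        insertion_length_dists[boundary] = _normalize(lengths)
        n = sum(lengths.values())
        insertion_mean_len[boundary] = (
            sum(l * c for l, c in lengths.items()) / n
        )
        bases = counts.insertion_bases.get(boundary, Counter())
        if not bases:
            bases = Counter({b: 1 for b in "ACGT"})
        insertion_base_freqs[boundary] = _normalize(bases)

    params = ParameterSet(
        q_g=q_g,
        deletion_dists=deletion_dists,
        insertion_length_dists=insertion_length_dists,
        insertion_mean_len=insertion_mean_len,
        insertion_base_freqs=insertion_base_freqs,
        mutation_freq=mutation_freq,
        overall_mutation_mean=overall_mean,
        tiers=tiers,
    )
    params.validate()
    return params


def viterbi_train(
    reads: list[tuple[str, str]],
    germline: GermlineSet,
    rounds: int = 1,
    min_obs: int = 20,
    sw_config=None,
    annotator_config=None,
) -> tuple[ParameterSet, list[list[Annotation]]]:
    """Smith-Waterman seeding followed by ``rounds`` of Viterbi training.

    Round 0 estimates parameters from SW provisional annotations; each
    subsequent round builds HMMs from the current parameters, re-annotates
    every read by Viterbi, and re-estimates.  Returns the final parameters
    and the per-round annotation sets (round 0 first).  Reads are
    deduplicated by sequence before counting, so unique sequences are the
    counting unit.
    """
    from .annotator import AnnotatorConfig, annotate_batch  # avoid import cycle
    from .sw import AnnotationFailure, SWConfig, sw_match

    if not reads:
        raise ValueError("empty read set")
    sw_config = sw_config or SWConfig()
    unique: dict[str, str] = {}
    for rid, seq in reads:
        unique.setdefault(seq, rid)
    unique_reads = [(rid, seq) for seq, rid in unique.items()]

    sw_results = {}
    provisional = []
    for rid, seq in unique_reads:
        try:
            sw = sw_match(seq, germline, sw_config, query_id=rid)
        except AnnotationFailure:
            continue
        sw_results[rid] = sw
        provisional.append(sw.provisional)
    if not provisional:
        raise ValueError("Smith-Waterman failed for every read")

    per_round = [provisional]
    params = build_parameter_set(
        count_events(provisional, germline), germline, min_obs
    )
    annotator_config = annotator_config or AnnotatorConfig()
    for _ in range(rounds):
        ok_reads = [(rid, seq) for rid, seq in unique_reads if rid in sw_results]
        annotations, failures = annotate_batch(
            ok_reads,
            germline,
            params,
            config=annotator_config,
            sw_cache=sw_results,
        )
        per_round.append(annotations)
        params = build_parameter_set(
            count_events(annotations, germline), germline, min_obs
        )
    return params, per_round


def _flatten(params: ParameterSet) -> dict:
    flat = {}
    for segment, table in params.q_g.items():
        for allele, p in table.items():
            flat[("q", allele)] = p
    for (allele, dtype), dist in params.deletion_dists.items():
        for length, p in dist.items():
            flat[("del", allele, dtype, length)] = p
    for boundary in BOUNDARIES:
        flat[("ins_mean", boundary)] = params.insertion_mean_len[boundary]
        for base, p in params.insertion_base_freqs[boundary].items():
            flat[("ins_base", boundary, base)] = p
    for allele, per_pos in params.mutation_freq.items():
        for pos, p in per_pos.items():
            flat[("mut", allele, pos)] = p
    return flat


def bootstrap_uncertainty(
    reads: list[tuple[str, str]],
    germline: GermlineSet,
    n_subsets: int = 10,
    rounds: int = 1,
    min_obs: int = 20,
) -> dict:
    """Across-subset parameter means and conservative uncertainties.

    Unique sequences are split round-robin into ``n_subsets`` disjoint
    subsets and parameters are estimated independently on each.  The
    reported uncertainty is twice the across-subset sample standard
    deviation: clonal expansion means unique sequences overstate the number
    of independent rearrangement events, and positing two-member clones
    halves the effective sample size.
    """
    if len(reads) < n_subsets:
        raise ValueError(
            f"{len(reads)} reads cannot fill {n_subsets} subsets"
        )
    subsets: list[list[tuple[str, str]]] = [[] for _ in range(n_subsets)]
    for i, read in enumerate(reads):
        subsets[i % n_subsets].append(read)
    flats = []
    for subset in subsets:
        params, _ = viterbi_train(subset, germline, rounds=rounds, min_obs=min_obs)
        flats.append(_flatten(params))
    keys = set()
    for flat in flats:
        keys.update(flat)
    out = {}
    for key in keys:
        values = np.array([flat.get(key, 0.0) for flat in flats])
        std = values.std(ddof=1) if len(values) > 1 else 0.0
        out[key] = (float(values.mean()), float(2.0 * std))
    return out
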