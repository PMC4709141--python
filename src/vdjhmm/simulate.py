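"""HMM-independent simulator of BCR rearrangement and hypermutation.

Ground-truth generator for validating the annotator.  A rearrangement event
is drawn either from an explicit joint categorical distribution over all
"rearrangement values" (allele choices, deletion lengths, insertion lengths
— sampling from the joint table implicitly preserves every correlation
between them), or from a :class:`~vdjhmm.parameters.ParameterSet` with the
tables treated as independent.  The naive sequence is the trimmed V +
sampled VD insert + trimmed D + sampled DJ insert + trimmed J.

Each naive sequence then diversifies down a birth-death lineage tree
(speciation 1.0, extinction 0.5, conditioned on the leaf count, branch
lengths rescaled to a height drawn from an empirical table).  Substitutions
are simulated per position with empirical relative rates, the tree height
scaled per segment (e.g. D mutates ~1.8x the overall rate, V ~0.98x,
J ~0.87x); N-regions mutate at the cross-segment average rate.  Substitution
targets are uniform over the three alternative bases; no indels, no
sequencing error.

None of this shares inference code with the annotator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .annotation import Annotation
from .germline import GermlineAllele, GermlineSet
from .parameters import ParameterSet

__all__ = [
    "RearrangementEvent",
    "JointRearrangementDistribution",
    "RearrangementValues",
    "SimulatorConfig",
    "sample_event",
    "sample_tree",
    "mutate_down_tree",
    "simulate_sample",
    "synthetic_germline_set",
    "example_parameter_set",
    "DEFAULT_SEGMENT_SCALINGS",
    "DEFAULT_TREE_HEIGHTS",
]

_BASES = "ACGT"

#: illustrative per-segment mutation-rate scalings (relative to the overall
#: rate); D mutates fastest, J slowest
DEFAULT_SEGMENT_SCALINGS = {"V": 0.98, "D": 1.8, "J": 0.87}

#: small discrete stand-in for an empirical tree-height table (root heights
#: in expected substitutions per site).  Calibrated so that leaf reads carry
#: about 5% mutated positions on average (mean leaf depth is roughly half
#: the root height in these birth-death trees), i.e. a typical human
#: memory-compartment mutation load; a 2x multiplier gives the ~10%
#: "doubled mutation" benchmark condition.
DEFAULT_TREE_HEIGHTS = {0.05: 0.3, 0.10: 0.35, 0.15: 0.25, 0.30: 0.1}


@dataclass(frozen=True)
class RearrangementValues:
    """One point in rearrangement space (insertion lengths, not contents)."""

    v_allele: str
    d_allele: str
    j_allele: str
    v_5p_del: int
    v_3p_del: int
    d_5p_del: int
    d_3p_del: int
    j_5p_del: int
    j_3p_del: int
    vd_insert_len: int
    dj_insert_len: int


@dataclass
class JointRearrangementDistribution:
    """Explicit joint categorical distribution over rearrangement values."""

    entries: list[tuple[RearrangementValues, float]]

    def validate(self, germline: GermlineSet) -> None:
        total = sum(p for _, p in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"joint probabilities sum to {total}, not 1")
        for values, _ in self.entries:
            _check_feasible(values, germline)

    def sample(self, rng: np.random.Generator) -> RearrangementValues:
        probs = np.array([p for _, p in self.entries])
        idx = rng.choice(len(self.entries), p=probs / probs.sum())
        return self.entries[idx][0]


def _check_feasible(v: RearrangementValues, germline: GermlineSet) -> None:
    for allele, d5, d3 in (
        (v.v_allele, v.v_5p_del, v.v_3p_del),
        (v.d_allele, v.d_5p_del, v.d_3p_del),
        (v.j_allele, v.j_5p_del, v.j_3p_del),
    ):
        if d5 < 0 or d3 < 0 or d5 + d3 > len(germline.seq(allele)) - 1:
            raise ValueError(
                f"infeasible deletions ({d5}, {d3}) for allele {allele}"
            )


@dataclass
class RearrangementEvent:
    """Simulator ground truth: the event, its tree, and the leaf reads."""

    values: RearrangementValues
    vd_insertion: str
    dj_insertion: str
    naive_seq: str
    tree: dendropy.Tree | None = None
    leaf_sequences: dict[str, str] = field(default_factory=dict)

    def region_slices(self, germline: GermlineSet) -> dict[str, slice]:
        v = self.values
        lv = len(germline.seq(v.v_allele)) - v.v_5p_del - v.v_3p_del
        ld = len(germline.seq(v.d_allele)) - v.d_5p_del - v.d_3p_del
        lj = len(germline.seq(v.j_allele)) - v.j_5p_del - v.j_3p_del
        out, start = {}, 0
        for name, length in (
            ("v", lv), ("vd", len(self.vd_insertion)), ("d", ld),
            ("dj", len(self.dj_insertion)), ("j", lj),
        ):
            out[name] = slice(start, start + length)
            start += length
        return out

    def to_annotation(self, query_ids: tuple[str, ...]) -> Annotation:
        """Truth row in the annotation column format."""
        v = self.values
        mutated = tuple(
            tuple(
                i
                for i, (a, b) in enumerate(
                    zip(self.leaf_sequences[q], self.naive_seq)
                )
                if a != b
            )
            for q in query_ids
        )
        return Annotation(
            query_ids=query_ids,
            v_allele=v.v_allele,
            d_allele=v.d_allele,
            j_allele=v.j_allele,
            v_5p_del=v.v_5p_del,
            v_3p_del=v.v_3p_del,
            d_5p_del=v.d_5p_del,
            d_3p_del=v.d_3p_del,
            j_5p_del=v.j_5p_del,
            j_3p_del=v.j_3p_del,
            vd_insertion=self.vd_insertion,
            dj_insertion=self.dj_insertion,
            naive_seq=self.naive_seq,
            mutated_positions=mutated,
        )


def _sample_categorical(table: dict, rng: np.random.Generator):
    keys = sorted(table)
    probs = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _sample_values_from_params(
    params: ParameterSet, germline: GermlineSet, rng: np.random.Generator
) -> RearrangementValues:
    """Independent draws from the per-table marginals (fixture path when no
    explicit joint table is supplied); infeasible deletion combinations are
    rejected and redrawn."""
    alleles = {}
    for segment in ("V", "D", "J"):
        alleles[segment] = _sample_categorical(params.q_g[segment], rng)
    dels = {}
    for segment, (d5, d3) in (
        ("V", ("v_5p", "v_3p")),
        ("D", ("d_5p", "d_3p")),
        ("J", ("j_5p", "j_3p")),
    ):
        allele = alleles[segment]
        n = len(germline.seq(allele))
        for _ in range(1000):
            a = _sample_categorical(params.deletion_dists[(allele, d5)], rng)
            b = _sample_categorical(params.deletion_dists[(allele, d3)], rng)
            if a + b <= n - 1:
                break
        else:
            raise ValueError(f"cannot draw feasible deletions for {allele}")
        dels[d5], dels[d3] = a, b
    return RearrangementValues(
        alleles["V"], alleles["D"], alleles["J"],
        dels["v_5p"], dels["v_3p"], dels["d_5p"], dels["d_3p"],
        dels["j_5p"], dels["j_3p"],
        _sample_categorical(params.insertion_length_dists["vd"], rng),
        _sample_categorical(params.insertion_length_dists["dj"], rng),
    )


def _sample_insert(
    length: int, base_freqs: dict, rng: np.random.Generator
) -> str:
    bases = sorted(base_freqs)
    probs = np.array([base_freqs[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    return "".join(bases[i] for i in rng.choice(len(bases), size=length, p=probs))


def sample_event(
    joint: JointRearrangementDistribution | ParameterSet,
    germline: GermlineSet,
    rng: np.random.Generator,
) -> RearrangementEvent:
    """Draw one rearrangement event and build its naive sequence."""
    if isinstance(joint, JointRearrangementDistribution):
        values = joint.sample(rng)
        base_freqs = {"vd": dict.fromkeys(_BASES, 0.25),
                      "dj": dict.fromkeys(_BASES, 0.25)}
    else:
        values = _sample_values_from_params(joint, germline, rng)
        base_freqs = joint.insertion_base_freqs
    vd = _sample_insert(values.vd_insert_len, base_freqs["vd"], rng)
    dj = _sample_insert(values.dj_insert_len, base_freqs["dj"], rng)
    v = germline.seq(values.v_allele)
    d = germline.seq(values.d_allele)
    j = germline.seq(values.j_allele)
    naive = (
        v[values.v_5p_del : len(v) - values.v_3p_del]
        + vd
        + d[values.d_5p_del : len(d) - values.d_3p_del]
        + dj
        + j[values.j_5p_del : len(j) - values.j_3p_del]
    )
    return RearrangementEvent(values, vd, dj, naive)


def sample_tree(
    n_leaves: int, height: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Birth-death lineage tree (speciation 1.0, extinction 0.5) conditioned
    on the leaf count, with branch lengths rescaled to the requested root
    height (in expected substitutions per site)."""
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if height < 0:
        raise ValueError("height must be >= 0")
    if n_leaves == 1:
        tree = dendropy.Tree()
        leaf = dendropy.Node(edge_length=height)
        tree.seed_node.add_child(leaf)
        leaf.taxon = tree.taxon_namespace.new_taxon(label="L0")
        return tree
    import random as _random

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.5,
        num_extant_tips=n_leaves,
        rng=_random.Random(int(rng.integers(2**31))),
    )
    realized = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    scale = height / realized
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"L{i}"
    return tree


def _site_rates(
    event: RearrangementEvent,
    germline: GermlineSet,
    params: ParameterSet,
    segment_scalings: dict[str, float],
) -> np.ndarray:
    """Relative substitution rate per naive position.

    Within each segment, per-position rates are the empirical mutation
    frequencies normalized to mean one, times the segment's scaling;
    N-regions use the average of the three segment scalings.
    """
    v = event.values
    slices = event.region_slices(germline)
    rates = np.zeros(len(event.naive_seq))
    n_avg = float(np.mean([segment_scalings[s] for s in "VDJ"]))
    for segment, region, allele, d5 in (
        ("V", "v", v.v_allele, v.v_5p_del),
        ("D", "d", v.d_allele, v.d_5p_del),
        ("J", "j", v.j_allele, v.j_5p_del),
    ):
        sl = slices[region]
        per_pos = np.array(
            [
                params.mutation_freq.get(allele, {}).get(
                    d5 + i, params.overall_mutation_mean
                )
                for i in range(sl.stop - sl.start)
            ]
        )
        mean = per_pos.mean()
        rel = per_pos / mean if mean > 0 else np.zeros_like(per_pos)
        rates[sl] = rel * segment_scalings[segment]
    for region in ("vd", "dj"):
        rates[slices[region]] = n_avg
    return rates


def mutate_down_tree(
    event: RearrangementEvent,
    tree: dendropy.Tree,
    germline: GermlineSet,
    params: ParameterSet,
    rng: np.random.Generator,
    segment_scalings: dict[str, float] | None = None,
) -> dict[str, str]:
    """Simulate substitutions down the tree; fills and returns the leaf
    sequences.

    Each branch applies, per position, a Jukes-Cantor-style substitution
    with site-specific rate: P(change) = 3/4 (1 - exp(-4/3 r t)), targets
    uniform among the three alternative bases.  Branch lengths are in
    expected substitutions per site at relative rate one.
    """
    segment_scalings = segment_scalings or DEFAULT_SEGMENT_SCALINGS
    rates = _site_rates(event, germline, params, segment_scalings)
    base_idx = np.frombuffer(event.naive_seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    root_state = lut[base_idx].astype(np.int8)
    leaf_seqs: dict[str, str] = {}
    seqs = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent = seqs[id(node.parent_node)]
        p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rates * t))
        hit = rng.random(len(parent)) < p_change
        child = parent.copy()
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            child[hit] = (child[hit] + shift) % 4
        seqs[id(node)] = child
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"L{len(leaf_seqs)}"
            leaf_seqs[label] = "".join(_BASES[i] for i in child)
    event.leaf_sequences = leaf_seqs
    return leaf_seqs


@dataclass
class SimulatorConfig:
    n_events: int = 100
    leaves_per_event: int = 5
    mutation_multiplier: float = 1.0  # scales sampled tree heights
    tree_heights: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_TREE_HEIGHTS)
    )
    segment_scalings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_SCALINGS)
    )


def simulate_sample(
    source: JointRearrangementDistribution | ParameterSet,
    germline: GermlineSet,
    config: SimulatorConfig,
    rng: np.random.Generator | int,
) -> tuple[list[RearrangementEvent], list[tuple[str, str]], list[Annotation]]:
    """Simulate a full truth-annotated sample.

    Returns the events, the reads as (id, sequence) pairs with ids
    ``ev{e}-L{l}`` encoding event membership, and the truth annotations (one
    per event, covering its leaves).  Deterministic given the seed.
    """
    if config.n_events < 1:
        raise ValueError("n_events must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    events, reads, truth = [], [], []
    for e in range(config.n_events):
        event = sample_event(source, germline, rng)
        height = float(_sample_categorical(config.tree_heights, rng))
        height *= config.mutation_multiplier
        tree = sample_tree(config.leaves_per_event, height, rng)
        leaves = mutate_down_tree(
            event, tree, germline, params=_params_for_rates(source),
            rng=rng, segment_scalings=config.segment_scalings,
        )
        event.tree = tree
        ids = tuple(f"ev{e}-{label}" for label in sorted(leaves))
        event.leaf_sequences = {
            f"ev{e}-{label}": seq for label, seq in leaves.items()
        }
        events.append(event)
        for rid in ids:
            reads.append((rid, event.leaf_sequences[rid]))
        truth.append(event.to_annotation(ids))
    return events, reads, truth


def _params_for_rates(source) -> ParameterSet:
    if isinstance(source, ParameterSet):
        return source
    # explicit joint tables carry no mutation profile: flat rates
    return ParameterSet(
        q_g={}, deletion_dists={}, insertion_length_dists={},
        insertion_mean_len={}, insertion_base_freqs={},
        mutation_freq={}, overall_mutation_mean=1.0,
    )


# ---------------------------------------------------------------------------
# Built-in study conditions: a scaled-down synthetic germline set and a
# matching parameter set, both fixed (internal constant seeds) so that they
# define reproducible simulation conditions independent of the user's seed.


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def synthetic_germline_set() -> GermlineSet:
    """Deterministic synthetic germline set with the IMGT name hierarchy.

    Gene lengths are scaled down relative to real IGH genes (V ~75, D ~16,
    J ~40 nt) to keep simulated reads short; allelic variants differ by a
    few point substitutions, as real alleles do.  Sequences are random and
    carry no biological homology to real IMGT entries.
    """
    rng = np.random.default_rng(20160111)
    alleles: dict[str, GermlineAllele] = {}

    def add(name: str, segment: str, seq: str, **kw) -> None:
        alleles[name] = GermlineAllele(name, segment, seq, **kw)

    def variants(seq: str, n_snps: int) -> str:
        s = list(seq)
        for pos in rng.choice(len(s), size=n_snps, replace=False):
            s[pos] = _BASES[(lut_idx(s[pos]) + int(rng.integers(1, 4))) % 4]
        return "".join(s)

    def lut_idx(b: str) -> int:
        return _BASES.index(b)

    v_genes = ["IGHV1-2", "IGHV1-18", "IGHV2-5", "IGHV3-23", "IGHV3-33"]
    for gene in v_genes:
        length = int(rng.integers(72, 79))
        base = _random_seq(rng, length)
        add(f"{gene}*01", "V", base, cyst_position=length - 12)
        if gene in ("IGHV1-2", "IGHV3-23", "IGHV3-33"):
            add(f"{gene}*02", "V", variants(base, 3), cyst_position=length - 12)
    d_genes = ["IGHD2-2", "IGHD3-10", "IGHD3-22", "IGHD4-17"]
    for gene in d_genes:
        length = int(rng.integers(14, 19))
        base = _random_seq(rng, length)
        add(f"{gene}*01", "D", base)
        if gene in ("IGHD3-10", "IGHD4-17"):
            add(f"{gene}*02", "D", variants(base, 2))
    for gene, length in (("IGHJ4", 38), ("IGHJ6", 45)):
        base = _random_seq(rng, length)
        add(f"{gene}*01", "J", base, tryp_position=10)
        if gene == "IGHJ4":
            add(f"{gene}*02", "J", variants(base, 2), tryp_position=10)
    return GermlineSet(alleles)


def _categorical_shape(
    rng: np.random.Generator, support: int, modes: int = 2
) -> dict[int, float]:
    """A lumpy categorical distribution over 0..support-1 (mixture of
    geometric-ish bumps), mimicking the multi-modal empirical shapes."""
    weights = np.zeros(support)
    for _ in range(modes):
        center = int(rng.integers(0, support))
        width = 0.5 + 2.0 * rng.random()
        weights += rng.random() * np.exp(
            -((np.arange(support) - center) ** 2) / (2 * width**2)
        )
    weights += 0.02
    weights /= weights.sum()
    return {i: float(w) for i, w in enumerate(weights)}


def example_parameter_set(germline: GermlineSet | None = None) -> ParameterSet:
    """Deterministic 'true' parameters used as simulation study conditions.

    Per-allele deletion tables are multi-modal categoricals over 0..6 (5' V
    and 3' J truncations over 0..3, emulating read-length variation);
    insertion lengths over 0..10 with mean ~4; per-position mutation
    frequencies (used by the simulator as relative rates) are drawn
    lognormal around a few percent, giving the order-of-magnitude
    position-to-position spread seen in repertoire data.
    """
    germline = germline or synthetic_germline_set()
    rng = np.random.default_rng(20160112)
    q_g: dict[str, dict[str, float]] = {}
    for segment in ("V", "D", "J"):
        names = germline.segment_alleles(segment)
        w = rng.dirichlet(np.full(len(names), 2.0))
        q_g[segment] = {n: float(p) for n, p in zip(names, w)}

    deletion_dists: dict = {}
    mutation_freq: dict = {}
    for segment, (d5, d3) in (
        ("V", ("v_5p", "v_3p")),
        ("D", ("d_5p", "d_3p")),
        ("J", ("j_5p", "j_3p")),
    ):
        for allele in germline.segment_alleles(segment):
            n = len(germline.seq(allele))
            if segment == "V":
                deletion_dists[(allele, d5)] = _categorical_shape(rng, 4, 1)
                deletion_dists[(allele, d3)] = _categorical_shape(rng, 7)
            elif segment == "J":
                deletion_dists[(allele, d5)] = _categorical_shape(rng, 7)
                deletion_dists[(allele, d3)] = _categorical_shape(rng, 4, 1)
            else:
                support = min(6, (n - 1) // 2)
                deletion_dists[(allele, d5)] = _categorical_shape(rng, support)
                deletion_dists[(allele, d3)] = _categorical_shape(rng, support)
            # lognormal sigma 0.9: the central 80% of positions span about
            # an order of magnitude in rate, as seen in repertoire data
            raw = np.exp(rng.normal(np.log(0.05), 0.9, size=n))
            mutation_freq[allele] = {
                i: float(min(0.4, r)) for i, r in enumerate(raw)
            }

    insertion_length_dists = {}
    insertion_mean_len = {}
    insertion_base_freqs = {}
    for boundary in ("vd", "dj"):
        weights = rng.random(11) * np.exp(-((np.arange(11) - 4.0) ** 2) / 8.0)
        weights[0] += 0.05
        weights /= weights.sum()
        dist = {i: float(w) for i, w in enumerate(weights)}
        insertion_length_dists[boundary] = dist
        insertion_mean_len[boundary] = sum(l * p for l, p in dist.items())
        freqs = rng.dirichlet(np.array([4.0, 3.0, 4.0, 3.0]))
        insertion_base_freqs[boundary] = {
            b: float(p) for b, p in zip(_BASES, freqs)
        }

    params = ParameterSet(
        q_g=q_g,
        deletion_dists=deletion_dists,
        insertion_length_dists=insertion_length_dists,
        insertion_mean_len=insertion_mean_len,
        insertion_base_freqs=insertion_base_freqs,
        mutation_freq=mutation_freq,
        overall_mutation_mean=0.05,
    )
    params.validate()
    return params
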