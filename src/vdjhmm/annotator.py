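"""Factorized per-allele VDJ HMMs and annotation inference.

Instead of one monolithic HMM holding every germline allele, each allele
gets its own small HMM (one state per germline position; D and J models
carry four N-insert states on their left).  For a read of length L the
total probability factorizes over the boundary partition (l_V, l_D) —
the number of read bases assigned to the V region and to the
VD-insert-plus-D region — as

    P(x) = sum_{l_V, l_D}  prod_{R in V,D,J}  sum_{g in R} q_g
                                              sum_{paths in g} P_R(x, path)

which returns exactly the same value as the monolithic HMM while running
dynamic programs only within single alleles.  Viterbi replaces the sums
over partitions, alleles, and paths with maximizations.

Multi-sequence (multi-HMM) annotation runs the same machinery on a k-tuple
of clonally related reads emitted along one shared hidden path, which lets
shared and private mutations be distinguished — including inside N-regions,
thanks to the four per-base insert states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import hmm
from .annotation import Annotation, naive_sequence
from .germline import GermlineAllele, GermlineSet
from .hmm import END, EmissionTuple, HMMModel, HMMState
from .parameters import ParameterSet, _clamp
from .sw import AnnotationFailure, KBounds, SWAnnotation, SWConfig, sw_match

__all__ = [
    "AlleleHMM",
    "AnnotatorConfig",
    "build_allele_hmm",
    "annotate",
    "annotate_batch",
    "annotation_log_prob",
    "merge_sw",
]

_BASES = "ACGT"
_NEG_INF = float("-inf")


@dataclass
class AlleleHMM:
    """One allele's HMM plus the bookkeeping to read paths back out.

    Germline states are named ``g{i}`` for germline position ``i``; entry
    probabilities encode 5' deletions and (conditional) exit probabilities
    encode 3' deletions.  D and J models carry insert states ``iA``..``iT``
    on the left whose nominal base spells the naive N-region.
    """

    allele: str
    segment: str
    model: HMMModel
    insert_boundary: str | None  # "vd" for D models, "dj" for J models
    gene_length: int


def _mutation_emissions(base: str, p: float) -> dict[str, float]:
    """Germline-style emissions: 1-p for the nominal base, p/3 for the rest."""
    return {b: (1.0 - p) if b == base else p / 3.0 for b in _BASES}


def _entry_distribution(dist_5p: dict[int, float], n: int) -> dict[int, float]:
    """5'-deletion table -> P(first germline state is position i), i < n."""
    feasible = {i: p for i, p in dist_5p.items() if 0 <= i < n and p > 0}
    if not feasible:
        return {0: 1.0}
    total = sum(feasible.values())
    return {i: p / total for i, p in feasible.items()}


def _exit_hazards(dist_3p: dict[int, float], n: int) -> list[float]:
    """Conditional END-transition probability after each germline position.

    The hazard at position i is P(3' deletion = n-1-i) / P(deletion <=
    n-1-i), which telescopes so that the unconditional exit mass reproduces
    the deletion table for any entry position.
    """
    hazards = []
    for i in range(n):
        d = n - 1 - i
        p_exit = dist_3p.get(d, 0.0)
        tail = sum(p for length, p in dist_3p.items() if 0 <= length <= d)
        hazards.append(p_exit / tail if tail > 0 else 0.0)
    hazards[-1] = 1.0  # last state can only exit (unreachable if P(del=0)=0)
    return hazards


def build_allele_hmm(
    allele: GermlineAllele, params: ParameterSet
) -> AlleleHMM:
    """Assemble the per-allele HMM from the (tiered) parameter tables."""
    seq = allele.sequence
    n = len(seq)
    name = allele.name
    segment = allele.segment
    d5, d3 = {
        "V": ("v_5p", "v_3p"),
        "D": ("d_5p", "d_3p"),
        "J": ("j_5p", "j_3p"),
    }[segment]
    entry = _entry_distribution(params.deletion_dists[(name, d5)], n)
    hazards = _exit_hazards(params.deletion_dists[(name, d3)], n)

    states: list[HMMState] = []
    boundary = {"V": None, "D": "vd", "J": "dj"}[segment]
    init: dict[str, float] = {}
    if boundary is not None:
        length_dist = params.insertion_length_dists[boundary]
        p_ins = sum(p for l, p in length_dist.items() if l > 0)
        pos_mass = {l: p for l, p in length_dist.items() if l > 0}
        if pos_mass:
            tot = sum(pos_mass.values())
            mean_pos = sum(l * p for l, p in pos_mass.items()) / tot
        else:
            mean_pos = 1.0
        # enter the insert block with the empirical P(length > 0); once
        # inside, stay with 1 - 1/m+ so the conditional geometric mean
        # matches the mean positive insertion length
        stay = max(0.0, 1.0 - 1.0 / mean_pos)
        base_freqs = params.insertion_base_freqs[boundary]
        p_bar = _clamp(params.overall_mutation_mean)
        for b in _BASES:
            trans: dict[str, float] = {}
            for b2 in _BASES:
                w = stay * base_freqs.get(b2, 0.0)
                if w > 0:
                    trans[f"i{b2}"] = w
            for i, p in entry.items():
                w = (1.0 - stay) * p
                if w > 0:
                    trans[f"g{i}"] = w
            states.append(
                HMMState(f"i{b}", _mutation_emissions(b, p_bar), trans)
            )
            w = p_ins * base_freqs.get(b, 0.0)
            if w > 0:
                init[f"i{b}"] = w
        for i, p in entry.items():
            w = (1.0 - p_ins) * p
            if w > 0:
                init[f"g{i}"] = w
    else:
        init = {f"g{i}": p for i, p in entry.items()}

    for i in range(n):
        p = params.mutation_p(name, i)
        trans = {}
        c = hazards[i]
        if c > 0:
            trans[END] = c
        if i + 1 < n and c < 1.0:
            trans[f"g{i + 1}"] = 1.0 - c
        elif c < 1.0:
            # no successor and no full exit mass: force exit to keep the
            # row stochastic (state is unreachable in this situation)
            trans = {END: 1.0}
        states.append(HMMState(f"g{i}", _mutation_emissions(seq[i], p), trans))

    model = HMMModel(name, list(_BASES), states, init)
    model.validate()
    return AlleleHMM(name, segment, model, boundary, n)


@dataclass
class AnnotatorConfig:
    mode: str = "viterbi"  # "viterbi" | "forward" | "both"
    exhaustive_kbounds: bool = False
    extra_fuzz: int = 0  # widen SW kbounds further
    sw: SWConfig = field(default_factory=SWConfig)


class _ModelCache:
    def __init__(self, germline: GermlineSet, params: ParameterSet):
        self.germline = germline
        self.params = params
        self._models: dict[str, AlleleHMM] = {}

    def get(self, allele: str) -> AlleleHMM:
        if allele not in self._models:
            self._models[allele] = build_allele_hmm(
                self.germline[allele], self.params
            )
        return self._models[allele]


def merge_sw(sws: list[SWAnnotation]) -> tuple[dict, KBounds]:
    """Combine per-read SW results for a clonal family: candidate union
    (best score per allele) and the envelope of the boundary bounds."""
    cands: dict[str, dict[str, int]] = {"V": {}, "D": {}, "J": {}}
    for sw in sws:
        for segment, scored in sw.candidates.items():
            for allele, score in scored:
                prev = cands[segment].get(allele)
                if prev is None or score > prev:
                    cands[segment][allele] = score
    ranked = {
        segment: sorted(table.items(), key=lambda t: (-t[1], t[0]))
        for segment, table in cands.items()
    }
    kb = KBounds(
        min(sw.kbounds.v_min for sw in sws),
        max(sw.kbounds.v_max for sw in sws),
        min(sw.kbounds.d_min for sw in sws),
        max(sw.kbounds.d_max for sw in sws),
    )
    return ranked, kb


def _segment_candidates(
    candidates: dict, params: ParameterSet, segment: str
) -> list[str]:
    """Candidate alleles with nonzero usage probability, IMGT-name order
    (name order also breaks Viterbi ties between alleles)."""
    q = params.q_g[segment]
    names = [a for a, _ in candidates.get(segment, [])]
    return sorted(a for a in names if q.get(a, 0.0) > 0.0)


def _logsumexp_pair(a: float, b: float) -> float:
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    m = max(a, b)
    return m + math.log(math.exp(a - m) + math.exp(b - m))


def annotate(
    reads: list[tuple[str, str]],
    germline: GermlineSet,
    params: ParameterSet,
    sw: SWAnnotation | list[SWAnnotation] | None = None,
    mode: str | None = None,
    config: AnnotatorConfig | None = None,
    _cache: _ModelCache | None = None,
) -> Annotation:
    """Annotate one read, or one clonal family of k reads, by factorized HMM.

    ``sw`` supplies candidate alleles and boundary bounds (one result per
    read; they are merged for k > 1).  If omitted, Smith-Waterman runs here.
    With ``config.exhaustive_kbounds`` every allele is a candidate and every
    feasible (l_V, l_D) partition is enumerated.
    """
    config = config or AnnotatorConfig()
    mode = mode or config.mode
    if mode not in ("viterbi", "forward", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = tuple(rid for rid, _ in reads)
    obs = EmissionTuple(tuple(seq for _, seq in reads))
    L = len(obs)
    cache = _cache or _ModelCache(germline, params)

    if config.exhaustive_kbounds:
        kb = KBounds.exhaustive(L)
        candidates = {
            seg: [(a, 0) for a in germline.segment_alleles(seg)]
            for seg in ("V", "D", "J")
        }
    else:
        if sw is None:
            sw = [
                sw_match(seq, germline, config.sw, query_id=rid)
                for rid, seq in reads
            ]
        elif isinstance(sw, SWAnnotation):
            sw = [sw]
        candidates, kb = merge_sw(sw)
        if config.extra_fuzz:
            kb = kb.widen(config.extra_fuzz, L)

    v_cands = _segment_candidates(candidates, params, "V")
    d_cands = _segment_candidates(candidates, params, "D")
    j_cands = _segment_candidates(candidates, params, "J")
    if not (v_cands and d_cands and j_cands):
        raise AnnotationFailure(
            ":".join(ids), "no candidate alleles with nonzero usage"
        )

    want_fwd = mode in ("forward", "both")
    want_vit = mode in ("viterbi", "both")
    v_lo, v_hi = kb.v_min, min(kb.v_max, L - 2)
    d_lo, d_hi = kb.d_min, min(kb.d_max, L - 2)
    if v_lo > v_hi or d_lo > d_hi:
        raise AnnotationFailure(":".join(ids), "boundary bounds admit no partition")
    log_q = {
        seg: {a: math.log(p) for a, p in params.q_g[seg].items() if p > 0}
        for seg in ("V", "D", "J")
    }

    # --- per-segment scores -------------------------------------------------
    # V: one DP table per allele over the read prefix gives P_V for every l_V
    n_v = v_hi - v_lo + 1
    fwd_V = np.full(n_v, _NEG_INF)
    vit_V = np.full(n_v, _NEG_INF)
    vit_V_allele: list[str | None] = [None] * n_v
    for allele in v_cands:
        am = cache.get(allele)
        c = am.model.compiled()
        lq = log_q["V"][allele]
        E = c.emission_matrix(obs.window(0, v_hi))
        if want_fwd:
            ends = _end_scores(
                _run_table(c, E, sum_mode=True), c.log_end, sum_mode=True
            )
            for idx, l_v in enumerate(range(v_lo, v_hi + 1)):
                fwd_V[idx] = _logsumexp_pair(fwd_V[idx], lq + ends[l_v - 1])
        if want_vit:
            ends = _end_scores(
                _run_table(c, E, sum_mode=False), c.log_end, sum_mode=False
            )
            for idx, l_v in enumerate(range(v_lo, v_hi + 1)):
                score = lq + ends[l_v - 1]
                if score > vit_V[idx]:
                    vit_V[idx] = score
                    vit_V_allele[idx] = allele

    # D: all l_V starts run simultaneously as one batched DP per allele,
    # covering every l_D end in one pass
    n_d = d_hi - d_lo + 1
    d_starts = list(range(v_lo, v_hi + 1))
    d_stops = [min(s + d_hi, L - 1) for s in d_starts]
    fwd_D = np.full((n_v, n_d), _NEG_INF)
    vit_D = np.full((n_v, n_d), _NEG_INF)
    vit_D_allele = np.full((n_v, n_d), -1, dtype=int)
    for ai, allele in enumerate(d_cands):
        am = cache.get(allele)
        c = am.model.compiled()
        lq = log_q["D"][allele]
        E_full = c.emission_matrix(obs)
        for sum_mode in ([True] if want_fwd else []) + (
            [False] if want_vit else []
        ):
            ends = _batched_run(
                c, E_full, d_starts, d_stops, sum_mode=sum_mode,
                per_column=True,
            )
            for vi, l_v in enumerate(d_starts):
                cols = np.arange(l_v + d_lo - 1, d_stops[vi])
                if len(cols) == 0:
                    continue
                scores = lq + ends[vi, cols]
                sel = slice(0, len(cols))
                if sum_mode:
                    fwd_D[vi, sel] = np.logaddexp(fwd_D[vi, sel], scores)
                else:
                    better = scores > vit_D[vi, sel]
                    vit_D[vi, sel][better] = scores[better]
                    row = vit_D_allele[vi, sel]
                    row[better] = ai
                    vit_D_allele[vi, sel] = row

    # J: all start positions (start = l_V + l_D) batched per allele
    j_starts = sorted(
        {
            l_v + l_d
            for l_v in range(v_lo, v_hi + 1)
            for l_d in range(d_lo, d_hi + 1)
            if l_v + l_d <= L - 1
        }
    )
    j_index = {s: i for i, s in enumerate(j_starts)}
    fwd_J = np.full(len(j_starts), _NEG_INF)
    vit_J = np.full(len(j_starts), _NEG_INF)
    vit_J_allele = np.full(len(j_starts), -1, dtype=int)
    for ai, allele in enumerate(j_cands):
        am = cache.get(allele)
        c = am.model.compiled()
        lq = log_q["J"][allele]
        E_full = c.emission_matrix(obs)
        if want_fwd:
            finals = _suffix_run(c, E_full, j_starts, sum_mode=True)
            fwd_J = np.logaddexp(fwd_J, lq + finals)
        if want_vit:
            finals = _suffix_run(c, E_full, j_starts, sum_mode=False)
            scores = lq + finals
            better = scores > vit_J
            vit_J[better] = scores[better]
            vit_J_allele[better] = ai

    # --- combine over the boundary partition --------------------------------
    forward_total = _NEG_INF
    best = None  # (score, l_v, l_d)
    for vi, l_v in enumerate(range(v_lo, v_hi + 1)):
        for di, l_d in enumerate(range(d_lo, d_hi + 1)):
            s = l_v + l_d
            if s > L - 1:
                continue
            ji = j_index[s]
            if want_fwd:
                tot = fwd_V[vi] + fwd_D[vi, di] + fwd_J[ji]
                forward_total = _logsumexp_pair(forward_total, tot)
            if want_vit:
                tot = vit_V[vi] + vit_D[vi, di] + vit_J[ji]
                if np.isfinite(tot) and (best is None or tot > best[0]):
                    best = (tot, l_v, l_d)

    if want_vit:
        if best is None:
            raise AnnotationFailure(
                ":".join(ids), "no valid path for any candidate partition"
            )
        vit_total, l_v, l_d = float(best[0]), best[1], best[2]
        vi, di = l_v - v_lo, l_d - d_lo
        v_allele = vit_V_allele[vi]
        d_allele = d_cands[vit_D_allele[vi, di]]
        j_allele = j_cands[vit_J_allele[j_index[l_v + l_d]]]
        ann = _backtrace(
            ids, obs, germline, cache, l_v, l_d,
            v_allele, d_allele, j_allele, vit_total,
        )
    else:
        if forward_total == _NEG_INF:
            raise AnnotationFailure(
                ":".join(ids), "zero forward probability for all partitions"
            )
        prov = sw[0].provisional if sw else None
        if prov is None:
            raise AnnotationFailure(
                ":".join(ids), "forward-only mode needs a SW provisional event"
            )
        ann = replace(prov, query_ids=ids)
    if want_fwd:
        ann.forward_log_prob = forward_total
    return ann


def _end_scores(table: np.ndarray, log_end: np.ndarray, sum_mode: bool):
    """Per prefix length: combine DP column with the END transition."""
    M = table + log_end[None, :]
    if sum_mode:
        mx = M.max(axis=1)
        out = np.full(len(M), _NEG_INF)
        ok = np.isfinite(mx)
        if ok.any():
            out[ok] = mx[ok] + np.log(
                np.exp(M[ok] - mx[ok][:, None]).sum(axis=1)
            )
        return out
    return M.max(axis=1)


def _lse_rows(M: np.ndarray) -> np.ndarray:
    """Log-sum-exp over the last axis, -inf-safe."""
    mx = M.max(axis=-1)
    safe = np.where(np.isfinite(mx), mx, 0.0)
    with np.errstate(divide="ignore"):
        return safe + np.log(
            np.exp(M - safe[..., None]).sum(axis=-1)
        )


def _batched_run(
    c,
    E_full: np.ndarray,
    starts: list[int],
    stops: list[int],
    sum_mode: bool,
    per_column: bool,
):
    """Run the DP for many start offsets simultaneously.

    Row ``b`` models a chain started (with the model's initial transitions)
    at read column ``starts[b]``.  With ``per_column`` the returned array
    has shape (B, max(stops)) holding, for every global column ``i``, the
    score of ending (via the END transition) a window that spans
    ``[starts[b], i]``; otherwise a length-B vector of end scores at column
    ``stops[b] - 1`` (all stops must then be equal).
    """
    B = len(starts)
    smin, smax = min(starts), max(stops)
    T = np.full((B, E_full.shape[1]), _NEG_INF)
    starts_arr = np.asarray(starts)
    ends = np.full((B, smax), _NEG_INF) if per_column else None
    for i in range(smin, smax):
        if i > smin:
            # M[b, s, r] = T[b, r] + a(r -> s); reduce over predecessors r
            M = T[:, None, :] + c.log_trans.T[None, :, :]
            T = (_lse_rows(M) if sum_mode else M.max(axis=-1)) + E_full[i]
        init_mask = starts_arr == i
        if init_mask.any():
            T[init_mask] = c.log_init + E_full[i]
        if per_column:
            M = T + c.log_end[None, :]
            ends[:, i] = _lse_rows(M) if sum_mode else M.max(axis=1)
    if per_column:
        return ends
    M = T + c.log_end[None, :]
    return _lse_rows(M) if sum_mode else M.max(axis=1)


def _suffix_run(
    c, E_full: np.ndarray, starts: list[int], sum_mode: bool
) -> np.ndarray:
    """Score of running the model over the read suffix [start, L), for all
    requested starts, via a single backward recursion.

    ``S[s]`` after processing column ``i`` is the (sum or max) score over
    paths that start in state ``s`` at column ``i`` (emission included) and
    finish with the END transition at column L-1.
    """
    L = E_full.shape[0]
    smin = min(starts)
    wanted = set(starts)
    vals: dict[int, float] = {}
    S = E_full[L - 1] + c.log_end
    if L - 1 in wanted:
        M0 = c.log_init + S
        vals[L - 1] = float(_lse_rows(M0)) if sum_mode else float(M0.max())
    for i in range(L - 2, smin - 1, -1):
        M = c.log_trans + S[None, :]
        S = E_full[i] + (_lse_rows(M) if sum_mode else M.max(axis=-1))
        if i in wanted:
            M0 = c.log_init + S
            vals[i] = float(_lse_rows(M0)) if sum_mode else float(M0.max())
    return np.array([vals[s] for s in starts])


def _run_table(c, E: np.ndarray, sum_mode: bool) -> np.ndarray:
    """Forward (sum) or Viterbi (max) DP table from a precomputed emission
    matrix slice."""
    L = E.shape[0]
    T = np.empty_like(E)
    T[0] = c.log_init + E[0]
    if sum_mode:
        for i in range(1, L):
            T[i] = E[i] + hmm._lse_step(T[i - 1], c.log_trans)
    else:
        for i in range(1, L):
            T[i] = E[i] + (T[i - 1][:, None] + c.log_trans).max(axis=0)
    return T


def _backtrace(
    ids, obs, germline, cache, l_v, l_d, v_allele, d_allele, j_allele, vit_total
) -> Annotation:
    """Recover deletions, insertions, and the naive sequence from the
    per-segment Viterbi paths of the winning combination."""
    L = len(obs)
    v_path = hmm.viterbi(cache.get(v_allele).model, obs.window(0, l_v)).path
    d_path = hmm.viterbi(cache.get(d_allele).model, obs.window(l_v, l_v + l_d)).path
    j_path = hmm.viterbi(cache.get(j_allele).model, obs.window(l_v + l_d, L)).path

    def split(path, gene_len):
        inserts = "".join(s[1] for s in path if s.startswith("i"))
        germ = [int(s[1:]) for s in path if s.startswith("g")]
        return inserts, germ[0], gene_len - 1 - germ[-1]

    _, v_5p, v_3p = split(v_path, len(germline.seq(v_allele)))
    vd_ins, d_5p, d_3p = split(d_path, len(germline.seq(d_allele)))
    dj_ins, j_5p, j_3p = split(j_path, len(germline.seq(j_allele)))
    naive = naive_sequence(
        germline, v_allele, d_allele, j_allele,
        v_5p, v_3p, d_5p, d_3p, j_5p, j_3p, vd_ins, dj_ins,
    )
    mutated = tuple(
        tuple(i for i in range(L) if seq[i] != naive[i] and seq[i] != "N")
        for seq in obs.sequences
    )
    ann = Annotation(
        query_ids=ids,
        v_allele=v_allele,
        d_allele=d_allele,
        j_allele=j_allele,
        v_5p_del=v_5p,
        v_3p_del=v_3p,
        d_5p_del=d_5p,
        d_3p_del=d_3p,
        j_5p_del=j_5p,
        j_3p_del=j_3p,
        vd_insertion=vd_ins,
        dj_insertion=dj_ins,
        naive_seq=naive,
        mutated_positions=mutated,
        viterbi_log_prob=vit_total,
    )
    ann.check_lengths(germline)
    return ann


def annotation_log_prob(
    ann: Annotation,
    reads: list[tuple[str, str]],
    germline: GermlineSet,
    params: ParameterSet,
    _cache: _ModelCache | None = None,
) -> float:
    """Log probability of one specific event for the given read(s).

    Scores the exact state path implied by the annotation (allele usage,
    entry/exit, insert states, emissions) under the factorized model; useful
    as an oracle for comparing a putative true event against the Viterbi
    optimum.
    """
    cache = _cache or _ModelCache(germline, params)
    obs = EmissionTuple(tuple(seq for _, seq in reads))
    bounds = ann.region_bounds(germline)
    total = 0.0
    for segment, allele, d5 in (
        ("V", ann.v_allele, ann.v_5p_del),
        ("D", ann.d_allele, ann.d_5p_del),
        ("J", ann.j_allele, ann.j_5p_del),
    ):
        q = params.q_g[segment].get(allele, 0.0)
        if q <= 0:
            return _NEG_INF
        total += math.log(q)
        am = cache.get(allele)
        region = segment.lower()
        lo, hi = bounds[region]
        path = []
        if segment == "D":
            path += [f"i{b}" for b in ann.vd_insertion]
            lo = bounds["vd"][0]
        elif segment == "J":
            path += [f"i{b}" for b in ann.dj_insertion]
            lo = bounds["dj"][0]
        n_germ = hi - bounds[region][0]
        path += [f"g{d5 + i}" for i in range(n_germ)]
        total += hmm.path_log_prob(am.model, obs.window(lo, hi), path)
    return total


def annotate_batch(
    reads: list[tuple[str, str]],
    germline: GermlineSet,
    params: ParameterSet,
    groupings: list[list[str]] | None = None,
    config: AnnotatorConfig | None = None,
    sw_cache: dict[str, SWAnnotation] | None = None,
) -> tuple[list[Annotation], list[tuple[str, str]]]:
    """Annotate every read (or clonal family); failures are listed, not
    dropped.

    ``groupings`` lists read-id groups for multi-HMM mode; ungrouped ids are
    annotated singly.  Identical single sequences are annotated once and the
    result is replicated per read id, so output is deterministic given fixed
    inputs.
    """
    config = config or AnnotatorConfig()
    cache = _ModelCache(germline, params)
    by_id = dict(reads)
    sw_cache = dict(sw_cache or {})
    annotations: list[Annotation] = []
    failures: list[tuple[str, str]] = []

    def get_sw(rid: str) -> SWAnnotation:
        if rid not in sw_cache:
            sw_cache[rid] = sw_match(
                by_id[rid], germline, config.sw, query_id=rid
            )
        return sw_cache[rid]

    groups: list[list[str]] = list(groupings) if groupings else []
    grouped_ids = {rid for group in groups for rid in group}
    singles = [rid for rid, _ in reads if rid not in grouped_ids]

    # a read whose SW boundary bounds admit no partition consistent with
    # the deletion-length supports gets one retry with exhaustive bounds
    exhaustive = replace(config, exhaustive_kbounds=True)

    def annotate_with_retry(group_reads, sws):
        try:
            return annotate(
                group_reads, germline, params, sw=sws, config=config,
                _cache=cache,
            )
        except AnnotationFailure:
            if config.exhaustive_kbounds:
                raise
            return annotate(
                group_reads, germline, params, sw=None, config=exhaustive,
                _cache=cache,
            )

    seen: dict[str, Annotation] = {}
    for rid in singles:
        seq = by_id[rid]
        if seq in seen:
            annotations.append(replace(seen[seq], query_ids=(rid,)))
            continue
        try:
            sw = None if config.exhaustive_kbounds else get_sw(rid)
            ann = annotate_with_retry([(rid, seq)], sw)
        except AnnotationFailure as fail:
            failures.append((rid, fail.reason))
            continue
        seen[seq] = ann
        annotations.append(ann)

    for group in groups:
        group_reads = [(rid, by_id[rid]) for rid in group]
        try:
            if config.exhaustive_kbounds:
                sws = None
            else:
                sws = [get_sw(rid) for rid in group]
            ann = annotate_with_retry(group_reads, sws)
        except AnnotationFailure as fail:
            failures.append((":".join(group), fail.reason))
            continue
        annotations.append(ann)
    return annotations, failures
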