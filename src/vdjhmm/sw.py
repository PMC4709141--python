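"""Smith-Waterman pre-annotation.

Before any HMM runs, each query read gets a quick local-alignment pass that
(1) ranks candidate germline alleles per segment, (2) bounds the search over
the V/D/J boundary partition (how many read bases belong to the V region and
to the VD-insert-plus-D region) so the factorized HMM sum stays tractable,
(3) produces a provisional annotation used to seed parameter estimation, and
(4) flags candidate insertion/deletion mutations (alignment gaps), which the
HMM itself does not model.

The default gap-opening penalty is set high so that indels are rare by
default; lowering it increases sensitivity to indel mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .annotation import Annotation, naive_sequence
from .germline import GermlineSet

__all__ = [
    "SWConfig",
    "KBounds",
    "IndelFlag",
    "SWAnnotation",
    "AnnotationFailure",
    "sw_match",
    "flag_indels",
    "reverse_indels",
]


class AnnotationFailure(Exception):
    """A query for which no acceptable annotation could be produced.

    Failures are recorded, never silently dropped: batch drivers catch this
    and list the query as failed.
    """

    def __init__(self, query_id: str, reason: str):
        super().__init__(f"{query_id}: {reason}")
        self.query_id = query_id
        self.reason = reason


@dataclass
class SWConfig:
    """Scoring and search configuration (all values configurable)."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -50  # high by default: indel mutations flagged, not expected
    gap_extend: int = -2
    kbound_fuzz: int = 5  # +/- bases around each best boundary
    # boundary re-scoring: local alignments happily extend across junction
    # bases through occasional mismatches (match runs pay for them); ends
    # are trimmed back to the running-score maximum under this harsher
    # mismatch penalty so boundary estimates stay near the junction
    boundary_mismatch: int = 10
    min_v_score: int = 30
    min_j_score: int = 15
    n_v_candidates: int = 5
    n_j_candidates: int = 3
    n_d_candidates: int | None = None  # None: keep every D allele

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


@dataclass(frozen=True)
class KBounds:
    """Inclusive search ranges for the boundary partition.

    ``l_v`` is the number of read bases assigned to the V region, ``l_d``
    the number assigned to VD-insert plus D germline; the J region takes the
    remainder.  Each region must keep at least one base.
    """

    v_min: int
    v_max: int
    d_min: int
    d_max: int

    def __post_init__(self):
        if self.v_min < 1 or self.d_min < 1 or self.v_max < self.v_min \
                or self.d_max < self.d_min:
            raise ValueError(f"empty or invalid kbounds {self}")

    def widen(self, fuzz: int, read_length: int) -> "KBounds":
        return KBounds(
            max(1, self.v_min - fuzz),
            min(read_length - 2, self.v_max + fuzz),
            max(1, self.d_min - fuzz),
            min(read_length - 2, self.d_max + fuzz),
        )

    @classmethod
    def exhaustive(cls, read_length: int) -> "KBounds":
        return cls(1, read_length - 2, 1, read_length - 2)


@dataclass(frozen=True)
class IndelFlag:
    """A candidate indel mutation seen as a gap inside a germline match."""

    query_position: int
    kind: str  # "insertion": extra read bases; "deletion": missing germline bases
    length: int
    bases: str  # inserted read bases, or the deleted germline bases


@dataclass
class SWAnnotation:
    query_id: str
    # per segment: candidate alleles ranked by (score desc, name)
    candidates: dict[str, list[tuple[str, int]]]
    # per segment: matched query window (half-open, full-read coordinates)
    windows: dict[str, tuple[int, int]]
    kbounds: KBounds
    indel_flags: list[IndelFlag]
    provisional: Annotation


def _coords(alignment) -> tuple[int, int, int, int, list]:
    """(q_start, q_end, g_start, g_end, block pairs) of a local alignment.

    The aligner is always called as ``align(read, germline)``, so the first
    coordinate set refers to the read.
    """
    read_blocks, germ_blocks = alignment.aligned
    q_start, q_end = int(read_blocks[0][0]), int(read_blocks[-1][1])
    g_start, g_end = int(germ_blocks[0][0]), int(germ_blocks[-1][1])
    return q_start, q_end, g_start, g_end, list(zip(read_blocks, germ_blocks))


def _gaps_to_flags(blocks, query: str, germ: str, offset: int) -> list[IndelFlag]:
    flags = []
    for (r1, g1), (r2, g2) in zip(blocks, blocks[1:]):
        r_gap = int(r2[0]) - int(r1[1])
        g_gap = int(g2[0]) - int(g1[1])
        if r_gap > 0 and g_gap == 0:
            flags.append(
                IndelFlag(
                    offset + int(r1[1]),
                    "insertion",
                    r_gap,
                    query[int(r1[1]) : int(r2[0])],
                )
            )
        elif g_gap > 0 and r_gap == 0:
            flags.append(
                IndelFlag(
                    offset + int(r1[1]),
                    "deletion",
                    g_gap,
                    germ[int(g1[1]) : int(g2[0])],
                )
            )
        elif r_gap > 0 and g_gap > 0:  # mismatched double gap: flag both
            flags.append(
                IndelFlag(
                    offset + int(r1[1]),
                    "insertion",
                    r_gap,
                    query[int(r1[1]) : int(r2[0])],
                )
            )
            flags.append(
                IndelFlag(
                    offset + int(r1[1]),
                    "deletion",
                    g_gap,
                    germ[int(g1[1]) : int(g2[0])],
                )
            )
    return flags


def flag_indels(
    query: str, germ: str, config: SWConfig | None = None, offset: int = 0
) -> list[IndelFlag]:
    """Candidate indels: every gap inside the best affine-gap local match.

    Raising the gap-opening penalty makes flags strictly rarer; at the high
    default, a flagged gap must beat the combined mismatch cost of the
    alternative gapless explanation.
    """
    config = config or SWConfig()
    aligner = config.aligner()
    alignments = aligner.align(query, germ)
    try:
        best = alignments[0]
    except (IndexError, ValueError):
        return []
    _, _, _, _, blocks = _coords(best)
    return _gaps_to_flags(blocks, query, germ, offset)


def reverse_indels(query: str, flags: list[IndelFlag]) -> str:
    """Undo flagged indels: strip flagged insertions, restore deleted bases.

    The result can be annotated alongside the original read, so candidate
    indels can be evaluated with and without the event.
    """
    out = query
    for flag in sorted(flags, key=lambda f: -f.query_position):
        if flag.kind == "insertion":
            out = out[: flag.query_position] + out[flag.query_position + flag.length :]
        else:
            out = out[: flag.query_position] + flag.bases + out[flag.query_position :]
    return out


def _trim_right(
    query: str, germ: str, q0: int, q1: int, g0: int, g1: int,
    match: int, penalty: int,
) -> tuple[int, int]:
    """Pull the right end of a gapless match back to its score maximum."""
    span = min(q1 - q0, g1 - g0)
    best, best_len, score = 0, 0, 0
    for i in range(span):
        score += match if query[q0 + i] == germ[g0 + i] else -penalty
        if score >= best:
            best, best_len = score, i + 1
    return q0 + best_len, g0 + best_len


def _trim_left(
    query: str, germ: str, q0: int, q1: int, g0: int, g1: int,
    match: int, penalty: int,
) -> tuple[int, int]:
    """Pull the left end of a gapless match forward to its score maximum."""
    span = min(q1 - q0, g1 - g0)
    best, best_len, score = 0, 0, 0
    for i in range(span):
        score += match if query[q1 - 1 - i] == germ[g1 - 1 - i] else -penalty
        if score >= best:
            best, best_len = score, i + 1
    return q1 - best_len, g1 - best_len


def _segment_scores(
    aligner, query: str, germline: GermlineSet, segment: str
) -> list[tuple[str, int]]:
    scored = []
    for name in germline.segment_alleles(segment):
        if len(query) == 0:
            continue
        score = int(aligner.score(query, germline.seq(name)))
        scored.append((name, score))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def sw_match(
    query: str,
    germline: GermlineSet,
    config: SWConfig | None = None,
    query_id: str = "query",
) -> SWAnnotation:
    """Full Smith-Waterman pre-annotation of one read.

    Matches V first, J to the right of the V match, then D inside the window
    between them (D genes are short; matching them against the whole read is
    noise-prone).  Boundary search bounds are the best boundaries +/- the
    configured fuzz, clipped so every segment keeps at least one base.
    """
    config = config or SWConfig()
    aligner = config.aligner()
    L = len(query)
    if L < 3:
        raise AnnotationFailure(query_id, f"read length {L} < 3")

    # --- V ---
    v_scores = _segment_scores(aligner, query, germline, "V")
    if not v_scores or v_scores[0][1] < config.min_v_score:
        best = v_scores[0][1] if v_scores else 0
        raise AnnotationFailure(
            query_id, f"best V score {best} below threshold {config.min_v_score}"
        )
    v_allele = v_scores[0][0]
    v_germ = germline.seq(v_allele)
    vq0, vq1, vg0, vg1, v_blocks = _coords(aligner.align(query, v_germ)[0])
    flags = _gaps_to_flags(v_blocks, query, v_germ, 0)
    (rq0, rq1), (rg0, rg1) = v_blocks[-1]
    tq1, tg1 = _trim_right(
        query, v_germ, int(rq0), int(rq1), int(rg0), int(rg1),
        config.match, config.boundary_mismatch,
    )
    if tq1 > vq0:
        vq1, vg1 = tq1, tg1
    # extend the match leftward to the start of the read, counting mismatches
    # as mutations; read bases that fall off the 5' end of the germline
    # cannot be explained without an indel
    if vg0 < vq0:
        raise AnnotationFailure(query_id, "read extends past the 5' end of V")
    vg0 -= vq0
    vq0 = 0
    v_5p = vg0
    v_span = vq1 - vq0
    if vq1 >= L - 1:
        raise AnnotationFailure(query_id, "V match leaves no room for D and J")

    # --- J (to the right of the V match) ---
    j_region = query[vq1:]
    j_scores = _segment_scores(aligner, j_region, germline, "J")
    if not j_scores or j_scores[0][1] < config.min_j_score:
        best = j_scores[0][1] if j_scores else 0
        raise AnnotationFailure(
            query_id, f"best J score {best} below threshold {config.min_j_score}"
        )
    j_allele = j_scores[0][0]
    j_germ = germline.seq(j_allele)
    jq0, jq1, jg0, jg1, j_blocks = _coords(aligner.align(j_region, j_germ)[0])
    flags += _gaps_to_flags(j_blocks, j_region, j_germ, vq1)
    (rq0, rq1), (rg0, rg1) = j_blocks[0]
    tq0, tg0 = _trim_left(
        j_region, j_germ, int(rq0), int(rq1), int(rg0), int(rg1),
        config.match, config.boundary_mismatch,
    )
    if tq0 < jq1:
        jq0, jg0 = tq0, tg0
    jq0 += vq1
    jq1 += vq1
    # extend the J match rightward to the end of the read
    ext = min(L - jq1, len(j_germ) - jg1)
    jq1 += ext
    jg1 += ext
    if jq1 < L:
        raise AnnotationFailure(query_id, "read extends past the 3' end of J")
    j_5p = jg0
    j_3p = len(j_germ) - jg1
    if jq0 - vq1 < 1:
        raise AnnotationFailure(query_id, "no bases left for the D segment")

    # --- D (inside the window between the V and J matches) ---
    d_window = query[vq1:jq0]
    d_scores = _segment_scores(aligner, d_window, germline, "D")
    if d_scores and d_scores[0][1] > 0:
        d_allele = d_scores[0][0]
        d_germ = germline.seq(d_allele)
        dq0, dq1, dg0, dg1, d_blocks = _coords(aligner.align(d_window, d_germ)[0])
        flags += _gaps_to_flags(d_blocks, d_window, d_germ, vq1)
        (rq0, rq1), (rg0, rg1) = d_blocks[0]
        tq0, tg0 = _trim_left(
            d_window, d_germ, int(rq0), int(rq1), int(rg0), int(rg1),
            config.match, config.boundary_mismatch,
        )
        if tq0 < dq1:
            dq0, dg0 = tq0, tg0
        (rq0, rq1), (rg0, rg1) = d_blocks[-1]
        tq1, tg1 = _trim_right(
            d_window, d_germ, int(rq0), int(rq1), int(rg0), int(rg1),
            config.match, config.boundary_mismatch,
        )
        if tq1 > dq0:
            dq1, dg1 = tq1, tg1
        dq0 += vq1
        dq1 += vq1
        d_5p = dg0
        d_3p = len(d_germ) - dg1
    else:
        # no D match at all: keep every D allele as a candidate with uniform
        # provisional weight rather than failing the read
        d_scores = [(name, 0) for name in germline.d_alleles]
        d_allele = d_scores[0][0]
        d_germ = germline.seq(d_allele)
        dq0, dq1 = jq0 - 1, jq0  # last window base as a 1-base D
        d_5p = 0
        d_3p = len(d_germ) - 1

    # provisional event, projected onto gapless coordinates
    v_3p = len(v_germ) - v_5p - v_span
    d_span = dq1 - dq0
    if d_span != len(d_germ) - d_5p - d_3p:
        d_3p = len(d_germ) - d_5p - d_span
    if v_3p < 0 or d_3p < 0 or min(v_span, d_span, jq1 - jq0) < 1:
        raise AnnotationFailure(query_id, "inconsistent alignment spans")
    vd_insertion = query[vq1:dq0]
    dj_insertion = query[dq1:jq0]
    naive = naive_sequence(
        germline, v_allele, d_allele, j_allele,
        v_5p, v_3p, d_5p, d_3p, j_5p, j_3p, vd_insertion, dj_insertion,
    )
    if len(naive) != L:
        raise AnnotationFailure(
            query_id, "provisional annotation is length-inconsistent (indel?)"
        )
    mutated = tuple(i for i in range(L) if query[i] != naive[i])
    provisional = Annotation(
        query_ids=(query_id,),
        v_allele=v_allele,
        d_allele=d_allele,
        j_allele=j_allele,
        v_5p_del=v_5p,
        v_3p_del=v_3p,
        d_5p_del=d_5p,
        d_3p_del=d_3p,
        j_5p_del=j_5p,
        j_3p_del=j_3p,
        vd_insertion=vd_insertion,
        dj_insertion=dj_insertion,
        naive_seq=naive,
        mutated_positions=(mutated,),
    )
    provisional.check_lengths(germline)

    l_v_best = vq1
    l_d_best = dq1 - vq1
    kbounds = KBounds(l_v_best, l_v_best, l_d_best, l_d_best).widen(
        config.kbound_fuzz, L
    )
    candidates = {
        "V": v_scores[: config.n_v_candidates],
        "D": d_scores[: config.n_d_candidates]
        if config.n_d_candidates
        else d_scores,
        "J": j_scores[: config.n_j_candidates],
    }
    return SWAnnotation(
        query_id=query_id,
        candidates=candidates,
        windows={"V": (vq0, vq1), "D": (dq0, dq1), "J": (jq0, jq1)},
        kbounds=kbounds,
        indel_flags=flags,
        provisional=provisional,
    )
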