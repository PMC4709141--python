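"""The annotation record: one inferred (or true) rearrangement event.

An :class:`Annotation` pins down a single VDJ rearrangement: which V, D, and
J alleles were joined, how much was trimmed from each junctional gene end
(exonuclease deletions, with 5' V and 3' J doubling as read-length
truncation), the two non-templated N-region insertions, and the implied
naive (unmutated ancestor) sequence.  In multi-HMM mode a single annotation
covers ``k`` clonally related reads that share one event.

Annotations round-trip losslessly through a CSV format with one row per
event; see :func:`write_annotations` / :func:`read_annotations`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .germline import GermlineSet

__all__ = [
    "Annotation",
    "naive_sequence",
    "germline_position_map",
    "write_annotations",
    "read_annotations",
]

DELETION_TYPES = ("v_5p", "v_3p", "d_5p", "d_3p", "j_5p", "j_3p")

CSV_COLUMNS = [
    "query_ids",
    "v_allele",
    "d_allele",
    "j_allele",
    "v_5p_del",
    "v_3p_del",
    "d_5p_del",
    "d_3p_del",
    "j_5p_del",
    "j_3p_del",
    "vd_insertion",
    "dj_insertion",
    "naive_seq",
    "mutated_positions",
    "n_mutations",
    "viterbi_log_prob",
    "forward_log_prob",
]


@dataclass
class Annotation:
    query_ids: tuple[str, ...]
    v_allele: str
    d_allele: str
    j_allele: str
    v_5p_del: int
    v_3p_del: int
    d_5p_del: int
    d_3p_del: int
    j_5p_del: int
    j_3p_del: int
    vd_insertion: str
    dj_insertion: str
    naive_seq: str
    # per query sequence: 0-based read positions that differ from the naive
    mutated_positions: tuple[tuple[int, ...], ...] = ()
    viterbi_log_prob: float | None = None
    forward_log_prob: float | None = None

    @property
    def k(self) -> int:
        return len(self.query_ids)

    def deletion(self, dtype: str) -> int:
        return getattr(self, f"{dtype}_del")

    def n_mutations(self) -> tuple[int, ...]:
        return tuple(len(m) for m in self.mutated_positions)

    def mutation_freqs(self) -> tuple[float, ...]:
        L = len(self.naive_seq)
        return tuple(len(m) / L for m in self.mutated_positions)

    def segment_lengths(self, germline: GermlineSet) -> dict[str, int]:
        """Number of read bases contributed by each region, in read order."""
        v = len(germline.seq(self.v_allele)) - self.v_5p_del - self.v_3p_del
        d = len(germline.seq(self.d_allele)) - self.d_5p_del - self.d_3p_del
        j = len(germline.seq(self.j_allele)) - self.j_5p_del - self.j_3p_del
        return {
            "v": v,
            "vd": len(self.vd_insertion),
            "d": d,
            "dj": len(self.dj_insertion),
            "j": j,
        }

    def region_bounds(self, germline: GermlineSet) -> dict[str, tuple[int, int]]:
        """Half-open read-coordinate interval of each region."""
        lens = self.segment_lengths(germline)
        bounds, start = {}, 0
        for region in ("v", "vd", "d", "dj", "j"):
            bounds[region] = (start, start + lens[region])
            start += lens[region]
        return bounds

    def check_lengths(self, germline: GermlineSet) -> None:
        lens = self.segment_lengths(germline)
        if any(lens[r] < 1 for r in ("v", "d", "j")):
            raise ValueError(
                f"annotation {self.query_ids}: a segment contributes "
                f"fewer than one base ({lens})"
            )
        total = sum(lens.values())
        if total != len(self.naive_seq):
            raise ValueError(
                f"annotation {self.query_ids}: region lengths sum to "
                f"{total} but naive sequence has length {len(self.naive_seq)}"
            )


def naive_sequence(
    germline: GermlineSet,
    v_allele: str,
    d_allele: str,
    j_allele: str,
    v_5p: int,
    v_3p: int,
    d_5p: int,
    d_3p: int,
    j_5p: int,
    j_3p: int,
    vd_insertion: str,
    dj_insertion: str,
) -> str:
    """Trimmed V + VD insert + trimmed D + DJ insert + trimmed J."""
    v = germline.seq(v_allele)
    d = germline.seq(d_allele)
    j = germline.seq(j_allele)
    return (
        v[v_5p : len(v) - v_3p]
        + vd_insertion
        + d[d_5p : len(d) - d_3p]
        + dj_insertion
        + j[j_5p : len(j) - j_3p]
    )


def germline_position_map(
    ann: Annotation, germline: GermlineSet
) -> dict[str, list[tuple[int, int]]]:
    """Per segment: list of (read position, germline position) pairs covered."""
    bounds = ann.region_bounds(germline)
    out: dict[str, list[tuple[int, int]]] = {}
    for segment, region, d5 in (
        ("V", "v", ann.v_5p_del),
        ("D", "d", ann.d_5p_del),
        ("J", "j", ann.j_5p_del),
    ):
        lo, hi = bounds[region]
        out[segment] = [(read_pos, d5 + (read_pos - lo)) for read_pos in range(lo, hi)]
    return out


def _encode_positions(mutated: tuple[tuple[int, ...], ...]) -> str:
    return ";".join(":".join(str(p) for p in per_read) for per_read in mutated)


def _decode_positions(text: str, k: int) -> tuple[tuple[int, ...], ...]:
    if text == "" and k == 0:
        return ()
    parts = text.split(";")
    return tuple(
        tuple(int(p) for p in part.split(":") if p != "") for part in parts
    )


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    """Write one CSV row per annotation (per clonal family in multi mode)."""
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for a in annotations:
            writer.writerow(
                {
                    "query_ids": ":".join(a.query_ids),
                    "v_allele": a.v_allele,
                    "d_allele": a.d_allele,
                    "j_allele": a.j_allele,
                    **{f"{dt}_del": a.deletion(dt) for dt in DELETION_TYPES},
                    "vd_insertion": a.vd_insertion,
                    "dj_insertion": a.dj_insertion,
                    "naive_seq": a.naive_seq,
                    "mutated_positions": _encode_positions(a.mutated_positions),
                    "n_mutations": ":".join(str(n) for n in a.n_mutations()),
                    "viterbi_log_prob": (
                        "" if a.viterbi_log_prob is None else repr(float(a.viterbi_log_prob))
                    ),
                    "forward_log_prob": (
                        "" if a.forward_log_prob is None else repr(float(a.forward_log_prob))
                    ),
                }
            )


def read_annotations(path: str | Path) -> list[Annotation]:
    out = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            ids = tuple(row["query_ids"].split(":"))
            out.append(
                Annotation(
                    query_ids=ids,
                    v_allele=row["v_allele"],
                    d_allele=row["d_allele"],
                    j_allele=row["j_allele"],
                    v_5p_del=int(row["v_5p_del"]),
                    v_3p_del=int(row["v_3p_del"]),
                    d_5p_del=int(row["d_5p_del"]),
                    d_3p_del=int(row["d_3p_del"]),
                    j_5p_del=int(row["j_5p_del"]),
                    j_3p_del=int(row["j_3p_del"]),
                    vd_insertion=row["vd_insertion"],
                    dj_insertion=row["dj_insertion"],
                    naive_seq=row["naive_seq"],
                    mutated_positions=_decode_positions(
                        row["mutated_positions"], len(ids)
                    ),
                    viterbi_log_prob=(
                        None
                        if row["viterbi_log_prob"] == ""
                        else float(row["viterbi_log_prob"])
                    ),
                    forward_log_prob=(
                        None
                        if row["forward_log_prob"] == ""
                        else float(row["forward_log_prob"])
                    ),
                )
            )
    return out
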