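"""Germline V/D/J allele sets and IMGT-style allele name parsing.

Allele names follow the standard IMGT convention for the heavy-chain locus:
``IGHV3-33*06`` is the 6th allele of gene ``IGHV3-33``, which belongs to the
``IGHV3`` gene family of the V segment.  Some D and J genes lack a
dash-number (e.g. ``IGHJ4*02``), in which case gene and family coincide.
All positions are 0-based, intervals half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SEGMENTS",
    "AlleleName",
    "GermlineAllele",
    "GermlineSet",
    "AlleleNameError",
    "GermlineError",
    "parse_allele_name",
    "load_germline",
    "write_germline",
    "load_codon_positions",
]

SEGMENTS = ("V", "D", "J")

_NAME_RE = re.compile(
    r"^(?P<family>IGH(?P<segment>[VDJ])(?P<famnum>\d+))"
    r"(?P<rest>(?:-[A-Za-z0-9.]+)*)"
    r"\*(?P<allele>\d+)$"
)

_VALID_BASES = set("ACGTN")


class GermlineError(Exception):
    pass


class AlleleNameError(GermlineError):
    pass


@dataclass(frozen=True)
class AlleleName:
    """Parsed IMGT hierarchy: segment > family > gene > allele."""

    segment: str
    family: str  # e.g. IGHV3
    gene: str  # e.g. IGHV3-33
    allele_id: str  # e.g. "06"

    def __str__(self) -> str:
        return f"{self.gene}*{self.allele_id}"


def parse_allele_name(name: str) -> AlleleName:
    """Parse e.g. ``"IGHV3-33*06"`` into its segment/family/gene/allele parts."""
    m = _NAME_RE.match(name)
    if m is None:
        raise AlleleNameError(f"cannot parse allele name {name!r}")
    family = m.group("family")
    gene = family + m.group("rest")
    return AlleleName(m.group("segment"), family, gene, m.group("allele"))


@dataclass
class GermlineAllele:
    """One germline allele: its sequence plus optional conserved-codon marks.

    ``cyst_position`` (V) and ``tryp_position`` (J) are the 0-based index of
    the first base of the conserved cysteine / tryptophan codon, i.e. the
    CDR3 boundaries; they are metadata only and never inferred.
    """

    name: str
    segment: str
    sequence: str
    cyst_position: int | None = None
    tryp_position: int | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise GermlineError(f"allele {self.name!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise GermlineError(
                f"allele {self.name!r}: invalid bases {sorted(bad)}"
            )
        parsed = parse_allele_name(self.name)
        if parsed.segment != self.segment:
            raise GermlineError(
                f"allele {self.name!r}: name implies segment {parsed.segment}, "
                f"got {self.segment}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GermlineSet:
    """All V, D, and J alleles available for annotation."""

    alleles: dict[str, GermlineAllele] = field(default_factory=dict)

    def __post_init__(self):
        for segment in SEGMENTS:
            if not self.segment_alleles(segment):
                raise GermlineError(f"no alleles in segment {segment}")

    def segment_alleles(self, segment: str) -> list[str]:
        return sorted(
            n for n, a in self.alleles.items() if a.segment == segment
        )

    @property
    def v_alleles(self) -> list[str]:
        return self.segment_alleles("V")

    @property
    def d_alleles(self) -> list[str]:
        return self.segment_alleles("D")

    @property
    def j_alleles(self) -> list[str]:
        return self.segment_alleles("J")

    def seq(self, name: str) -> str:
        return self.alleles[name].sequence

    def __getitem__(self, name: str) -> GermlineAllele:
        return self.alleles[name]

    def __contains__(self, name: str) -> bool:
        return name in self.alleles


def load_germline(fasta_paths: dict[str, str | Path]) -> GermlineSet:
    """Read one FASTA per segment (keys ``"V"``, ``"D"``, ``"J"``).

    Headers must carry IMGT-style allele names; sequences are uppercased.
    Duplicate names and empty segment files are rejected.
    """
    alleles: dict[str, GermlineAllele] = {}
    for segment in SEGMENTS:
        path = Path(fasta_paths[segment])
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise GermlineError(f"no sequences in {path} (segment {segment})")
        for rec in records:
            name = rec.id
            if name in alleles:
                raise GermlineError(f"duplicate allele name {name!r} in {path}")
            alleles[name] = GermlineAllele(name, segment, str(rec.seq))
    return GermlineSet(alleles)


def write_germline(germline: GermlineSet, out_dir: str | Path) -> dict[str, Path]:
    """Write one FASTA per segment into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for segment in SEGMENTS:
        path = out_dir / f"igh{segment.lower()}.fasta"
        records = [
            SeqRecord(Seq(germline.seq(n)), id=n, description="")
            for n in germline.segment_alleles(segment)
        ]
        SeqIO.write(records, str(path), "fasta")
        paths[segment] = path
    return paths


def load_reads(path: str | Path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Load query reads from FASTA or FASTQ as ``(id, sequence)`` pairs.

    Format is taken from the file suffix unless given explicitly.  FASTQ
    quality scores are read but ignored: no platform-specific error model
    is applied downstream.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
    if not reads:
        raise GermlineError(f"no reads in {path}")
    return reads


def load_codon_positions(csv_path: str | Path, germline: GermlineSet) -> None:
    """Attach conserved-codon positions from a metadata CSV (in place).

    Expected columns: ``allele,codon,position`` with codon ``cyst`` or
    ``tryp`` and 0-based positions.
    """
    import csv

    with open(csv_path, newline="") as handle:
        for row in csv.DictReader(handle):
            allele = germline.alleles.get(row["allele"])
            if allele is None:
                continue
            pos = int(row["position"])
            if row["codon"] == "cyst":
                allele.cyst_position = pos
            elif row["codon"] == "tryp":
                allele.tryp_position = pos
            else:
                raise GermlineError(f"unknown codon kind {row['codon']!r}")
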