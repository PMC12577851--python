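"""Core domain objects shared across the pipeline.

All coordinates are 0-based, half-open, on both query and target axes
(PAF-native). Format dialects that use other conventions (AGP) are converted
at the I/O boundary in :mod:`refweave.seqio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """One pairwise alignment in PAF semantics."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str  # '+' or '-'
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    residue_matches: int
    alignment_block_length: int
    mapping_quality: int = 0
    alignment_type: str = "primary"  # primary | secondary | inversion
    cigar: Optional[str] = None

    def __post_init__(self) -> None:
        for axis, (s, e, ln) in {
            "query": (self.query_start, self.query_end, self.query_length),
            "target": (self.target_start, self.target_end, self.target_length),
        }.items():
            if not (0 <= s < e <= ln):
                raise ValueError(
                    f"invalid {axis} interval [{s},{e}) on length {ln} "
                    f"({self.query_name} vs {self.target_name})"
                )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.residue_matches > self.alignment_block_length:
            raise ValueError("residue_matches cannot exceed alignment_block_length")

    @property
    def query_span_fraction(self) -> float:
        return (self.query_end - self.query_start) / self.query_length

    @property
    def identity(self) -> float:
        return self.residue_matches / self.alignment_block_length


@dataclass(frozen=True, order=True)
class GenomicInterval:
    sequence_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_name == other.sequence_name
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ScaffoldComponent:
    """One contig placed in a scaffold, plus the gap that follows it (if any)."""

    contig_name: str
    contig_length: int
    orientation: str  # '+' or '-'
    gap_length_after: Optional[int] = None  # bp; None for the last component

    def __post_init__(self) -> None:
        if self.gap_length_after is not None and self.gap_length_after < 1:
            raise ValueError("gap_length_after must be >= 1 where present")


@dataclass
class ScaffoldPlan:
    """Ordering/orientation of contigs against a guide genome (AGP semantics).

    ``scaffolds`` maps scaffold name -> ordered components.  ``provenance``
    maps contig name -> (guide sequence name, placement interval, strand).
    """

    scaffolds: dict[str, list[ScaffoldComponent]] = field(default_factory=dict)
    provenance: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    unplaced: list[str] = field(default_factory=list)

    def placed_contigs(self) -> list[str]:
        return [c.contig_name for comps in self.scaffolds.values() for c in comps]

    def gaps(self) -> list[tuple[str, int, str, str]]:
        """All gaps as (scaffold, gap_length, left_contig, right_contig)."""
        out = []
        for name, comps in self.scaffolds.items():
            for left, right in zip(comps, comps[1:]):
                if left.gap_length_after is not None:
                    out.append(
                        (name, left.gap_length_after, left.contig_name, right.contig_name)
                    )
        return out

    def n_gaps(self) -> int:
        return len(self.gaps())


@dataclass
class AlignmentBlock:
    """A region of the mixed genome selected for localized assembly."""

    region: GenomicInterval
    source: str  # gap_flank | read_support
    gap_id: Optional[str] = None
    support: int = 0

    @property
    def block_id(self) -> str:
        r = self.region
        return f"{r.sequence_name}_{r.start}_{r.end}"


@dataclass
class BlockBundle:
    """A block plus the reads assigned to it and its mixed-genome backbone."""

    block: AlignmentBlock
    reads: list[SequenceRecord]
    backbone: SequenceRecord


@dataclass
class CandidateSequence:
    """A locally assembled sequence with filter verdicts and provenance."""

    id: str
    sequence: str
    block_id: str
    verdicts: dict[str, str] = field(default_factory=dict)  # name -> pass|fail|not_run
    read_provenance: list[str] = field(default_factory=list)
    fail_reasons: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def record_verdict(self, name: str, passed: bool, reason: str = "") -> None:
        self.verdicts[name] = "pass" if passed else "fail"
        if not passed and reason:
            self.fail_reasons[name] = reason

    @property
    def all_pass(self) -> bool:
        return bool(self.verdicts) and all(v == "pass" for v in self.verdicts.values())

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(id=self.id, sequence=self.sequence)


@dataclass
class CoverageProfile:
    """Per-base read depth over one sequence (retained primary alignments)."""

    sequence_name: str
    depth: "object"  # numpy int array, length == sequence length


@dataclass
class MixedGenome:
    """Reference genome after polishing with target HiFi reads."""

    sequences: dict[str, SequenceRecord]
    # (sequence_name, position, ref_base, new_base)
    edit_log: list[tuple[str, int, str, str]] = field(default_factory=list)

    def get(self, name: str) -> SequenceRecord:
        return self.sequences[name]
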