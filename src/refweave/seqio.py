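"""Readers and writers for FASTA/FASTQ (+gzip), PAF, AGP v2.1 and BED3.

Coordinate conventions: everything in memory is 0-based half-open; AGP rows
are converted to/from their native 1-based inclusive coordinates here and
nowhere else.
"""

from __future__ import annotations

import gzip
import io
import logging
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO as _BioSeqIO

from .model import (
    AlignmentRecord,
    GenomicInterval,
    ScaffoldComponent,
    ScaffoldPlan,
    SequenceRecord,
)

log = logging.getLogger("refweave")

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: PathLike) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ValueError(f"{path}: cannot determine sequence format")
    raise ValueError(f"{path}: empty file")


def read_sequences(path: PathLike, format: str | None = None) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA/FASTQ file, transparently gunzipping.

    Sequences are uppercased and U is mapped to T.  Duplicate ids raise.
    """
    fmt = format or _sniff_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format: {fmt}")
    seen: set[str] = set()
    with _open_text(path) as fh:
        try:
            for rec in _BioSeqIO.parse(fh, fmt):
                if rec.id in seen:
                    raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
                seen.add(rec.id)
                seq = str(rec.seq).upper().replace("U", "T")
                qual = None
                if "phred_quality" in rec.letter_annotations:
                    qual = list(rec.letter_annotations["phred_quality"])
                yield SequenceRecord(id=rec.id, sequence=seq, quality=qual)
        except ValueError:
            raise
        except Exception as exc:  # Biopython parse failures
            raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc


def load_sequences(path: PathLike, format: str | None = None) -> dict[str, SequenceRecord]:
    return {r.id: r for r in read_sequences(path, format)}


def write_sequences(
    records: Iterable[SequenceRecord], path: PathLike, format: str = "fasta"
) -> None:
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    if opener is gzip.open:
        # mtime=0 keeps gzipped output byte-stable across runs
        raw = open(path, "wb")
        fh = io.TextIOWrapper(gzip.GzipFile(fileobj=raw, mode="wb", mtime=0))
    else:
        raw = None
        fh = open(path, "wt")
    try:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n{rec.sequence}\n")
            elif format == "fastq":
                qual = rec.quality or [40] * len(rec.sequence)
                qstr = "".join(chr(q + 33) for q in qual)
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")
            else:
                raise ValueError(f"unsupported format {format}")
    finally:
        fh.close()
        if raw is not None:
            raw.close()


# ---------------------------------------------------------------------------
# PAF

_TP_MAP = {"P": "primary", "S": "secondary", "I": "inversion", "i": "inversion"}
_TP_INV = {"primary": "P", "secondary": "S", "inversion": "I"}


def read_paf(path: PathLike) -> Iterator[AlignmentRecord]:
    """Parse a PAF file (12+ tab-separated columns, optional SAM-style tags)."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            yield parse_paf_line(line, lineno=lineno)


def parse_paf_line(line: str, lineno: int = 0) -> AlignmentRecord:
    cols = line.split("\t")
    if len(cols) < 12:
        raise ValueError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
    try:
        qlen, qstart, qend = int(cols[1]), int(cols[2]), int(cols[3])
        tlen, tstart, tend = int(cols[6]), int(cols[7]), int(cols[8])
        matches, blocklen, mapq = int(cols[9]), int(cols[10]), int(cols[11])
    except ValueError as exc:
        raise ValueError(f"PAF line {lineno}: non-numeric coordinate field: {exc}") from exc
    aln_type = "primary"  # conservative default when tp is absent
    cigar = None
    for tag in cols[12:]:
        if tag.startswith("tp:A:"):
            aln_type = _TP_MAP.get(tag[5:], "primary")
        elif tag.startswith("cg:Z:"):
            cigar = tag[5:]
    return AlignmentRecord(
        query_name=cols[0],
        query_length=qlen,
        query_start=qstart,
        query_end=qend,
        strand=cols[4],
        target_name=cols[5],
        target_length=tlen,
        target_start=tstart,
        target_end=tend,
        residue_matches=matches,
        alignment_block_length=blocklen,
        mapping_quality=mapq,
        alignment_type=aln_type,
        cigar=cigar,
    )


def format_paf_line(rec: AlignmentRecord) -> str:
    cols = [
        rec.query_name,
        str(rec.query_length),
        str(rec.query_start),
        str(rec.query_end),
        rec.strand,
        rec.target_name,
        str(rec.target_length),
        str(rec.target_start),
        str(rec.target_end),
        str(rec.residue_matches),
        str(rec.alignment_block_length),
        str(rec.mapping_quality),
        f"tp:A:{_TP_INV[rec.alignment_type]}",
    ]
    if rec.cigar:
        cols.append(f"cg:Z:{rec.cigar}")
    return "\t".join(cols)


def write_paf(records: Iterable[AlignmentRecord], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(format_paf_line(rec) + "\n")


# ---------------------------------------------------------------------------
# AGP v2.1

_AGP_GAP_TYPE = "scaffold"
_AGP_EVIDENCE = "align_genus"


def write_agp(plan: ScaffoldPlan, path: PathLike) -> None:
    """Serialize a scaffold plan as AGP v2.1 (1-based inclusive coordinates)."""
    with open(path, "wt") as fh:
        fh.write("##agp-version\t2.1\n")
        for scaffold, comps in plan.scaffolds.items():
            pos = 0  # 0-based cursor on the object
            part = 0
            for comp in comps:
                part += 1
                beg, end = pos + 1, pos + comp.contig_length
                fh.write(
                    "\t".join(
                        [
                            scaffold,
                            str(beg),
                            str(end),
                            str(part),
                            "W",
                            comp.contig_name,
                            "1",
                            str(comp.contig_length),
                            comp.orientation,
                        ]
                    )
                    + "\n"
                )
                pos = end
                if comp.gap_length_after is not None:
                    part += 1
                    gbeg, gend = pos + 1, pos + comp.gap_length_after
                    fh.write(
                        "\t".join(
                            [
                                scaffold,
                                str(gbeg),
                                str(gend),
                                str(part),
                                "N",
                                str(comp.gap_length_after),
                                _AGP_GAP_TYPE,
                                "yes",
                                _AGP_EVIDENCE,
                            ]
                        )
                        + "\n"
                    )
                    pos = gend


def read_agp(path: PathLike) -> ScaffoldPlan:
    plan = ScaffoldPlan()
    pending: dict[str, list[ScaffoldComponent]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"AGP line {lineno}: too few columns")
            scaffold, comp_type = cols[0], cols[4]
            comps = pending.setdefault(scaffold, [])
            if comp_type in ("W", "D", "F", "O", "A"):
                if comps and any(c.contig_name == cols[5] for c in comps):
                    raise ValueError(f"AGP line {lineno}: contig {cols[5]} placed twice")
                length = int(cols[7]) - int(cols[6]) + 1
                comps.append(
                    ScaffoldComponent(
                        contig_name=cols[5],
                        contig_length=length,
                        orientation=cols[8] if len(cols) > 8 else "+",
                    )
                )
            elif comp_type in ("N", "U"):
                if not comps:
                    raise ValueError(f"AGP line {lineno}: gap before any component")
                comps[-1].gap_length_after = int(cols[5])
            else:
                raise ValueError(f"AGP line {lineno}: unknown component type {comp_type}")
    plan.scaffolds = pending
    return plan


# ---------------------------------------------------------------------------
# BED3(+)

def write_bed(intervals: Iterable[tuple[GenomicInterval, str, int]], path: PathLike) -> None:
    """Write (interval, name, score) triples as BED3+2."""
    with open(path, "wt") as fh:
        for iv, name, score in intervals:
            fh.write(f"{iv.sequence_name}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")
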