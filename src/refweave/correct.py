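"""Reference correction: polish the reference with target HiFi reads.

This is the first pipeline stage: reads are (optionally) screened so only
target-haplotype reads participate, then a per-column majority consensus is
applied to the reference, producing the "mixed genome" — a reference whose
covered columns have been rewritten to the target's alleles.

Polishing is substitution-only: the builtin aligner is gapless, so there is
never indel evidence to act on.  Externally polished genomes can be supplied
to the pipeline directly instead.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np

from .align import Aligner, AlignerConfig, best_primary_per_query
from .model import (
    AlignmentRecord,
    CoverageProfile,
    MixedGenome,
    SequenceRecord,
)
from .seqio import reverse_complement

log = logging.getLogger("refweave")

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


def select_haplotype_reads(
    reads: Mapping[str, SequenceRecord],
    target_contigs: Mapping[str, SequenceRecord],
    min_primary_fraction: float = 0.9,
    alignments: Iterable[AlignmentRecord] | None = None,
    config: AlignerConfig | None = None,
) -> set[str]:
    """Ids of reads whose primary alignment to the target contigs spans
    >= ``min_primary_fraction`` of the read.  Screens out reads from other
    haplotypes/organisms before they can vote in polishing."""
    if alignments is None:
        aligner = Aligner(target_contigs, config or AlignerConfig())
        alignments = (rec for r in reads.values() for rec in aligner.map(r))
    best = best_primary_per_query(alignments)
    kept = {
        name
        for name, rec in best.items()
        if rec.query_span_fraction >= min_primary_fraction
    }
    if not kept:
        raise RuntimeError("no haplotype reads retained")
    log.info("correct | retained %d/%d haplotype reads", len(kept), len(reads))
    return kept


def _aligned_query_slice(rec: AlignmentRecord, read: SequenceRecord) -> str:
    """Query bases over the alignment, oriented along the target axis."""
    piece = read.sequence[rec.query_start : rec.query_end]
    return reverse_complement(piece) if rec.strand == "-" else piece


def _vote(
    reference: Mapping[str, SequenceRecord],
    reads: Mapping[str, SequenceRecord],
    alignments: Iterable[AlignmentRecord],
) -> dict[str, np.ndarray]:
    """Per-column base counts (L x 4) from primary, gapless alignments."""
    counts = {
        name: np.zeros((len(rec.sequence), 4), dtype=np.int32)
        for name, rec in reference.items()
    }
    for rec in alignments:
        if rec.alignment_type != "primary":
            continue
        read = reads.get(rec.query_name)
        if read is None:
            continue
        qslice = _aligned_query_slice(rec, read)
        span = rec.target_end - rec.target_start
        if len(qslice) != span:  # gapped external record; skip conservatively
            continue
        codes = np.frombuffer(qslice.encode("ascii"), dtype=np.uint8)
        code_arr = np.full(codes.size, -1, dtype=np.int8)
        for base, idx in _CODE.items():
            code_arr[codes == ord(base)] = idx
        valid = code_arr >= 0
        pos = np.arange(rec.target_start, rec.target_end)[valid]
        np.add.at(counts[rec.target_name], (pos, code_arr[valid].astype(np.int64)), 1)
    return counts


def polish(
    reference: Mapping[str, SequenceRecord],
    reads: Mapping[str, SequenceRecord],
    consensus_min_depth: int = 3,
    consensus_min_fraction: float = 0.6,
    alignments: Iterable[AlignmentRecord] | None = None,
    config: AlignerConfig | None = None,
) -> MixedGenome:
    """Majority-consensus polish of ``reference`` using ``reads``.

    A column is rewritten when read depth >= ``consensus_min_depth`` and the
    majority allele holds >= ``consensus_min_fraction`` of the votes; every
    applied edit is logged.  Columns below the depth gate keep the reference
    base.
    """
    if not reads:
        raise ValueError("empty read set")
    if alignments is None:
        aligner = Aligner(reference, config or AlignerConfig())
        alignments = (rec for r in reads.values() for rec in aligner.map(r))
    counts = _vote(reference, reads, alignments)
    sequences: dict[str, SequenceRecord] = {}
    edit_log: list[tuple[str, int, str, str]] = []
    for name, ref_rec in reference.items():
        cnt = counts[name]
        depth = cnt.sum(axis=1)
        maj = cnt.argmax(axis=1)  # ties resolve to the lexicographically first base
        maj_cnt = cnt[np.arange(cnt.shape[0]), maj]
        ref_codes = np.full(len(ref_rec.sequence), -1, dtype=np.int8)
        raw = np.frombuffer(ref_rec.sequence.encode("ascii"), dtype=np.uint8)
        for base, idx in _CODE.items():
            ref_codes[raw == ord(base)] = idx
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, maj_cnt / np.maximum(depth, 1), 0.0)
        edit_mask = (
            (depth >= consensus_min_depth)
            & (frac >= consensus_min_fraction)
            & (maj.astype(np.int8) != ref_codes)
        )
        new = raw.copy()
        positions = np.nonzero(edit_mask)[0]
        for pos in positions:
            new_base = _BASES[maj[pos]]
            edit_log.append((name, int(pos), ref_rec.sequence[pos], new_base))
            new[pos] = ord(new_base)
        sequences[name] = SequenceRecord(id=name, sequence=new.tobytes().decode("ascii"))
    log.info("correct | polish applied %d edits", len(edit_log))
    return MixedGenome(sequences=sequences, edit_log=edit_log)


def coverage_profiles(
    alignments: Iterable[AlignmentRecord],
    lengths: Mapping[str, int],
    primary_only: bool = True,
) -> dict[str, CoverageProfile]:
    """Per-base depth of retained alignments over each target sequence."""
    diffs = {name: np.zeros(n + 1, dtype=np.int64) for name, n in lengths.items()}
    for rec in alignments:
        if primary_only and rec.alignment_type != "primary":
            continue
        d = diffs.get(rec.target_name)
        if d is None:
            continue
        d[rec.target_start] += 1
        d[rec.target_end] -= 1
    return {
        name: CoverageProfile(sequence_name=name, depth=np.cumsum(d[:-1]))
        for name, d in diffs.items()
    }
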