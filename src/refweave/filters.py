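"""Multistage QC that turns raw candidates into clean alternative long sequences.

Order matters and mirrors the pipeline's intent: (i) coverage-breakpoint
screening drops chimeric or unsupported joins, (ii) identity screening drops
candidates that either add nothing over the existing contigs or look like
reference artifacts, (iii) a length floor keeps only sequences long enough
to act as ultralong-read stand-ins.  Each filter records a verdict on every
candidate and returns the survivors; all are idempotent.

In related-species mode the identity filter is skipped entirely: with a
diverged reference there is no same-species contig comparison to make, so
only coverage and length screening apply.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .align import Aligner, AlignerConfig
from .model import CandidateSequence, SequenceRecord

log = logging.getLogger("refweave")


@dataclass
class FilterConfig:
    """Thresholds for the QC stages.

    min_depth / max_breakpoint_run: an internal run of > max_breakpoint_run
    consecutive bases with read depth < min_depth is a coverage breakpoint
    (defaults: any internal zero-depth base).  identity_ceiling +
    containment_fraction define "adds nothing new"; identity_floor defines
    "too divergent".  min_output_length is the final length floor in bp.
    """

    min_depth: int = 1
    max_breakpoint_run: int = 0
    identity_ceiling: float = 0.999
    identity_floor: float = 0.90
    containment_fraction: float = 0.95
    min_output_length: int = 50_000

    def __post_init__(self) -> None:
        if not (0 < self.identity_floor < self.identity_ceiling <= 1):
            raise ValueError("need 0 < identity_floor < identity_ceiling <= 1")


def depth_profile(
    candidate: CandidateSequence,
    reads: Iterable[SequenceRecord],
    config: AlignerConfig | None = None,
) -> np.ndarray:
    """Per-base depth of primary read alignments over one candidate."""
    target = SequenceRecord(id=candidate.id, sequence=candidate.sequence)
    aligner = Aligner({candidate.id: target}, config or AlignerConfig())
    diff = np.zeros(len(candidate.sequence) + 1, dtype=np.int64)
    for read in reads:
        for rec in aligner.map(read):
            if rec.alignment_type == "primary":
                diff[rec.target_start] += 1
                diff[rec.target_end] -= 1
    return np.cumsum(diff[:-1])


def find_breakpoints(
    depth: np.ndarray, min_depth: int, max_run: int, edge_zone: int
) -> list[tuple[int, int]]:
    """Internal runs of below-threshold depth longer than ``max_run`` bp."""
    lo = min(edge_zone, len(depth))
    hi = max(lo, len(depth) - edge_zone)
    low = depth[lo:hi] < min_depth
    if not low.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
    runs = []
    for i in range(0, len(edges), 2):
        s, e = int(edges[i]) + lo, int(edges[i + 1]) + lo
        if e - s > max_run:
            runs.append((s, e))
    return runs


def coverage_breakpoint_filter(
    candidates: list[CandidateSequence],
    reads: Mapping[str, SequenceRecord],
    cfg: FilterConfig,
    config: AlignerConfig | None = None,
    block_reads: Mapping[str, list[str]] | None = None,
) -> list[CandidateSequence]:
    """Fail candidates whose internal coverage drops below ``cfg.min_depth``.

    ``block_reads`` optionally restricts which read ids are aligned to each
    candidate (keyed by block id); otherwise all reads are used.  The first
    and last half-median-read-length bases are excluded, since coverage
    necessarily ramps at sequence ends.
    """
    survivors = []
    for cand in candidates:
        if block_reads is not None:
            pool = [reads[r] for r in block_reads.get(cand.block_id, []) if r in reads]
        else:
            pool = list(reads.values())
        if not pool:
            cand.record_verdict("coverage", False, "uncovered")
            continue
        edge = int(statistics.median(len(r.sequence) for r in pool) // 2)
        depth = depth_profile(cand, pool, config)
        if not depth.any():
            cand.record_verdict("coverage", False, "uncovered")
            continue
        runs = find_breakpoints(depth, cfg.min_depth, cfg.max_breakpoint_run, edge)
        if runs:
            cand.record_verdict(
                "coverage", False, f"breakpoint at {runs[0][0]}-{runs[0][1]}"
            )
        else:
            cand.record_verdict("coverage", True)
            survivors.append(cand)
    log.info("filter | coverage: %d/%d pass", len(survivors), len(candidates))
    return survivors


def identity_verdict(i: float, c: float, cfg: FilterConfig) -> tuple[bool, str]:
    """Decision rule for one (identity, containment) pair; (passed, reason)."""
    if i >= cfg.identity_ceiling and c >= cfg.containment_fraction:
        return False, f"identical:i={i:.4f},c={c:.3f}"
    if i < cfg.identity_floor:
        return False, f"divergent:i={i:.4f}"
    return True, ""


def identity_filter(
    candidates: list[CandidateSequence],
    target_contigs: Mapping[str, SequenceRecord],
    cfg: FilterConfig,
    mode: str = "same",
    config: AlignerConfig | None = None,
) -> list[CandidateSequence]:
    """Fail candidates completely identical to, or too divergent from, the contigs.

    The best primary alignment of the candidate against the contigs gives
    identity i and containment c (aligned fraction of the candidate).  A
    candidate fails as "adds nothing new" when i >= identity_ceiling and
    c >= containment_fraction, and as "too divergent" when i <
    identity_floor or it does not align at all.  Only applied in
    same-species mode; with a related-species reference the verdict is
    recorded as not_run.
    """
    if mode == "related":
        for cand in candidates:
            cand.verdicts.setdefault("identity", "not_run")
        return list(candidates)
    aligner = Aligner(target_contigs, config or AlignerConfig.for_mode("genome_to_genome"))
    survivors = []
    for cand in candidates:
        recs = [
            r for r in aligner.map(cand.as_record()) if r.alignment_type == "primary"
        ]
        if not recs:
            cand.record_verdict("identity", False, "divergent:unaligned")
            continue
        best = recs[0]
        passed, reason = identity_verdict(best.identity, best.query_span_fraction, cfg)
        cand.record_verdict("identity", passed, reason)
        if passed:
            survivors.append(cand)
    log.info("filter | identity: %d/%d pass", len(survivors), len(candidates))
    return survivors


def length_filter(
    candidates: list[CandidateSequence], cfg: FilterConfig
) -> list[CandidateSequence]:
    """Drop candidates shorter than ``cfg.min_output_length``; order preserved."""
    survivors = []
    for cand in candidates:
        if len(cand.sequence) < cfg.min_output_length:
            cand.record_verdict("length", False, f"len={len(cand.sequence)}")
        else:
            cand.record_verdict("length", True)
            survivors.append(cand)
    log.info("filter | length: %d/%d pass", len(survivors), len(candidates))
    return survivors


@dataclass
class ContigAudit:
    contig_id: str
    length: int
    original_read_fraction: float  # of bases covered by original-read alignments
    alt_ids_in_provenance: list[str]

    @property
    def flagged(self) -> bool:
        return bool(self.alt_ids_in_provenance)


def provenance_audit(
    final_contigs: Mapping[str, SequenceRecord],
    original_reads: Mapping[str, SequenceRecord],
    alternative_sequences: Mapping[str, SequenceRecord],
    provenance: Mapping[str, list[str]] | None = None,
    config: AlignerConfig | None = None,
) -> list[ContigAudit]:
    """Verify final contigs are built from original reads only.

    For each contig, the fraction of bases covered by primary alignments of
    the original reads is reported, and any alternative-sequence id found in
    the contig's assembly provenance (when available) raises a flag — guide
    sequences must contribute no bases.
    """
    alt_ids = set(alternative_sequences)
    reports = []
    for name, contig in final_contigs.items():
        aligner = Aligner({name: contig}, config or AlignerConfig())
        diff = np.zeros(len(contig.sequence) + 1, dtype=np.int64)
        for read in original_reads.values():
            for rec in aligner.map(read):
                if rec.alignment_type == "primary":
                    diff[rec.target_start] += 1
                    diff[rec.target_end] -= 1
        depth = np.cumsum(diff[:-1])
        frac = float(np.count_nonzero(depth > 0)) / max(len(contig.sequence), 1)
        prov_ids = list(provenance.get(name, [])) if provenance else []
        flagged = sorted(alt_ids.intersection(prov_ids))
        reports.append(
            ContigAudit(
                contig_id=name,
                length=len(contig.sequence),
                original_read_fraction=frac,
                alt_ids_in_provenance=flagged,
            )
        )
    return reports


def apply_filters(
    candidates: list[CandidateSequence],
    reads: Mapping[str, SequenceRecord],
    target_contigs: Mapping[str, SequenceRecord],
    cfg: FilterConfig,
    mode: str = "same",
    block_reads: Mapping[str, list[str]] | None = None,
    aligner_config: AlignerConfig | None = None,
) -> list[CandidateSequence]:
    """coverage -> identity -> length, in that order."""
    out = coverage_breakpoint_filter(candidates, reads, cfg, aligner_config, block_reads)
    out = identity_filter(out, target_contigs, cfg, mode=mode)
    out = length_filter(out, cfg)
    return out
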