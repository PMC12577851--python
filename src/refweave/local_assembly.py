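"""Localized hybrid assembly of each alignment block.

Per block, the reads whose primary alignment overlaps the block are bundled
with the mixed-genome excerpt ("backbone" — the stand-in for an ONT
ultralong read).  The builtin backend is a backbone-guided consensus: reads
are aligned onto the backbone, and the candidate sequences are the maximal
stretches in which every column carries at least ``builtin_min_depth`` read
votes, spelled by the majority read allele.  By construction the backend
emits no base the reads do not cover, which is what lets the downstream
provenance audit hold exactly.

A production run swaps in an external assembler (e.g. a UL-aware string
graph assembler) through :func:`external_assembler_adapter`.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .align import Aligner, AlignerConfig, best_primary_per_query
from .correct import _BASES, _CODE, _aligned_query_slice
from .model import (
    AlignmentBlock,
    AlignmentRecord,
    BlockBundle,
    CandidateSequence,
    MixedGenome,
    SequenceRecord,
)
from .seqio import load_sequences, write_sequences

log = logging.getLogger("refweave")

DEFAULT_BUILTIN_MIN_DEPTH = 2


def partition_reads(
    read_alignments: Iterable[AlignmentRecord],
    blocks: list[AlignmentBlock],
    reads: Mapping[str, SequenceRecord],
    mixed: MixedGenome,
) -> list[BlockBundle]:
    """Assign each read to the (single) block its primary alignment overlaps.

    Blocks are disjoint, so a read lands in at most one bundle; bundles with
    zero reads are dropped with a warning.  Each bundle carries the
    mixed-genome excerpt at its block as backbone.
    """
    ordered = sorted(blocks, key=lambda b: (b.region.sequence_name, b.region.start))
    assigned: dict[int, list[str]] = {i: [] for i in range(len(ordered))}
    best = best_primary_per_query(read_alignments)
    for name, rec in sorted(best.items()):
        for i, blk in enumerate(ordered):
            r = blk.region
            if (
                rec.target_name == r.sequence_name
                and rec.target_start < r.end
                and r.start < rec.target_end
            ):
                assigned[i].append(name)
                break
    bundles: list[BlockBundle] = []
    for i, blk in enumerate(ordered):
        names = assigned[i]
        if not names:
            log.warning("assemble | block %s has no assigned reads, skipped", blk.block_id)
            continue
        r = blk.region
        backbone = SequenceRecord(
            id=f"ul_{blk.block_id}",
            sequence=mixed.get(r.sequence_name).sequence[r.start : r.end],
        )
        bundles.append(
            BlockBundle(block=blk, reads=[reads[n] for n in names], backbone=backbone)
        )
    return bundles


def assemble_block(
    bundle: BlockBundle,
    builtin_min_depth: int = DEFAULT_BUILTIN_MIN_DEPTH,
    config: AlignerConfig | None = None,
) -> list[CandidateSequence]:
    """Backbone-guided consensus assembly of one bundle.

    Candidates are the maximal runs of backbone columns with read depth
    >= ``builtin_min_depth``; each column is spelled by the majority read
    vote (ties to the lexicographically first base), so uncovered backbone
    never leaks into a candidate.
    """
    if not bundle.reads:
        raise ValueError(f"empty bundle for block {bundle.block.block_id}")
    aligner = Aligner({bundle.backbone.id: bundle.backbone}, config or AlignerConfig())
    L = len(bundle.backbone.sequence)
    counts = np.zeros((L, 4), dtype=np.int32)
    read_extents: list[tuple[int, int, str]] = []
    for read in bundle.reads:
        recs = aligner.map(read)
        for rec in recs:
            if rec.alignment_type != "primary":
                continue
            qslice = _aligned_query_slice(rec, read)
            if len(qslice) != rec.target_end - rec.target_start:
                continue
            codes = np.frombuffer(qslice.encode("ascii"), dtype=np.uint8)
            code_arr = np.full(codes.size, -1, dtype=np.int8)
            for base, idx in _CODE.items():
                code_arr[codes == ord(base)] = idx
            valid = code_arr >= 0
            pos = np.arange(rec.target_start, rec.target_end)[valid]
            np.add.at(counts, (pos, code_arr[valid].astype(np.int64)), 1)
            read_extents.append((rec.target_start, rec.target_end, read.id))
    depth = counts.sum(axis=1)
    covered = depth >= builtin_min_depth
    maj = counts.argmax(axis=1)
    candidates: list[CandidateSequence] = []
    run_start = None
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    for idx in range(0, len(edges), 2):
        run_start, run_end = int(edges[idx]), int(edges[idx + 1])
        seq = "".join(_BASES[maj[p]] for p in range(run_start, run_end))
        provenance = sorted(
            {rid for s, e, rid in read_extents if s < run_end and run_start < e}
        )
        candidates.append(
            CandidateSequence(
                id=f"{bundle.block.block_id}.cand{idx // 2}",
                sequence=seq,
                block_id=bundle.block.block_id,
                read_provenance=provenance,
            )
        )
    log.info(
        "assemble | block %s: %d reads -> %d candidates",
        bundle.block.block_id, len(bundle.reads), len(candidates),
    )
    return candidates


def external_assembler_adapter(
    bundle: BlockBundle,
    command_template: str,
    workdir: "str | Path",
) -> list[CandidateSequence]:
    """Run an external assembler on one bundle.

    ``command_template`` must contain ``{reads}``, ``{ul}`` and ``{out}``
    placeholders; nonzero exit, a missing binary or empty output skips the
    block (logged) and the pipeline continues.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    bid = bundle.block.block_id
    reads_fa = workdir / f"block_{bid}.reads.fa"
    ul_fa = workdir / f"block_{bid}.ul.fa"
    out_fa = workdir / f"block_{bid}.raw.fa"
    write_sequences(bundle.reads, reads_fa)
    write_sequences([bundle.backbone], ul_fa)
    cmd = command_template.format(reads=str(reads_fa), ul=str(ul_fa), out=str(out_fa))
    try:
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
    except FileNotFoundError as exc:
        log.error("assemble | block %s: assembler not found (%s), skipped", bid, exc)
        return []
    if proc.returncode != 0:
        log.error(
            "assemble | block %s: assembler exit %d, skipped: %s",
            bid, proc.returncode, proc.stderr.strip()[:500],
        )
        return []
    if not out_fa.exists() or out_fa.stat().st_size == 0:
        log.error("assemble | block %s: assembler produced no output, skipped", bid)
        return []
    out = []
    for i, rec in enumerate(load_sequences(out_fa).values()):
        out.append(
            CandidateSequence(
                id=f"{bid}.ext{i}",
                sequence=rec.sequence,
                block_id=bid,
                read_provenance=["unknown-external"],
            )
        )
    return out
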