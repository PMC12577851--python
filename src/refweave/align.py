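"""Alignment backend: a builtin toy-scale gapless aligner plus a PAF adapter.

The builtin aligner finds exact k-mer anchors, groups them by (target,
strand, diagonal) — in a gapless model all anchors of one true locus share a
single diagonal, so collinear chaining reduces to diagonal voting — and then
extends each voted diagonal without gaps using an x-drop rule, counting
mismatches along the way.  It is adequate for high-accuracy (HiFi-like)
reads and for genome-to-genome comparison of closely related sequences; the
production path for anything else is externally produced PAF via
:func:`ingest_external`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .model import AlignmentRecord, SequenceRecord
from .seqio import PathLike, read_paf, reverse_complement

log = logging.getLogger("refweave")


@dataclass
class AlignerConfig:
    """Seed-and-extend parameters for the builtin aligner.

    ``mode`` mirrors the two-preset usage of production long-read mappers:
    read_to_genome (HiFi reads onto an assembly) vs genome_to_genome
    (assembly onto assembly), the latter raising the seed length and the
    allowed anchor gap.
    """

    k: int = 15
    min_chain_anchors: int = 3
    max_gap_between_anchors: int = 500
    mode: str = "read_to_genome"
    max_secondary: int = 5
    max_occurrences: int = 10
    xdrop: int = 30

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.min_chain_anchors < 1:
            raise ValueError("min_chain_anchors must be >= 1")
        if self.mode not in ("read_to_genome", "genome_to_genome"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def for_mode(cls, mode: str, **kw) -> "AlignerConfig":
        if mode == "genome_to_genome":
            kw.setdefault("k", 19)
            kw.setdefault("max_gap_between_anchors", 5000)
        return cls(mode=mode, **kw)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class Aligner:
    """Index a target sequence set once, then map queries against it."""

    def __init__(self, targets: Mapping[str, SequenceRecord] | Iterable[SequenceRecord],
                 config: AlignerConfig | None = None):
        if not isinstance(targets, Mapping):
            targets = {t.id: t for t in targets}
        if not targets:
            raise ValueError("empty target set")
        self.config = config or AlignerConfig()
        self.names: list[str] = list(targets)
        self.seqs: list[str] = [targets[n].sequence for n in self.names]
        self.arrays: list[np.ndarray] = [_encode(s) for s in self.seqs]
        self.lengths: list[int] = [len(s) for s in self.seqs]
        self._index = self._build_index()

    def _build_index(self) -> dict[str, list[tuple[int, int]]]:
        k = self.config.k
        index: dict[str, list[tuple[int, int]]] = {}
        for tidx, seq in enumerate(self.seqs):
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((tidx, pos))
        cap = self.config.max_occurrences
        return {km: hits for km, hits in index.items() if len(hits) <= cap}

    # -- anchoring ---------------------------------------------------------

    def _anchors(self, qseq: str) -> dict[tuple[int, int], list[int]]:
        """Map (target index, diagonal) -> [count, min qpos, max qpos]."""
        k = self.config.k
        stride = max(1, k // 3)
        clusters: dict[tuple[int, int], list[int]] = {}
        index = self._index
        for i in range(0, len(qseq) - k + 1, stride):
            hits = index.get(qseq[i : i + k])
            if not hits:
                continue
            for tidx, tpos in hits:
                key = (tidx, tpos - i)
                cl = clusters.get(key)
                if cl is None:
                    clusters[key] = [1, i, i]
                else:
                    cl[0] += 1
                    if i < cl[1]:
                        cl[1] = i
                    if i > cl[2]:
                        cl[2] = i
        return clusters

    @staticmethod
    def _xdrop_extent(m: np.ndarray, xdrop: int) -> int:
        """Length of the prefix of match-vector ``m`` kept by x-drop extension."""
        if m.size == 0:
            return 0
        score = np.where(m, 1, -2).cumsum()
        runmax = np.maximum.accumulate(score)
        bad = np.nonzero(runmax - score > xdrop)[0]
        stop = int(bad[0]) if bad.size else m.size
        if stop == 0:
            return 0
        best = int(np.argmax(score[:stop]))
        return best + 1 if score[best] > 0 else 0

    def map(self, query: SequenceRecord) -> list[AlignmentRecord]:
        cfg = self.config
        qlen = len(query.sequence)
        if qlen < cfg.k:
            log.debug("align | query %s shorter than k=%d, skipped", query.id, cfg.k)
            return []
        candidates: list[tuple[int, str, int, int, int, int]] = []
        strands = {"+": query.sequence, "-": reverse_complement(query.sequence)}
        for strand, qseq in strands.items():
            qarr = _encode(qseq)
            for (tidx, diag), (count, qmin, qmax) in self._anchors(qseq).items():
                if count < cfg.min_chain_anchors:
                    continue
                ext = self._extend(qarr, tidx, diag, qmin, qmax + cfg.k)
                if ext is not None:
                    qs_s, qs_e, matches = ext
                    candidates.append((tidx, strand, diag, qs_s, qs_e, matches))
        return self._finalize(query, candidates)

    def _extend(self, qarr: np.ndarray, tidx: int, diag: int,
                seed_lo: int, seed_hi: int) -> tuple[int, int, int] | None:
        tarr = self.arrays[tidx]
        lo = max(0, -diag)
        hi = min(qarr.size, tarr.size - diag)
        if hi - lo < self.config.k:
            return None
        m = qarr[lo:hi] == tarr[lo + diag : hi + diag]
        s0 = max(0, min(seed_lo - lo, m.size))
        s1 = max(0, min(seed_hi - lo, m.size))
        left = self._xdrop_extent(m[:s0][::-1], self.config.xdrop)
        right = self._xdrop_extent(m[s1:], self.config.xdrop)
        a, b = s0 - left, s1 + right
        if b <= a:
            return None
        matches = int(np.count_nonzero(m[a:b]))
        if matches < self.config.k * self.config.min_chain_anchors:
            return None
        return lo + a, lo + b, matches

    def _finalize(self, query: SequenceRecord,
                  candidates: list[tuple[int, str, int, int, int, int]]
                  ) -> list[AlignmentRecord]:
        if not candidates:
            return []
        qlen = len(query.sequence)
        # best-first; deterministic tie-break by target name then start
        candidates.sort(
            key=lambda c: (-c[5], self.names[c[0]], c[3] + c[2])
        )
        kept: list[tuple[int, str, int, int, int, int]] = []
        for cand in candidates:
            tidx, strand, diag, qs_s, qs_e, _ = cand
            redundant = False
            for other in kept:
                if other[0] != tidx:
                    continue
                t0, t1 = qs_s + diag, qs_e + diag
                o0, o1 = other[3] + other[2], other[4] + other[2]
                ovl = min(t1, o1) - max(t0, o0)
                if ovl > 0.5 * min(t1 - t0, o1 - o0):
                    redundant = True
                    break
            if not redundant:
                kept.append(cand)
        records = []
        best_matches = kept[0][5]
        second = kept[1][5] if len(kept) > 1 else None
        for rank, (tidx, strand, diag, qs_s, qs_e, matches) in enumerate(kept):
            if rank > self.config.max_secondary:
                break
            if strand == "+":
                q_start, q_end = qs_s, qs_e
            else:
                q_start, q_end = qlen - qs_e, qlen - qs_s
            mapq = 0
            if rank == 0:
                mapq = 60 if (second is None or best_matches > second) else 3
            records.append(
                AlignmentRecord(
                    query_name=query.id,
                    query_length=qlen,
                    query_start=q_start,
                    query_end=q_end,
                    strand=strand,
                    target_name=self.names[tidx],
                    target_length=self.lengths[tidx],
                    target_start=qs_s + diag,
                    target_end=qs_e + diag,
                    residue_matches=matches,
                    alignment_block_length=qs_e - qs_s,
                    mapping_quality=mapq,
                    alignment_type="primary" if rank == 0 else "secondary",
                )
            )
        return records


def align(
    queries: Iterable[SequenceRecord],
    target: Mapping[str, SequenceRecord] | Iterable[SequenceRecord],
    config: AlignerConfig | None = None,
) -> Iterator[AlignmentRecord]:
    """Map each query against the target set; exactly one primary per aligned query."""
    aligner = Aligner(target, config)
    for q in queries:
        yield from aligner.map(q)


def ingest_external(paf_path: PathLike) -> Iterator[AlignmentRecord]:
    """Adapter for externally produced alignments (e.g. minimap2 PAF output)."""
    yield from read_paf(paf_path)


def primary_only(records: Iterable[AlignmentRecord]) -> Iterator[AlignmentRecord]:
    for rec in records:
        if rec.alignment_type == "primary":
            yield rec


def best_primary_per_query(records: Iterable[AlignmentRecord]) -> dict[str, AlignmentRecord]:
    """Highest-scoring primary record per query (deterministic tie-break)."""
    best: dict[str, AlignmentRecord] = {}
    for rec in primary_only(records):
        cur = best.get(rec.query_name)
        if cur is None or (
            (rec.residue_matches, cur.target_name, cur.target_start)
            > (cur.residue_matches, rec.target_name, rec.target_start)
        ):
            best[rec.query_name] = rec
    return best
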