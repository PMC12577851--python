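"""Block discovery on the mixed genome.

Two paths, matching the two reference scenarios:

* same species — contigs are scaffolded against the mixed genome by
  homology, and high-identity collinear alignments near each scaffold gap
  define gap-flank blocks;
* related species — no reliable gap prediction exists, so blocks are the
  merged footprints of near-full-length primary HiFi read alignments.

Blocks are the units handed to localized assembly.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from .align import best_primary_per_query
from .model import (
    AlignmentBlock,
    AlignmentRecord,
    GenomicInterval,
    MixedGenome,
    ScaffoldComponent,
    ScaffoldPlan,
)

log = logging.getLogger("refweave")

DEFAULT_FLANK = 500_000
DEFAULT_MIN_BLOCK_LENGTH = 20_000
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_READ_FRACTION = 0.99


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]], distance: int = 0
) -> list[tuple[str, int, int, int]]:
    """Union of intervals, joining neighbours separated by <= ``distance`` bp.

    Returns (sequence_name, start, end, n_merged) sorted by position.
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for name, start, end in intervals:
        by_seq.setdefault(name, []).append((start, end))
    out: list[tuple[str, int, int, int]] = []
    for name in sorted(by_seq):
        ivs = sorted(by_seq[name])
        cur_s, cur_e = ivs[0]
        n = 1
        for s, e in ivs[1:]:
            if s - cur_e <= distance:
                cur_e = max(cur_e, e)
                n += 1
            else:
                out.append((name, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        out.append((name, cur_s, cur_e, n))
    return out


def homology_scaffold(
    contigs: Mapping[str, object],
    mixed: MixedGenome,
    alignments: Iterable[AlignmentRecord],
    min_placement_fraction: float = 0.5,
    default_gap: int = 1,
) -> ScaffoldPlan:
    """Order and orient contigs along the mixed genome by their primary placement.

    A contig is placed when its primary alignment covers at least
    ``min_placement_fraction`` of its length; placements are sorted by
    midpoint per mixed sequence, and the gap after each contig is the
    distance to the next placement, floored at ``default_gap`` (so touching
    or overlapping placements still record a minimal gap).
    """
    best = best_primary_per_query(alignments)
    placements: dict[str, list[tuple[float, str, int, int, str]]] = {}
    plan = ScaffoldPlan()
    for name in contigs:
        rec = best.get(name)
        if rec is None or rec.query_span_fraction < min_placement_fraction:
            plan.unplaced.append(name)
            continue
        mid = (rec.target_start + rec.target_end) / 2
        placements.setdefault(rec.target_name, []).append(
            (mid, name, rec.target_start, rec.target_end, rec.strand)
        )
        plan.provenance[name] = (rec.target_name, rec.target_start, rec.target_end, rec.strand)
    if not placements:
        raise RuntimeError("zero placeable contigs")
    for tname in sorted(placements):
        placed = sorted(placements[tname])
        comps: list[ScaffoldComponent] = []
        for i, (_, cname, tstart, tend, strand) in enumerate(placed):
            gap = None
            if i + 1 < len(placed):
                gap = max(default_gap, placed[i + 1][2] - tend)
            comps.append(
                ScaffoldComponent(
                    contig_name=cname,
                    contig_length=len(contigs[cname].sequence),
                    orientation=strand,
                    gap_length_after=gap,
                )
            )
        plan.scaffolds[f"scaffold_{tname}"] = comps
    log.info(
        "blocks | scaffolded %d contigs into %d scaffolds (%d unplaced, %d gaps)",
        len(plan.placed_contigs()), len(plan.scaffolds), len(plan.unplaced), plan.n_gaps(),
    )
    return plan


def _plan_gap_intervals(plan: ScaffoldPlan) -> list[tuple[str, str, int, int]]:
    """Gaps projected onto the mixed genome: (gap_id, mixed_name, start, end)."""
    out = []
    for scaffold, comps in plan.scaffolds.items():
        for i, (left, right) in enumerate(zip(comps, comps[1:])):
            if left.gap_length_after is None:
                continue
            lprov = plan.provenance[left.contig_name]
            rprov = plan.provenance[right.contig_name]
            gap_start = lprov[2]
            gap_end = max(rprov[1], gap_start + 1)
            out.append((f"{scaffold}:gap{i}", lprov[0], gap_start, gap_end))
    return out


def gap_flank_blocks(
    plan: ScaffoldPlan,
    collinear: Iterable[AlignmentRecord],
    mixed_lengths: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_block_length: int = DEFAULT_MIN_BLOCK_LENGTH,
) -> list[AlignmentBlock]:
    """High-identity collinear footprints within ``flank`` bp of each scaffold gap.

    Windows of neighbouring gaps whose retained footprints touch are merged
    into one block carrying both gap ids.
    """
    gaps = _plan_gap_intervals(plan)
    if not gaps:
        log.warning("blocks | no gaps; nothing to improve")
        return []
    retained = [
        rec
        for rec in collinear
        if rec.identity >= min_identity
    ]
    piece_gap_ids: dict[tuple[str, int, int], set[str]] = {}
    support: dict[tuple[str, int, int], int] = {}
    for gap_id, mname, gstart, gend in gaps:
        seqlen = mixed_lengths[mname]
        w0 = max(0, gstart - flank)
        w1 = min(seqlen, gend + flank)
        # the gap's own projection belongs to the block: the extracted
        # backbone must cross the gap for localized assembly to close it
        gpiece = (mname, gstart, min(gend, seqlen))
        piece_gap_ids.setdefault(gpiece, set()).add(gap_id)
        support.setdefault(gpiece, 0)
        for rec in retained:
            if rec.target_name != mname:
                continue
            s = max(rec.target_start, w0)
            e = min(rec.target_end, w1)
            if e > s:
                key = (mname, s, e)
                piece_gap_ids.setdefault(key, set()).add(gap_id)
                support[key] = max(support.get(key, 0), 1)
    blocks: list[AlignmentBlock] = []
    merged = merge_intervals(piece_gap_ids, distance=0)
    for mname, s, e, _ in merged:
        if e - s < min_block_length:
            continue
        ids: set[str] = set()
        n_support = 0
        for (pn, ps, pe), gids in piece_gap_ids.items():
            if pn == mname and ps < e and s < pe:
                ids.update(gids)
                n_support += support[(pn, ps, pe)]
        blocks.append(
            AlignmentBlock(
                region=GenomicInterval(mname, s, e),
                source="gap_flank",
                gap_id=",".join(sorted(ids)),
                support=n_support,
            )
        )
    blocks.sort(key=lambda b: (b.region.sequence_name, b.region.start))
    log.info("blocks | %d gap-flank blocks from %d gaps", len(blocks), len(gaps))
    return blocks


def read_support_blocks(
    read_alignments: Iterable[AlignmentRecord],
    min_read_fraction: float = DEFAULT_MIN_READ_FRACTION,
    merge_distance: int = 0,
    min_block_length: int = DEFAULT_MIN_BLOCK_LENGTH,
    length_metric: str = "span",
) -> list[AlignmentBlock]:
    """Merged footprints of primary, near-full-length read alignments.

    A record is retained when it is the read's primary alignment and its
    aligned length covers >= ``min_read_fraction`` of the read —
    ``length_metric`` selects whether "aligned length" means the query span
    or the matched residues.
    """
    if length_metric not in ("span", "matches"):
        raise ValueError(f"unknown length metric {length_metric!r}")
    pieces = []
    for rec in read_alignments:
        if rec.alignment_type != "primary":
            continue
        frac = (
            rec.query_span_fraction
            if length_metric == "span"
            else rec.residue_matches / rec.query_length
        )
        if frac < min_read_fraction:
            continue
        pieces.append((rec.target_name, rec.target_start, rec.target_end))
    if not pieces:
        log.warning("blocks | zero read alignments survive the %.2f rule", min_read_fraction)
        return []
    blocks = [
        AlignmentBlock(
            region=GenomicInterval(name, s, e), source="read_support", support=n
        )
        for name, s, e, n in merge_intervals(pieces, distance=merge_distance)
        if e - s >= min_block_length
    ]
    blocks.sort(key=lambda b: (b.region.sequence_name, b.region.start))
    log.info("blocks | %d read-support blocks from %d alignments", len(blocks), len(pieces))
    return blocks
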