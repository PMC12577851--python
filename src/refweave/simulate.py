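"""Truth-labelled synthetic instances for every pipeline stage.

The generator emulates, at desk scale, the structure the pipeline assumes in
the wild: a truth genome with diverged repeat copies, a same- or
related-species reference derived from it by substitution, a fragmented
contig assembly whose planted gaps sit inside repeats (the failure mode gaps
are typically attributed to), HiFi-like reads (long, ~99.8% accurate), and
optionally one cross-sequence misjoin emulating a chromosome-fusion
assembly error.  Everything is substitution-only, matching the gapless toy
aligner and polisher, and byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .model import GenomicInterval, SequenceRecord
from .seqio import reverse_complement, write_sequences

log = logging.getLogger("refweave")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic instance.

    Defaults describe the standard same-species scenario: a 200 kb single
    sequence genome, four diverged 5 kb repeat copies, a reference 0.5%
    diverged from the truth, 30x HiFi-like reads (mean 9 kb, sd 1.5 kb,
    0.2% substitution error) and two 8 kb assembly gaps planted inside
    repeats.
    """

    genome_length: int = 200_000
    n_sequences: int = 1
    repeat_count: int = 4
    repeat_length: int = 5_000
    repeat_copy_divergence: float = 0.01
    divergence: float = 0.005  # reference vs truth; related-species ~0.03-0.08
    read_mean_length: int = 9_000
    read_length_sd: int = 1_500
    read_min_length: int = 1_000
    read_error_rate: float = 0.002
    depth: float = 30.0
    n_gaps: int = 2
    gap_length: int = 8_000
    gaps_in_repeats: bool = True
    misjoin: bool = False
    shuffle_contigs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.divergence, self.read_error_rate, self.repeat_copy_divergence):
            if not (0 <= rate < 1):
                raise ValueError("rates must lie in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_gaps and self.gap_length * 3 * self.n_gaps > self.genome_length:
            raise ValueError("gaps too long for the genome")
        if self.misjoin and self.n_sequences < 2:
            raise ValueError("a misjoin needs at least two truth sequences")


@dataclass
class TruthSet:
    """A synthetic instance plus the labels the test oracles need."""

    truth_genome: dict[str, SequenceRecord]
    reference: dict[str, SequenceRecord]
    contigs: dict[str, SequenceRecord]
    reads: dict[str, SequenceRecord]
    read_sources: dict[str, tuple[str, int, int, str]]
    gap_coords: list[GenomicInterval]
    contig_sources: dict[str, tuple[str, int, int, str]]
    repeat_coords: list[GenomicInterval] = field(default_factory=list)
    misjoin_coords: Optional[dict] = None
    config: Optional[SimulationConfig] = None


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability ``rate``."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.int8)) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_instance(cfg: SimulationConfig) -> TruthSet:
    """Generate one deterministic truth-labelled instance."""
    rng = np.random.default_rng(cfg.seed)
    seq_names = [f"chr{i + 1}" for i in range(cfg.n_sequences)]

    # truth genome with planted, slightly diverged repeat copies
    truth_codes: dict[str, np.ndarray] = {}
    repeat_coords: list[GenomicInterval] = []
    unit = _random_codes(rng, cfg.repeat_length)
    for name in seq_names:
        codes = _random_codes(rng, cfg.genome_length)
        margin = max(cfg.gap_length, 25_000)
        if cfg.repeat_count and cfg.genome_length > 2 * margin + cfg.repeat_length:
            slots = np.linspace(
                margin, cfg.genome_length - margin - cfg.repeat_length,
                cfg.repeat_count,
            ).astype(int)
            jitter = rng.integers(-2000, 2001, size=cfg.repeat_count)
            for pos in np.clip(slots + jitter, margin,
                               cfg.genome_length - margin - cfg.repeat_length):
                copy = _mutate(unit, cfg.repeat_copy_divergence, rng)
                codes[pos : pos + cfg.repeat_length] = copy
                repeat_coords.append(GenomicInterval(name, int(pos), int(pos + cfg.repeat_length)))
        truth_codes[name] = codes

    reference = {
        name: SequenceRecord(id=name, sequence=_to_str(_mutate(c, cfg.divergence, rng)))
        for name, c in truth_codes.items()
    }

    # planted assembly gaps (inside repeats by default)
    gap_coords: list[GenomicInterval] = []
    n_gaps = 0 if cfg.misjoin else cfg.n_gaps
    if n_gaps:
        if cfg.gaps_in_repeats:
            if n_gaps > len(repeat_coords):
                raise ValueError("more gaps requested than repeat copies planted")
            picked = rng.choice(len(repeat_coords), size=n_gaps, replace=False)
            for idx in sorted(int(i) for i in picked):
                rc = repeat_coords[idx]
                center = (rc.start + rc.end) // 2
                s = max(0, center - cfg.gap_length // 2)
                e = min(cfg.genome_length, s + cfg.gap_length)
                gap_coords.append(GenomicInterval(rc.sequence_name, s, e))
        else:
            per_seq = max(1, n_gaps // cfg.n_sequences)
            for name in seq_names:
                lo, hi = 30_000, cfg.genome_length - 30_000 - cfg.gap_length
                starts = np.sort(rng.integers(lo, hi, size=per_seq))
                for s in starts:
                    gap_coords.append(GenomicInterval(name, int(s), int(s + cfg.gap_length)))
                if len(gap_coords) >= n_gaps:
                    break
        gap_coords.sort()

    # contigs: truth fragments that omit the gap segments; optional misjoin
    pieces: list[tuple[str, int, int]] = []  # (seq, start, end) on truth
    misjoin_coords = None
    if cfg.misjoin:
        # one contig fuses interior segments of two different sequences,
        # emulating a cross-chromosome fusion assembly error; the second
        # sequence's fused segment is covered by no correct contig
        s0, s1 = seq_names[0], seq_names[1]
        l = cfg.genome_length
        a, b0, b1 = int(0.4 * l), int(0.75 * l), int(0.65 * l)
        pieces.extend([(s0, 0, a), (s0, b0, l), (s1, 0, a), (s1, b1, l)])
        fused = np.concatenate([truth_codes[s0][a:b0], truth_codes[s1][a:b1]])
        misjoin_coords = {
            "left": (s0, a, b0),
            "right": (s1, a, b1),
            "junction_truth": [(s0, b0), (s1, a), (s1, b1)],
            "junction_offset": b0 - a,
        }
        for name in seq_names[2:]:
            pieces.append((name, 0, cfg.genome_length))
    else:
        for name in seq_names:
            cursor = 0
            for gap in [g for g in gap_coords if g.sequence_name == name]:
                if gap.start > cursor:
                    pieces.append((name, cursor, gap.start))
                cursor = gap.end
            if cursor < cfg.genome_length:
                pieces.append((name, cursor, cfg.genome_length))

    order = list(range(len(pieces)))
    orientations = ["+"] * len(pieces)
    if cfg.shuffle_contigs:
        rng.shuffle(order)
        flips = rng.random(len(pieces)) < 0.5
        orientations = ["-" if f else "+" for f in flips]

    contigs: dict[str, SequenceRecord] = {}
    contig_sources: dict[str, tuple[str, int, int, str]] = {}
    fused_seq = _to_str(fused) if cfg.misjoin else None
    for rank, piece_idx in enumerate(order):
        name, s, e = pieces[piece_idx]
        cname = f"ctg{rank + 1:04d}"
        seq = _to_str(truth_codes[name][s:e])
        strand = orientations[piece_idx]
        if strand == "-":
            seq = reverse_complement(seq)
        contigs[cname] = SequenceRecord(id=cname, sequence=seq)
        contig_sources[cname] = (name, s, e, strand)
    if cfg.misjoin:
        cname = f"ctg{len(order) + 1:04d}"
        contigs[cname] = SequenceRecord(id=cname, sequence=fused_seq)
        contig_sources[cname] = ("misjoin", 0, len(fused_seq), "+")
        misjoin_coords["contig"] = cname

    # HiFi-like reads with recorded source coordinates
    reads: dict[str, SequenceRecord] = {}
    read_sources: dict[str, tuple[str, int, int, str]] = {}
    total_target = cfg.depth * sum(len(c) for c in truth_codes.values())
    weights = np.array([len(truth_codes[n]) for n in seq_names], dtype=float)
    weights /= weights.sum()
    total = 0
    i = 0
    while total < total_target:
        name = seq_names[int(rng.choice(len(seq_names), p=weights))]
        codes = truth_codes[name]
        length = int(np.clip(
            round(rng.normal(cfg.read_mean_length, cfg.read_length_sd)),
            cfg.read_min_length, len(codes),
        ))
        start = int(rng.integers(0, len(codes) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rcodes = _mutate(codes[start : start + length], cfg.read_error_rate, rng)
        seq = _to_str(rcodes)
        if strand == "-":
            seq = reverse_complement(seq)
        rid = f"read{i + 1:06d}"
        reads[rid] = SequenceRecord(id=rid, sequence=seq)
        read_sources[rid] = (name, start, start + length, strand)
        total += length
        i += 1
    log.info("simulate | %d reads (%.1fx), %d contigs, %d gaps",
             len(reads), total / sum(len(c) for c in truth_codes.values()),
             len(contigs), len(gap_coords))

    return TruthSet(
        truth_genome={n: SequenceRecord(id=n, sequence=_to_str(c))
                      for n, c in truth_codes.items()},
        reference=reference,
        contigs=contigs,
        reads=reads,
        read_sources=read_sources,
        gap_coords=gap_coords,
        contig_sources=contig_sources,
        repeat_coords=repeat_coords,
        misjoin_coords=misjoin_coords,
        config=cfg,
    )


PRESETS: dict[str, dict] = {
    "same-species": {},
    "related-species": {"divergence": 0.05},
    "misjoin": {
        "n_sequences": 2,
        "genome_length": 100_000,
        "repeat_count": 2,
        "misjoin": True,
        "n_gaps": 0,
    },
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


def write_instance(ts: TruthSet, outdir: "str | Path") -> None:
    """truth.fa, ref.fa, contigs.fa, reads.fq.gz and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sequences(ts.truth_genome.values(), outdir / "truth.fa")
    write_sequences(ts.reference.values(), outdir / "ref.fa")
    write_sequences(ts.contigs.values(), outdir / "contigs.fa")
    write_sequences(ts.reads.values(), outdir / "reads.fq.gz", format="fastq")
    payload = {
        "gap_coords": [
            [g.sequence_name, g.start, g.end] for g in ts.gap_coords
        ],
        "repeat_coords": [
            [g.sequence_name, g.start, g.end] for g in ts.repeat_coords
        ],
        "read_sources": {k: list(v) for k, v in ts.read_sources.items()},
        "contig_sources": {k: list(v) for k, v in ts.contig_sources.items()},
        "misjoin_coords": ts.misjoin_coords,
    }
    with open(outdir / "truth.json", "wt") as fh:
        json.dump(payload, fh, indent=1)
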