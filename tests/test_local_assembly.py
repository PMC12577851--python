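import sys

import numpy as np
import pytest

from refweave.align import Aligner, AlignerConfig
from refweave.local_assembly import (
    assemble_block,
    external_assembler_adapter,
    partition_reads,
)
from refweave.model import (
    AlignmentBlock,
    BlockBundle,
    GenomicInterval,
    MixedGenome,
    SequenceRecord,
)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _tile(genome, length, step, prefix="r"):
    reads = []
    for i, start in enumerate(range(0, len(genome) - length + 1, step)):
        reads.append(SequenceRecord(f"{prefix}{i}", genome[start : start + length]))
    return reads


def _tile2(genome, length, step, prefix="r"):
    """Tiling with duplicated end reads so every column has depth >= 2."""
    reads = _tile(genome, length, step, prefix)
    reads.append(SequenceRecord(f"{prefix}_head", genome[:length]))
    reads.append(SequenceRecord(f"{prefix}_tail", genome[-length:]))
    return reads


@pytest.fixture(scope="module")
def backbone_world():
    rng = np.random.default_rng(40)
    genome = _random_seq(rng, 60_000)
    mixed = MixedGenome(sequences={"g": SequenceRecord("g", genome)})
    return rng, genome, mixed


class TestPartitionReads:
    def _blocks(self):
        return [
            AlignmentBlock(GenomicInterval("g", 10_000, 25_000), "read_support"),
            AlignmentBlock(GenomicInterval("g", 40_000, 55_000), "read_support"),
        ]

    def test_assignment_matches_bruteforce_oracle(self, backbone_world):
        rng, genome, mixed = backbone_world
        rng2 = np.random.default_rng(41)
        reads, sources = {}, {}
        for i in range(120):
            start = int(rng2.integers(0, 55_000))
            length = int(rng2.integers(2_000, 5_000))
            length = min(length, 60_000 - start)
            rid = f"r{i}"
            reads[rid] = SequenceRecord(rid, genome[start : start + length])
            sources[rid] = (start, start + length)
        blocks = self._blocks()
        aligner = Aligner(mixed.sequences, AlignerConfig())
        alns = [rec for r in reads.values() for rec in aligner.map(r)]
        bundles = partition_reads(alns, blocks, reads, mixed)
        got = {b.block.block_id: {r.id for r in b.reads} for b in bundles}
        # oracle: interval overlap of the recorded source against each block
        expect = {b.block_id: set() for b in blocks}
        for rid, (s, e) in sources.items():
            for b in blocks:
                if s < b.region.end and b.region.start < e:
                    expect[b.block_id].add(rid)
                    break
        assert {k: v for k, v in expect.items() if v} == got

    def test_one_bp_overlap_is_assigned(self, backbone_world):
        _, genome, mixed = backbone_world
        block = AlignmentBlock(GenomicInterval("g", 10_000, 25_000), "read_support")
        # read ends exactly 1 bp inside the block
        read = SequenceRecord("edge", genome[6_001:10_001])
        aligner = Aligner(mixed.sequences, AlignerConfig())
        bundles = partition_reads(
            aligner.map(read), [block], {"edge": read}, mixed
        )
        assert bundles and bundles[0].reads[0].id == "edge"

    def test_backbone_is_mixed_substring(self, backbone_world):
        _, genome, mixed = backbone_world
        block = AlignmentBlock(GenomicInterval("g", 10_000, 25_000), "read_support")
        read = SequenceRecord("r", genome[12_000:18_000])
        aligner = Aligner(mixed.sequences, AlignerConfig())
        (bundle,) = partition_reads(aligner.map(read), [block], {"r": read}, mixed)
        assert bundle.backbone.sequence == genome[10_000:25_000]


def _bundle(genome, start, end, reads):
    block = AlignmentBlock(GenomicInterval("g", start, end), "read_support")
    return BlockBundle(
        block=block,
        reads=reads,
        backbone=SequenceRecord(f"ul_{block.block_id}", genome[start:end]),
    )


class TestAssembleBlock:
    def test_consensus_fixed_point_on_tiling_reads(self, backbone_world):
        _, genome, _ = backbone_world
        piece = genome[10_000:30_000]
        reads = _tile2(piece, 4_000, 1_000)
        cands = assemble_block(_bundle(genome, 10_000, 30_000, reads))
        assert len(cands) == 1
        assert cands[0].sequence == piece
        assert set(cands[0].read_provenance) == {r.id for r in reads}

    def test_uncovered_center_splits_candidates(self, backbone_world):
        _, genome, _ = backbone_world
        # reads tile two flanks; the central 5 kb is absent from every read
        left = _tile2(genome[10_000:20_000], 4_000, 1_000, prefix="L")
        right = _tile2(genome[25_000:35_000], 4_000, 1_000, prefix="R")
        cands = assemble_block(_bundle(genome, 10_000, 35_000, left + right))
        assert len(cands) == 2
        assert cands[0].sequence == genome[10_000:20_000]
        assert cands[1].sequence == genome[25_000:35_000]
        assert {r.id for r in left} == set(cands[0].read_provenance)

    def test_read_alleles_win_over_backbone(self, backbone_world):
        rng, genome, _ = backbone_world
        rng2 = np.random.default_rng(43)
        piece = list(genome[10_000:30_000])
        positions = sorted(rng2.choice(np.arange(500, 19_500), 20, replace=False))
        for p in positions:
            piece[p] = "ACGT"[("ACGT".index(piece[p]) + 1) % 4]
        read_truth = "".join(piece)  # reads carry 20 SNPs vs the backbone
        reads = _tile2(read_truth, 4_000, 130)  # ~30x
        cands = assemble_block(_bundle(genome, 10_000, 30_000, reads))
        assert len(cands) == 1
        hits = sum(cands[0].sequence[p] == read_truth[p] for p in positions)
        assert hits >= 19

    def test_no_base_without_coverage(self, backbone_world):
        _, genome, _ = backbone_world
        reads = _tile(genome[12_000:18_000], 3_000, 1_500)
        cands = assemble_block(_bundle(genome, 10_000, 30_000, reads))
        total = sum(len(c.sequence) for c in cands)
        assert total <= 6_000  # never exceeds the read-covered span

    def test_reproducible(self, backbone_world):
        _, genome, _ = backbone_world
        reads = _tile(genome[10_000:25_000], 4_000, 900)
        a = assemble_block(_bundle(genome, 10_000, 25_000, reads))
        b = assemble_block(_bundle(genome, 10_000, 25_000, reads))
        assert [(c.id, c.sequence, c.read_provenance) for c in a] == [
            (c.id, c.sequence, c.read_provenance) for c in b]

    def test_empty_bundle_rejected(self, backbone_world):
        _, genome, _ = backbone_world
        with pytest.raises(ValueError, match="empty bundle"):
            assemble_block(_bundle(genome, 0, 10_000, []))


class TestExternalAdapter:
    def test_identity_stub(self, backbone_world, tmp_path):
        _, genome, _ = backbone_world
        reads = _tile(genome[0:10_000], 3_000, 2_000)
        bundle = _bundle(genome, 0, 10_000, reads)
        cands = external_assembler_adapter(bundle, "cp {reads} {out}", tmp_path)
        assert [c.sequence for c in cands] == [r.sequence for r in reads]
        assert all(c.read_provenance == ["unknown-external"] for c in cands)

    def test_missing_binary_skips_block(self, backbone_world, tmp_path):
        _, genome, _ = backbone_world
        bundle = _bundle(genome, 0, 10_000, _tile(genome[:10_000], 3_000, 2_000))
        out = external_assembler_adapter(
            bundle, "definitely-not-a-binary {reads} {ul} {out}", tmp_path)
        assert out == []

    def test_nonzero_exit_skips_block(self, backbone_world, tmp_path):
        _, genome, _ = backbone_world
        bundle = _bundle(genome, 0, 10_000, _tile(genome[:10_000], 3_000, 2_000))
        out = external_assembler_adapter(bundle, "false {reads} {ul} {out}", tmp_path)
        assert out == []

    def test_self_adapter_matches_builtin(self, backbone_world, tmp_path):
        """Builtin backend exposed as a shell command gives identical sequences."""
        _, genome, _ = backbone_world
        reads = _tile(genome[10_000:25_000], 4_000, 900)
        bundle = _bundle(genome, 10_000, 25_000, reads)
        builtin = assemble_block(bundle)
        helper = tmp_path / "wrap.py"
        helper.write_text(
            "import sys\n"
            "from refweave.local_assembly import assemble_block\n"
            "from refweave.model import AlignmentBlock, BlockBundle, GenomicInterval\n"
            "from refweave.seqio import load_sequences, write_sequences\n"
            "reads_fa, ul_fa, out_fa = sys.argv[1:4]\n"
            "reads = list(load_sequences(reads_fa).values())\n"
            "(ul,) = load_sequences(ul_fa).values()\n"
            "block = AlignmentBlock(GenomicInterval('g', 0, len(ul.sequence)), 'x')\n"
            "bundle = BlockBundle(block=block, reads=reads, backbone=ul)\n"
            "write_sequences((c.as_record() for c in assemble_block(bundle)), out_fa)\n"
        )
        cands = external_assembler_adapter(
            bundle, f"{sys.executable} {helper} {{reads}} {{ul}} {{out}}", tmp_path)
        assert [c.sequence for c in cands] == [c.sequence for c in builtin]
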