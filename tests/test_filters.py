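import numpy as np
import pytest

from refweave.filters import (
    FilterConfig,
    coverage_breakpoint_filter,
    depth_profile,
    find_breakpoints,
    identity_filter,
    identity_verdict,
    length_filter,
    provenance_audit,
)
from refweave.model import CandidateSequence, SequenceRecord


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _tile(genome, length, step, prefix="r"):
    out = {}
    for i, start in enumerate(range(0, len(genome) - length + 1, step)):
        out[f"{prefix}{i}"] = SequenceRecord(f"{prefix}{i}", genome[start : start + length])
    out[f"{prefix}_head"] = SequenceRecord(f"{prefix}_head", genome[:length])
    out[f"{prefix}_tail"] = SequenceRecord(f"{prefix}_tail", genome[-length:])
    return out


@pytest.fixture(scope="module")
def world():
    rng = np.random.default_rng(50)
    genome = _random_seq(rng, 60_000)
    return rng, genome


def _cand(seq, cid="cand", block="b"):
    return CandidateSequence(id=cid, sequence=seq, block_id=block)


class TestCoverageBreakpointFilter:
    def test_tiled_candidate_passes(self, world):
        _, genome = world
        piece = genome[10_000:40_000]
        reads = _tile(piece, 4_000, 1_000)
        cand = _cand(piece)
        out = coverage_breakpoint_filter([cand], reads, FilterConfig())
        assert out == [cand] and cand.verdicts["coverage"] == "pass"

    def test_foreign_insert_fails(self, world):
        rng, genome = world
        piece = genome[10_000:40_000]
        reads = _tile(piece, 4_000, 1_000)
        rng2 = np.random.default_rng(51)
        foreign = _random_seq(rng2, 2_000)
        chimera = piece[:15_000] + foreign + piece[15_000:]
        cand = _cand(chimera, cid="chimera")
        out = coverage_breakpoint_filter([cand], reads, FilterConfig())
        assert out == []
        assert cand.verdicts["coverage"] == "fail"
        assert "breakpoint" in cand.fail_reasons["coverage"]

    def test_unaligned_candidate_fails_uncovered(self, world):
        rng, genome = world
        reads = _tile(genome[:20_000], 4_000, 1_000)
        rng2 = np.random.default_rng(52)
        cand = _cand(_random_seq(rng2, 10_000), cid="alien")
        out = coverage_breakpoint_filter([cand], reads, FilterConfig())
        assert out == [] and cand.fail_reasons["coverage"] == "uncovered"

    def test_depth_profile_matches_bruteforce(self, world):
        _, genome = world
        piece = genome[10_000:20_000]
        reads = {}
        brute = np.zeros(len(piece), dtype=int)
        for i, (s, ln) in enumerate(
            [(0, 3000), (1500, 2500), (2000, 4000), (5500, 3000), (6000, 4000),
             (500, 2000), (7000, 3000), (3000, 3500), (4200, 2200), (100, 3300)]
        ):
            reads[f"r{i}"] = SequenceRecord(f"r{i}", piece[s : s + ln])
            brute[s : s + ln] += 1
        depth = depth_profile(_cand(piece), list(reads.values()))
        assert np.array_equal(depth, brute)

    def test_idempotent(self, world):
        _, genome = world
        piece = genome[10_000:30_000]
        reads = _tile(piece, 4_000, 1_000)
        cfg = FilterConfig()
        once = coverage_breakpoint_filter([_cand(piece)], reads, cfg)
        twice = coverage_breakpoint_filter(list(once), reads, cfg)
        assert [c.id for c in once] == [c.id for c in twice]


class TestFindBreakpoints:
    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            depth = rng.integers(0, 4, size=500)
            min_depth = int(rng.integers(1, 3))
            max_run = int(rng.integers(0, 5))
            edge = int(rng.integers(0, 100))
            got = find_breakpoints(depth, min_depth, max_run, edge)
            # brute force: scan runs inside the internal zone
            lo, hi = edge, max(edge, 500 - edge)
            runs, s = [], None
            for i in range(lo, hi):
                if depth[i] < min_depth:
                    if s is None:
                        s = i
                else:
                    if s is not None and i - s > max_run:
                        runs.append((s, i))
                    s = None
            if s is not None and hi - s > max_run:
                runs.append((s, hi))
            assert got == runs


class TestIdentityFilter:
    def test_exact_substring_fails_identical(self, world):
        _, genome = world
        contigs = {"c": SequenceRecord("c", genome[:40_000])}
        cand = _cand(genome[5_000:35_000])
        out = identity_filter([cand], contigs, FilterConfig())
        assert out == []
        assert cand.fail_reasons["identity"].startswith("identical")

    def test_unrelated_sequence_fails_divergent(self, world):
        rng, genome = world
        contigs = {"c": SequenceRecord("c", genome[:40_000])}
        rng2 = np.random.default_rng(54)
        cand = _cand(_random_seq(rng2, 30_000))
        out = identity_filter([cand], contigs, FilterConfig())
        assert out == []
        assert cand.fail_reasons["identity"].startswith("divergent")

    def test_gap_spanner_passes(self, world):
        rng, genome = world
        # two contigs flank an 8 kb region absent from both; the candidate
        # spans it — exactly the survivor class the pipeline wants
        contigs = {
            "left": SequenceRecord("left", genome[:26_000]),
            "right": SequenceRecord("right", genome[34_000:]),
        }
        cand = _cand(genome[10_000:50_000])
        out = identity_filter([cand], contigs, FilterConfig())
        assert out == [cand] and cand.verdicts["identity"] == "pass"

    def test_related_mode_skips(self, world):
        _, genome = world
        contigs = {"c": SequenceRecord("c", genome[:40_000])}
        cand = _cand(genome[5_000:35_000])
        out = identity_filter([cand], contigs, FilterConfig(), mode="related")
        assert out == [cand] and cand.verdicts["identity"] == "not_run"

    def test_decision_rule_matches_bruteforce(self):
        rng = np.random.default_rng(55)
        cfg = FilterConfig()
        for _ in range(1000):
            i = float(rng.random())
            c = float(rng.random())
            passed, _ = identity_verdict(i, c, cfg)
            expect = not (
                (i >= cfg.identity_ceiling and c >= cfg.containment_fraction)
                or i < cfg.identity_floor
            )
            assert passed == expect


class TestLengthFilter:
    @pytest.mark.parametrize("length,passes", [(49_999, False), (50_000, True)])
    def test_boundary(self, length, passes):
        cand = _cand("A" * length)
        out = length_filter([cand], FilterConfig())
        assert (out == [cand]) is passes

    def test_matches_threshold_scan(self):
        rng = np.random.default_rng(56)
        lengths = rng.integers(1, 120_000, size=1000)
        cands = [_cand("A" * int(n), cid=f"c{i}") for i, n in enumerate(lengths)]
        out = length_filter(cands, FilterConfig())
        assert {c.id for c in out} == {
            f"c{i}" for i, n in enumerate(lengths) if n >= 50_000}

    def test_monotone_in_min_output_length(self):
        rng = np.random.default_rng(57)
        lengths = [int(n) for n in rng.integers(1, 100_000, size=200)]
        prev = None
        for thr in (10_000, 30_000, 60_000, 90_000):
            cands = [_cand("A" * n, cid=f"c{i}") for i, n in enumerate(lengths)]
            out = {c.id for c in length_filter(cands, FilterConfig(min_output_length=thr))}
            if prev is not None:
                assert out <= prev
            prev = out


class TestProvenanceAudit:
    def test_clean_contig_full_attribution(self, world):
        _, genome = world
        contig = {"asm1": SequenceRecord("asm1", genome[10_000:40_000])}
        reads = _tile(genome[10_000:40_000], 4_000, 1_000)
        alts = {"alt1": SequenceRecord("alt1", genome[10_000:40_000])}
        (rep,) = provenance_audit(contig, reads, alts,
                                  provenance={"asm1": list(reads)})
        assert rep.original_read_fraction == 1.0
        assert not rep.flagged

    def test_injected_alt_sequence_flagged(self, world):
        _, genome = world
        contig = {"asm1": SequenceRecord("asm1", genome[10_000:40_000])}
        reads = _tile(genome[10_000:40_000], 4_000, 1_000)
        alts = {"alt1": SequenceRecord("alt1", genome[10_000:40_000])}
        (rep,) = provenance_audit(
            contig, reads, alts, provenance={"asm1": list(reads) + ["alt1"]})
        assert rep.flagged and rep.alt_ids_in_provenance == ["alt1"]

    def test_attribution_matches_substring_oracle(self, world):
        _, genome = world
        piece = genome[10_000:30_000]
        contig = {"asm1": SequenceRecord("asm1", piece)}
        # error-free reads: aligner coverage must equal exact-substring coverage
        reads = _tile(piece, 3_000, 2_500)
        (rep,) = provenance_audit(contig, reads, {})
        covered = np.zeros(len(piece), dtype=bool)
        for r in reads.values():
            idx = piece.find(r.sequence)
            assert idx >= 0
            covered[idx : idx + len(r.sequence)] = True
        assert rep.original_read_fraction == covered.mean()


def test_pipeline_order_and_no_pass_after_fail(world):
    _, genome = world
    from refweave.filters import apply_filters

    piece = genome[10_000:40_000]
    reads = _tile(piece, 4_000, 1_000)
    contigs = {"c": SequenceRecord("c", genome)}
    cand = _cand(piece, cid="dup")  # fully contained -> identity fail
    out = apply_filters([cand], reads, contigs,
                        FilterConfig(min_output_length=10_000))
    assert out == []
    assert cand.verdicts["coverage"] == "pass"
    assert cand.verdicts["identity"] == "fail"
    # later stages never ran, so the fail verdict is final
    assert "length" not in cand.verdicts
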