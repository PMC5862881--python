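"""The structural-variant caller: discordance rules, split-read
breakpoint refinement, homology filtering, clustering and blacklist."""

import numpy as np
import pytest

from progenomix import breakfast
from progenomix.align import ToyAligner, revcomp
from progenomix.io import AlignmentRecord, MatePair


def _mate(chrom, pos, mapq=60, reverse=False, seq="A" * 90, unmapped=False):
    return AlignmentRecord(read_id="r", chrom=None if unmapped else chrom,
                           pos=None if unmapped else pos, mapq=mapq,
                           is_reverse=reverse, is_unmapped=unmapped, sequence=seq)


def _pair(c1, p1, c2, p2, mapq=(60, 60), rid="r"):
    mp = MatePair(rid, _mate(c1, p1, mapq[0]), _mate(c2, p2, mapq[1],
                                                     reverse=True))
    mp.mate1.read_id = mp.mate2.read_id = rid
    return mp


class TestDiscordance:
    def test_100kb_boundary_exclusive(self):
        # inner coordinates: forward mate at pos -> pos + 90
        near = _pair("chr1", 0, "chr1", 100_089 - 1)   # span exactly 99_999
        assert breakfast.find_discordant_pairs([near]) == []
        far = _pair("chr1", 0, "chr1", 100_091)
        assert len(breakfast.find_discordant_pairs([far])) == 1

    def test_interchromosomal_is_discordant(self):
        out = breakfast.find_discordant_pairs([_pair("chr1", 5, "chr2", 5)])
        assert len(out) == 1 and out[0].evidence == "read_pair"

    def test_low_mapq_mate_discarded(self):
        out = breakfast.find_discordant_pairs(
            [_pair("chr1", 5, "chr2", 5, mapq=(60, 19))])
        assert out == []

    def test_reorientation_idempotent_and_order_free(self):
        p = breakfast.DiscordantPair("chr2", 10, "chr1", 99, "read_pair", "r")
        once = p.reoriented()
        assert (once.chrom_a, once.pos_a) == ("chr1", 99)
        assert once.reoriented() == once


def _random_ref(rng, n=4000):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="module")
def junction_setup():
    """Two unrelated chromosomes and a read spanning a junction that
    joins chrA:1000 (left flank end) to chrB:2000 (right flank start)."""
    rng = np.random.default_rng(8)
    ref = {"chrA": _random_ref(rng), "chrB": _random_ref(rng)}
    read = ref["chrA"][955:1000] + ref["chrB"][2000:2045]
    return ref, read


class TestSplitReads:
    def test_concordant_read_produces_no_candidate(self):
        rng = np.random.default_rng(1)
        ref = {"chrA": _random_ref(rng)}
        aligner = ToyAligner(ref)
        read = ref["chrA"][500:590]
        cands, _ = breakfast.split_read_anchors([("r1", read)], aligner,
                                                max_span=100)
        assert cands == []

    def test_translocation_read_yields_candidate_and_exact_refinement(
            self, junction_setup):
        ref, read = junction_setup
        aligner = ToyAligner(ref)
        cands, n_amb = breakfast.split_read_anchors([("r1", read)], aligner)
        assert len(cands) == 1 and n_amb == 0
        pair, split = breakfast.refine_breakpoint(cands[0], ref)
        assert (pair.chrom_a, pair.pos_a) == ("chrA", 1000)
        assert (pair.chrom_b, pair.pos_b) == ("chrB", 2000)
        assert pair.mismatches == 0 and split == 45

    def test_single_error_keeps_breakpoint(self, junction_setup):
        ref, read = junction_setup
        aligner = ToyAligner(ref)
        # perturb one base between the anchors, away from the junction
        mutated = read[:30] + ("A" if read[30] != "A" else "C") + read[31:]
        cands, _ = breakfast.split_read_anchors([("r1", mutated)], aligner)
        pair, _ = breakfast.refine_breakpoint(cands[0], ref)
        assert (pair.pos_a, pair.pos_b) == (1000, 2000)
        assert pair.mismatches == 1

    def test_reverse_complement_read_same_breakends(self, junction_setup):
        ref, read = junction_setup
        aligner = ToyAligner(ref)
        cands, _ = breakfast.split_read_anchors([("r1", revcomp(read))],
                                                aligner)
        pair, _ = breakfast.refine_breakpoint(cands[0], ref)
        assert (pair.chrom_a, pair.pos_a, pair.chrom_b, pair.pos_b) == \
            ("chrA", 1000, "chrB", 2000)

    def test_mismatch_cap_rejects_bad_candidate(self, junction_setup):
        ref, read = junction_setup
        aligner = ToyAligner(ref)
        # scramble the middle third so no split fits well
        middle = revcomp(read[30:60])
        bad = read[:30] + middle + read[60:]
        cands, _ = breakfast.split_read_anchors([("r1", bad)], aligner)
        if cands:
            assert breakfast.refine_breakpoint(cands[0], ref,
                                               mismatch_cap=5) is None


class TestHomologyFilter:
    def test_random_junction_kept(self, junction_setup):
        ref, read = junction_setup
        aligner = ToyAligner(ref)
        cands, _ = breakfast.split_read_anchors([("r1", read)], aligner)
        _, split = breakfast.refine_breakpoint(cands[0], ref)
        assert breakfast.homology_filter(cands[0], split, ref)

    def test_tandem_duplication_junction_discarded(self):
        # a 'junction' joining two copies of the same sequence: the
        # flank continuation matches the read perfectly on both sides
        rng = np.random.default_rng(5)
        unit = _random_ref(rng, 2000)
        ref = {"chrA": unit}
        dup_cand = breakfast.SplitCandidate(
            read_id="r", seq=ref["chrA"][955:1045],
            anchor_a=breakfast.AnchorPlacement("chrA", 955, "+"),
            anchor_b=breakfast.AnchorPlacement("chrA", 1020, "+"),
            anchor_len=25)
        assert not breakfast.homology_filter(dup_cand, 45, ref)

    def test_identity_exactly_70_percent_kept(self):
        # construct flank continuation with exactly 70% identity to the
        # distal read segment (7 of 10 bases match)
        rng = np.random.default_rng(6)
        left = _random_ref(rng, 1000)
        right_seg = "ACGTACGTAC"                      # read bases past split
        cont = "ACGTACG" + "GCA"                      # 7 matches, 3 mismatch
        assert sum(a == b for a, b in zip(right_seg, cont)) == 7
        ref = {"chrA": left + cont + _random_ref(rng, 500),
               "chrB": _random_ref(rng, 2000)}
        read = ref["chrA"][1000 - 80:1000] + right_seg
        # place anchor B so that read[80:] maps to chrB
        ref["chrB"] = ref["chrB"][:500] + right_seg + ref["chrB"][510:]
        cand = breakfast.SplitCandidate(
            read_id="r", seq=read,
            anchor_a=breakfast.AnchorPlacement("chrA", 920, "+"),
            anchor_b=breakfast.AnchorPlacement("chrB", 485, "+"),
            anchor_len=25)
        assert breakfast.homology_filter(cand, 80, ref, max_identity=0.70)


class TestClustering:
    def _dp(self, pos_a, pos_b, evidence, rid, mm=0):
        return breakfast.DiscordantPair("chr1", pos_a, "chr2", pos_b,
                                        evidence, rid, mm)

    def test_mixed_evidence_accepted_with_counts(self):
        pairs = [self._dp(1000 + i * 50, 5000 + i * 40, "read_pair", f"rp{i}")
                 for i in range(3)]
        pairs += [self._dp(1200, 5100, "split_read", "s1", mm=1),
                  self._dp(1201, 5101, "split_read", "s2", mm=0)]
        calls = breakfast.cluster_calls(pairs, window=1000)
        assert len(calls) == 1
        call = calls[0]
        assert call.accepted and call.n_read_pair == 3 and call.n_split == 2
        # representative breakends come from the best split read
        assert (call.pos_a, call.pos_b) == (1201, 5101)

    def test_split_only_cluster_rejected(self):
        pairs = [self._dp(1000, 5000, "split_read", "s1"),
                 self._dp(1001, 5002, "split_read", "s2")]
        calls = breakfast.cluster_calls(pairs, window=1000)
        assert len(calls) == 1 and not calls[0].accepted

    def test_distant_junctions_stay_separate(self):
        pairs = [self._dp(1000, 5000, "read_pair", "a"),
                 self._dp(11_000, 5000, "read_pair", "b")]
        calls = breakfast.cluster_calls(pairs, window=1000)
        assert len(calls) == 2

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        pairs = [self._dp(int(p), int(p) + 4000,
                          "split_read" if i % 3 else "read_pair", f"r{i}")
                 for i, p in enumerate(rng.integers(0, 50_000, 40))]
        calls1 = breakfast.cluster_calls(pairs, window=800)
        calls2 = breakfast.cluster_calls(pairs[::-1], window=800)
        key = lambda c: (c.chrom_a, c.pos_a, c.chrom_b, c.pos_b,
                         c.n_read_pair, c.n_split)
        assert sorted(map(key, calls1)) == sorted(map(key, calls2))


class TestBlacklist:
    def _call(self, pos_a, pos_b=50_000):
        return breakfast.BreakendCall("chr1", pos_a, "chr2", pos_b,
                                      n_read_pair=2, n_split=1, accepted=True)

    def test_margin_inclusive_and_boundary(self):
        control = [self._call(10_000, 90_000)]
        kept = breakfast.blacklist_filter(
            [self._call(10_500), self._call(11_001)], control)
        assert [c.pos_a for c in kept] == [11_001]

    def test_empty_control_keeps_everything(self):
        calls = [self._call(1), self._call(2)]
        assert breakfast.blacklist_filter(calls, []) == calls


class TestEndToEnd:
    def test_error_free_calls_exact(self, sv_setup, sv_calls):
        truth = {(a, pa, b, pb) for a, pa, b, pb, _ in sv_setup["breakends"]}
        got = {(c.chrom_a, c.pos_a, c.chrom_b, c.pos_b) for c in sv_calls}
        assert got == truth                      # precision = recall = 1
        for c in sv_calls:
            assert c.n_read_pair >= 1 and c.n_split >= 1
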