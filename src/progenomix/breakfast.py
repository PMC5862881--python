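"""Split-read structural-variant calling from paired-end alignments.

The evidence model combines two read classes:

* *discordant pairs* — both mates aligned (mapping quality >= 20) but on
  different chromosomes or more than ``max_span`` apart (100 kb for a
  full-size genome);
* *split reads* — mates that failed to align full-length are split into
  25 bp terminal anchors, each realigned independently; anchor pairs
  passing the same discordance criteria become breakpoint candidates.
  The full read sequence is then compared against the reference for
  every possible split position between the anchors, and the split with
  the fewest nucleotide mismatches defines the exact breakpoint
  (leftmost split on ties). Candidates whose read shows more than 70%
  ungapped identity to the continuation of either flanking sequence
  across the breakpoint are discarded as likely alignment artifacts.

Reoriented discordant pairs (lower chromosome/coordinate first) are
clustered by a sliding window; a cluster becomes a call only when it
contains at least one discordant read pair and one split read. Calls
within 1 kb of any breakpoint seen in benign control samples are
blacklisted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from progenomix.align import ToyAligner, revcomp
from progenomix.io import MatePair, read_alignments

DEFAULT_MIN_MAPQ = 20
DEFAULT_MAX_SPAN = 100_000
DEFAULT_ANCHOR_LEN = 25
DEFAULT_WINDOW = 1_000
DEFAULT_MISMATCH_CAP = 5
DEFAULT_MAX_IDENTITY = 0.70
DEFAULT_BLACKLIST_MARGIN = 1_000


@dataclass
class DiscordantPair:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    evidence: str                     # read_pair | split_read
    read_id: str
    mismatches: Optional[int] = None

    def reoriented(self) -> "DiscordantPair":
        if (self.chrom_a, self.pos_a) <= (self.chrom_b, self.pos_b):
            return self
        return DiscordantPair(self.chrom_b, self.pos_b, self.chrom_a,
                              self.pos_a, self.evidence, self.read_id,
                              self.mismatches)


@dataclass
class BreakendCall:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    n_read_pair: int
    n_split: int
    read_ids: list[str] = field(default_factory=list)
    accepted: bool = False
    blacklisted: bool = False


def _is_discordant(chrom_a: str, pos_a: int, chrom_b: str, pos_b: int,
                   max_span: int) -> bool:
    return chrom_a != chrom_b or abs(pos_a - pos_b) > max_span


# ---------------------------------------------------------------------------
# Discordant read pairs
# ---------------------------------------------------------------------------

def find_discordant_pairs(mate_pairs: Iterable[MatePair],
                          min_mapq: int = DEFAULT_MIN_MAPQ,
                          max_span: int = DEFAULT_MAX_SPAN,
                          ) -> list[DiscordantPair]:
    """Reoriented discordant pairs from mate-joined alignments.

    Mates with mapping quality below ``min_mapq`` or unmapped are
    discarded. The reported coordinate of each mate is its junction-side
    (inner) end: the rightmost base for forward-strand mates, the
    leftmost for reverse-strand mates.
    """
    out: list[DiscordantPair] = []
    for mp in mate_pairs:
        m1, m2 = mp.mate1, mp.mate2
        if m1.is_unmapped or m2.is_unmapped:
            continue
        if m1.mapq < min_mapq or m2.mapq < min_mapq:
            continue
        p1 = m1.pos if m1.is_reverse else m1.pos + len(m1.sequence)
        p2 = m2.pos if m2.is_reverse else m2.pos + len(m2.sequence)
        if _is_discordant(m1.chrom, p1, m2.chrom, p2, max_span):
            out.append(DiscordantPair(m1.chrom, p1, m2.chrom, p2,
                                      "read_pair", mp.read_id).reoriented())
    return out


# ---------------------------------------------------------------------------
# Split reads
# ---------------------------------------------------------------------------

@dataclass
class AnchorPlacement:
    chrom: str
    pos: int                          # leftmost ref coordinate of the anchor
    strand: str


@dataclass
class SplitCandidate:
    read_id: str
    seq: str                          # read in the orientation that was anchored
    anchor_a: AnchorPlacement         # read[:anchor_len]
    anchor_b: AnchorPlacement         # read[-anchor_len:]
    anchor_len: int


def split_read_anchors(unaligned: Iterable[tuple[str, str]],
                       aligner: ToyAligner,
                       anchor_len: int = DEFAULT_ANCHOR_LEN,
                       max_span: int = DEFAULT_MAX_SPAN,
                       ) -> tuple[list[SplitCandidate], int]:
    """Anchor the first and last ``anchor_len`` bp of each unaligned
    read independently; keep pairs whose placements are discordant.

    Returns (candidates, n_ambiguous): reads with a non-unique anchor
    placement are discarded and counted.
    """
    candidates: list[SplitCandidate] = []
    n_ambiguous = 0
    for read_id, seq in unaligned:
        if len(seq) < 2 * anchor_len:
            continue
        hit_a = aligner.align(seq[:anchor_len], max_mismatches=0,
                              seed_offsets=[0, anchor_len - aligner.k])
        hit_b = aligner.align(seq[-anchor_len:], max_mismatches=0,
                              seed_offsets=[0, anchor_len - aligner.k])
        if hit_a is None or hit_b is None:
            continue
        if not (hit_a.unique and hit_b.unique):
            n_ambiguous += 1
            continue
        if not _is_discordant(hit_a.chrom, hit_a.pos, hit_b.chrom,
                              hit_b.pos, max_span):
            continue
        candidates.append(SplitCandidate(
            read_id=read_id, seq=seq,
            anchor_a=AnchorPlacement(hit_a.chrom, hit_a.pos, hit_a.strand),
            anchor_b=AnchorPlacement(hit_b.chrom, hit_b.pos, hit_b.strand),
            anchor_len=anchor_len))
    return candidates, n_ambiguous


def _left_flank_segment(cand: SplitCandidate, reference: dict[str, str],
                        s: int) -> Optional[tuple[str, int]]:
    """Reference sequence matching read[:s] through anchor A, and the
    breakend coordinate of the A side for this split."""
    a = cand.anchor_a
    ref = reference[a.chrom]
    if a.strand == "+":
        start, end = a.pos, a.pos + s
        if start < 0 or end > len(ref):
            return None
        return ref[start:end], end
    start, end = a.pos + cand.anchor_len - s, a.pos + cand.anchor_len
    if start < 0 or end > len(ref):
        return None
    return revcomp(ref[start:end]), start


def _right_flank_segment(cand: SplitCandidate, reference: dict[str, str],
                         s: int) -> Optional[tuple[str, int]]:
    """Reference sequence matching read[s:] through anchor B, and the
    breakend coordinate of the B side."""
    b = cand.anchor_b
    ref = reference[b.chrom]
    n_right = len(cand.seq) - s
    if b.strand == "+":
        start = b.pos + cand.anchor_len - n_right
        end = b.pos + cand.anchor_len
        if start < 0 or end > len(ref):
            return None
        return ref[start:end], start
    start = b.pos
    end = b.pos + n_right
    if start < 0 or end > len(ref):
        return None
    return revcomp(ref[start:end]), end


def _count_mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def refine_breakpoint(cand: SplitCandidate, reference: dict[str, str],
                      mismatch_cap: int = DEFAULT_MISMATCH_CAP,
                      ) -> Optional[tuple[DiscordantPair, int]]:
    """Scan every split position between the anchors and pick the one
    with the fewest total mismatches (leftmost on ties).

    Returns a split_read DiscordantPair carrying the exact breakend
    coordinates, or None when the best split still exceeds the cap.
    """
    L = len(cand.seq)
    best: Optional[tuple[int, int, int, int]] = None   # (mm, s, bkA, bkB)
    for s in range(cand.anchor_len, L - cand.anchor_len + 1):
        left = _left_flank_segment(cand, reference, s)
        right = _right_flank_segment(cand, reference, s)
        if left is None or right is None:
            continue
        mm = (_count_mismatches(cand.seq[:s], left[0])
              + _count_mismatches(cand.seq[s:], right[0]))
        if best is None or mm < best[0]:
            best = (mm, s, left[1], right[1])
    if best is None or best[0] > mismatch_cap:
        return None
    mm, s, bk_a, bk_b = best
    return DiscordantPair(cand.anchor_a.chrom, bk_a, cand.anchor_b.chrom,
                          bk_b, "split_read", cand.read_id,
                          mismatches=mm).reoriented(), s


def homology_filter(cand: SplitCandidate, split_pos: int,
                    reference: dict[str, str],
                    max_identity: float = DEFAULT_MAX_IDENTITY) -> bool:
    """True (keep) when neither flank continues across the breakpoint
    with more than ``max_identity`` ungapped identity to the read
    nucleotides assigned to the other anchor.

    High identity means the read could equally be explained by a
    continuous alignment on one side — a self-homologous false junction.
    """
    s = split_pos
    L = len(cand.seq)
    # continuation of flank A across the breakpoint vs read[s:]
    right_len = L - s
    ext_a = _left_flank_segment(cand, reference, s + right_len)
    if ext_a is not None:
        cont = ext_a[0][s:]
        if cont:
            ident = 1 - _count_mismatches(cand.seq[s:], cont) / len(cont)
            if ident > max_identity:
                return False
    # continuation of flank B before the breakpoint vs read[:s]
    ext_b = _right_flank_segment(cand, reference, 0)
    if ext_b is not None:
        cont = ext_b[0][:s]
        if cont:
            ident = 1 - _count_mismatches(cand.seq[:s], cont) / len(cont)
            if ident > max_identity:
                return False
    return True


# ---------------------------------------------------------------------------
# Clustering, acceptance and blacklist
# ---------------------------------------------------------------------------

def cluster_calls(pairs: list[DiscordantPair],
                  window: int = DEFAULT_WINDOW) -> list[BreakendCall]:
    """Single-linkage clustering of reoriented discordant pairs: two
    pairs join when they share the chromosome pair and both breakend
    coordinates differ by at most ``window``.

    The call's coordinates come from the split read with the fewest
    mismatches (median of members when no split read exists). A call is
    accepted when it has >= 1 read pair and >= 1 split read.
    """
    pairs = sorted((p.reoriented() for p in pairs),
                   key=lambda p: (p.chrom_a, p.chrom_b, p.pos_a, p.pos_b))
    by_chroms: dict[tuple[str, str], list[DiscordantPair]] = {}
    for p in pairs:
        by_chroms.setdefault((p.chrom_a, p.chrom_b), []).append(p)
    calls: list[BreakendCall] = []
    for (ca, cb), members in sorted(by_chroms.items()):
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if members[j].pos_a - members[i].pos_a > window:
                    break
                if abs(members[i].pos_b - members[j].pos_b) <= window:
                    ri, rj = find(i), find(j)
                    parent[ri] = rj
        groups: dict[int, list[DiscordantPair]] = {}
        for i, p in enumerate(members):
            groups.setdefault(find(i), []).append(p)
        for grp in groups.values():
            splits = [p for p in grp if p.evidence == "split_read"]
            rps = [p for p in grp if p.evidence == "read_pair"]
            if splits:
                rep = min(splits, key=lambda p: (p.mismatches or 0,
                                                 p.pos_a, p.pos_b))
                pos_a, pos_b = rep.pos_a, rep.pos_b
            else:
                pos_a = int(np.median([p.pos_a for p in grp]))
                pos_b = int(np.median([p.pos_b for p in grp]))
            calls.append(BreakendCall(
                chrom_a=ca, pos_a=pos_a, chrom_b=cb, pos_b=pos_b,
                n_read_pair=len(rps), n_split=len(splits),
                read_ids=sorted({p.read_id for p in grp}),
                accepted=bool(rps and splits)))
    return sorted(calls, key=lambda c: (c.chrom_a, c.pos_a, c.chrom_b,
                                        c.pos_b))


def blacklist_filter(calls: list[BreakendCall],
                     control_calls: list[BreakendCall],
                     margin: int = DEFAULT_BLACKLIST_MARGIN,
                     ) -> list[BreakendCall]:
    """Drop calls with either breakend within ``margin`` bp (inclusive)
    of any breakend called in control (benign) samples."""
    control_bks = [(c.chrom_a, c.pos_a) for c in control_calls] + \
                  [(c.chrom_b, c.pos_b) for c in control_calls]

    def near_control(chrom: str, pos: int) -> bool:
        return any(chrom == cc and abs(pos - cp) <= margin
                   for cc, cp in control_bks)

    out = []
    for call in calls:
        if near_control(call.chrom_a, call.pos_a) or \
                near_control(call.chrom_b, call.pos_b):
            call.blacklisted = True
        else:
            out.append(call)
    return out


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------

def call_structural_variants(sam_path, reference: dict[str, str],
                             min_mapq: int = DEFAULT_MIN_MAPQ,
                             max_span: int = DEFAULT_MAX_SPAN,
                             anchor_len: int = DEFAULT_ANCHOR_LEN,
                             window: int = DEFAULT_WINDOW,
                             mismatch_cap: int = DEFAULT_MISMATCH_CAP,
                             max_identity: float = DEFAULT_MAX_IDENTITY,
                             control_calls: list[BreakendCall] | None = None,
                             ) -> list[BreakendCall]:
    """Full pipeline: discordant pairs + split-read refinement +
    clustering + acceptance (+ optional control blacklist). Returns the
    accepted calls."""
    mate_pairs = list(read_alignments(sam_path))
    evidence = find_discordant_pairs(mate_pairs, min_mapq=min_mapq,
                                     max_span=max_span)
    aligner = ToyAligner(reference)
    unaligned: list[tuple[str, str]] = []
    for mp in mate_pairs:
        for mate in (mp.mate1, mp.mate2):
            if mate.is_unmapped and mate.sequence:
                unaligned.append((mp.read_id, mate.sequence))
    candidates, _ = split_read_anchors(unaligned, aligner,
                                       anchor_len=anchor_len,
                                       max_span=max_span)
    for cand in candidates:
        refined = refine_breakpoint(cand, reference,
                                    mismatch_cap=mismatch_cap)
        if refined is None:
            continue
        pair, split_pos = refined
        if not homology_filter(cand, split_pos, reference,
                               max_identity=max_identity):
            continue
        evidence.append(pair)
    calls = [c for c in cluster_calls(evidence, window=window) if c.accepted]
    if control_calls:
        calls = blacklist_filter(calls, control_calls)
    return calls


def calls_frame(calls: list[BreakendCall]):
    import pandas as pd

    return pd.DataFrame([{
        "chrom_a": c.chrom_a, "pos_a": c.pos_a,
        "chrom_b": c.chrom_b, "pos_b": c.pos_b,
        "n_read_pair": c.n_read_pair, "n_split": c.n_split,
        "accepted": c.accepted, "blacklisted": c.blacklisted,
    } for c in calls])
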