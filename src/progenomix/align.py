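"""A minimal exact-seed + extension read aligner.

Sufficient for error-free or low-error synthetic reads against small
reference genomes: seeds are exact k-mer matches (k = 20 by default,
tried at several offsets so a single sequencing error rarely kills all
seeds), extension is ungapped full-length mismatch counting on both
strands. Unique best hits get mapping quality 60, ties 0. Externally
aligned SAM input remains usable everywhere the pipeline accepts
alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Hit:
    chrom: str
    pos: int            # 0-based leftmost on the forward reference strand
    strand: str         # '+' or '-'
    mismatches: int
    unique: bool

    @property
    def mapq(self) -> int:
        return 60 if self.unique else 0


class ToyAligner:
    """Exact-seed index over the forward strand of a small genome."""

    def __init__(self, reference: dict[str, str], k: int = 20):
        self.reference = {c: s.upper() for c, s in reference.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.reference.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((chrom, i))

    def _mismatches(self, chrom: str, pos: int, query: str,
                    cap: int) -> Optional[int]:
        ref = self.reference[chrom]
        if pos < 0 or pos + len(query) > len(ref):
            return None
        mm = 0
        for a, b in zip(query, ref[pos:pos + len(query)]):
            if a != b:
                mm += 1
                if mm > cap:
                    return None
        return mm

    def align(self, seq: str, max_mismatches: int = 5,
              seed_offsets: Optional[list[int]] = None) -> Optional[Hit]:
        """Best full-length ungapped placement of ``seq`` on either
        strand, or None. Ties in mismatch count are flagged non-unique
        (the lexicographically first placement is reported)."""
        seq = seq.upper()
        if len(seq) < self.k:
            raise ValueError(f"query shorter than seed size {self.k}")
        if seed_offsets is None:
            seed_offsets = list(range(0, len(seq) - self.k + 1,
                                      max(self.k, 1)))
            if seed_offsets[-1] != len(seq) - self.k:
                seed_offsets.append(len(seq) - self.k)
        candidates: set[tuple[str, int, str]] = set()
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for off in seed_offsets:
                for chrom, pos in self.index.get(query[off:off + self.k], ()):
                    candidates.add((chrom, pos - off, strand))
        best: list[tuple[str, int, str, int]] = []
        best_mm = max_mismatches
        for chrom, start, strand in sorted(candidates):
            query = seq if strand == "+" else revcomp(seq)
            mm = self._mismatches(chrom, start, query, best_mm)
            if mm is None:
                continue
            if mm < best_mm or not best:
                best = [(chrom, start, strand, mm)]
                best_mm = mm
            elif mm == best_mm:
                best.append((chrom, start, strand, mm))
        if not best:
            return None
        chrom, pos, strand, mm = best[0]
        return Hit(chrom=chrom, pos=pos, strand=strand, mismatches=mm,
                   unique=len(best) == 1)
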