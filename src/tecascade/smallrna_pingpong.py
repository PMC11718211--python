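"""piRNA response quantification against a TE consensus.

Two statistics distinguish an active germline piRNA response from somatic,
trap-model silencing: the strand distribution of TE-mapping piRNAs (somatic
clusters like flamenco produce antisense-only piRNA) and the ping-pong
signature — an excess of sense/antisense piRNA pairs whose 5' ends overlap
by exactly 10 nt, the footprint of the germline amplification loop.  The
signature is summarised as a z-score of the overlap-10 pair count against
the counts at overlaps 1-9 and 11-20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .te_library import TEConsensus, reverse_complement

DEFAULT_ADAPTOR = "GAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class SmallRnaHit:
    """One mapping of a small RNA on the consensus (weight 1/n for multimappers)."""

    read: str
    strand: str  # '+' (sense) or '-' (antisense)
    start: int  # interval [start, end) on the consensus
    end: int
    weight: float

    @property
    def five_prime(self) -> int:
        """Consensus coordinate of the read's 5' terminus."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PingPongProfile:
    te: str
    overlap_counts: np.ndarray  # index o-1 holds the weighted count at overlap o (1..20)
    z10: float | None
    sense_fraction: float
    per_position_coverage: np.ndarray  # shape (2, L): sense row 0, antisense row 1


def trim_adaptor(
    reads: Iterable[tuple[str, str]],
    adaptor: str = DEFAULT_ADAPTOR,
    min_len: int = 18,
    max_len: int = 35,
    max_mismatch: int = 1,
) -> list[tuple[str, str]]:
    """Remove the 3' sequencing adaptor and length-filter the reads.

    The adaptor (full-length, up to ``max_mismatch`` mismatches) is located at
    its first occurrence; it and everything 3' of it are removed.  Reads whose
    length falls outside [min_len, max_len] after trimming are dropped.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    la = len(adaptor)
    out = []
    for name, seq in reads:
        cut = len(seq)
        for p in range(0, len(seq) - la + 1):
            window = seq[p : p + la]
            if sum(a != b for a, b in zip(window, adaptor)) <= max_mismatch:
                cut = p
                break
        trimmed = seq[:cut]
        if min_len <= len(trimmed) <= max_len:
            out.append((name, trimmed))
    return out


def _occurrences(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _matches_upto(consensus: np.ndarray, cons_str: str, read: str, max_mm: int) -> list[tuple[int, int]]:
    """(position, mismatches) of all full-length matches with <= max_mm mismatches.

    Pigeonhole: any match with <= 1 mismatch contains an exact occurrence of
    at least one read half, so candidate positions come from exact searches
    of the two halves.
    """
    l = len(read)
    if l > len(cons_str):
        return []
    enc = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    candidates: set[int] = set()
    half = l // 2
    for offset, part in ((0, read[:half]), (half, read[half:])):
        for p in _occurrences(cons_str, part):
            start = p - offset
            if 0 <= start <= len(cons_str) - l:
                candidates.add(start)
    hits = []
    for start in sorted(candidates):
        mm = int(np.count_nonzero(consensus[start : start + l] != enc))
        if mm <= max_mm:
            hits.append((start, mm))
    return hits


def map_small_rnas(
    reads: Iterable[tuple[str, str]],
    consensus: TEConsensus,
    max_mismatch: int = 1,
) -> list[SmallRnaHit]:
    """Full-length matching of small RNAs on both strands of the consensus.

    Each read keeps its best matches (fewest mismatches, up to
    ``max_mismatch``); a read matching n positions within the TE contributes
    weight 1/n at each.  Antisense reads are those matching the reverse
    complement; their 5' end is the rightmost consensus coordinate of the
    matched interval.
    """
    cons = consensus.sequence
    enc = np.frombuffer(cons.encode("ascii"), dtype=np.uint8)
    out: list[SmallRnaHit] = []
    for name, seq in reads:
        seq = seq.upper()
        placements: list[tuple[int, str, int]] = []  # (mismatches, strand, start)
        for start, mm in _matches_upto(enc, cons, seq, max_mismatch):
            placements.append((mm, "+", start))
        for start, mm in _matches_upto(enc, cons, reverse_complement(seq), max_mismatch):
            placements.append((mm, "-", start))
        if not placements:
            continue
        best_mm = min(p[0] for p in placements)
        best = [p for p in placements if p[0] == best_mm]
        w = 1.0 / len(best)
        for _mm, strand, start in best:
            out.append(
                SmallRnaHit(read=name, strand=strand, start=start, end=start + len(seq), weight=w)
            )
    return out


def strand_profile(
    hits: Sequence[SmallRnaHit], consensus_length: int
) -> tuple[float, np.ndarray]:
    """Weighted sense fraction and per-strand coverage along the consensus."""
    if not hits:
        raise ValueError("no mapped reads; cannot build a strand profile")
    coverage = np.zeros((2, consensus_length))
    total = sense = 0.0
    for h in hits:
        row = 0 if h.strand == "+" else 1
        coverage[row, h.start : h.end] += h.weight
        total += h.weight
        sense += h.weight if h.strand == "+" else 0.0
    return sense / total, coverage


def ping_pong_signature(
    hits: Sequence[SmallRnaHit],
    consensus_length: int,
    te: str = "",
    max_overlap: int = 20,
) -> PingPongProfile:
    """Histogram of 5'-5' overlaps between sense/antisense pairs, and z10.

    A sense read with 5' end s and an antisense read with 5' end a at
    distance |a - s| = o - 1 form a pair with 5'-5' overlap o; pair weights
    multiply.  Counting both arrangements (whichever strand carries the
    upstream 5' end) makes the histogram symmetric in the strand labels;
    genuine ping-pong pairs have the antisense 5' end downstream.  z10 is
    the overlap-10 count standardised against the counts at overlaps
    {1..9, 11..20} (sample s.d.); it is None (undefined) when reads map to
    only one strand or the background s.d. is zero.
    """
    sense5 = np.zeros(consensus_length)
    anti5 = np.zeros(consensus_length)
    for h in hits:
        (sense5 if h.strand == "+" else anti5)[h.five_prime] += h.weight
    counts = np.zeros(max_overlap)
    for o in range(1, max_overlap + 1):
        shift = o - 1
        if shift == 0:
            counts[o - 1] = 2.0 * float(np.dot(sense5, anti5))
        else:
            counts[o - 1] = float(np.dot(sense5[:-shift], anti5[shift:])) + float(
                np.dot(anti5[:-shift], sense5[shift:])
            )
    sense_fraction, coverage = strand_profile(hits, consensus_length)
    if sense5.sum() == 0 or anti5.sum() == 0:
        z10 = None
    else:
        bg = np.delete(counts, 9)
        sd = float(np.std(bg, ddof=1))
        z10 = None if sd == 0 else float((counts[9] - bg.mean()) / sd)
    return PingPongProfile(
        te=te,
        overlap_counts=counts,
        z10=z10,
        sense_fraction=sense_fraction,
        per_position_coverage=coverage,
    )
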