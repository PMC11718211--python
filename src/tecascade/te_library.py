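"""TE consensus data model, LTR detection, and shared FASTA/GFF helpers.

An LTR retrotransposon carries two near-identical long terminal repeats
(LTRs), one at each end of the element.  Because the two copies are created
from a single template during reverse transcription, they are essentially
identical at the time of insertion; their residual identity in a consensus
sequence lets us delimit them by aligning the 5' terminus of the element
against its 3' terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA records (empty sequence, duplicate names...)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open, 0-based interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "."  # '+', '-' or '.' (unstranded)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TEConsensus:
    """A named TE reference sequence with optional LTR coordinates.

    ``ltr5``/``ltr3`` are (start, end) half-open intervals on the consensus;
    when present the 5' LTR starts at 0, the 3' LTR ends at the consensus
    length, and both have width ``ltr_length``.
    """

    name: str
    sequence: str
    ltr_length: int | None = None
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"consensus {self.name!r} has empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"consensus {self.name!r} contains invalid bases: {sorted(bad)}"
            )
        if self.ltr_length is not None:
            n = len(self.sequence)
            if self.ltr5 != (0, self.ltr_length):
                raise ValueError("ltr5 must start at 0 and span ltr_length")
            if self.ltr3 != (n - self.ltr_length, n):
                raise ValueError("ltr3 must end at the consensus length")
            if self.ltr5[1] > self.ltr3[0]:
                raise ValueError("LTR intervals overlap")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_ltrs(self) -> bool:
        return self.ltr_length is not None


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (name, sequence).

    Sequences are upper-cased and multi-line records concatenated.  Duplicate
    record names and empty sequences raise :class:`FastaFormatError` naming
    the offending record.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        seq = str(rec.seq).upper()
        if not name:
            raise FastaFormatError(f"{path}: record with empty header")
        if not seq:
            raise FastaFormatError(f"{path}: record {name!r} has empty sequence")
        if name in seen:
            raise FastaFormatError(f"{path}: duplicate record name {name!r}")
        seen.add(name)
        records.append((name, seq))
    if not records and path.stat().st_size > 0:
        raise FastaFormatError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _encode(seq: str) -> "np.ndarray":
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _terminal_mismatches(enc: "np.ndarray", length: int) -> int:
    """Mismatches between the 5' and 3' terminal windows of ``length`` nt.

    N counts as a mismatch even against N (conservative).
    """
    head = enc[:length]
    tail = enc[-length:]
    n_code = ord("N")
    return int(np.count_nonzero((head != tail) | (head == n_code)))


def detect_ltrs(
    consensus: TEConsensus,
    min_ltr: int = 100,
    max_mismatch_frac: float = 0.05,
) -> TEConsensus | None:
    """Delimit LTRs by aligning the element's two termini against each other.

    Returns a copy of ``consensus`` with ``ltr5``/``ltr3``/``ltr_length``
    filled in.  Candidate windows must have identity >= ``1 - max_mismatch_frac``
    and length >= ``min_ltr``; among candidates the boundary maximises
    ``matches - 5 * mismatches``, which stops the window from drifting into
    the core by chance matches while still extending through isolated
    substitutions.  Returns None when no window qualifies.
    """
    if min_ltr < 20:
        raise ValueError("min_ltr < 20 is too short to delimit a meaningful LTR")
    seq = consensus.sequence
    n = len(seq)
    if n <= 2 * min_ltr:
        raise ValueError(
            f"consensus {consensus.name!r} ({n} nt) too short for min_ltr={min_ltr}"
        )
    enc = _encode(seq)
    best: int | None = None
    best_score = -1.0
    for length in range(min_ltr, n // 2 + 1):
        mism = _terminal_mismatches(enc, length)
        if mism > max_mismatch_frac * length:
            continue
        score = (length - mism) - 5 * mism
        if score > best_score:
            best, best_score = length, score
    if best is None:
        return None
    return TEConsensus(
        name=consensus.name,
        sequence=seq,
        ltr_length=best,
        ltr5=(0, best),
        ltr3=(n - best, n),
    )


def ltr_gff_lines(consensus: TEConsensus) -> list[str]:
    """GFF3 lines (1-based inclusive coordinates) for detected LTRs."""
    if not consensus.has_ltrs:
        return []
    lines = []
    for label, (start, end) in (("ltr5", consensus.ltr5), ("ltr3", consensus.ltr3)):
        lines.append(
            "\t".join(
                [
                    consensus.name,
                    "tecascade",
                    "long_terminal_repeat",
                    str(start + 1),
                    str(end),
                    ".",
                    "+",
                    ".",
                    f"ID={consensus.name}_{label}",
                ]
            )
        )
    return lines


def load_consensus_library(
    path: str | Path, min_ltr: int = 100, max_mismatch_frac: float = 0.05
) -> list[TEConsensus]:
    """Read a consensus FASTA and annotate LTRs where detectable."""
    out = []
    for name, seq in read_fasta(path):
        cons = TEConsensus(name=name, sequence=seq)
        if len(seq) > 2 * min_ltr:
            detected = detect_ltrs(cons, min_ltr=min_ltr, max_mismatch_frac=max_mismatch_frac)
            if detected is not None:
                cons = detected
        out.append(cons)
    return out
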