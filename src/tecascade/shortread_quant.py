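"""Coverage-normalised TE copy number and TE-internal SNPs from short reads.

The estimator follows the single-copy-gene normalisation logic: reads are
mapped to a joint reference of TE consensus sequences and single-copy genes
(SCGs), per-position pileups are built on each reference, and the copy
number of a TE is its mean consensus coverage divided by the mean of the
per-SCG mean coverages.  Since an SCG is present once per haploid genome,
the ratio reads out haploid-equivalent TE copies.  A TE is called present
in a strain when the estimate exceeds 1, which ignores sub-single-copy
coverage from degraded ancient fragments.

TE-internal SNPs are variants segregating among the dispersed copies of a
family: on the consensus pileup they appear as intermediate-frequency
minor alleles.  A site is called when its minor allele frequency exceeds
0.1 (strictly) at adequate depth.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
import pysam

from .te_library import reverse_complement

_BASE_IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte codes
_BASES = "ACGT"
_CIGAR_RE = re.compile(r"(\d+)([=XIDMSH])")

DEFAULT_SEED_K = 31
DEFAULT_MIN_IDENTITY = 0.85


@dataclass
class Alignment:
    """One read aligned to one reference, oriented to the reference strand."""

    read: str
    ref: str
    pos: int  # 0-based leftmost reference position
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]  # ops in {'=', 'X', 'M', 'I', 'D', 'S'}
    seq: str  # read sequence in reference orientation
    edit_distance: int

    @property
    def identity(self) -> float:
        return 1.0 - self.edit_distance / max(1, len(self.seq))


@dataclass
class CopyNumberEstimate:
    strain: str
    te: str
    copy_number: float
    te_mean_depth: float
    scg_mean_depths: list[float]

    @property
    def present(self) -> bool:
        return self.copy_number > 1.0


@dataclass(frozen=True)
class TESnp:
    te: str
    pos: int
    major: str
    minor: str
    maf: float


@dataclass(frozen=True)
class PileupColumn:
    ref: str
    pos: int
    depth: int
    counts: tuple[int, int, int, int]  # A, C, G, T


class Pileup:
    """Per-position base counts along one reference."""

    def __init__(self, ref: str, length: int):
        self.ref = ref
        self.counts = np.zeros((length, 4), dtype=np.int64)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.counts) else 0.0

    def columns(self) -> list[PileupColumn]:
        d = self.depth
        return [
            PileupColumn(self.ref, i, int(d[i]), tuple(int(c) for c in self.counts[i]))
            for i in range(len(self.counts))
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(_BASES))
        df.insert(0, "pos", np.arange(len(self.counts)))
        df.insert(0, "ref", self.ref)
        df["depth"] = self.counts.sum(axis=1)
        return df


def trim_reads(
    reads: Iterable[tuple[str, str]], target_length: int = 100
) -> tuple[list[tuple[str, str]], int]:
    """Truncate reads to ``target_length`` from the 3' end; drop shorter reads.

    Returns (trimmed reads, number dropped).
    """
    if target_length < 30:
        raise ValueError("target_length must be >= 30")
    out, dropped = [], 0
    for name, seq in reads:
        if len(seq) < target_length:
            dropped += 1
        else:
            out.append((name, seq[:target_length]))
    if not out:
        warnings.warn("no reads survived trimming")
    return out, dropped


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


class _ReferenceIndex:
    """Sampled k-mer index over reference sequences for candidate filtering."""

    def __init__(self, references: Sequence[tuple[str, str]], k: int):
        self.k = k
        self.names = [name for name, _ in references]
        self.seqs = [seq.upper() for _, seq in references]
        for name, seq in zip(self.names, self.seqs):
            if set(seq) - set("ACGTN"):
                raise ValueError(f"reference {name!r} contains non-ACGTN characters")
        self.kmer_refs: dict[str, set[int]] = {}
        for i, seq in enumerate(self.seqs):
            for j in range(len(seq) - k + 1):
                self.kmer_refs.setdefault(seq[j : j + k], set()).add(i)

    def candidates(self, seq: str) -> set[int]:
        k = self.k
        if len(seq) < k:
            return set(range(len(self.names)))
        hits: set[int] = set()
        stride = max(1, (len(seq) - k) // 8 or 1)
        positions = list(range(0, len(seq) - k + 1, stride))
        if positions[-1] != len(seq) - k:
            positions.append(len(seq) - k)
        for j in positions:
            refs = self.kmer_refs.get(seq[j : j + k])
            if refs:
                hits |= refs
        return hits


def map_reads(
    reads: Iterable[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    k: int = DEFAULT_SEED_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[Alignment]:
    """Best-hit mapping of reads to small references (TE consensus + SCGs).

    Candidate references are found by exact k-mer seeding; the gapped
    extension against each candidate is a banded edit-distance alignment
    (infix mode: the read must align end-to-end, the reference locally).
    Both strands are searched; the best alignment by edit distance wins,
    ties broken by forward strand, then reference order, then leftmost
    position.  Alignments below ``min_identity`` are discarded.
    """
    if not references:
        raise ValueError("no references given")
    index = _ReferenceIndex(references, k)
    out: list[Alignment] = []
    max_dist = lambda L: int(np.floor((1.0 - min_identity) * L))
    for name, seq in reads:
        seq = seq.upper()
        best: Alignment | None = None
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            cand = index.candidates(oriented)
            for ref_i in sorted(cand):
                res = edlib.align(
                    oriented,
                    index.seqs[ref_i],
                    mode="HW",
                    task="path",
                    k=max_dist(len(oriented)),
                )
                if res["editDistance"] < 0:
                    continue
                start = res["locations"][0][0]
                aln = Alignment(
                    read=name,
                    ref=index.names[ref_i],
                    pos=start,
                    strand=strand,
                    cigar=_parse_cigar(res["cigar"]),
                    seq=oriented,
                    edit_distance=res["editDistance"],
                )
                if best is None or aln.edit_distance < best.edit_distance:
                    best = aln
        if best is not None:
            out.append(best)
    return out


def pileup(
    alignments: Iterable[Alignment], references: Sequence[tuple[str, str]]
) -> dict[str, Pileup]:
    """Per-reference pileups: aligned (match/mismatch) bases counted per column.

    Deletions skip columns, insertions are ignored, soft-clipped bases are
    excluded.  An alignment running past the reference end raises, naming
    the read.
    """
    lengths = {name: len(seq) for name, seq in references}
    piles = {name: Pileup(name, L) for name, L in lengths.items()}
    for aln in alignments:
        if aln.ref not in piles:
            raise ValueError(f"read {aln.read!r} aligned to unknown reference {aln.ref!r}")
        pile = piles[aln.ref]
        ref_pos = aln.pos
        read_pos = 0
        enc = np.frombuffer(aln.seq.encode("ascii"), dtype=np.uint8)
        for op, n in aln.cigar:
            if op in ("=", "X", "M"):
                if ref_pos + n > lengths[aln.ref]:
                    raise ValueError(
                        f"read {aln.read!r} aligns past the end of {aln.ref!r}"
                    )
                seg = enc[read_pos : read_pos + n]
                base_idx = np.array([_BASE_IDX.get(b, -1) for b in seg])
                valid = base_idx >= 0
                np.add.at(
                    pile.counts,
                    (np.arange(ref_pos, ref_pos + n)[valid], base_idx[valid]),
                    1,
                )
                ref_pos += n
                read_pos += n
            elif op == "D":
                ref_pos += n
            elif op in ("I", "S"):
                read_pos += n
            elif op == "H":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op!r} in read {aln.read!r}")
    return piles


def estimate_copy_number(
    te_pileup: Pileup, scg_pileups: Sequence[Pileup], strain: str = ""
) -> CopyNumberEstimate:
    """TE mean coverage normalised by mean single-copy-gene coverage."""
    scg_means = [p.mean_depth for p in scg_pileups]
    if not scg_means or all(m == 0 for m in scg_means):
        raise ValueError(
            "all single-copy genes have zero coverage; normalisation impossible "
            "(failed sequencing or mapping?)"
        )
    norm = float(np.mean(scg_means))
    te_mean = te_pileup.mean_depth
    return CopyNumberEstimate(
        strain=strain,
        te=te_pileup.ref,
        copy_number=te_mean / norm,
        te_mean_depth=te_mean,
        scg_mean_depths=scg_means,
    )


def call_te_snps(
    te_pileup: Pileup, maf_threshold: float = 0.1, min_depth: int = 10
) -> list[TESnp]:
    """Sites where the minor allele frequency strictly exceeds the threshold.

    The minor allele is the second-most-frequent base, so maf <= 0.5 always.
    """
    counts = te_pileup.counts
    depth = counts.sum(axis=1)
    order = np.argsort(counts, axis=1)
    out = []
    for pos in np.nonzero(depth >= min_depth)[0]:
        major_i = order[pos, 3]
        minor_i = order[pos, 2]
        maf = counts[pos, minor_i] / depth[pos]
        if maf > maf_threshold:
            out.append(
                TESnp(
                    te=te_pileup.ref,
                    pos=int(pos),
                    major=_BASES[major_i],
                    minor=_BASES[minor_i],
                    maf=float(maf),
                )
            )
    return out


# --- SAM interchange -------------------------------------------------------


def write_sam(
    alignments: Iterable[Alignment],
    references: Sequence[tuple[str, str]],
    path: str | Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in references],
    }
    ref_ids = {name: i for i, (name, _) in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.read
            a.query_sequence = aln.seq
            a.flag = 16 if aln.strand == "-" else 0
            a.reference_id = ref_ids[aln.ref]
            a.reference_start = aln.pos
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{op}" for op, n in aln.cigar)
            a.set_tag("NM", aln.edit_distance)
            fh.write(a)


def read_sam(path: str | Path) -> list[Alignment]:
    """Load externally produced alignments (SAM); standard flags/CIGAR honoured."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cigar = [
                ("MIDNSHP=XB"[op], n) for op, n in rec.cigartuples or []
            ]
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                Alignment(
                    read=rec.query_name,
                    ref=rec.reference_name,
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    cigar=cigar,
                    seq=rec.query_sequence or "",
                    edit_distance=int(nm),
                )
            )
    return out


# --- One-call convenience used by the analysis drivers ---------------------


def quantify(
    reads: Sequence[tuple[str, str]],
    te_references: Sequence[tuple[str, str]],
    scg_references: Sequence[tuple[str, str]],
    strain: str = "",
    maf_threshold: float = 0.1,
    min_depth: int = 10,
    trim_to: int | None = 100,
    sam_path: str | Path | None = None,
    alignments: Sequence[Alignment] | None = None,
) -> tuple[list[CopyNumberEstimate], dict[str, list[TESnp]], dict[str, Pileup]]:
    """Trim, map, pile up, and report copy numbers + SNPs for each TE."""
    if trim_to is not None:
        reads, _ = trim_reads(reads, trim_to)
    refs = list(te_references) + list(scg_references)
    if alignments is None:
        alignments = map_reads(reads, refs)
        if sam_path is not None:
            write_sam(alignments, refs, sam_path)
    piles = pileup(alignments, refs)
    scg_piles = [piles[name] for name, _ in scg_references]
    estimates, snps = [], {}
    for name, _seq in te_references:
        est = estimate_copy_number(piles[name], scg_piles, strain=strain)
        estimates.append(est)
        snps[name] = call_te_snps(piles[name], maf_threshold, min_depth)
    return estimates, snps, piles


def estimates_to_frame(estimates: Sequence[CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": [e.strain for e in estimates],
            "te": [e.te for e in estimates],
            "copy_number": [e.copy_number for e in estimates],
            "present": [e.present for e in estimates],
        }
    )


def snps_to_frame(snps: Sequence[TESnp]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "te": [s.te for s in snps],
            "pos": [s.pos for s in snps],
            "major": [s.major for s in snps],
            "minor": [s.minor for s in snps],
            "maf": [s.maf for s in snps],
        }
    )
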