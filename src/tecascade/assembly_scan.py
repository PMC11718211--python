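"""Find and characterise TE insertions in genome assemblies.

A seed-and-extend local-alignment scanner locates copies of a TE consensus
in an assembly; hits are filtered with the insertion-counting rules used
throughout the analysis (aligned length strictly > 750 bp, divergence
strictly < 10%), classified as full-length (> 80% of the consensus with
both LTRs), and summarised across assemblies with the similarity statistic
s = best score in an assembly / best score in any assembly, so s = 1 marks
the assembly carrying the closest relative of the consensus and s = 0 an
assembly with no detectable similarity.

The same alignment engine backs pairwise insertion identity and the
horizontal-transfer divergence test: a TE transferred between two species
recently is more similar between them than any vertically inherited host
gene, so HT is supported when the TE identity exceeds the maximum host
ortholog identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .te_library import GenomicInterval, TEConsensus, reverse_complement

_N = ord("N")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a gap of length L costs gap_open + gap_extend * L."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1


DEFAULT_SCORING = ScoringScheme()


@dataclass
class LocalAlignment:
    score: int
    query_span: tuple[int, int]  # [start, end) on query
    target_span: tuple[int, int]  # [start, end) on target
    matches: int
    mismatches: int
    gap_columns: int

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches

    @property
    def divergence(self) -> float:
        """Percent mismatched of aligned (match+mismatch) columns; gaps excluded."""
        cols = self.aligned_columns
        return 100.0 * self.mismatches / cols if cols else 0.0

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return 100.0 * self.matches / cols if cols else 0.0


@dataclass
class InsertionHit:
    assembly: str
    location: GenomicInterval
    te: str
    score: int
    divergence: float
    consensus_span: tuple[int, int]  # forward-consensus coordinates
    fraction_of_consensus: float
    full_length: bool = False

    @property
    def aligned_length(self) -> int:
        return len(self.location)


@dataclass(frozen=True)
class SimilarityScore:
    assembly: str
    te: str
    s: float
    best_score: int
    max_score: int


@dataclass
class ClusterCount:
    assembly: str
    cluster: str
    te: str
    insertion_sites: list[GenomicInterval] = field(default_factory=list)

    @property
    def n_insertions(self) -> int:
        return len(self.insertion_sites)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def smith_waterman(
    query: str, target: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> LocalAlignment | None:
    """Optimal local alignment under affine gap costs (full dynamic program).

    Vectorised row-by-row; the horizontal gap state is folded into a running
    prefix maximum, which is exact because with a negative open cost a single
    gap always scores at least as well as any chain of gaps covering the same
    columns.  Returns None when the best local score is 0 (no alignment).
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    q = _encode(query)
    t = _encode(target)
    n, m = len(q), len(t)
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    NEG = np.int32(-(2**30))
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    F = np.full(m, NEG, dtype=np.int32)
    cols = np.arange(m, dtype=np.int32)
    best_score, best_i, best_j = 0, 0, 0
    for i in range(1, n + 1):
        eq = (t == q[i - 1]) & (t != _N) & (q[i - 1] != _N)
        sub = np.where(eq, ma, mi).astype(np.int32)
        diag = H[i - 1, :-1] + sub
        F = np.maximum(F + ge, H[i - 1, 1:] + go + ge)
        G = np.maximum(np.maximum(diag, F), 0)
        # horizontal gaps: E[j] = max_{j'<j} (G[j'] + go + ge*(j - j'))
        M = np.maximum.accumulate(G - ge * cols)
        row = G.copy()
        if m > 1:
            E = M[:-1] + go + ge * cols[1:]
            np.maximum(row[1:], E, out=row[1:])
        H[i, 1:] = row
        j_best = int(np.argmax(row))
        if row[j_best] > best_score:
            best_score, best_i, best_j = int(row[j_best]), i, j_best + 1
    if best_score <= 0:
        return None
    return _traceback(H, q, t, best_i, best_j, best_score, scoring)


def _traceback(
    H: np.ndarray,
    q: np.ndarray,
    t: np.ndarray,
    i: int,
    j: int,
    score: int,
    scoring: ScoringScheme,
) -> LocalAlignment:
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    q_end, t_end = i, j
    matches = mismatches = gap_cols = 0
    while H[i, j] > 0:
        is_match = q[i - 1] == t[j - 1] and q[i - 1] != _N and t[j - 1] != _N
        s = ma if is_match else mi
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
            matches += int(is_match)
            mismatches += int(not is_match)
            i -= 1
            j -= 1
            continue
        stepped = False
        for l in range(1, j + 1):  # horizontal gap (consumes target)
            if H[i, j] == H[i, j - l] + go + ge * l and H[i, j - l] > 0:
                gap_cols += l
                j -= l
                stepped = True
                break
        if stepped:
            continue
        for l in range(1, i + 1):  # vertical gap (consumes query)
            cand = H[i - l, j] + go + ge * l
            if H[i, j] == cand and H[i - l, j] > 0:
                gap_cols += l
                i -= l
                stepped = True
                break
        if not stepped:
            raise RuntimeError("traceback failed; inconsistent DP matrix")
    return LocalAlignment(
        score=score,
        query_span=(i, q_end),
        target_span=(j, t_end),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gap_cols,
    )


# --- seed-and-extend scanning ---------------------------------------------


def _seed_clusters(
    query: str, target: str, k: int, cluster_gap: int
) -> list[tuple[int, int]]:
    """Target positions sharing a k-mer with the query, merged into clusters."""
    kmers: dict[str, bool] = {}
    for i in range(len(query) - k + 1):
        kmers[query[i : i + k]] = True
    positions = [j for j in range(len(target) - k + 1) if target[j : j + k] in kmers]
    clusters: list[tuple[int, int]] = []
    for p in positions:
        if clusters and p - clusters[-1][1] <= cluster_gap:
            clusters[-1] = (clusters[-1][0], p + k)
        else:
            clusters.append((p, p + k))
    return clusters


def scan_assembly(
    assembly: Sequence[tuple[str, str]],
    consensus: TEConsensus,
    min_len: int = 750,
    max_div: float = 10.0,
    scoring: ScoringScheme = DEFAULT_SCORING,
    seed_k: int = 13,
    cluster_gap: int = 400,
    window_margin: int = 300,
    merge_gap: int = 100,
    min_score: int = 50,
    assembly_name: str = "assembly",
    apply_filters: bool = True,
) -> list[InsertionHit]:
    """Locate consensus copies in an assembly on both strands.

    Candidate loci are found by exact k-mer seeding and each locus is resolved
    with the full local-alignment dynamic program on a padded window, so for
    targets no larger than one window the scan reduces to the exact optimum.
    Nearby same-strand hits are chained into one insertion.  Chained hits
    scoring below ``min_score`` are discarded as seed-level noise (chance
    k-mer matches in unrelated sequence); the insertion-counting filters
    (aligned length strictly > ``min_len``, divergence strictly <
    ``max_div``) are applied on top unless ``apply_filters`` is False.
    """
    hits: list[InsertionHit] = []
    for contig, seq in assembly:
        seq = seq.upper()
        for strand, query in (("+", consensus.sequence), ("-", reverse_complement(consensus.sequence))):
            for lo, hi in _seed_clusters(query, seq, seed_k, cluster_gap):
                w_lo = max(0, lo - window_margin)
                w_hi = min(len(seq), hi + window_margin)
                aln = smith_waterman(query, seq[w_lo:w_hi], scoring)
                if aln is None:
                    continue
                qs, qe = aln.query_span
                if strand == "-":
                    L = consensus.length
                    qs, qe = L - qe, L - qs
                hits.append(
                    InsertionHit(
                        assembly=assembly_name,
                        location=GenomicInterval(
                            contig, w_lo + aln.target_span[0], w_lo + aln.target_span[1], strand
                        ),
                        te=consensus.name,
                        score=aln.score,
                        divergence=aln.divergence,
                        consensus_span=(qs, qe),
                        fraction_of_consensus=(qe - qs) / consensus.length,
                    )
                )
    hits = merge_hits(hits, merge_gap=merge_gap, consensus_length=consensus.length)
    hits = [h for h in hits if h.score >= min_score]
    if apply_filters:
        hits = apply_hit_filters(hits, min_len=min_len, max_div=max_div)
    return hits


def merge_hits(
    hits: Sequence[InsertionHit],
    merge_gap: int = 100,
    consensus_length: int | None = None,
) -> list[InsertionHit]:
    """Chain same-contig, same-strand hits within ``merge_gap`` nt into one.

    The chained insertion keeps the best component's score, spans the union of
    the component intervals and consensus spans, and averages divergence
    weighted by aligned length.
    """
    order = sorted(
        hits, key=lambda h: (h.location.contig, h.location.strand, h.location.start)
    )
    out: list[InsertionHit] = []
    for h in order:
        if out:
            p = out[-1]
            same = (
                p.location.contig == h.location.contig
                and p.location.strand == h.location.strand
                and h.location.start - p.location.end <= merge_gap
            )
            if same:
                w_p, w_h = len(p.location), len(h.location)
                cs = (
                    min(p.consensus_span[0], h.consensus_span[0]),
                    max(p.consensus_span[1], h.consensus_span[1]),
                )
                if consensus_length is None:
                    # recover the consensus length from a component's fraction
                    consensus_length = round(
                        (p.consensus_span[1] - p.consensus_span[0])
                        / max(p.fraction_of_consensus, 1e-9)
                    )
                best = p if (p.score, w_p) >= (h.score, w_h) else h
                out[-1] = replace(
                    best,
                    location=GenomicInterval(
                        p.location.contig,
                        p.location.start,
                        max(p.location.end, h.location.end),
                        p.location.strand,
                    ),
                    divergence=(p.divergence * w_p + h.divergence * w_h) / (w_p + w_h),
                    consensus_span=cs,
                    fraction_of_consensus=min(1.0, (cs[1] - cs[0]) / consensus_length),
                )
                continue
        out.append(h)
    return sorted(out, key=lambda h: (h.location.contig, h.location.start))


def apply_hit_filters(
    hits: Iterable[InsertionHit], min_len: int = 750, max_div: float = 10.0
) -> list[InsertionHit]:
    """Insertion-counting filters: aligned length > min_len AND divergence < max_div.

    Both inequalities are strict: a 750 bp hit or a 10.0% diverged hit is
    excluded.
    """
    return [
        h for h in hits if h.aligned_length > min_len and h.divergence < max_div
    ]


def classify_full_length(hit: InsertionHit, consensus: TEConsensus) -> bool:
    """Complete insertion: > 80% of the consensus covered, including both LTRs.

    "Including an LTR" is read as the consensus span covering at least 80% of
    that LTR interval.
    """
    if not consensus.has_ltrs:
        raise ValueError(
            f"consensus {consensus.name!r} has no LTR annotation; run detect_ltrs first"
        )
    if hit.fraction_of_consensus <= 0.8:
        return False
    a, b = hit.consensus_span
    for lo, hi in (consensus.ltr5, consensus.ltr3):
        covered = max(0, min(b, hi) - max(a, lo))
        if covered < 0.8 * (hi - lo):
            return False
    return True


def similarity_scores(
    hits_by_assembly: Mapping[str, Sequence[InsertionHit]], te: str
) -> list[SimilarityScore]:
    """s = best hit score per assembly / best hit score over all assemblies."""
    best: dict[str, int] = {}
    for assembly, hits in hits_by_assembly.items():
        scores = [h.score for h in hits if h.te == te]
        best[assembly] = max(scores) if scores else 0
    max_score = max(best.values(), default=0)
    if max_score == 0:
        warnings.warn(f"no hits for {te!r} in any assembly; all s = 0")
        return [
            SimilarityScore(a, te, 0.0, 0, 0) for a in hits_by_assembly
        ]
    return [
        SimilarityScore(a, te, best[a] / max_score, best[a], max_score)
        for a in hits_by_assembly
    ]


# --- genic context ---------------------------------------------------------

GENIC_CLASSES = ("promoter", "five_prime_utr", "exon", "intron", "three_prime_utr", "intergenic")


def read_gff(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "frame", "attributes"],
        dtype={"start": int, "end": int},
    )
    return df


def genic_context(
    hit: InsertionHit, genes: pd.DataFrame, promoter_window: int = 1000
) -> str:
    """Classify an insertion's genic location, promoter taking precedence.

    Promoter = within ``promoter_window`` nt upstream of a transcription start
    site (strand-aware).  Otherwise the innermost overlapping feature wins
    (UTR over exon over intron); no overlap with any gene → intergenic.
    GFF coordinates are 1-based inclusive; hits are 0-based half-open.
    """
    loc = hit.location
    feats = genes[genes["seqid"] == loc.contig]
    gene_rows = feats[feats["type"].str.lower().isin(["gene", "mrna"])]
    for _, g in gene_rows.iterrows():
        if g["strand"] not in ("+", "-"):
            raise ValueError(f"gene record without strand: {g['attributes']}")
        if g["strand"] == "+":
            win_lo, win_hi = g["start"] - 1 - promoter_window, g["start"] - 1
        else:
            win_lo, win_hi = g["end"], g["end"] + promoter_window
        if loc.start < win_hi and win_lo < loc.end:
            return "promoter"
    overlap_types: set[str] = set()
    for _, f in feats.iterrows():
        f_lo, f_hi = f["start"] - 1, f["end"]
        if loc.start < f_hi and f_lo < loc.end:
            overlap_types.add(str(f["type"]).lower())
    for cls in ("five_prime_utr", "three_prime_utr"):
        if cls in overlap_types:
            return cls
    if "exon" in overlap_types:
        return "exon"
    if "intron" in overlap_types or overlap_types & {"gene", "mrna"}:
        return "intron"
    return "intergenic"


# --- piRNA-cluster (trap model) accounting ---------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def count_in_cluster(
    hits: Iterable[InsertionHit],
    cluster_intervals: Sequence[GenomicInterval],
    cluster_name: str = "flamenco",
    te: str | None = None,
    assembly_name: str = "assembly",
) -> ClusterCount:
    """Count hits overlapping the piRNA cluster (>= 1 bp overlap counts)."""
    sites = []
    te_name = te
    for h in hits:
        if te is not None and h.te != te:
            continue
        te_name = h.te if te_name is None else te_name
        if any(h.location.overlaps(c) for c in cluster_intervals):
            sites.append(h.location)
    return ClusterCount(
        assembly=assembly_name,
        cluster=cluster_name,
        te=te_name or "",
        insertion_sites=sites,
    )


def trap_check(count: ClusterCount) -> str:
    """Trap-model expectation: exactly one cluster insertion stops an invasion.

    'consistent' for exactly one insertion, 'pre_trap' for none (invasion not
    yet stopped), 'multi' for two or more.
    """
    n = count.n_insertions
    if n == 0:
        return "pre_trap"
    if n == 1:
        return "consistent"
    return "multi"


def _flank_signature(
    site: GenomicInterval,
    te_annotations: Sequence[tuple[GenomicInterval, str]],
    flank_window: int,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    left = [
        (iv.start, name)
        for iv, name in te_annotations
        if iv.contig == site.contig and iv.end <= site.start and iv.end > site.start - flank_window
    ]
    right = [
        (iv.start, name)
        for iv, name in te_annotations
        if iv.contig == site.contig and iv.start >= site.end and iv.start < site.end + flank_window
    ]
    return (
        tuple(name for _s, name in sorted(left)),
        tuple(name for _s, name in sorted(right)),
    )


def independent_insertion_sites(
    cluster_counts: Mapping[str, ClusterCount],
    te_annotations: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    flank_window: int = 2000,
) -> int:
    """Number of independent cluster-insertion events across strains.

    Two strains' cluster insertions descend from the same event iff the
    ordered TE names flanking the insertion match on at least one side
    (synteny of the TE neighbourhood); lack of synteny on both sides is
    evidence for independent insertion.  Counts equivalence classes under
    the transitive closure of that relation.  Empty flank signatures on both
    sides are treated as uninformative and never merge two strains.
    """
    entries = []
    for strain, count in cluster_counts.items():
        for site in count.insertion_sites:
            sig = _flank_signature(site, te_annotations.get(strain, ()), flank_window)
            entries.append((strain, sig))
    parent = list(range(len(entries)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            (l1, r1), (l2, r2) = entries[i][1], entries[j][1]
            if (l1 and l1 == l2) or (r1 and r1 == r2):
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    return len({find(i) for i in range(len(entries))})


# --- pairwise identity and the HT divergence test --------------------------


def pairwise_identity(
    seq_a: str, seq_b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> tuple[float, int]:
    """Percent identity over the best local alignment, plus aligned columns."""
    if len(seq_a) <= 100 or len(seq_b) <= 100:
        raise ValueError("sequences must be > 100 nt for a meaningful identity")
    aln = smith_waterman(seq_a, seq_b, scoring)
    if aln is None:
        return 0.0, 0
    return aln.identity, aln.aligned_columns


def ht_divergence_test(
    te_identity: float, host_identities: Sequence[float]
) -> tuple[str, float]:
    """Horizontal transfer supported iff the TE is more similar between the
    species than ANY host ortholog (strictly); returns (verdict, margin in
    percentage points)."""
    if len(host_identities) < 10:
        raise ValueError("need >= 10 host ortholog identities")
    margin = te_identity - max(host_identities)
    return ("supported" if margin > 0 else "not_supported"), margin


def hits_to_frame(hits: Sequence[InsertionHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "assembly": [h.assembly for h in hits],
            "contig": [h.location.contig for h in hits],
            "start": [h.location.start for h in hits],
            "end": [h.location.end for h in hits],
            "strand": [h.location.strand for h in hits],
            "te": [h.te for h in hits],
            "score": [h.score for h in hits],
            "divergence": [h.divergence for h in hits],
            "consensus_start": [h.consensus_span[0] for h in hits],
            "consensus_end": [h.consensus_span[1] for h in hits],
            "fraction_of_consensus": [h.fraction_of_consensus for h in hits],
            "full_length": [h.full_length for h in hits],
        }
    )


def hits_to_gff(hits: Sequence[InsertionHit]) -> list[str]:
    lines = []
    for i, h in enumerate(hits):
        attrs = (
            f"ID=te_hit_{i};te={h.te};divergence={h.divergence:.3f};"
            f"score={h.score};full_length={int(h.full_length)}"
        )
        lines.append(
            "\t".join(
                [
                    h.location.contig,
                    "tecascade",
                    "transposable_element",
                    str(h.location.start + 1),
                    str(h.location.end),
                    str(h.score),
                    h.location.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return lines
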