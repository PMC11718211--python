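import numpy as np
import pytest

from tecascade.synthetic_data import SimulationConfig, _random_sequence, synthetic_consensus


@pytest.fixture(scope="session")
def consensus():
    """A 2 kb synthetic LTR element with 300 nt terminal repeats."""
    return synthetic_consensus(seed=1)


@pytest.fixture(scope="session")
def scgs():
    """Three single-copy-gene references, 2 kb each."""
    rng = np.random.default_rng(99)
    return [(f"scg{i}", _random_sequence(rng, 2000)) for i in range(3)]


def planted_snp_spec(consensus, freqs, start=400, step=40):
    """SNP spec in the internal (non-LTR) region, alternate != consensus base."""
    spec = []
    for i, f in enumerate(freqs):
        pos = start + step * i
        alt = "A" if consensus.sequence[pos] != "A" else "C"
        spec.append((pos, alt, f))
    return spec


def brute_force_smith_waterman(q, t, match=1, mismatch=-2, gap_open=-3, gap_extend=-1):
    """Independent cell-by-cell affine-gap local alignment (score only).

    Textbook three-matrix recurrence; a gap of length L costs
    gap_open + gap_extend * L.
    """
    n, m = len(q), len(t)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            s = match if qi == t[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def uniform_5prime_hits(rng, n, consensus_length, weight=1.0):
    """Small-RNA hits whose 5' ends are uniform over the consensus (null model).

    Intervals are clipped at the consensus edges so the 5'-end positions stay
    exactly uniform on both strands.
    """
    from tecascade.smallrna_pingpong import SmallRnaHit

    L = consensus_length
    hits = []
    for i in range(n):
        l = int(rng.integers(23, 30))
        strand = "+" if rng.random() < 0.5 else "-"
        u = int(rng.integers(0, L))  # the 5'-end coordinate
        if strand == "+":
            start, end = u, min(L, u + l)
        else:
            start, end = max(0, u - l + 1), u + 1
        hits.append(SmallRnaHit(f"r{i}", strand, start, end, weight))
    return hits
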