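"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the downstream analyses
assume: genomes carrying dispersed, slightly diverged copies of a TE
consensus (with internal SNPs segregating among copies at set population
frequencies), uniform-coverage error-bearing short reads, piRNA pools with
tunable ping-pong pairing and strand bias, and multi-strain time series in
which a TE is absent before a set invasion year and accumulates copies
afterwards.

Everything returns truth objects alongside the data so tests can score
recovery against planted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .te_library import GenomicInterval, TEConsensus, reverse_complement

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


class PlacementError(RuntimeError):
    """Could not place the requested insertions without overlap."""


@dataclass
class SimulationConfig:
    """Knobs for all generators; fractions are in [0, 1].

    ``te_snp_spec`` lists (consensus position, alternate base, population
    frequency): each planted insertion carries the alternate allele in a
    deterministically rounded ``round(freq * n_insertions)`` subset of copies,
    so the realised frequency is the closest achievable to the requested one.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_insertions: int = 0
    insertion_divergence: float = 0.0
    te_snp_spec: Sequence[tuple[int, str, float]] = ()
    read_length: int = 100
    depth: float = 30.0
    error_rate: float = 0.005
    pirna_n: int = 20_000
    pingpong_fraction: float = 0.0
    antisense_fraction: float = 0.5
    invasion_year: int = 1995
    growth_rate: float = 2.0
    copy_cap: float = 30.0
    min_insertion_spacing: int = 500

    def __post_init__(self) -> None:
        for name in (
            "insertion_divergence",
            "error_rate",
            "pingpong_fraction",
            "antisense_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        for pos, alt, freq in self.te_snp_spec:
            if alt not in _BASE_STR:
                raise ValueError(f"invalid SNP allele {alt!r}")
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"SNP frequency {freq} outside [0, 1]")


@dataclass
class TruthSet:
    """Ground truth recorded by the generators."""

    insertions: list[GenomicInterval] = field(default_factory=list)
    insertion_spans: list[tuple[int, int]] = field(default_factory=list)
    snp_frequencies: dict[int, tuple[str, float]] = field(default_factory=dict)
    copy_numbers: dict[str, float] = field(default_factory=dict)
    invasion_years: dict[str, int] = field(default_factory=dict)
    transfer_edges: list[tuple[str, str, int]] = field(default_factory=list)
    contaminants: set[str] = field(default_factory=set)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at the given per-site rate (always to a different base)."""
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def make_genome(
    config: SimulationConfig,
    consensus: TEConsensus,
    single_copy_genes: Sequence[tuple[str, str]] = (),
    fragments: Sequence[tuple[int, int] | None] | None = None,
    contig: str = "chr1",
) -> tuple[str, TruthSet]:
    """Random background with planted, independently diverged TE copies.

    Each of ``config.n_insertions`` copies of ``consensus`` (or the fragment
    span given in ``fragments``) is mutated at ``insertion_divergence`` and
    spliced into an i.i.d. background of ``genome_length`` nt; planted copies
    keep at least ``min_insertion_spacing`` background nt between them.
    ``single_copy_genes`` are planted exactly once each (undiverged), serving
    as coverage yardsticks.  Truth intervals are in final genome coordinates.
    """
    n = config.n_insertions
    if fragments is not None and len(fragments) != n:
        raise ValueError("fragments must have one entry per insertion")
    if n * consensus.length >= config.genome_length / 2 and n > 0:
        raise ValueError(
            "insertions would exceed half the background; enlarge genome_length"
        )
    rng = np.random.default_rng([config.seed, 1])
    background = _random_sequence(rng, config.genome_length)

    spans = [
        (0, consensus.length) if fragments is None or fragments[i] is None else fragments[i]
        for i in range(n)
    ]
    # which copies carry each planted SNP allele: deterministic rounded counts
    snp_carriers: dict[int, set[int]] = {}
    truth_snps: dict[int, tuple[str, float]] = {}
    for pos, alt, freq in config.te_snp_spec:
        count = int(round(freq * n))
        carriers = set(rng.permutation(n)[:count].tolist()) if n else set()
        snp_carriers[pos] = carriers
        truth_snps[pos] = (alt, count / n if n else 0.0)

    copies: list[str] = []
    for i in range(n):
        a, b = spans[i]
        copy = _mutate(rng, consensus.sequence[a:b], config.insertion_divergence)
        arr = list(copy)
        for pos, alt, _freq in config.te_snp_spec:
            if not a <= pos < b:
                continue
            # override any divergence mutation so realised frequency is exact
            arr[pos - a] = alt if i in snp_carriers[pos] else consensus.sequence[pos]
        copies.append("".join(arr))

    inserts = list(copies) + [seq.upper() for _name, seq in single_copy_genes]
    spacing = config.min_insertion_spacing
    n_ins = len(inserts)
    # draw sorted cut points from a shrunken interval, then re-expand: this
    # yields uniform placements conditioned on pairwise gaps >= spacing
    reduced = config.genome_length - max(0, n_ins - 1) * spacing
    if n_ins and reduced < n_ins:
        raise PlacementError(
            f"could not place {n_ins} insertions with spacing {spacing} "
            f"in a {config.genome_length} nt background"
        )
    raw = np.sort(rng.choice(reduced, size=n_ins, replace=False)) if n_ins else np.array([], dtype=int)
    cuts = raw + spacing * np.arange(n_ins)

    pieces: list[str] = []
    truth = TruthSet()
    prev = 0
    offset = 0
    scg_names = [name for name, _seq in single_copy_genes]
    for idx, cut in enumerate(cuts.tolist()):
        pieces.append(background[prev:cut])
        offset += cut - prev
        ins = inserts[idx]
        start, end = offset, offset + len(ins)
        if idx < n:
            truth.insertions.append(GenomicInterval(contig, start, end, "+"))
            truth.insertion_spans.append(spans[idx])
        pieces.append(ins)
        offset = end
        prev = cut
    pieces.append(background[prev:])
    truth.snp_frequencies = truth_snps
    return "".join(pieces), truth


def simulate_reads(
    genome: str, config: SimulationConfig, read_prefix: str = "read"
) -> list[tuple[str, str]]:
    """Uniform single-end reads at target depth with substitution errors.

    The read count is ``round(depth * len(genome) / read_length)``, so the
    same configuration always yields the same number of reads; the whole
    stream is deterministic under ``config.seed``.
    """
    if not genome:
        raise ValueError("genome is empty")
    L = config.read_length
    n_reads = int(round(config.depth * len(genome) / L))
    if n_reads < 1:
        import warnings

        warnings.warn("requested depth yields <1 read; emitting one read")
        n_reads = 1
    if len(genome) < L:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng([config.seed, 2])
    starts = rng.integers(0, len(genome) - L + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    out = []
    for i, (s, rc) in enumerate(zip(starts.tolist(), strands.tolist())):
        seq = genome[s : s + L]
        if config.error_rate > 0:
            n_err = rng.binomial(L, config.error_rate)
            if n_err:
                seq = _apply_errors(rng, seq, n_err)
        if rc:
            seq = reverse_complement(seq)
        out.append((f"{read_prefix}_{i}", seq))
    return out


def _apply_errors(rng: np.random.Generator, seq: str, n_err: int) -> str:
    arr = list(seq)
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        choices = [b for b in _BASE_STR if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_pirnas(
    consensus: TEConsensus, config: SimulationConfig
) -> list[tuple[str, str, str]]:
    """piRNA-sized reads (23-29 nt) from the consensus, as (name, seq, strand).

    A ``pingpong_fraction`` of reads is generated as sense/antisense pairs
    whose 5' ends overlap by exactly 10 nt (the ping-pong hallmark); the
    remainder is positioned uniformly, antisense with probability
    ``antisense_fraction``.  Strand labels are returned for truth-checking;
    the mapper never sees them.
    """
    L = consensus.length
    if L <= 50:
        raise ValueError("consensus too short for piRNA simulation")
    rng = np.random.default_rng([config.seed, 3])
    n = config.pirna_n
    n_pair_reads = int(round(config.pingpong_fraction * n))
    n_pairs = n_pair_reads // 2
    out: list[tuple[str, str, str]] = []
    seq = consensus.sequence
    for p in range(n_pairs):
        l_s = int(rng.integers(23, 30))
        l_a = int(rng.integers(23, 30))
        # sense 5' at s, antisense 5' at s+9 -> 10 nt 5'-5' overlap
        s = int(rng.integers(l_a - 10, L - l_s + 1))
        sense = seq[s : s + l_s]
        a_hi = s + 10  # antisense occupies [a_hi - l_a, a_hi)
        anti = reverse_complement(seq[a_hi - l_a : a_hi])
        out.append((f"pp{p}_s", sense, "+"))
        out.append((f"pp{p}_a", anti, "-"))
    n_rest = n - 2 * n_pairs
    for i in range(n_rest):
        l = int(rng.integers(23, 30))
        s = int(rng.integers(0, L - l + 1))
        if rng.random() < config.antisense_fraction:
            out.append((f"bg{i}", reverse_complement(seq[s : s + l]), "-"))
        else:
            out.append((f"bg{i}", seq[s : s + l], "+"))
    return out


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def fastq_records(path: str | Path) -> list[tuple[str, str, str]]:
    """Minimal FASTQ reader returning (name, sequence, quality)."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append((header.strip().lstrip("@"), seq, qual))
    return out


@dataclass
class SpeciesPlan:
    """Sampling plan for one species in a cohort time series."""

    species: str
    years: Sequence[int]
    invasion_year: int
    growth_rate: float = 2.0
    strains_per_year: int = 1
    locations: Sequence[str] = ("main",)


@dataclass
class CohortResult:
    samples: pd.DataFrame  # strain_id, species, year, location, fastq_path
    truth: TruthSet
    genomes: dict[str, str] = field(default_factory=dict)


def simulate_cohort(
    plans: Sequence[SpeciesPlan],
    config: SimulationConfig,
    consensus: TEConsensus | None = None,
    single_copy_genes: Sequence[tuple[str, str]] = (),
    generate_reads: bool = False,
    outdir: str | Path | None = None,
    contaminant: tuple[str, int] | None = None,
) -> CohortResult:
    """Multi-species, multi-year cohort with a set invasion year per species.

    True copy number per strain is 0 before the species' invasion year and
    ``min(copy_cap, growth_rate * (year - invasion_year))`` afterwards.  With
    ``generate_reads`` a genome and FASTQ are synthesised per strain (round of
    the true copy number gives the planted copy count); otherwise only truth
    copy numbers are recorded, which is what presence/absence analyses need.
    ``contaminant`` plants one extra strain of (species, year) sampled before
    the invasion yet carrying copies — emulating a mislabelled/contaminated
    sample — and flags it in the truth set.
    """
    rng = np.random.default_rng([config.seed, 4])
    truth = TruthSet()
    rows = []
    genomes: dict[str, str] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    def true_copies(plan: SpeciesPlan, year: int) -> float:
        if year <= plan.invasion_year:
            return 0.0
        return min(config.copy_cap, plan.growth_rate * (year - plan.invasion_year))

    strain_serial = 0
    extra = []
    if contaminant is not None:
        extra.append(contaminant)
    for plan in plans:
        if len(set(plan.years)) < 2:
            raise ValueError(f"{plan.species}: need >=2 distinct sampling years")
        truth.invasion_years[plan.species] = plan.invasion_year
        for year in plan.years:
            for k in range(plan.strains_per_year):
                strain = f"{plan.species}_{year}_{strain_serial}"
                strain_serial += 1
                cn = true_copies(plan, year)
                loc = plan.locations[strain_serial % len(plan.locations)]
                rows.append(_cohort_row(strain, plan.species, year, loc))
                truth.copy_numbers[strain] = cn
                if generate_reads:
                    genomes[strain] = _strain_genome(
                        config, consensus, single_copy_genes, cn, seed=config.seed + strain_serial
                    )
    for species, year in extra:
        plan = next(p for p in plans if p.species == species)
        strain = f"{species}_{year}_cont{strain_serial}"
        strain_serial += 1
        cn = max(2.0, config.copy_cap / 2)
        rows.append(_cohort_row(strain, species, year, plan.locations[0]))
        truth.copy_numbers[strain] = cn
        truth.contaminants.add(strain)
        if generate_reads:
            genomes[strain] = _strain_genome(
                config, consensus, single_copy_genes, cn, seed=config.seed + strain_serial
            )

    samples = pd.DataFrame(rows)
    if generate_reads and outdir is not None:
        paths = []
        for row in rows:
            strain = row["strain_id"]
            fq = outdir / f"{strain}.fastq"
            cfg = replace(config, seed=config.seed + hash(strain) % 2**20)
            write_fastq(fq, simulate_reads(genomes[strain], cfg, read_prefix=strain))
            paths.append(str(fq))
        samples["fastq_path"] = paths
    return CohortResult(samples=samples, truth=truth, genomes=genomes)


def _cohort_row(strain: str, species: str, year: int, location: str) -> dict:
    return {
        "strain_id": strain,
        "species": species,
        "year": year,
        "location": location,
        "fastq_path": "",
    }


def _strain_genome(
    config: SimulationConfig,
    consensus: TEConsensus | None,
    single_copy_genes: Sequence[tuple[str, str]],
    copy_number: float,
    seed: int,
) -> str:
    if consensus is None:
        raise ValueError("generate_reads requires a consensus sequence")
    cfg = replace(config, seed=seed, n_insertions=int(round(copy_number)))
    genome, _truth = make_genome(cfg, consensus, single_copy_genes=single_copy_genes)
    return genome


def synthetic_consensus(
    seed: int = 0, internal_length: int = 1400, ltr_length: int = 300, name: str = "synthTE"
) -> TEConsensus:
    """A synthetic LTR element: identical terminal repeats around a random core."""
    rng = np.random.default_rng([seed, 5])
    ltr = _random_sequence(rng, ltr_length)
    core = _random_sequence(rng, internal_length)
    seq = ltr + core + ltr
    return TEConsensus(
        name=name,
        sequence=seq,
        ltr_length=ltr_length,
        ltr5=(0, ltr_length),
        ltr3=(len(seq) - ltr_length, len(seq)),
    )
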