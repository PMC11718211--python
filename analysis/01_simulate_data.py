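#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Produces, under results/data/: a TE consensus library (FASTA + LTR GFF),
four genome assemblies carrying one planted insertion each at increasing
divergence, a depth-30 short-read FASTQ for one strain, two piRNA pools
(one with ping-pong pairing on both strands, one antisense-only), and a
multi-species cohort sample sheet with true copy numbers per strain.
"""

import json
from pathlib import Path

import numpy as np

from tecascade.synthetic_data import (
    SimulationConfig,
    SpeciesPlan,
    _random_sequence,
    make_genome,
    simulate_cohort,
    simulate_pirnas,
    simulate_reads,
    synthetic_consensus,
    write_fastq,
)
from tecascade.te_library import ltr_gff_lines, write_fasta

OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 11


def main() -> None:
    consensus = synthetic_consensus(seed=SEED)
    rng = np.random.default_rng([SEED, 99])
    scgs = [(f"scg{i}", _random_sequence(rng, 2000)) for i in range(3)]
    write_fasta(OUT / "te_consensus.fasta", [(consensus.name, consensus.sequence)])
    write_fasta(OUT / "scg.fasta", scgs)
    (OUT / "te_consensus_ltrs.gff").write_text("\n".join(ltr_gff_lines(consensus)) + "\n")

    divergences = [0.0, 0.03, 0.06, 0.09]
    for i, div in enumerate(divergences):
        cfg = SimulationConfig(seed=SEED + i, genome_length=30_000, n_insertions=1,
                               insertion_divergence=div)
        genome, truth = make_genome(cfg, consensus)
        write_fasta(OUT / f"assembly_div{int(div*100):02d}.fasta", [("chr1", genome)])
    print(f"wrote {len(divergences)} assemblies with planted divergence {divergences}")

    cfg = SimulationConfig(seed=SEED, genome_length=60_000, n_insertions=5,
                           depth=30, error_rate=0.005)
    genome, truth = make_genome(cfg, consensus, single_copy_genes=scgs)
    write_fastq(OUT / "strain_reads.fastq", simulate_reads(genome, cfg))
    print(f"wrote depth-30 reads for a 5-copy strain "
          f"({len(truth.insertions)} planted insertions)")

    for tag, pp, anti in [("germline", 0.5, 0.5), ("somatic", 0.0, 1.0)]:
        cfg = SimulationConfig(seed=SEED, pirna_n=20_000, pingpong_fraction=pp,
                               antisense_fraction=anti)
        reads = [(n, s) for n, s, _ in simulate_pirnas(consensus, cfg)]
        write_fastq(OUT / f"pirnas_{tag}.fastq", reads)
    print("wrote germline-like and somatic-like piRNA pools (20k reads each)")

    plans = [
        SpeciesPlan("D.simulans", years=[1961, 1975, 1982, 1988, 1998, 2004, 2015],
                    invasion_year=1995),
        SpeciesPlan("D.mauritiana", years=[1985, 1999, 2006, 2012], invasion_year=2003),
        SpeciesPlan("D.sechellia", years=[1981, 2003, 2012, 2019], invasion_year=2008),
    ]
    res = simulate_cohort(plans, SimulationConfig(seed=SEED),
                          contaminant=("D.simulans", 1975))
    res.samples.to_csv(OUT / "sample_sheet.tsv", sep="\t", index=False)
    with open(OUT / "cohort_truth.json", "w") as fh:
        json.dump(
            {
                "copy_numbers": res.truth.copy_numbers,
                "invasion_years": res.truth.invasion_years,
                "contaminants": sorted(res.truth.contaminants),
            },
            fh, indent=2,
        )
    n_pre = sum(1 for v in res.truth.copy_numbers.values() if v == 0)
    print(f"cohort: {len(res.samples)} strains, {n_pre} pre-invasion, "
          f"1 planted contaminant")


if __name__ == "__main__":
    main()
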