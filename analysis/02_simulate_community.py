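#!/usr/bin/env python
"""Generate the synthetic gut community and its cleavage reads.

Study conditions: 20 genomes of 200 kb; 10% of genomes carry a PT system
(one single-strand C*AG carrier, one bistranded G*AAC/G*TTC carrier) at
12.5% consensus occupancy; 200k reads of 150 nt with a 20% background-nick
fraction.  Sequence data (FASTA/FASTQ) go to scratch/ (large); the ground
truth tables and run configuration go to results/.
"""

import argparse
from pathlib import Path

import yaml

from ptscope import community

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()

    results = ROOT / "results"
    scratch = ROOT / "scratch"
    results.mkdir(exist_ok=True)
    scratch.mkdir(exist_ok=True)

    com = community.build_community(seed=args.seed)
    reads = community.simulate_ptseq_reads(com, seed=args.seed + 1)

    com.write_fasta(scratch / "community_genomes.fasta")
    reads.write_fastq(scratch / "ptseq_reads.fastq")
    com.truth_frame().to_csv(results / "planted_sites.tsv", sep="\t", index=False)

    config = {
        "master_seed": args.seed,
        "read_seed": args.seed + 1,
        "n_genomes": len(com.genomes),
        "genome_length": com.genomes[0].length,
        "pt_genomes": {
            gid: next(g for g in com.genomes if g.genome_id == gid).systems[0].label()
            for gid in com.pt_genome_ids
        },
        "abundances": {g: round(float(a), 6) for g, a in zip(com.genome_ids, com.abundances)},
        "n_reads": len(reads),
        "read_length": reads.read_length,
        "background_nick_rate": 0.2,
        "occupancy": 0.125,
        "paths": {
            "genomes_fasta": "scratch/community_genomes.fasta",
            "reads_fastq": "scratch/ptseq_reads.fastq",
            "truth_tsv": "results/planted_sites.tsv",
        },
    }
    (results / "community_config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))

    n_sites = sum(len(v) for v in com.planted.values())
    print(f"community: {len(com.genomes)} genomes, PT carriers {com.pt_genome_ids} "
          f"({n_sites} planted sites), {len(reads)} reads")
    print("wrote scratch/community_genomes.fasta, scratch/ptseq_reads.fastq,")
    print("      results/planted_sites.tsv, results/community_config.yaml")


if __name__ == "__main__":
    main()
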