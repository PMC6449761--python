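#!/usr/bin/env python
"""Generate the benchmark dataset: 5 related genomes, 100 shared ortholog
groups in conserved operons, and one planted palindromic regulon (5 target
groups, 2 sites per upstream region, 20% of site copies weakened into the
rescue band).  Writes genomes (GFF3 + FASTA), the ortholog table and the
ground truth under results/data/."""

import pandas as pd

from _common import DATA, SEED, generate
from regulonscan import io as rio


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    genomes, table, truth = generate()
    table.to_tsv(DATA / "orthologs.tsv")
    for g in genomes:
        rio.write_gff_fasta(g, DATA / f"{g.genome_id}.gff3", DATA / f"{g.genome_id}.fna")
    pd.DataFrame(
        [(s.tf_name, s.genome_id, s.gene_id, s.group_id, s.position, s.strand,
          s.sequence, s.category) for s in truth.planted_sites],
        columns=["tf", "genome", "gene", "group", "position", "strand",
                 "sequence", "category"],
    ).to_csv(DATA / "truth_sites.tsv", sep="\t", index=False)

    n_weak = sum(s.category == "weak" for s in truth.planted_sites)
    print(f"seed {SEED}: {len(genomes)} genomes of "
          f"{len(genomes[0].genes)} genes ({len(genomes[0].contigs['chr'])} nt)")
    print(f"planted {len(truth.planted_sites)} sites over "
          f"{len(truth.regulon_membership['AphS'])} target groups; "
          f"{n_weak} site copies weakened into the rescue band")
    print(f"outputs under {DATA}")


if __name__ == "__main__":
    main()
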