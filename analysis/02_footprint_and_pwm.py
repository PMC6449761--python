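#!/usr/bin/env python
"""Phylogenetic footprinting of the training groups and PWM construction.

Star-aligns the orthologous upstream regions of the 3 training groups, calls
runs of conserved columns, extracts a uniform-length site set and builds the
symmetrized log-odds PWM.  Writes the alignments, the conserved-window
table, the site set and the motif (MEME + TSV) under results/motif/."""

import pandas as pd

from _common import RESULTS, load_dataset, training_groups
from regulonscan import io as rio
from regulonscan.pipeline import footprint_training_sites, symmetric_background
from regulonscan.pwm import SiteSet, build_pwm, information_content


def main() -> None:
    out = RESULTS / "motif"
    out.mkdir(parents=True, exist_ok=True)
    genomes, table, truth = load_dataset()
    training = training_groups(truth)

    site_set, alignments, windows = footprint_training_sites(
        "AphS", genomes, table, training)
    for group, aln in alignments.items():
        rio.write_alignment_fasta(aln, out / f"{group}.aln.fasta")
    pd.DataFrame([(g, w.col_start, w.col_end, w.width, round(w.mean_identity, 4))
                  for g, w in sorted(windows.items())],
                 columns=["group", "col_start", "col_end", "width", "mean_identity"]
                 ).to_csv(out / "conserved_windows.tsv", sep="\t", index=False)
    pd.DataFrame({"site": site_set.sites}).to_csv(out / "training_sites.tsv",
                                                  sep="\t", index=False)

    motif = build_pwm(site_set, 0.5, symmetric_background(genomes), palindromic=True)
    rio.write_motif_meme(motif, out / "AphS.meme")
    rio.write_motif_tsv(motif, out / "AphS.pwm.tsv")
    _, total_bits = information_content(motif)

    print(f"footprinted {len(training)} training groups -> "
          f"{len(site_set.sites)} sites of length {site_set.length}")
    print(f"motif consensus {motif.consensus} "
          f"({total_bits:.1f} bits, palindromic={motif.palindromic})")
    print(f"outputs under {out}")


if __name__ == "__main__":
    main()
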