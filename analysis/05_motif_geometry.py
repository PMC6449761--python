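#!/usr/bin/env python
"""Motif-geometry analyses: palindromes, TGCA spacers, LysR boxes, phasing.

Checks the printed consensus strings (AphS/BphS 14-nt palindrome, BoxR/BzdR
TGCA repeats and 16-nt palindrome, LysR AkACC-N5-GGTAT box) and reports the
helical phasing of the multi-site arrangements found by the scan.  Writes
TSV reports under results/geometry/."""

import pandas as pd

from _common import (APHS_CONSENSUS, BOXR_PALINDROME, LYSR_BOX, RESULTS,
                     load_dataset, training_groups)
from regulonscan.geometry import (PatternNotFoundError, central_gap,
                                  check_palindrome, enumerate_halfsite_spacers,
                                  lysr_box_spacer, site_phasing)
from regulonscan.pipeline import reconstruct_regulon


def main() -> None:
    out = RESULTS / "geometry"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, consensus in (("AphS/BphS", APHS_CONSENSUS),
                            ("BoxR/BzdR", BOXR_PALINDROME),
                            ("LysR box", LYSR_BOX)):
        pal = check_palindrome(consensus)
        try:
            lysr = lysr_box_spacer(consensus)
        except PatternNotFoundError:
            lysr = None
        rows.append((name, consensus, pal.is_palindrome, pal.length, pal.parity,
                     lysr, central_gap(consensus)))
        print(f"{name}: {consensus} palindrome={pal.is_palindrome} "
              f"length={pal.length} ({pal.parity}), T-Nx-A spacer={lysr}")
    pd.DataFrame(rows, columns=["tf", "consensus", "is_palindrome", "length",
                                "parity", "t_nx_a_spacer", "central_gap"]
                 ).to_csv(out / "consensus_geometry.tsv", sep="\t", index=False)

    hist = enumerate_halfsite_spacers(
        [BOXR_PALINDROME] + ["GG" + "TGCA" + "C" * n + "TGCA" + "GG" for n in (1, 15)],
        "TGCA", range(0, 21))
    pd.DataFrame(sorted(hist.counts.items()), columns=["spacer_nt", "count"]
                 ).to_csv(out / "tgca_spacers.tsv", sep="\t", index=False)
    print(f"TGCA half-site spacers observed: {sorted(hist.counts)}")

    # helical phasing of the multi-site upstream regions found by the scan
    genomes, table, truth = load_dataset()
    res = reconstruct_regulon("AphS", genomes, table, training_groups(truth),
                              palindromic=True)
    by_gene = {}
    for h in res.final_hits:
        by_gene.setdefault((h.genome_id, h.gene_id), []).append(h)
    phas = []
    L = res.motif.length
    for (genome_id, gene_id), hs in sorted(by_gene.items()):
        if len(hs) < 2:
            continue
        centers = sorted(h.position + L / 2 for h in hs)
        rep = site_phasing(centers)
        phas.append((genome_id, gene_id,
                     ",".join(f"{d:g}" for d in rep.distances),
                     ",".join(str(t) for t in rep.turns)))
    pd.DataFrame(phas, columns=["genome", "gene", "center_distances_nt", "turns"]
                 ).to_csv(out / "phasing.tsv", sep="\t", index=False)
    turn_counts = pd.Series(
        [int(t) for _, _, _, ts in phas for t in ts.split(",")]).value_counts()
    print(f"{len(phas)} multi-site regions; turn counts "
          f"{dict(sorted(turn_counts.items()))}")
    print(f"outputs under {out}")


if __name__ == "__main__":
    main()
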