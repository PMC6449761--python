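"""Shared input handling for the numbered analysis drivers.

The benchmark dataset (5 genomes x 100 ortholog groups, one planted
palindromic regulon of 5 target groups, 2 sites per region, 20% weakened
site copies, seed 1) is written by 01_simulate.py; later drivers reload it
from disk, or regenerate it deterministically if the files are absent.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

APHS_CONSENSUS = "AAATmTCGAkATTT"
BOXR_PALINDROME = "ATGCACTATAGTGCAT"
LYSR_BOX = "AkACCNNNNNGGTAT"
SEED = 1
N_GENOMES, N_GROUPS, N_TARGETS = 5, 100, 5


def generate():
    from regulonscan.synthetic import OperonSpec, PlantSpec, generate_dataset
    return generate_dataset(
        N_GENOMES, N_GROUPS, OperonSpec(), 0.55,
        [PlantSpec("AphS", APHS_CONSENSUS, N_TARGETS,
                   sites_per_region=2, weak_fraction=0.2)],
        seed=SEED)


def load_dataset():
    """Genomes + ortholog table from results/data (or regenerate); the truth
    tables always come from the deterministic generator."""
    genomes_on_disk = sorted(DATA.glob("genome*.gff3")) if DATA.exists() else []
    genomes, table, truth = generate()
    if len(genomes_on_disk) == N_GENOMES:
        from regulonscan import io as rio
        from regulonscan.orthology import OrthologTable
        genomes = [rio.read_gff_fasta(p, p.with_suffix(".fna"), p.stem)
                   for p in genomes_on_disk]
        table = OrthologTable.from_tsv(DATA / "orthologs.tsv")
    return genomes, table, truth


def training_groups(truth):
    # the first 3 planted groups seed the PWM; the rest must be rediscovered
    return sorted(truth.regulon_membership["AphS"])[:3]
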