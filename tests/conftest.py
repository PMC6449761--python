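import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regulonscan.genome import Gene, Genome, ScanConfig
from regulonscan.synthetic import OperonSpec, PlantSpec, generate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

APHS_CONSENSUS = "AAATmTCGAkATTT"
BOXR_PALINDROME = "ATGCACTATAGTGCAT"
LYSR_BOX = "AkACCNNNNNGGTAT"


@pytest.fixture(scope="session")
def default_config():
    return ScanConfig()


@pytest.fixture(scope="session")
def toy_genome():
    """One 5000 nt contig with a handful of genes on both strands."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    genes = [
        Gene("gA", "c1", 1000, 1900, "+"),
        Gene("gB", "c1", 2050, 2600, "+"),
        Gene("gC", "c1", 3300, 4100, "-"),
    ]
    return Genome("toy", {"c1": seq}, genes)


@pytest.fixture(scope="session")
def planted_dataset():
    """5 genomes x 100 ortholog groups with one planted palindromic regulon
    (5 target groups, 2 sites per region, 20% weak copies), seed 1."""
    return generate_dataset(
        5, 100, OperonSpec(), 0.55,
        [PlantSpec("AphS", APHS_CONSENSUS, 5, sites_per_region=2, weak_fraction=0.2)],
        seed=1)


@pytest.fixture(scope="session")
def clean_dataset():
    """Same layout with all-strong planted sites (weak_fraction 0)."""
    return generate_dataset(
        5, 100, OperonSpec(), 0.55,
        [PlantSpec("AphS", APHS_CONSENSUS, 5, sites_per_region=2, weak_fraction=0.0)],
        seed=1)


@pytest.fixture(autouse=True)
def _quiet_biopython(caplog):
    logging.getLogger("Bio").setLevel(logging.WARNING)
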