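import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gblscreen.genome_io import CodonUsageTable
from gblscreen.primer_design import bundled_primers
from gblscreen.synth_fixtures import PlantSpec, generate_pair_locus, reference_proteins

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def codon_table():
    return CodonUsageTable.bundled()


@pytest.fixture(scope="session")
def primers(codon_table):
    return bundled_primers(codon_table)


@pytest.fixture(scope="session")
def queries():
    """Synthetic receptor/synthase query proteins."""
    return reference_proteins()


@pytest.fixture(scope="session")
def demo_locus(codon_table):
    """A divergent YFHF/ETLRQ locus with a 180 bp intergenic gap."""
    return generate_pair_locus(PlantSpec(gap=180, seed=7), codon_table)


def smith_waterman_affine(a: str, b: str, matrix, gap_open: float = -11.0,
                          gap_extend: float = -1.0) -> float:
    """Quadratic affine-gap local alignment score (independent oracle).

    gap_open is the score of the first gap character, gap_extend of each
    additional one.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best
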