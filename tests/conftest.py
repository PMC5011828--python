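import numpy as np
import pytest

from mismap.simulate import SimConfig, simulate_cohort
from mismap.types import GenotypePanel, MarkerRecord

# Desk-scale study conditions used by most unit tests: a small two-chromosome
# genome dense enough for LD blocks and the default planted-event layout.
SMALL_SIM = SimConfig(
    n_chromosomes=2,
    chrom_length_bp=6_000_000,
    n_markers_per_chrom=300,
    n_founder_haplotypes=80,
    n_samples=80,
    seed=5,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_SIM)


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    """Population A under the corrupted (reported) map."""
    return small_cohort.panel("A", "reported")


@pytest.fixture()
def toy_panel():
    """Hand-sized panel: 4 samples x 4 markers with one missing call."""
    markers = [
        MarkerRecord("m1", "1", 100, "A", "C"),
        MarkerRecord("m2", "1", 2_000, "G", "T"),
        MarkerRecord("m3", "1", 350_000, "A", "G"),
        MarkerRecord("m4", "2", 5_000, "C", "T"),
    ]
    dosages = np.array(
        [
            [0.0, 1.0, 2.0, 0.0],
            [1.0, np.nan, 2.0, 1.0],
            [2.0, 1.0, 0.0, 2.0],
            [0.0, 0.0, 1.0, 1.0],
        ]
    )
    return GenotypePanel(["s1", "s2", "s3", "s4"], markers, dosages)
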