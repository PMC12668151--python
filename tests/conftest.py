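import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from g4age.synthetic import simulate_study  # noqa: E402


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    return simulate_study(
        seed=42, n_chrom=1, chrom_length=200_000, planted_motifs=60,
        n_genes=8, n_peaks=200,
    )


@pytest.fixture(scope="session")
def default_small_kwargs():
    """Down-scaled study layout for tests that need fresh simulations."""
    return dict(n_chrom=1, chrom_length=200_000, planted_motifs=60,
                n_genes=8, n_peaks=200)
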