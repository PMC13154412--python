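import numpy as np
import pytest

from pepcore.evostats import joint_frequencies, site_frequencies
from pepcore.peptide_io import ALPHABET, PeptideAlignment
from pepcore.synthdata import make_anchored_spec, make_benchmark_suite, sample_msa


def random_alignment(rng: np.random.Generator, M: int, L: int,
                     alphabet_size: int = 20, allotype: str = "") -> PeptideAlignment:
    """Uniform random alignment over the first ``alphabet_size`` letters."""
    enc = rng.integers(0, alphabet_size, size=(M, L))
    seqs = ["".join(ALPHABET[v] for v in row) for row in enc]
    return PeptideAlignment(seqs, allotype=allotype)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_alignment():
    return PeptideAlignment(["ACDEF", "ACDEG", "ACDFH", "LMNPQ"], allotype="T1")


@pytest.fixture(scope="session")
def benchmark_suite():
    return make_benchmark_suite(seed=5)


@pytest.fixture(scope="session")
def coupled_target():
    """Strongly coupled synthetic allotype used across design tests."""
    spec = make_anchored_spec(seed=1, contrast=0.98, K=2, anchor_weight=0.95)
    native = sample_msa(spec, 200, seed=2)
    return spec, native


@pytest.fixture(scope="session")
def small_stats(benchmark_suite):
    ds, _ = benchmark_suite
    return {
        name: (site_frequencies(aln, 1e-3), joint_frequencies(aln, 1e-3))
        for name, aln in ds.items()
    }
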