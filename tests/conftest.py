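import numpy as np
import pytest

from hexaprime.mining import ProteinSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_family():
    """Four tiny homologs sharing the YWDCCK motif verbatim."""
    return ProteinSet.from_pairs(
        [
            ("s1", "MAYWDCCKLA"),
            ("s2", "MTYWDCCKIA"),
            ("s3", "MAYWDCCKLG"),
            ("s4", "MSYWDCCKVA"),
        ]
    )


def random_degenerate_seq(rng, max_len=60, alphabet="ACGTRYSWKMBDHVNI"):
    n = int(rng.integers(1, max_len + 1))
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


def random_concrete_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))
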