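import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from peptwin.spectra import PeakList, SpectrumRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_peaklist(rng, max_peaks=30, mz_range=(100.0, 1500.0)):
    n = int(rng.integers(1, max_peaks + 1))
    mz = np.sort(rng.uniform(*mz_range, size=n))
    intensity = rng.uniform(0.01, 1.0, size=n)
    return PeakList(mz, intensity)


def random_protein(rng, min_len=50, max_len=300):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def random_library(rng, n_records=5):
    """Synthetic spectral records with every optional field populated, for
    round-trip tests."""
    records = []
    for _ in range(n_records):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(7, 15))))
        n_peaks = int(rng.integers(3, 12))
        records.append(
            SpectrumRecord(
                name=f"{seq}/2",
                sequence=seq,
                charge=2,
                precursor_mz=float(np.round(rng.uniform(300, 900), 6)),
                retention=float(np.round(rng.uniform(-20, 120), 4)),
                retention_kind="irt",
                peaks=PeakList(
                    np.round(np.sort(rng.uniform(100, 1200, size=n_peaks)), 6),
                    np.round(rng.uniform(0.01, 1.0, size=n_peaks), 6),
                ),
            )
        )
    return records
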