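from __future__ import annotations

import numpy as np
import pytest

from agnospec import HistogramConfig, Peak, Spectrum, build_dataset, generate_dataset


def random_spectrum(rng: np.random.Generator, n_peaks: int,
                    sample_id: str = "rand") -> Spectrum:
    """A random fixture spectrum; masses may spill outside the m/z window
    and intensities are wide enough that some abundance coordinates fall
    outside [0, 1], so the drop rules are exercised."""
    mz = rng.uniform(140.0, 760.0, n_peaks)
    intensity = np.exp(rng.normal(3.0, 3.5, n_peaks))
    peaks = [Peak(float(m), float(a)) for m, a in zip(mz, intensity)]
    return Spectrum(sample_id, peaks)


@pytest.fixture(scope="session")
def default_cfg() -> HistogramConfig:
    return HistogramConfig()


@pytest.fixture(scope="session")
def default_spectra():
    """The packaged four-class synthetic dataset at its default scale."""
    return generate_dataset(per_class=40, master_seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_spectra):
    return build_dataset(default_spectra)
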