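import numpy as np
import pytest

import fossilftir as ff


@pytest.fixture(scope="session")
def default_dataset():
    """The full emulated study: 102 labeled synthetic spectra, seed 0."""
    return ff.generate_dataset()


@pytest.fixture(scope="session")
def preprocessed_dataset(default_dataset):
    return ff.apply_recipe(default_dataset, "atr-paper")


@pytest.fixture(scope="session")
def band_table(preprocessed_dataset):
    return ff.extract_band_matrix(preprocessed_dataset)


@pytest.fixture()
def small_spectrum():
    wn = np.arange(650.0, 4000.0, 4.0)
    ab = np.exp(-0.5 * ((wn - 1615.0) / 17.0) ** 2)
    return ff.Spectrum(sample_id="s", wavenumbers=wn, absorbance=ab)
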