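import warnings

import numpy as np
import pytest

from plumage.errors import ESSWarning, HalfMaxWarning, RegionWarning, ResolutionWarning
from plumage.spectra import ReflectanceSpectrum
from plumage.synth import SyntheticConfig, gen_microstructure, gen_pigments, gen_spectra, gen_tree


@pytest.fixture(autouse=True)
def _quiet_known_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        warnings.filterwarnings("ignore", category=ResolutionWarning)
        warnings.filterwarnings("ignore", category=RegionWarning)
        warnings.filterwarnings("ignore", category=ESSWarning)
        yield


@pytest.fixture(scope="session")
def synth_cfg():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def tree(synth_cfg):
    return gen_tree(synth_cfg)


@pytest.fixture(scope="session")
def spectra_bundle(synth_cfg):
    return gen_spectra(synth_cfg)


@pytest.fixture(scope="session")
def pigment_bundle(synth_cfg, tree):
    return gen_pigments(synth_cfg, tree)


@pytest.fixture(scope="session")
def micro_table(synth_cfg):
    return gen_microstructure(synth_cfg)


def make_spectrum(wavelengths, reflectance, **kw):
    defaults = dict(species="sp", sex="M", patch="rump", incidence_deg=90)
    defaults.update(kw)
    return ReflectanceSpectrum(np.asarray(wavelengths, dtype=float),
                               np.asarray(reflectance, dtype=float), **defaults)


@pytest.fixture
def flat_spectrum():
    w = np.arange(300.0, 701.0)
    return make_spectrum(w, np.full(w.size, 0.5))
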