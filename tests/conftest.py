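import pytest

from fluorograde.presets import TissueType, make_tissue_preset
from fluorograde.synthetic import noiseless_spectrum
from fluorograde.unmixing import fit_spectrum


@pytest.fixture(scope="session")
def presets():
    return {tt: make_tissue_preset(tt) for tt in TissueType}


@pytest.fixture(scope="session")
def preset_fits(presets):
    """Noiseless fits of every preset at every excitation (shared, slow)."""
    fits = {}
    for tt, preset in presets.items():
        for exc in (275.0, 810.0, 890.0):
            fits[(tt, exc)] = fit_spectrum(noiseless_spectrum(preset, exc),
                                           n_restarts=2, seed=0)
    return fits
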