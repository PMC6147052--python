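import numpy as np
import pytest

from peatflux import synth


@pytest.fixture(scope="session")
def small_landscape():
    """120x120 synthetic raster stack with its rule-oracle class map."""
    cfg = synth.SynthConfig(seed=11, landscape_size=(120, 120))
    return synth.gen_landscape(cfg)


@pytest.fixture(scope="session")
def flux_records():
    """Synthetic flux records at the published study conditions, with truth."""
    return synth.gen_flux_records(synth.SynthConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
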