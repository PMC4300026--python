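import logging

import numpy as np
import pytest

from brainseg.phantom import PhantomSpec, generate_phantom

logging.getLogger("brainseg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240914)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free, texture-free phantom: piecewise-constant tissues."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        noise_pct=0.0,
        bias_pct=0.0,
        tissue_sds={k: 0.0 for k in ("background", "csf", "gm", "wm", "skull")},
        seed=101,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study conditions at reduced scale: 3% noise, 20% bias."""
    return generate_phantom(PhantomSpec(shape=(64, 64, 64), noise_pct=3.0, bias_pct=20.0, seed=202))
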