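import numpy as np
import pytest

from dbmasym import PhantomSpec, build_template, synthesize_subject
from dbmasym.phantom import AsymSite, default_asym_site


def clean_spec(shape=(32, 32, 32), **kw):
    """Noiseless, jitter-free spec for deterministic geometry checks."""
    base = dict(grid_shape=shape, noise_sd=0.0, scale_jitter_sd=0.0,
                shape_jitter_sd=0.0, translation_jitter_mm=0.0)
    base.update(kw)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def spec32():
    return clean_spec((32, 32, 32))


@pytest.fixture(scope="session")
def spec48():
    return PhantomSpec(grid_shape=(48, 48, 48))


@pytest.fixture(scope="session")
def template32(spec32):
    return build_template(spec32, "neonatal")


@pytest.fixture(scope="session")
def clean_pair(spec32):
    return synthesize_subject(spec32, 7)


@pytest.fixture(scope="session")
def bumped_spec48():
    """48-cube spec with a smooth left-hemisphere growth bump."""
    spec0 = clean_spec((48, 48, 48))
    semi = spec0.semi_axes
    center = spec0.center + semi * np.array([-0.45, 0.25, 0.0])
    site = AsymSite(tuple(center), radius_mm=float(semi[0] * 0.6),
                    peak_factor=1.2, hemisphere="L")
    return clean_spec((48, 48, 48), asym_sites=(site,))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
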