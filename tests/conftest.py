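import numpy as np
import pytest

import hawkesmix as hm


def window_for(cat: hm.EventCatalog) -> hm.TimeWindow:
    """Half-open observation window just covering the catalog."""
    return hm.TimeWindow(0.0, float(np.nextafter(cat.t[-1], np.inf)))


@pytest.fixture(scope="session")
def region() -> hm.SpatialRegion:
    return hm.burglary_region()


@pytest.fixture(scope="session")
def single_catalog(region) -> hm.EventCatalog:
    """One reference single-component catalog at the standard study size."""
    cfg = hm.SimConfig(
        kernel=hm.burglary_single_kernel(),
        region=region,
        target_n=5000,
        trim=2000,
        seed=11,
    )
    return hm.simulate_catalog(cfg)


@pytest.fixture(scope="session")
def multi_catalog(region) -> hm.EventCatalog:
    """One reference two-component catalog at the standard study size."""
    cfg = hm.SimConfig(
        kernel=hm.burglary_two_component_kernel(),
        region=region,
        target_n=5000,
        trim=2000,
        seed=12,
    )
    return hm.simulate_catalog(cfg)


@pytest.fixture()
def toy_model() -> hm.ModelSpec:
    """Small smooth model convenient for quadrature cross-checks."""
    bg = hm.BackgroundParams(
        a=[0.8, 0.3], c=[1.5, 2.5], d=[2.0, 1.0], alpha=[0.5, 0.9], beta=[0.6, 0.4]
    )
    tr = hm.TriggerParams(
        b=[0.25, 0.1], alpha=[1.2, 0.7], beta=[0.9, 1.5], gamma=[0.8, 1.6]
    )
    return hm.ModelSpec(background=bg, trigger=tr, z=50.0, n_star=None)


@pytest.fixture()
def toy_catalog() -> hm.EventCatalog:
    rng = np.random.default_rng(7)
    t = np.sort(rng.uniform(0.0, 4.0, 8))
    x = rng.uniform(0.5, 3.5, 8)
    y = rng.uniform(0.5, 3.5, 8)
    return hm.EventCatalog(x, y, t)
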