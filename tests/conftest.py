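import numpy as np
import pytest

import sxmerge as sx


@pytest.fixture(scope="session")
def sg20():
    return sx.get_spacegroup(20)


@pytest.fixture(scope="session")
def sg1():
    return sx.get_spacegroup(1)


@pytest.fixture(scope="session")
def cell_ortho():
    return sx.UnitCell(40.0, 50.0, 60.0)


@pytest.fixture(scope="session")
def clean_ensemble():
    """10 noise-free datasets with known scales — scaling ground truth."""
    cfg = sx.SynthConfig(n_datasets=10, seed=1, noise=False, low_isa_fraction=0.0)
    return sx.generate_ensemble(cfg)


@pytest.fixture(scope="session")
def noisy_ensemble():
    """40 datasets with counting noise, one isomorphism class."""
    cfg = sx.SynthConfig(n_datasets=40, seed=2, low_isa_fraction=0.0)
    return sx.generate_ensemble(cfg)


@pytest.fixture(scope="session")
def mixed_ensemble():
    """Majority cluster + non-isomorphous cluster + low-ISa datasets."""
    cfg = sx.showcase_config(seed=3, n_datasets=40)
    return sx.generate_ensemble(cfg)


def make_miniset(
    hkl,
    intensity,
    sigma=None,
    ds_id="test",
    cell=None,
    sg_number=20,
    **kw,
):
    hkl = np.asarray(hkl)
    intensity = np.asarray(intensity, dtype=float)
    if sigma is None:
        sigma = np.maximum(np.sqrt(np.abs(intensity)), 1.0)
    return sx.Miniset(
        id=ds_id,
        cell=cell or sx.UnitCell(40.0, 50.0, 60.0),
        spacegroup_number=sg_number,
        wavelength=1.0,
        hkl=hkl,
        intensity=intensity,
        sigma=np.asarray(sigma, dtype=float),
        **kw,
    )
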