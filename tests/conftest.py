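import numpy as np
import pytest

from reefdiet.growth import VBGFParams
from reefdiet.simulate import SimConfig, SpeciesSpec, default_config, simulate_dataset


def small_species(name="sp", a=2e-5, b=3.0, sigma_w=0.0, sigma_l=0.0,
                  zones=("z1",), diet=None, linf=90.0, k=0.4):
    """Minimal single-profile species spec for focused tests."""
    if diet is None:
        diet = {z: {"taxA": 5.0, "taxB": 5.0} for z in zones}
    return SpeciesSpec(
        name=name, a=a, b=b,
        weight_sigma={z: sigma_w for z in zones},
        vbgf={z: VBGFParams(linf, k, -2.0) for z in zones},
        age_range=(3, 9), length_sigma=sigma_l, diet=diet,
        depth_meanlog=np.log(5000.0), depth_sdlog=0.3,
    )


def small_config(seed=0, zones=("z1",), reefs=1, fish=10, **kw):
    sp = small_species(zones=zones, **kw)
    return SimConfig(
        seed=seed, zones=zones, reefs_per_zone=reefs,
        fish_per_reef_per_species=fish, species=(sp,),
        coral_cover={z: (20.0, 2.0) for z in zones},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic study shared across tests (seed 11)."""
    return simulate_dataset(default_config(11))
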