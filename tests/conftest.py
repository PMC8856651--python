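import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famseg import (
    Affection,
    FamilySimConfig,
    load_family_fixture,
    obligate_carriers,
    simulate_family,
)

settings.register_profile(
    "famseg",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("famseg")


@pytest.fixture(scope="session")
def family_ped():
    return load_family_fixture()


@pytest.fixture(scope="session")
def family_carriers(family_ped):
    """Full carrier map under complete co-segregation: genotyped statuses from
    affection, plus resolved obligate carriers and proxy non-carriers."""
    carriers = {i.id: i.affected is Affection.AFFECTED
                for i in family_ped if i.genotyped}
    full = dict(carriers)
    for iid in obligate_carriers(family_ped, carriers):
        full[iid] = True
    for ind in family_ped:
        if ind.id not in full and not ind.genotyped \
                and ind.affected is Affection.UNAFFECTED:
            full[ind.id] = False
    return full


@pytest.fixture(scope="session")
def family_sim():
    """One seeded family simulation shared across tests (small background)."""
    return simulate_family(FamilySimConfig(seed=1, n_background_variants=500))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
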