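import numpy as np
import pytest

from lesionkit import simulate as sim


@pytest.fixture(scope="session")
def focal_cohort():
    """Cohort whose deficit is driven by a small planted critical region."""
    return sim.simulate_cohort(sim.focal_scenario(seed=1))


@pytest.fixture(scope="session")
def size_cohort():
    """Cohort whose deficit is driven by overall lesion size only."""
    return sim.simulate_cohort(sim.size_driven_scenario(seed=1))


@pytest.fixture(scope="session")
def battery_cohort():
    """Cohort with a 17-measure battery over 3 planted factors."""
    return sim.simulate_cohort(sim.battery_scenario(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed cohort (n=48) for pipeline plumbing tests."""
    cfg = sim.ScenarioConfig(
        n_participants=48,
        deficit_models={
            "focal": sim.DeficitModel(
                w_focal=1.0, critical_center=(12, 21, 16), noise_sd=0.5
            ),
            "size": sim.DeficitModel(w_size=1.0, noise_sd=0.5),
        },
        seed=5,
    )
    return sim.simulate_cohort(cfg)


def make_toy_cohort(mask_arrays, geometry=None, behavior=None):
    """Cohort from explicit boolean arrays (for handcrafted unit tests)."""
    import pandas as pd

    from lesionkit.cohort import LesionCohort, LesionMask, VolumeGeometry

    if geometry is None:
        shape = np.asarray(mask_arrays[0]).shape
        geometry = VolumeGeometry(shape=shape, affine=np.eye(4))
    masks = [
        LesionMask(participant_id=f"p{i:03d}", data=np.asarray(a, dtype=bool))
        for i, a in enumerate(mask_arrays)
    ]
    if behavior is None:
        behavior = pd.DataFrame(index=range(len(masks)))
    return LesionCohort(geometry=geometry, masks=masks, behavior=behavior)
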