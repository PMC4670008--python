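import pytest
from hypothesis import HealthCheck, settings

import oxyscale as ox

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Full study grid, noise-free, every embryo hatches: the exact ground truth."""
    cfg = ox.default_config(n_per_condition=3, noise_sd=0.0, fate="all_hatched", seed=1)
    return cfg, ox.generate_dataset(cfg)


@pytest.fixture()
def complete_obs():
    """One embryo with all nine landmarks, hatched."""
    times = {
        "pole_bud_appearance": 0.5,
        "membrane_reaches_yolk": 3.0,
        "pole_cell_invagination": 4.2,
        "amnioproctodeal_invagination": 5.6,
        "amnioserosa_exposure": 13.4,
        "clypeolabrum_retraction": 17.0,
        "cephalic_lobes_even": 19.2,
        "heart_shaped_midgut": 19.8,
        "trachea_fill": 23.0,
    }
    return ox.EmbryoObservation(
        embryo_id="e1", condition=ox.Condition(21.0, 27.5), event_times=times, hatched=True
    )
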