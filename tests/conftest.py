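import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lamella.synthetic import LamellarSpec, generate_lamellar_config, generate_lamellar_trajectory

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sys1_spec():
    """Water-only reference stack (three bilayers, d 6.1, d_PP 3.85)."""
    return LamellarSpec(n_bilayers=3, lipids_per_leaflet=50, seed=11)


@pytest.fixture(scope="session")
def sys1_frame(sys1_spec):
    return generate_lamellar_config(sys1_spec)


@pytest.fixture(scope="session")
def system_specs():
    """Fixtures shaped like the three simulated ethanol conditions:
    water, 48 vol% and 57 vol% ethanol."""
    common = dict(n_bilayers=3, lipids_per_leaflet=64, jitter=0.05, seed=23)
    return [
        LamellarSpec(area_per_lipid=0.647, d_pp=3.85, d_spacing=6.1,
                     order_target=0.35, ethanol_vol_pct=0.0,
                     membrane_partition=0.0, **common),
        LamellarSpec(area_per_lipid=0.851, d_pp=3.42, d_spacing=4.7,
                     order_target=0.22, ethanol_vol_pct=48.0,
                     membrane_partition=0.3, **common),
        LamellarSpec(area_per_lipid=0.926, d_pp=3.34, d_spacing=4.4,
                     order_target=0.18, ethanol_vol_pct=57.0,
                     membrane_partition=0.35, **common),
    ]


@pytest.fixture(scope="session")
def system_trajectories(system_specs):
    return [generate_lamellar_trajectory(spec, n_frames=5) for spec in system_specs]
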