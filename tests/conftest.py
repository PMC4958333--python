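import numpy as np
import pytest

import dermaclone as dc


@pytest.fixture(scope="session")
def paper_matched_tables():
    """Zero-noise paper-matched measurement and density tables."""
    measurements, densities, truth = dc.synthetic.gen_measurements(noise_cv=0.0, seed=0)
    return measurements, densities, truth


@pytest.fixture()
def small_sim_config():
    """A light simulation configuration for fast stochastic checks."""
    return dc.SimConfig(
        lx_um=500.0,
        ly_um=500.0,
        layer_bounds_um=(("papillary", 0.0, 60.0), ("reticular", 60.0, 140.0), ("DWAT", 140.0, 200.0)),
        start_age_days=0.0,
        end_age_days=4.0,
        initial_density_per_mm2=(("papillary", 200.0), ("reticular", 150.0), ("DWAT", 50.0)),
        division_rate=0.0,
        death_rate=0.0,
        expansion=dc.ExpansionSchedule.linear(0.0, 4.0, (2.0, 2.0, 2.0)),
        label_age_days=0.0,
        labels_per_region=1.0,
        region_pitch_um=250.0,
        seed=0,
    )
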