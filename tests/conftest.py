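import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import spadspec as sp

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_clean_set():
    """Noise/scatter-free 40-leaf V12 dataset; spectra are pure renderings."""
    cfg = sp.GeneratorConfig(
        groups=(sp.GroupSpec("V12", "apical", 40, 50.6, 4.3),),
        scatter_gain_sd=0.0,
        scatter_offset_sd=0.0,
        noise_sd=0.0,
        seed=5,
    )
    samples, truth = sp.generate_dataset(cfg)
    return samples, truth


@pytest.fixture(scope="session")
def default_group_set():
    """Default study conditions scaled to 60 leaves/group (all 9 groups)."""
    cfg = sp.GeneratorConfig(groups=sp.scaled_field_groups(60), seed=11)
    samples, truth = sp.generate_dataset(cfg)
    return samples, truth


@pytest.fixture
def tiny_sample_set():
    """Hand-built 3-sample set on the full grid for I/O contract tests."""
    wl = sp.DEFAULT_WAVELENGTHS
    refl = np.vstack(
        [sp.synth.generate_spectrum(0.04 + 0.01 * i, wl) for i in range(3)]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "stage": ["V6", "R1", "R1"],
            "leaf_position": ["apical", "ear", "upper_ear"],
            "variety": ["Zhengdan958"] * 3,
            "nitrogen": ["N0", "N2", "N4"],
            "spad": [48.0, 55.5, 61.2],
        }
    )
    return sp.SampleSet(wl, refl, meta)
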