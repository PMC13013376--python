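import numpy as np
import pytest
from hypothesis import settings

import netshift as ns

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast generator: 12 regions, 8 subjects, short series."""
    return ns.GeneratorConfig(
        n_subjects=8,
        n_regions=12,
        n_modules=3,
        n_volumes=120,
        within_r=0.5,
        between_r=0.1,
        subject_jitter_sd=0.05,
        effect=ns.EffectSpec(
            clustering_delta=0.1, hub_node=2, hub_delta=0.2,
            degraded_node=7, degraded_delta=0.1,
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return ns.generate_paired_dataset(tiny_config)


@pytest.fixture(scope="session")
def z90(rng):
    """One 90-region Fisher-z matrix from the default generator."""
    cfg = ns.GeneratorConfig(n_subjects=1, seed=5)
    rec = ns.generate_paired_dataset(cfg)[0]
    cm = ns.connectivity_from_timeseries(
        ns.ROITimeSeries(rec.ts_A, ns.atlas.AAL90_LABELS)
    )
    return cm.z
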