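import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("gammaswitch").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def recovery_run():
    """One full pipeline run on the default synthetic cohort.

    Shared by the end-to-end recovery checks: 3 patients, the default
    two-ROI montage, and the default burst layout (switch-modulated
    precuneus burst at 330-780 ms with a 1.5x multiplier).
    """
    from gammaswitch.pipeline import analyze_cohort, default_pipeline_config
    from gammaswitch.synth import build_montage, generate_cohort

    cfg = default_pipeline_config(seed=11)
    montage = build_montage(cfg.roi_channels, n_excluded=cfg.n_excluded_channels)
    patients = generate_cohort(cfg.n_patients, cfg.generator, montage, seed=11)
    results = analyze_cohort(patients, cfg)
    return cfg, patients, results
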