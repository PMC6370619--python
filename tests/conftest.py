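import dataclasses

import numpy as np
import pytest

from immunorecov.cohort import VisitSchedule
from immunorecov.synthesis import default_config, generate_cohort


@pytest.fixture
def schedule():
    return VisitSchedule()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-default synthetic cohort (14 AIR-like + 19 PIR-like)."""
    return generate_cohort(default_config(seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, fully observed cohort: series lie exactly on the mean curves."""
    cfg = default_config(seed=7)
    cd4 = {g: dataclasses.replace(k, sigma_a=0.0, sigma_b=0.0, sigma_eps=0.0)
           for g, k in cfg.cd4.items()}
    ratio = {g: dataclasses.replace(k, sigma_a=0.0, sigma_b=0.0, sigma_eps=0.0)
             for g, k in cfg.ratio.items()}
    cfg = dataclasses.replace(
        cfg, cd4=cd4, ratio=ratio,
        covariates=dataclasses.replace(cfg.covariates, missingness=0.0),
    )
    return generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def separated_cohort():
    """Low-noise cohort whose two groups are unambiguously separable."""
    cfg = default_config(seed=3)
    cd4 = {g: dataclasses.replace(k, sigma_a=10.0, sigma_b=20.0, sigma_eps=10.0)
           for g, k in cfg.cd4.items()}
    cfg = dataclasses.replace(
        cfg, cd4=cd4,
        covariates=dataclasses.replace(cfg.covariates, missingness=0.0),
    )
    return generate_cohort(cfg, seed=3)
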