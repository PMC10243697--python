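import numpy as np
import pandas as pd
import pytest

from actisleep.synthetic import CohortConfig, GroupParams, generate_cohort


def _quiet_group(name: str, **overrides) -> GroupParams:
    """A group with every noise source switched off and deterministic counts."""
    base = dict(
        name=name,
        workday_bedtime_mean=23.0 + 28.0 / 60.0,
        workday_bedtime_sd=0.0,
        workday_risetime_mean=7.0 + 5.0 / 60.0,
        workday_risetime_sd=0.0,
        weekend_bedtime_mean=21.0 / 60.0,
        weekend_bedtime_sd=0.0,
        weekend_risetime_mean=8.0 + 17.0 / 60.0,
        weekend_risetime_sd=0.0,
        night_sd=0.0,
        sleep_onset_latency_mean_min=0.0,
        waso_rate_min_per_h=0.0,
        activity_dispersion=None,
    )
    base.update(overrides)
    return GroupParams(**base)


@pytest.fixture
def zero_noise_config() -> CohortConfig:
    """Both arms noiseless: diary equals truth, scoring is exact."""
    return CohortConfig(
        n_per_group=3,
        onsite=_quiet_group("onsite"),
        home_office=_quiet_group(
            "home_office",
            workday_bedtime_mean=7.0 / 60.0,
            workday_risetime_mean=7.0 + 44.0 / 60.0,
            weekend_bedtime_mean=45.0 / 60.0,
            weekend_risetime_mean=8.0 + 47.0 / 60.0,
        ),
        diary_error_sd_min=0.0,
        p_diary_gross_error=0.0,
        p_nonwear_day=0.0,
        seed=7,
    )


@pytest.fixture
def zero_noise_cohort(zero_noise_config):
    return generate_cohort(zero_noise_config)


@pytest.fixture(scope="session")
def default_small_cohort():
    """Default (noisy) conditions at a size small enough for unit tests."""
    return generate_cohort(CohortConfig(n_per_group=8, seed=11))


def quiet_config(**kwargs) -> CohortConfig:
    cfg = CohortConfig(
        n_per_group=kwargs.pop("n_per_group", 3),
        onsite=_quiet_group("onsite"),
        home_office=_quiet_group(
            "home_office",
            workday_bedtime_mean=7.0 / 60.0,
            workday_risetime_mean=7.0 + 44.0 / 60.0,
            weekend_bedtime_mean=45.0 / 60.0,
            weekend_risetime_mean=8.0 + 47.0 / 60.0,
        ),
        diary_error_sd_min=0.0,
        p_diary_gross_error=0.0,
        p_nonwear_day=0.0,
        seed=kwargs.pop("seed", 7),
    )
    for k, v in kwargs.items():
        setattr(cfg, k, v)
    return cfg
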