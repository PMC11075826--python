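import numpy as np
import pytest

from svagree import cohort, pipeline


def zero_noise_traj(**overrides) -> cohort.TrajectoryParams:
    kw = dict(beat_noise_sd=0.0, map_beat_noise_sd=0.0,
              bin_noise_sd_us=0.0, bin_noise_sd_pwa=0.0)
    kw.update(overrides)
    return cohort.TrajectoryParams(**kw)


def zero_noise_disc(**overrides) -> cohort.DiscrepancyParams:
    kw = dict(sigma_between=0.0, sigma_within=0.0)
    kw.update(overrides)
    return cohort.DiscrepancyParams(**kw)


@pytest.fixture(scope="session")
def small_run():
    """One 12-subject cohort at the calibrated defaults, fully analyzed."""
    return pipeline.run_study(n_subjects=12, seed=11)


@pytest.fixture(scope="session")
def small_bins(small_run):
    return pipeline.analysis_bins(small_run["bins"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
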