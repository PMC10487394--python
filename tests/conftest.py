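import numpy as np
import pytest

from eveninghrv import (CohortConfig, FilterConfig, RRSeries,
                        generate_cohort, observations_from_recordings)
from eveninghrv.io import PipelineConfig


def make_series(rr_values, start=0.0, participant_id="T"):
    """RRSeries from a list of interval values (beat times by cumsum)."""
    rr = np.asarray(rr_values, dtype=float)
    return RRSeries(beat_time=np.cumsum(rr) + start, rr=rr,
                    participant_id=participant_id)


def random_series(rng, n=200, mean=800.0, sd=40.0):
    rr = np.clip(rng.normal(mean, sd, size=n), 450, 1250)
    return make_series(rr)


@pytest.fixture(scope="session")
def full_cohort_obs():
    """The study-sized cohort (32 x 5) pushed through the whole pipeline."""
    recordings, q_rows = generate_cohort(CohortConfig(n_participants=32, seed=7))
    rr = {r.participant_id: r.rr_series for r in recordings}
    return observations_from_recordings(rr, q_rows, PipelineConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 6-participant cohort run through the full pipeline once."""
    cfg = CohortConfig(n_participants=6, seed=11)
    recordings, q_rows = generate_cohort(cfg)
    rr = {r.participant_id: r.rr_series for r in recordings}
    obs = observations_from_recordings(rr, q_rows, PipelineConfig())
    return recordings, q_rows, obs
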