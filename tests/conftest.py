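import numpy as np
import pytest

import eyegaba as eg


def make_run(event_list, duration=10.0, cw_eye="right", subject="S01", run_id=1):
    """events as (time, state) tuples -> RivalryRun."""
    return eg.RivalryRun(
        events=tuple(eg.KeypressEvent(t, s) for t, s in event_list),
        duration=duration,
        cw_eye=cw_eye,
        subject_id=subject,
        run_id=run_id,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210823)


@pytest.fixture(scope="session")
def coupled_cohort():
    """One simulated study-sized cohort with a strong latent coupling."""
    return eg.simulate_cohort(eg.CohortSimParams(seed=3, latent_effect=0.8))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort with every degradation switched off: reports are exact,
    metabolite values carry no noise."""
    from dataclasses import replace

    riv = eg.RivalrySimParams(p_mixed=0.0, latency_mean=0.0, p_dropout=0.0)
    params = eg.CohortSimParams(
        seed=11, latent_effect=0.5, gaba_noise_sd=0.0, rivalry=riv
    )
    return eg.simulate_cohort(params)
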