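import numpy as np
import pytest

import nirsync as ns


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort shared by read-only tests."""
    params = ns.CohortParams(
        n_participants=5,
        n_long_channels=6,
        n_short_channels=2,
        duration_s=120,
        stimuli=("task",),
        signal_channels_intact=("S001-D001", "S002-D002"),
        signal_channels_scrambled=("S001-D001",),
    )
    return ns.generate_cohort(params, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(98765)


def make_hb(hbo, hbr=None, fs=3.9063, channel_ids=None):
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    if hbr is None:
        hbr = -0.6 * hbo
    if channel_ids is None:
        channel_ids = [f"C{i}" for i in range(hbo.shape[0])]
    return ns.HemoglobinSeries(hbo=hbo, hbr=np.atleast_2d(hbr), fs=fs,
                               channel_ids=list(channel_ids))
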