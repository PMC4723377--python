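"""Shared fixtures for the test suite.

``theta_star`` is the canonical synthetic ground truth used across the
fitting and recovery tests: an outbreak with effective reproduction ratio
alpha*S0/beta = 0.8/0.7 ~ 1.14 (just above threshold) and logistic
recruitment toward K = 1000.
"""

import numpy as np
import pandas as pd
import pytest

import sirdiffusion as sd

THETA_STAR = {"alpha": 0.008, "beta": 0.7, "mu": 0.13, "K": 1000.0}
S0_STAR = 100.0


@pytest.fixture(scope="session")
def theta_star() -> sd.SIRParams:
    return sd.SIRParams(**THETA_STAR)


@pytest.fixture(scope="session")
def init_star() -> sd.InitialState:
    return sd.InitialState(S0=S0_STAR, I0=1.0, R0=0.0)


@pytest.fixture(scope="session")
def noiseless_series(theta_star, init_star) -> sd.ObservedSeries:
    """n = 30 noiseless observations of the canonical outbreak."""
    spec = sd.SyntheticSpec(params=theta_star, init=init_star, horizon=29, seed=0)
    series, _ = sd.generate_series(spec)
    return series


@pytest.fixture(scope="session")
def default_fit(noiseless_series) -> sd.GASIRFitter:
    """One default-configuration fit of the canonical noiseless series.

    Session-scoped because the full GA run takes seconds; several tests
    assert different invariants on the same fitted estimator.
    """
    return sd.GASIRFitter(random_state=0).fit(noiseless_series.counts)


def make_post_log(rows) -> pd.DataFrame:
    """Build a post log DataFrame from (thread, post, author, ts, topic) rows."""
    return pd.DataFrame(
        rows,
        columns=["thread_id", "post_id", "author_id", "timestamp", "topic_label"],
    )


@pytest.fixture()
def crafted_log() -> pd.DataFrame:
    """12 posts over 3 months with 3, 2, 4 unique authors per month.

    Hand-crafted oracle: month 1 has authors a1, a2, a3 (a1 twice),
    month 2 has a1, a4 (a4 twice), month 3 has a2, a5, a6, a7.
    """
    rows = [
        ("t1", "p01", "a1", "2005-01-03T10:00:00", "stock"),
        ("t1", "p02", "a1", "2005-01-05T11:00:00", "stock"),
        ("t1", "p03", "a2", "2005-01-10T12:00:00", "stock"),
        ("t2", "p04", "a3", "2005-01-20T13:00:00", "stock"),
        ("t1", "p05", "a1", "2005-02-02T10:00:00", "stock"),
        ("t2", "p06", "a4", "2005-02-14T09:00:00", "stock"),
        ("t2", "p07", "a4", "2005-02-15T09:30:00", "stock"),
        ("t3", "p08", "a2", "2005-03-01T08:00:00", "stock"),
        ("t3", "p09", "a5", "2005-03-11T08:00:00", "stock"),
        ("t3", "p10", "a6", "2005-03-21T08:00:00", "stock"),
        ("t1", "p11", "a7", "2005-03-28T23:00:00", "stock"),
        ("t9", "p12", "a9", "2005-02-05T07:00:00", "other-topic"),
    ]
    return make_post_log(rows)


def series_from(counts) -> sd.ObservedSeries:
    counts = np.asarray(counts, dtype=float)
    return sd.ObservedSeries(
        topic_label="test", t=np.arange(len(counts)), counts=counts
    )
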