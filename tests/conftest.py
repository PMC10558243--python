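"""Shared fixtures: synthetic sessions at two scales.

The full-scale session uses the generator defaults (32 channels, 5 dead,
60 s per state at 24 414 Hz) and is expensive, so it is built once per test
run; the small session (8 channels, 18 s per state) serves the cheaper unit
tests.
"""

import numpy as np
import pytest

import engdecode as ed


@pytest.fixture(scope="session")
def default_session():
    return ed.generate_session(ed.SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_tables(default_session):
    """(train, test) feature tables at the default 0.55 s / 0.11 s framing."""
    pre = ed.preprocess_session(default_session)
    return ed.session_to_tables(pre, ed.WindowSpec(), test_fraction=0.1)


@pytest.fixture(scope="session")
def small_session():
    cfg = ed.SynthConfig(
        n_channels=8, n_dead_channels=2, segment_duration_s=18.0, seed=7
    )
    return ed.generate_session(cfg)


@pytest.fixture(scope="session")
def small_tables(small_session):
    pre = ed.preprocess_session(small_session)
    return ed.session_to_tables(pre, ed.WindowSpec(), test_fraction=0.1)
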