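"""Shared fixtures: simulated cases and tables, reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from hrvarousal.config import AnalysisConfig, WindowSpec
from hrvarousal.preprocess import RRSeries, clean
from hrvarousal.simulate import (
    SimCaseParams,
    SimStateProfile,
    simulate_case,
    simulate_study_table,
)


@pytest.fixture(scope="session")
def short_params() -> SimCaseParams:
    """A short (10 min) case: drug stop at 300 s, BIS crossing at 480 s."""
    return SimCaseParams(duration=600.0, drug_stop=300.0, t0=480.0, seed=11)


@pytest.fixture(scope="session")
def short_case(short_params):
    """(RRSeries, BISTrace, drug_stop) of the short case."""
    return simulate_case(short_params, SimStateProfile(), case_id="short")


@pytest.fixture(scope="session")
def clean_rr(short_case) -> RRSeries:
    rr, _, _ = short_case
    cleaned, _ = clean(rr)
    return cleaned


@pytest.fixture(scope="session")
def tracks(clean_rr):
    from hrvarousal.features import sliding_features

    return sliding_features(clean_rr, WindowSpec())


@pytest.fixture(scope="session")
def study_table():
    """Measurement table with the published design shape (208 rows)."""
    return simulate_study_table(seed=0)


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
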