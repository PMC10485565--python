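"""Shared fixtures: synthetic sessions generated once per test run."""
import numpy as np
import pytest

from pwavekit import synth
from pwavekit.pwave_detect import run_pwave_detection
from pwavekit.swr_detect import detect_swrs


@pytest.fixture(scope="session")
def hour_session():
    """One-hour, 1 kHz reference session at default study conditions."""
    return synth.generate_session(synth.SessionConfig(duration=3600.0, rate=1000.0, seed=0))


@pytest.fixture(scope="session")
def short_session():
    """Ten-minute session for cheaper whole-pipeline checks."""
    return synth.generate_session(synth.SessionConfig(duration=600.0, rate=1000.0, seed=1))


@pytest.fixture(scope="session")
def hour_pwaves(hour_session):
    ses = hour_session
    return run_pwave_detection(ses.signals["pons_a"], ses.signals["pons_b"],
                               ses.signals["emg"], ses.hypnogram)


@pytest.fixture(scope="session")
def hour_swrs(hour_session):
    ses = hour_session
    return detect_swrs(ses.signals["hpc_a"], ses.hypnogram)


def match_events(detected: np.ndarray, truth: np.ndarray, tol: float):
    """Greedy nearest matching; returns (recall, n_duplicates, errors of matched)."""
    if len(truth) == 0:
        return float("nan"), 0, np.array([])
    if len(detected) == 0:
        return 0.0, 0, np.array([])
    errs = np.array([np.min(np.abs(detected - t)) for t in truth])
    matched = errs <= tol
    assign = [int(np.argmin(np.abs(truth - d))) for d in detected
              if np.min(np.abs(truth - d)) <= tol]
    dup = len(assign) - len(set(assign))
    return float(np.mean(matched)), dup, errs[matched]
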