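"""Interrupter-technique resistance extraction (R_eo-f, R_eo-s) with QC.

A handheld occlusion device briefly blocks early expiration until a nominal
peak pressure of 400 Pa is sensed, then releases the shutter and records the
ensuing flow decay.  Two resistances are derived per breath:

* ``R_eo-f`` ("fast"): occlusion peak pressure divided by the maximum flow
  reached within 50 ms of shutter release.
* ``R_eo-s`` ("slow"): peak pressure divided by exp(b0), where b0 is the
  t = 0 intercept of an ordinary least-squares line fitted to ln(flow)
  between 5 and 200 ms after release.

Breaths are screened for artifact/forceful expiration, tests require at
least three valid breaths, and a session averages the valid tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "RejectionReason",
    "BreathResistance",
    "TestResult",
    "ReomSessionResult",
    "compute_reof",
    "compute_reos",
    "validate_breath",
    "analyze_breath",
    "aggregate_test",
    "aggregate_session",
]

# Packaged analysis constants (window conventions and validity thresholds).
REOF_WINDOW_S = (0.0, 0.050)  # (0, 50] ms after release
REOS_WINDOW_S = (0.005, 0.200)  # [5, 200] ms after release, inclusive
MIN_FIT_SAMPLES = 20
FORCEFUL_FLOW_MULTIPLE = 2.5
MIN_VALID_BREATHS_PER_TEST = 3
MIN_VALID_TESTS_PER_SESSION = 2

# Artifact screening: a passive decay seen through a first-order sensor is
# unimodal (one rise, one fall); effort transients break that.  The screen
# smooths the post-release flow and flags any dip during the rise or rebound
# during the fall larger than this fraction of the peak.  A within-test
# consistency screen (aggregate_test) then drops breaths whose estimates sit
# far off the test median, catching artifacts that merge into the flow peak.
UNIMODALITY_TOL = 0.05
UNIMODALITY_SMOOTH_S = 0.015
UNIMODALITY_SPAN_S = 0.25
CONSISTENCY_LOG_TOL = 0.2


class EstimationError(ValueError):
    """A breath trace cannot support the requested resistance estimate."""


class RejectionReason(str, Enum):
    NONE = "none"
    NEGATIVE_FLOW = "negative_flow"
    POOR_FIT = "poor_fit"
    FORCEFUL_EXPIRATION = "forceful_expiration"
    TOO_FEW_SAMPLES = "too_few_samples"


@dataclass
class BreathResistance:
    """Per-breath estimates plus fit diagnostics and validity flag."""

    reof: float | None
    reos: float | None
    fit_r2: float | None
    n_fit_samples: int
    valid: bool = False
    rejection_reason: RejectionReason = RejectionReason.NONE


@dataclass
class TestResult:
    """One occlusion test: aggregate over its (5-11) breaths."""

    reof: float | None
    reos: float | None
    n_valid_breaths: int
    test_valid: bool
    breaths: list[BreathResistance] = field(default_factory=list)


@dataclass
class ReomSessionResult:
    """Three-test session aggregate for one participant."""

    test_values: list[TestResult]
    session_reof: float | None
    session_reos: float | None
    session_valid: bool


def _window_samples(flow, release_index: int, fs: float, window: tuple[float, float],
                    inclusive_left: bool):
    """Times (s, from release) and flows for samples inside a window."""
    flow = np.asarray(flow, dtype=float)
    idx = np.arange(flow.size)
    t = (idx - release_index) / fs
    lo, hi = window
    if inclusive_left:
        mask = (t >= lo) & (t <= hi)
    else:
        mask = (t > lo) & (t <= hi)
    return t[mask], flow[mask]


def compute_reof(flow, release_index: int, P_peak: float, fs: float) -> float:
    """Fast interrupter resistance: P_peak / max flow within 50 ms of release.

    Parameters
    ----------
    flow : array-like
        Measured flow trace, L/s, covering the release.
    release_index : int
        Sample index of shutter release (t = 0).
    P_peak : float
        Occlusion peak pressure, kPa (a 400 Pa device trigger is 0.4).
    fs : float
        Sampling rate, Hz.
    """
    _, w = _window_samples(flow, release_index, fs, REOF_WINDOW_S, inclusive_left=False)
    if w.size == 0:
        raise EstimationError("no samples in the (0, 50] ms window after release")
    peak = float(np.max(w))
    if peak <= 0:
        raise EstimationError("no strictly positive flow within 50 ms of release")
    return P_peak / peak


def compute_reos(flow, release_index: int, P_peak: float, fs: float):
    """Slow interrupter resistance from the log-linear decay fit.

    OLS of ln(flow) on time over the 5-200 ms post-release window (positive
    flow samples only); the intercept b0 is evaluated at t = 0 and the
    resistance is P_peak / exp(b0).

    Returns
    -------
    (float, dict)
        Resistance in kPa*s/L and diagnostics {"fit_r2", "n_fit_samples"}.

    Raises
    ------
    EstimationError
        If fewer than 20 strictly positive flow samples fall in the window.
    """
    t, w = _window_samples(flow, release_index, fs, REOS_WINDOW_S, inclusive_left=True)
    pos = w > 0
    t, w = t[pos], w[pos]
    if t.size < MIN_FIT_SAMPLES:
        raise EstimationError(
            f"only {t.size} usable samples in the 5-200 ms window "
            f"(minimum {MIN_FIT_SAMPLES})"
        )
    y = np.log(w)
    slope, b0 = np.polyfit(t, y, 1)
    resid = y - (slope * t + b0)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return P_peak / float(np.exp(b0)), {"fit_r2": r2, "n_fit_samples": int(t.size)}


def unimodality_deviation(flow, release_index: int, fs: float) -> float:
    """Largest departure from a single-peaked post-release flow shape,
    as a fraction of the smoothed peak (0 for a clean passive decay)."""
    f = np.asarray(flow, dtype=float)[release_index:
                                      release_index + int(UNIMODALITY_SPAN_S * fs)]
    if f.size < 3:
        return 0.0
    k = max(int(UNIMODALITY_SMOOTH_S * fs), 1)
    s = np.convolve(f, np.ones(k) / k, mode="valid")
    pk = int(np.argmax(s))
    peak = float(s[pk])
    if peak <= 0:
        return float("inf")
    rise, fall = s[: pk + 1], s[pk:]
    dip = float(np.max(np.maximum.accumulate(rise) - rise))
    rebound = float(np.max(fall - np.minimum.accumulate(fall)))
    return max(dip, rebound) / peak


def validate_breath(flow, release_index: int, P_peak: float, fs: float,
                    prelim: BreathResistance) -> tuple[bool, RejectionReason]:
    """Screen one breath for artifact or forceful expiration.

    A breath is invalid when any flow sample in the 5-200 ms window is
    non-positive, when the post-release flow is not single-peaked (effort
    artifact), or when the early peak flow exceeds 2.5x the flow implied by
    the slow resistance (forceful expiration).
    """
    if prelim.rejection_reason == RejectionReason.TOO_FEW_SAMPLES:
        return False, RejectionReason.TOO_FEW_SAMPLES
    _, w = _window_samples(flow, release_index, fs, REOS_WINDOW_S, inclusive_left=True)
    if w.size == 0 or np.any(w <= 0):
        return False, RejectionReason.NEGATIVE_FLOW
    if unimodality_deviation(flow, release_index, fs) > UNIMODALITY_TOL:
        return False, RejectionReason.POOR_FIT
    _, wf = _window_samples(flow, release_index, fs, REOF_WINDOW_S, inclusive_left=False)
    if wf.size and prelim.reos is not None and prelim.reos > 0:
        if float(np.max(wf)) > FORCEFUL_FLOW_MULTIPLE * P_peak / prelim.reos:
            return False, RejectionReason.FORCEFUL_EXPIRATION
    return True, RejectionReason.NONE


def analyze_breath(flow, release_index: int, P_peak: float, fs: float) -> BreathResistance:
    """Run both estimators plus validity screening on one breath trace."""
    try:
        reos, diag = compute_reos(flow, release_index, P_peak, fs)
        prelim = BreathResistance(
            reof=None, reos=reos, fit_r2=diag["fit_r2"],
            n_fit_samples=diag["n_fit_samples"],
        )
    except EstimationError:
        prelim = BreathResistance(
            reof=None, reos=None, fit_r2=None, n_fit_samples=0,
            rejection_reason=RejectionReason.TOO_FEW_SAMPLES,
        )
    try:
        prelim.reof = compute_reof(flow, release_index, P_peak, fs)
    except EstimationError:
        prelim.valid = False
        prelim.rejection_reason = RejectionReason.NEGATIVE_FLOW
        return prelim
    prelim.valid, prelim.rejection_reason = validate_breath(
        flow, release_index, P_peak, fs, prelim
    )
    return prelim


def aggregate_test(breaths: Sequence[BreathResistance]) -> TestResult:
    """Per-test aggregation: median over valid breaths; valid iff >= 3 of them.

    Before aggregating, a within-test consistency screen invalidates breaths
    whose fast/slow estimate ratio sits more than ~20% (log scale) off the
    test median ratio: effort transients that merge smoothly into the early
    flow peak distort the fast estimate while barely moving the slow fit,
    whereas legitimate breath-to-breath variation moves both together.
    """
    if not 5 <= len(breaths) <= 11:
        raise ValueError(f"a test holds 5-11 breaths, got {len(breaths)}")
    valid = [b for b in breaths if b.valid]
    if len(valid) >= MIN_VALID_BREATHS_PER_TEST:
        med_ratio = float(np.median([b.reof / b.reos for b in valid]))
        for b in valid:
            if abs(np.log(b.reof / b.reos / med_ratio)) > CONSISTENCY_LOG_TOL:
                b.valid = False
                b.rejection_reason = RejectionReason.POOR_FIT
        valid = [b for b in breaths if b.valid]
    ok = len(valid) >= MIN_VALID_BREATHS_PER_TEST
    reof = float(np.median([b.reof for b in valid])) if ok else None
    reos = float(np.median([b.reos for b in valid])) if ok else None
    return TestResult(reof=reof, reos=reos, n_valid_breaths=len(valid),
                      test_valid=ok, breaths=list(breaths))


def aggregate_session(tests: Sequence[TestResult]) -> ReomSessionResult:
    """Session aggregation over exactly 3 tests: mean of valid tests.

    The session is valid when at least 2 of the 3 tests are; invalid
    sessions carry None values and are excluded (and counted) downstream.
    """
    if len(tests) != 3:
        raise ValueError(f"a session holds exactly 3 tests, got {len(tests)}")
    valid = [t for t in tests if t.test_valid]
    ok = len(valid) >= MIN_VALID_TESTS_PER_SESSION
    reof = float(np.mean([t.reof for t in valid])) if ok else None
    reos = float(np.mean([t.reos for t in valid])) if ok else None
    return ReomSessionResult(test_values=list(tests), session_reof=reof,
                             session_reos=reos, session_valid=ok)
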