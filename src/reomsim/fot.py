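"""Cross-spectral impedance estimation and the replicate QC loop.

Impedance at each multisine tone is estimated from a recording by the H1
cross-spectral estimator Z(f) = S_qp(f) / S_qq(f) (flow q as reference
input, pressure p as output) on Hann windows of 4 s with 50% overlap, so the
lowest tone (5 Hz) sees >= 20 periods per window.  Magnitude-squared
coherence below 0.9 at a tone marks it unreliable; a replicate whose 5 or
19 Hz tone is unreliable is rejected but still counts against the 6-attempt
session budget.

Sessions follow the usual oscillometry acceptability rule: replicates are
collected until the coefficient of variation of the lowest-frequency
resistance across collected replicates is <= 10% (minimum 3, maximum 6
attempts); accepted sessions report the mean R5 and R19 over collected
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .mechanics import LungModel
from .simulate import DeviceModel, FotReplicate, NoiseSpec, simulate_fot_replicate

__all__ = [
    "ImpedanceEstimate",
    "FotSessionResult",
    "estimate_impedance",
    "replicate_qc_session",
]

WINDOW_S = 4.0
OVERLAP = 0.5
MIN_COHERENCE = 0.9
CV_THRESHOLD = 0.10
MIN_REPLICATES = 3
MAX_REPLICATES = 6


@dataclass
class ImpedanceEstimate:
    """Per-tone impedance and coherence from one replicate."""

    frequencies: np.ndarray  # tone frequencies, Hz
    Z: np.ndarray  # complex, kPa*s/L
    coherence: np.ndarray  # magnitude-squared coherence in [0, 1]
    R5: float
    R19: float

    @property
    def reliable(self) -> np.ndarray:
        return self.coherence >= MIN_COHERENCE


@dataclass
class FotSessionResult:
    """Outcome of the 3-6 replicate QC loop for one participant."""

    replicate_R5: list[float] = field(default_factory=list)
    replicate_R19: list[float] = field(default_factory=list)
    n_attempts: int = 0
    n_rejected: int = 0
    cv_lowest_freq: float = float("nan")  # percent
    accepted: bool = False
    session_R5: float | None = None
    session_R19: float | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_R5)


def estimate_impedance(rep: FotReplicate, device: DeviceModel) -> ImpedanceEstimate:
    """H1 cross-spectral impedance at the device tones, with coherence.

    Raises
    ------
    ValueError
        If the replicate is shorter than two analysis windows.
    """
    fs = device.fs_fot
    nperseg = int(round(WINDOW_S * fs))
    noverlap = int(round(OVERLAP * nperseg))
    if rep.flow.size < nperseg + (nperseg - noverlap):
        raise ValueError("replicate shorter than two analysis windows")

    f, s_qq = signal.welch(rep.flow, fs=fs, window="hann",
                           nperseg=nperseg, noverlap=noverlap)
    _, s_qp = signal.csd(rep.flow, rep.pressure, fs=fs, window="hann",
                         nperseg=nperseg, noverlap=noverlap)
    _, coh = signal.coherence(rep.flow, rep.pressure, fs=fs, window="hann",
                              nperseg=nperseg, noverlap=noverlap)
    tones = np.asarray(device.tones, dtype=float)
    idx = np.array([int(np.argmin(np.abs(f - tone))) for tone in tones])
    z = s_qp[idx] / s_qq[idx]
    c = np.clip(coh[idx], 0.0, 1.0)
    r5 = float(z.real[np.argmin(np.abs(tones - 5.0))])
    r19 = float(z.real[np.argmin(np.abs(tones - 19.0))])
    return ImpedanceEstimate(frequencies=tones, Z=z, coherence=c, R5=r5, R19=r19)


def _tone_reliable(est: ImpedanceEstimate, tone: float) -> bool:
    return bool(est.reliable[np.argmin(np.abs(est.frequencies - tone))])


def replicate_qc_session(model: LungModel, device: DeviceModel,
                         noise: NoiseSpec, seed) -> FotSessionResult:
    """Simulate-and-estimate replicates until the CV rule accepts.

    From the third collected replicate onward the CV (sd/mean, percent) of
    R at the lowest tone is computed over all collected replicates; the
    session stops and is accepted at the first CV <= 10%, with a hard stop
    after 6 attempts (accepted = False if the rule was never met).  Failed
    sessions are flagged, never silently dropped.
    """
    ss = np.random.SeedSequence(entropy=seed) if isinstance(seed, int) else seed
    result = FotSessionResult()
    for rep_seed in ss.spawn(MAX_REPLICATES):
        result.n_attempts += 1
        rep = simulate_fot_replicate(model, device, noise, rep_seed)
        est = estimate_impedance(rep, device)
        if not (_tone_reliable(est, 5.0) and _tone_reliable(est, 19.0)):
            result.n_rejected += 1
            continue
        result.replicate_R5.append(est.R5)
        result.replicate_R19.append(est.R19)
        if result.n_replicates >= MIN_REPLICATES:
            r = np.asarray(result.replicate_R5)
            cv = float(np.std(r, ddof=1) / np.mean(r)) * 100.0
            result.cv_lowest_freq = cv
            if cv <= CV_THRESHOLD * 100.0:
                result.accepted = True
                break
    if result.accepted:
        result.session_R5 = float(np.mean(result.replicate_R5))
        result.session_R19 = float(np.mean(result.replicate_R19))
    return result
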