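"""Raw-waveform simulators for both measurement modalities.

``simulate_reom_test`` produces occlusion-release breath trains (flow decays
seen through a first-order flow sensor, with multiplicative measurement noise
and occasional effort artifacts); ``simulate_fot_replicate`` produces
multisine (5-37 Hz) pressure-flow recordings superimposed on tidal breathing.
Both are deterministic given a seed.

Device-participant couplings live on :class:`DeviceModel`:

* ``sensor_fc`` - the flow channel is a first-order low-pass; a sluggish
  sensor undershoots the early post-release flow peak, which inflates the
  measured fast interrupter resistance above the latent airway resistance.
* ``p_overshoot`` - the shutter opens a short mechanical delay after the
  400 Pa trigger is sensed, during which expiratory effort keeps charging
  the system; the true release pressure is ``p_overshoot`` x the trigger,
  while the device reports (and the estimator divides by) the nominal
  trigger pressure, deflating both interrupter resistances by 1/p_overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .mechanics import LungModel, free_expiration_flow, impedance

__all__ = [
    "DeviceModel",
    "NoiseSpec",
    "Breath",
    "ReomTestRecording",
    "FotReplicate",
    "simulate_reom_test",
    "simulate_fot_replicate",
    "apply_cheek_hold",
    "CHEEK_HOLD_SCALES",
    "DEFAULT_TONES",
]

DEFAULT_TONES = (5.0, 11.0, 13.0, 17.0, 19.0, 23.0, 29.0, 31.0, 37.0)

# Shutter-to-decay capture length; the slow fit needs 200 ms plus margin.
REOM_PRE_S = 0.05
REOM_POST_S = 0.35


@dataclass(frozen=True)
class DeviceModel:
    """Instrument characteristics for both modalities.

    P_trigger : occlusion release (trigger) pressure, kPa; nominal 0.4.
    sensor_fc : first-order low-pass cutoff of the flow channel, Hz.
    p_overshoot : true release pressure / trigger pressure, >= 1.
    fs_reom / fs_fot : sampling rates, Hz.
    tones : multisine component frequencies, Hz (must contain 5 and 19).
    rep_duration : oscillometry replicate length, s.
    tone_amplitude : per-tone pressure amplitude, kPa.
    """

    P_trigger: float = 0.4
    sensor_fc: float = 50.0
    p_overshoot: float = 1.0
    fs_reom: float = 1000.0
    fs_fot: float = 256.0
    tones: tuple[float, ...] = DEFAULT_TONES
    rep_duration: float = 16.0
    tone_amplitude: float = 0.1

    def __post_init__(self) -> None:
        if not self.P_trigger > 0:
            raise ValueError("P_trigger must be > 0")
        if not self.sensor_fc > 0:
            raise ValueError("sensor_fc must be > 0")
        if self.p_overshoot < 1.0:
            raise ValueError("p_overshoot must be >= 1")
        if 5.0 not in self.tones or 19.0 not in self.tones:
            raise ValueError("tones must include 5 and 19 Hz")
        if min(self.tones) < 5.0 or max(self.tones) > 37.0:
            raise ValueError("tones must lie within [5, 37] Hz")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise and artifact settings for the simulators.

    flow_cv : multiplicative per-sample flow noise CV (unitless).
    artifact_prob : probability a breath carries an injected effort artifact.
    artifact_scale : artifact amplitude relative to the local flow peak.
    breath_rate / breath_flow_amp : tidal breathing sinusoid under the
        oscillometry multisine, Hz and L/s.
    """

    flow_cv: float = 0.04
    artifact_prob: float = 0.15
    artifact_scale: float = 0.5
    breath_rate: float = 0.25
    breath_flow_amp: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.artifact_prob <= 1:
            raise ValueError("artifact_prob must be in [0, 1]")
        if self.flow_cv < 0:
            raise ValueError("flow_cv must be >= 0")

    def quiet(self) -> "NoiseSpec":
        """Noise-free, artifact-free copy (for oracles and calibration)."""
        return replace(self, flow_cv=0.0, artifact_prob=0.0, breath_flow_amp=0.0)


@dataclass
class Breath:
    """One simulated occlusion-release breath."""

    t: np.ndarray  # s, uniform grid covering the release
    flow: np.ndarray  # measured flow, L/s
    P_peak: float  # device-reported occlusion peak pressure, kPa
    release_index: int  # sample index of shutter release (t = 0 of decay)
    injected_artifact: bool = False


@dataclass
class ReomTestRecording:
    """A train of 5-11 occlusion breaths forming one device test."""

    breaths: list[Breath]

    @property
    def n_breaths(self) -> int:
        return len(self.breaths)


@dataclass
class FotReplicate:
    """One multisine oscillometry recording."""

    t: np.ndarray  # s
    pressure: np.ndarray  # kPa
    flow: np.ndarray  # L/s
    duration: float  # s


def _lowpass_first_order(x: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Discrete one-pole low-pass with zero initial state (flow is zero
    during the occlusion, so the sensor output starts relaxed)."""
    dt = 1.0 / fs
    alpha = dt / (dt + 1.0 / (2.0 * np.pi * fc))
    return signal.lfilter([alpha], [1.0, alpha - 1.0], x)


def _simulate_breath(model: LungModel, device: DeviceModel, noise: NoiseSpec,
                     rng: np.random.Generator) -> Breath:
    fs = device.fs_reom
    n_pre = int(round(REOM_PRE_S * fs))
    n_post = int(round(REOM_POST_S * fs)) + 1
    t_decay = np.arange(n_post) / fs
    p_release = device.p_overshoot * device.P_trigger
    true_flow = free_expiration_flow(model, p_release, t_decay)
    x = np.concatenate([np.zeros(n_pre), true_flow])
    y = _lowpass_first_order(x, device.sensor_fc, fs)
    if noise.flow_cv > 0:
        y = y * (1.0 + rng.normal(0.0, noise.flow_cv, size=y.size))

    flagged = False
    if noise.artifact_prob > 0 and rng.random() < noise.artifact_prob:
        flagged = True
        # Gaussian-bump effort transient (or sign-flipped dip), centred
        # somewhere in the first 200 ms of the decay; brief glottal/effort
        # events, ~5-30 ms wide.
        center = rng.uniform(1e-3, 0.200)
        width = rng.uniform(0.005, 0.030)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        amp = sign * noise.artifact_scale * float(np.max(true_flow))
        tt = np.arange(y.size) / fs - n_pre / fs
        y = y + amp * np.exp(-0.5 * ((tt - center) / width) ** 2)

    # The device senses ~the trigger pressure (1% sensor jitter, clipped to
    # the 2% device contract), not the overshoot reached during the
    # shutter's mechanical opening delay.
    jitter = float(np.clip(0.01 * rng.standard_normal(), -0.02, 0.02))
    p_peak = device.P_trigger * (1.0 + jitter) \
        if noise.flow_cv > 0 else device.P_trigger
    t = (np.arange(y.size) - n_pre) / fs
    return Breath(t=t, flow=y, P_peak=p_peak, release_index=n_pre,
                  injected_artifact=flagged)


def simulate_reom_test(model: LungModel, device: DeviceModel, noise: NoiseSpec,
                       n_breaths: int, seed) -> ReomTestRecording:
    """Simulate one occlusion test of ``n_breaths`` (5-11) breaths.

    Deterministic given ``seed`` (an int or numpy SeedSequence).
    """
    if not 5 <= n_breaths <= 11:
        raise ValueError(f"n_breaths must be in [5, 11], got {n_breaths}")
    rng = np.random.default_rng(seed)
    breaths = [_simulate_breath(model, device, noise, rng) for _ in range(n_breaths)]
    return ReomTestRecording(breaths=breaths)


def simulate_fot_replicate(model: LungModel, device: DeviceModel,
                           noise: NoiseSpec, seed) -> FotReplicate:
    """Simulate one multisine oscillometry replicate.

    The excitation pressure is a sum of equal-amplitude cosines at the device
    tones with random phases; the oscillatory flow response is computed
    tone-by-tone through the analytic impedance (steady state).  Tidal
    breathing is added to the flow as a sinusoid, plus white measurement
    noise of sd ``flow_cv * breath_flow_amp``.
    """
    rng = np.random.default_rng(seed)
    fs = device.fs_fot
    n = int(round(fs * device.rep_duration))
    t = np.arange(n) / fs
    tones = np.asarray(device.tones, dtype=float)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=tones.size)
    z = impedance(model, tones).Z

    pressure = np.zeros(n)
    flow = np.zeros(n)
    for fk, ph, zk in zip(tones, phases, z):
        w = 2.0 * np.pi * fk
        pressure += device.tone_amplitude * np.cos(w * t + ph)
        flow += (device.tone_amplitude / np.abs(zk)) * np.cos(w * t + ph - np.angle(zk))

    if noise.breath_flow_amp > 0:
        flow = flow + noise.breath_flow_amp * np.sin(
            2.0 * np.pi * noise.breath_rate * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.flow_cv > 0 and noise.breath_flow_amp > 0:
        flow = flow + rng.normal(
            0.0, noise.flow_cv * noise.breath_flow_amp, size=n
        )
    return FotReplicate(t=t, pressure=pressure, flow=flow,
                        duration=device.rep_duration)


def noiseless_breath(model: LungModel, device: DeviceModel) -> Breath:
    """One noise-free, artifact-free occlusion breath.

    This is the deterministic forward model used by participant calibration
    and by estimator oracles; it follows exactly the same code path as
    :func:`simulate_reom_test` with a quiet noise spec.
    """
    rng = np.random.default_rng(0)  # consumed only by noise branches (none)
    return _simulate_breath(model, device, NoiseSpec().quiet(), rng)


CHEEK_HOLD_SCALES = {"none": 1.0, "one_hand": 0.5, "two_hands": 0.1}


def apply_cheek_hold(model: LungModel, condition: str,
                     c0: float = 0.02) -> LungModel:
    """Return a copy of the model with the shunt compliance set by the
    cheek-hold condition: no hold leaves the participant's baseline shunt
    ``c0`` (L/kPa) in place, a one-handed hold halves it, and a two-handed
    hold (technician-assisted) reduces it to 10%."""
    try:
        scale = CHEEK_HOLD_SCALES[condition]
    except KeyError:
        raise ValueError(
            f"unknown cheek-hold condition {condition!r}; "
            f"expected one of {sorted(CHEEK_HOLD_SCALES)}"
        ) from None
    return model.with_shunt(scale * c0)
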