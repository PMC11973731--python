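"""Synthetic COPD cohort generation calibrated to printed group summaries.

Participants come in two severity groups (mild, GOLD 1, n = 9; very severe,
GOLD 4, n = 8).  For each participant a "truth" quadruple of session-level
resistances (R5, R19, Reo_s, Reo_f) is drawn from lognormal marginals whose
median and interquartile range default to the emulated study's group tables,
coupled by a Gaussian copula (both devices measure the same physiology, so
the four values are strongly correlated within a participant).  A mechanical
model plus device couplings (sensor bandwidth, release-pressure overshoot)
is then calibrated so that the noiseless simulate-then-estimate pipeline
reproduces the drawn quadruple; noisy simulations downstream therefore
scatter around distributions whose medians match the published tables.

Demographics (age, BMI, pack-years, sex) are drawn from group normals
truncated at the study's eligibility floors and act purely as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .mechanics import LungModel, resistance_at
from .reom import analyze_breath
from .simulate import DeviceModel, noiseless_breath

__all__ = [
    "GroupSpec",
    "Demographics",
    "Participant",
    "GOLD1_DEFAULT",
    "GOLD4_DEFAULT",
    "CalibrationError",
    "draw_target_quadruple",
    "calibrate_participant",
    "assign_demographics",
    "generate_cohort",
]

MEASURES = ("R5", "R19", "Reo_s", "Reo_f")

# Probit of 0.75: lognormal sigma maps IQR onto log-scale quantiles.
_Z75 = 0.6744897501960817

# Eligibility floors (study inclusion criteria).
AGE_FLOOR = 40.0
PACK_YEARS_FLOOR = 10.0
BMI_FLOOR = 14.0


@dataclass(frozen=True)
class GroupSpec:
    """Target distributions for one severity group.

    ``medians``/``iqrs`` hold the four session resistances in kPa*s/L keyed
    by R5, R19, Reo_s, Reo_f; demographics are means/SDs of normals truncated
    at the eligibility floors; ``copula_rho`` couples the four resistances.
    """

    label: str
    n: int
    medians: dict[str, float]
    iqrs: dict[str, float]
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    pack_years_mean: float
    pack_years_sd: float
    female_fraction: float
    copula_rho: float = 0.95

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        for k in MEASURES:
            if self.medians[k] <= 0:
                raise ValueError(f"median for {k} must be > 0")
            if self.iqrs[k] < 0:
                raise ValueError(f"IQR for {k} must be >= 0")
        if not -1 < self.copula_rho < 1:
            raise ValueError("copula_rho must be in (-1, 1)")


GOLD1_DEFAULT = GroupSpec(
    label="GOLD1",
    n=9,
    medians={"R5": 0.319, "R19": 0.253, "Reo_s": 0.237, "Reo_f": 0.231},
    iqrs={"R5": 0.090, "R19": 0.071, "Reo_s": 0.037, "Reo_f": 0.043},
    age_mean=71.78, age_sd=5.76,
    bmi_mean=26.66, bmi_sd=2.66,
    pack_years_mean=29.44, pack_years_sd=18.78,
    female_fraction=5.0 / 9.0,
)

GOLD4_DEFAULT = GroupSpec(
    label="GOLD4",
    n=8,
    medians={"R5": 0.721, "R19": 0.392, "Reo_s": 0.632, "Reo_f": 0.615},
    iqrs={"R5": 0.223, "R19": 0.252, "Reo_s": 0.123, "Reo_f": 0.178},
    age_mean=60.38, age_sd=6.44,
    bmi_mean=20.98, bmi_sd=5.55,
    pack_years_mean=32.75, pack_years_sd=19.17,
    female_fraction=4.0 / 8.0,
)


@dataclass
class Demographics:
    age: float
    sex: str  # "F" or "M"
    bmi: float
    pack_years: float


@dataclass
class Participant:
    """One synthetic study participant: truth targets, calibrated latent
    mechanics + device couplings, and covariates."""

    id: str
    group: str
    targets: dict[str, float]
    model: LungModel
    device: DeviceModel
    demographics: Demographics
    c0_shunt: float = 0.02  # baseline cheek shunt compliance, L/kPa
    calibration_residual: float = 0.0
    calibration_ok: bool = True

    def __post_init__(self) -> None:
        if self.demographics.age < AGE_FLOOR:
            raise ValueError("participants are >= 40 years by eligibility")
        if self.demographics.pack_years < PACK_YEARS_FLOOR:
            raise ValueError("participants have >= 10 pack-years by eligibility")
        if not self.targets["R5"] > self.targets["R19"]:
            raise ValueError("R5 target must exceed R19 target")


class CalibrationError(RuntimeError):
    """Persistent failure to invert the mechanics onto a drawn quadruple."""


def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given median and IQR.

    With q25*q75 = median^2 the IQR constraint gives
    sigma = asinh(IQR / (2*median)) / z_0.75, equivalently
    ln(q75/q25) / (2*z_0.75).
    """
    mu = np.log(median)
    sigma = np.arcsinh(iqr / (2.0 * median)) / _Z75
    return mu, sigma


def draw_target_quadruple(spec: GroupSpec, seed) -> dict[str, float]:
    """Draw one (R5, R19, Reo_s, Reo_f) truth quadruple, kPa*s/L.

    Lognormal marginals matched to the spec's median/IQR, Gaussian copula
    with pairwise correlation ``spec.copula_rho``; redrawn (at most 100
    times) until R5 > R19.  The Reo_s > Reo_f ordering seen in the group
    medians is not enforced per participant.
    """
    rng = np.random.default_rng(seed)
    mus, sigmas = zip(*(_lognormal_params(spec.medians[k], spec.iqrs[k])
                        for k in MEASURES))
    mus = np.array(mus)
    sigmas = np.array(sigmas)
    corr = np.full((4, 4), spec.copula_rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    for _ in range(100):
        z = chol @ rng.standard_normal(4)
        x = np.exp(mus + sigmas * z)
        if x[0] > x[1]:  # R5 > R19
            return dict(zip(MEASURES, (float(v) for v in x)))
    raise RuntimeError("could not draw a quadruple with R5 > R19 in 100 tries")


# Calibration bounds: (Raw, Rve, tau_ve, Crs, sensor_fc, p_overshoot).
CALIBRATION_BOUNDS = (
    np.array([0.01, 0.0, 0.005, 0.2, 5.0, 1.0]),
    np.array([2.0, 20.0, 0.5, 3.0, 200.0, 2.0]),
)
CALIBRATION_TOL = 0.02  # max relative residual for success


def _predict_quadruple(theta: np.ndarray, base_device: DeviceModel) -> np.ndarray:
    raw, rve, tau, crs, fc, ov = theta
    model = LungModel(Raw=raw, Rve=rve, tau_ve=tau, Crs=crs)
    device = replace(base_device, sensor_fc=fc, p_overshoot=ov)
    r5 = resistance_at(model, 5.0)
    r19 = resistance_at(model, 19.0)
    b = noiseless_breath(model, device)
    br = analyze_breath(b.flow, b.release_index, b.P_peak, device.fs_reom)
    return np.array([r5, r19, br.reos, br.reof])


def _warm_start(targets: np.ndarray) -> np.ndarray:
    """Closed-form (R5, R19) inversion at tau_ve = 0.1 seeds the search."""
    a5 = 1.0 / (1.0 + (2.0 * np.pi * 5.0 * 0.1) ** 2)
    a19 = 1.0 / (1.0 + (2.0 * np.pi * 19.0 * 0.1) ** 2)
    rve0 = max((targets[0] - targets[1]) / (a5 - a19), 0.01)
    raw0 = max(targets[1] - rve0 * a19, 0.02)
    return np.array([raw0, rve0, 0.1, 1.0, 50.0, 1.2])


def calibrate_participant(targets: dict[str, float],
                          bounds=CALIBRATION_BOUNDS,
                          base_device: DeviceModel | None = None,
                          x0: np.ndarray | None = None):
    """Invert the mechanics + device couplings onto a target quadruple.

    Least squares (trust-region reflective with finite differences) over
    theta = (Raw, Rve, tau_ve, Crs, sensor_fc, p_overshoot) minimising the
    relative misfit of (analytic R5, R19; noiseless simulated-and-estimated
    Reo_s, Reo_f) against the targets.

    Returns
    -------
    (LungModel, DeviceModel, float, bool)
        Calibrated model, device with fitted sensor_fc/p_overshoot, the max
        relative residual, and a success flag (residual <= 2%).
    """
    if base_device is None:
        base_device = DeviceModel()
    t = np.array([targets[k] for k in MEASURES], dtype=float)
    if np.any(t <= 0):
        raise ValueError("targets must be positive")
    if not t[0] > t[1]:
        raise ValueError("targets must satisfy R5 > R19")
    lb, ub = bounds
    if x0 is None:
        x0 = _warm_start(t)
    x0 = np.clip(x0, lb, ub)

    sol = optimize.least_squares(
        lambda th: _predict_quadruple(th, base_device) / t - 1.0,
        x0, bounds=(lb, ub), xtol=1e-6, ftol=1e-8, max_nfev=120,
    )
    raw, rve, tau, crs, fc, ov = sol.x
    model = LungModel(Raw=raw, Rve=rve, tau_ve=tau, Crs=crs)
    device = replace(base_device, sensor_fc=fc, p_overshoot=ov)
    residual = float(np.max(np.abs(sol.fun)))
    return model, device, residual, residual <= CALIBRATION_TOL


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float) -> float:
    if sd == 0:
        return max(mean, floor)
    a = (floor - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))


def assign_demographics(spec: GroupSpec, seed) -> Demographics:
    """Draw covariates from group normals truncated at eligibility floors."""
    rng = np.random.default_rng(seed)
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, AGE_FLOOR)
    bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, BMI_FLOOR)
    pack = _truncated_normal(rng, spec.pack_years_mean, spec.pack_years_sd,
                             PACK_YEARS_FLOOR)
    sex = "F" if rng.random() < spec.female_fraction else "M"
    return Demographics(age=age, sex=sex, bmi=bmi, pack_years=pack)


MAX_CALIBRATION_ATTEMPTS = 20


def _make_participant(pid: str, spec: GroupSpec, seed,
                      base_device: DeviceModel | None = None,
                      x0: np.ndarray | None = None) -> Participant:
    ss = np.random.SeedSequence(entropy=seed) if isinstance(seed, int) else seed
    demo_seed, *draw_seeds = ss.spawn(MAX_CALIBRATION_ATTEMPTS + 1)
    demo = assign_demographics(spec, demo_seed)
    best = None
    for draw_seed in draw_seeds:
        targets = draw_target_quadruple(spec, draw_seed)
        model, device, residual, ok = calibrate_participant(
            targets, base_device=base_device, x0=x0)
        if best is None or residual < best[3]:
            best = (targets, model, device, residual, ok)
        if ok:
            break
    targets, model, device, residual, ok = best
    return Participant(
        id=pid, group=spec.label, targets=targets, model=model, device=device,
        demographics=demo, calibration_residual=residual, calibration_ok=ok,
    )


def generate_group(spec: GroupSpec, seed) -> list[Participant]:
    """Generate one severity group of ``spec.n`` calibrated participants.

    Deterministic given ``seed``.  Each participant draws a truth quadruple
    and is calibrated; if no draw calibrates within tolerance after 20
    attempts the best fit is kept with ``calibration_ok=False`` (flagged,
    never silently dropped).  All participants are warm-started from the
    group-median calibration.
    """
    ss = np.random.SeedSequence(entropy=seed) if isinstance(seed, int) else seed
    med_model, med_device, _, _ = calibrate_participant(spec.medians)
    x0 = np.array([med_model.Raw, med_model.Rve, med_model.tau_ve,
                   med_model.Crs, med_device.sensor_fc, med_device.p_overshoot])
    return [
        _make_participant(f"{spec.label}-{i:02d}", spec, sub, x0=x0)
        for i, sub in enumerate(ss.spawn(spec.n), start=1)
    ]


def generate_cohort(spec1: GroupSpec = GOLD1_DEFAULT,
                    spec4: GroupSpec = GOLD4_DEFAULT,
                    seed=0) -> list[Participant]:
    """Generate the full two-group cohort (defaults: 9 + 8 participants),
    deterministic given ``seed``."""
    ss = np.random.SeedSequence(entropy=seed) if isinstance(seed, int) else seed
    ss1, ss4 = ss.spawn(2)
    return generate_group(spec1, ss1) + generate_group(spec4, ss4)
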