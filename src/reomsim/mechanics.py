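"""Analytic respiratory-mechanics model shared by both simulated modalities.

The respiratory system is represented as a Newtonian airway resistance ``Raw``
in series with a Kelvin body (tissue resistance ``Rve`` in parallel with a
tissue compliance, summarised by the time constant ``tau_ve``) and the overall
respiratory compliance ``Crs``.  This is the minimal passive linear model that
produces both hallmarks the package needs to emulate:

* negative frequency dependence of oscillatory resistance (Re Z falls as the
  forcing frequency rises), and
* a biexponential flow decay after an expiratory occlusion is released.

An optional inertance ``Iaw`` and an upper-airway (cheek) shunt compliance
``Cshunt`` can be switched on; both default to zero.

Units follow clinical oscillometry convention throughout: pressure kPa,
flow L/s, resistance kPa*s/L, compliance L/kPa, inertance kPa*s^2/L.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LungModel",
    "ImpedanceSpectrum",
    "impedance",
    "resistance_at",
    "free_expiration_flow",
]


@dataclass(frozen=True)
class LungModel:
    """Latent mechanical parameters of one synthetic participant.

    Parameters
    ----------
    Raw : float
        Newtonian airway resistance, kPa*s/L. Must be positive.
    Rve : float
        Viscoelastic tissue resistance, kPa*s/L. Non-negative.
    tau_ve : float
        Viscoelastic time constant of the Kelvin body, s. Positive.
    Crs : float
        Respiratory-system compliance, L/kPa. Positive.
    Iaw : float, optional
        Airway inertance, kPa*s^2/L. Default 0.
    Cshunt : float, optional
        Upper-airway/cheek shunt compliance in parallel with the respiratory
        system, L/kPa. Default 0 (ideal cheek support).
    """

    Raw: float
    Rve: float = 0.0
    tau_ve: float = 0.1
    Crs: float = 1.0
    Iaw: float = 0.0
    Cshunt: float = 0.0

    def __post_init__(self) -> None:
        if not self.Raw > 0:
            raise ValueError(f"Raw must be > 0, got {self.Raw}")
        if self.Rve < 0:
            raise ValueError(f"Rve must be >= 0, got {self.Rve}")
        if not self.tau_ve > 0:
            raise ValueError(f"tau_ve must be > 0, got {self.tau_ve}")
        if not self.Crs > 0:
            raise ValueError(f"Crs must be > 0, got {self.Crs}")
        if self.Iaw < 0:
            raise ValueError(f"Iaw must be >= 0, got {self.Iaw}")
        if self.Cshunt < 0:
            raise ValueError(f"Cshunt must be >= 0, got {self.Cshunt}")

    def with_shunt(self, cshunt: float) -> "LungModel":
        """Return a copy with a different shunt compliance."""
        return replace(self, Cshunt=cshunt)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex respiratory input impedance evaluated on a frequency grid."""

    frequencies: np.ndarray  # Hz, strictly positive, ascending
    Z: np.ndarray  # complex, kPa*s/L

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.Z, dtype=complex)
        if f.shape != z.shape:
            raise ValueError("frequencies and Z must have equal length")
        if f.size and (np.any(f <= 0) or np.any(np.diff(f) <= 0)):
            raise ValueError("frequencies must be strictly positive and ascending")
        if not np.all(np.isfinite(z.real)):
            raise ValueError("Re(Z) must be finite at every frequency")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "Z", z)

    @property
    def resistance(self) -> np.ndarray:
        """Real part of Z per frequency (the oscillometric 'R')."""
        return self.Z.real


def impedance(model: LungModel, frequencies) -> ImpedanceSpectrum:
    """Analytic input impedance of the model at the given frequencies.

    Z(f) = Raw + j*2*pi*f*Iaw + Rve / (1 + j*2*pi*f*tau_ve) + 1/(j*2*pi*f*Crs),
    combined in parallel with the shunt branch Zsh = 1/(j*2*pi*f*Cshunt)
    when Cshunt > 0.  The elastance term contributes only reactance, so with
    Iaw = Cshunt = 0 the real part is non-increasing in frequency, falling
    from Raw + Rve toward Raw.

    Raises
    ------
    ValueError
        If any frequency is non-positive.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive")
    w = 2.0 * np.pi * f
    z = (
        model.Raw
        + 1j * w * model.Iaw
        + model.Rve / (1.0 + 1j * w * model.tau_ve)
        + 1.0 / (1j * w * model.Crs)
    )
    if model.Cshunt > 0:
        zsh = 1.0 / (1j * w * model.Cshunt)
        z = z * zsh / (z + zsh)
    return ImpedanceSpectrum(frequencies=f, Z=z)


def resistance_at(model: LungModel, f: float) -> float:
    """Re Z(f), kPa*s/L, at a single positive frequency f (Hz)."""
    return float(impedance(model, [f]).Z.real[0])


def _decay_matrix(model: LungModel) -> np.ndarray:
    """State matrix of the passive expiratory decay, states (P_el, P_ve)."""
    k = 1.0 / model.Raw
    return np.array(
        [
            [-k / model.Crs, k / model.Crs],
            [model.Rve * k / model.tau_ve, -(model.Rve * k + 1.0) / model.tau_ve],
        ]
    )


def free_expiration_flow(model: LungModel, P0: float, t_grid) -> np.ndarray:
    """Passive expiratory flow after release of an occlusion held at P0.

    The elastic compartment starts charged to ``P0`` and the viscoelastic
    dashpot fully relaxed (P_ve(0) = 0; the occlusion is brief and flow is
    approximately zero during it).  With expiratory flow positive,

        flow      = (P_el - P_ve) / Raw
        dP_el/dt  = -flow / Crs
        dP_ve/dt  = (Rve * flow - P_ve) / tau_ve

    which is a 2-state linear system solved here in closed form by
    eigen-decomposition, so flow(0) = P0/Raw exactly and the trace is a
    biexponential that decays to zero.

    Parameters
    ----------
    model : LungModel
    P0 : float
        Occlusion (alveolar/elastic) pressure at release, kPa. Positive.
    t_grid : array-like
        Ascending times from release, s, starting at 0.

    Returns
    -------
    ndarray
        Flow in L/s on ``t_grid``.
    """
    if not P0 > 0:
        raise ValueError("P0 must be > 0")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t[0] != 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t_grid must be ascending and start at 0")

    A = _decay_matrix(model)
    x0 = np.array([P0, 0.0])
    lam, V = np.linalg.eig(A)
    # The physical system is overdamped: eigenvalues real and negative.
    # Guard against numerically complex output of eig.
    coeff = np.linalg.solve(V, x0)
    states = (V * coeff) @ np.exp(np.outer(lam, t))  # 2 x len(t)
    states = np.real(states)
    flow = (states[0] - states[1]) / model.Raw
    return flow
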