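"""Pulsatile inflow waveform, Reynolds scaling, resistive outlets, CFL.

The inflow model is a smooth periodic surrogate of a patient-averaged common
carotid artery (CCA) flow waveform: a truncated Fourier series of a
periodized von Mises pulse, peaking at the systolic phase (default
``t/T = 0.15``) with a diastolic plateau.  Because all cosine coefficients
about the peak are positive, the series attains its maximum exactly at the
peak phase and its period mean is the constant term, so calibration to a
target peak and mean Reynolds number is closed-form and idempotent.

Outlets are purely resistive (degenerate Windkessel), ``dp = R * Q``, with
the vascular resistances treated as given constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ive


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: kinematic viscosity ``nu`` (m^2/s), density ``rho``
    (kg/m^3).  Dynamic viscosity ``mu = rho * nu`` (Pa s) by definition.

    The density of the blood-analog fluid is configurable (default
    1050 kg/m^3, whole blood); every wall-shear output records the
    ``(rho, nu)`` pair used.
    """

    nu: float = 6.95e-7
    rho: float = 1050.0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("kinematic viscosity nu must be positive")
        if self.rho <= 0:
            raise ValueError("density rho must be positive")

    @property
    def mu(self) -> float:
        return self.rho * self.nu


#: Blood-analog working fluid used throughout: nu = 6.95e-7 m^2/s.
BLOOD_ANALOG = FluidProperties()


def reynolds(U: float, D: float, nu: float) -> float:
    """Inlet Reynolds number ``Re = U * D / nu``."""
    if D <= 0 or nu <= 0:
        raise ValueError("D and nu must be positive")
    return U * D / nu


@dataclass
class InflowWaveform:
    """Spatial-mean CCA inlet velocity ``U(t)``, periodic with period ``T``.

    ``U(t) = c0 + c1 * sum_k w_k cos(2 pi k (t - t_peak) / T)`` with
    von Mises weights ``w_k = I_k(kappa) / I_1(kappa)`` for ``k = 1..n``.
    """

    T: float
    c0: float
    c1: float
    weights: np.ndarray
    t_peak: float
    target_peak_Re: float | None = None
    target_mean_Re: float | None = None
    D: float | None = None
    nu: float | None = None
    metadata: dict = field(default_factory=dict)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        theta = 2.0 * np.pi * (t - self.t_peak) / self.T
        k = np.arange(1, len(self.weights) + 1)
        s = np.tensordot(self.weights, np.cos(np.multiply.outer(k, theta)), axes=(0, 0))
        return self.c0 + self.c1 * s

    @property
    def mean_velocity(self) -> float:
        """Exact period mean of U(t) (the constant Fourier term)."""
        return self.c0

    @property
    def peak_velocity(self) -> float:
        """Exact maximum of U(t), attained at t_peak."""
        return self.c0 + self.c1 * float(np.sum(self.weights))

    def reynolds_trace(self, t, D: float | None = None, nu: float | None = None):
        D = self.D if D is None else D
        nu = self.nu if nu is None else nu
        if D is None or nu is None:
            raise ValueError("diameter and viscosity required for Re(t)")
        return self(t) * D / nu

    def fourier_modes(self, n_max: int | None = None):
        """Complex mean-velocity Fourier coefficients ``Utilde_k`` such that
        ``U(t) = Re{ sum_k Utilde_k exp(i 2 pi k t / T) }`` (k >= 0)."""
        n = len(self.weights) if n_max is None else min(n_max, len(self.weights))
        modes = np.zeros(n + 1, dtype=complex)
        modes[0] = self.c0
        k = np.arange(1, n + 1)
        modes[1:] = self.c1 * self.weights[:n] * np.exp(-2j * np.pi * k * self.t_peak / self.T)
        return modes

    def to_csv(self, path, n: int = 1000) -> None:
        t = np.arange(n) * (self.T / n)
        np.savetxt(path, np.column_stack([t, self(t)]), delimiter=",",
                   header="t_seconds,U_m_per_s", comments="")


def make_waveform(T: float = 1.0, peak_Re: float = 1530.0, mean_Re: float = 385.0,
                  D: float = 6.5e-3, fluid: FluidProperties = BLOOD_ANALOG,
                  n_harmonics: int = 8, peak_phase: float = 0.15,
                  kappa: float = 10.0) -> InflowWaveform:
    """Build the calibrated pulsatile inflow surrogate.

    Parameters
    ----------
    T : period (s); peak_Re, mean_Re : target peak / period-mean Reynolds
    numbers; D : inlet diameter (m); n_harmonics : Fourier truncation;
    peak_phase : systolic peak location in ``t/T``; kappa : von Mises
    concentration (larger = narrower systolic pulse).

    The calibration is affine and exact: ``max_t Re(t) = peak_Re`` and
    ``mean_t Re(t) = mean_Re`` to machine precision.
    """
    if not peak_Re > mean_Re > 0:
        raise ValueError("need peak_Re > mean_Re > 0 for a calibratable waveform")
    if T <= 0 or D <= 0:
        raise ValueError("T and D must be positive")
    k = np.arange(1, n_harmonics + 1)
    # ive = exp(-kappa) * iv: ratios are stable for large kappa
    weights = ive(k, kappa) / ive(1, kappa)
    s_max = float(np.sum(weights))  # value of the pulse series at the peak
    U_mean = mean_Re * fluid.nu / D
    U_peak = peak_Re * fluid.nu / D
    c0 = U_mean
    c1 = (U_peak - U_mean) / s_max
    wf = InflowWaveform(T=T, c0=c0, c1=c1, weights=weights, t_peak=peak_phase * T,
                        target_peak_Re=peak_Re, target_mean_Re=mean_Re, D=D,
                        nu=fluid.nu,
                        metadata={"n_harmonics": n_harmonics, "kappa": kappa,
                                  "peak_phase": peak_phase})
    # reference waveform must not reverse at the inlet
    tt = np.linspace(0.0, T, 4001)
    if np.min(wf(tt)) <= 0:
        raise ValueError("calibrated waveform reverses; decrease kappa or the "
                         "peak/mean Reynolds ratio")
    return wf


def waveform_from_samples(t: np.ndarray, U: np.ndarray, T: float | None = None):
    """Periodic interpolant through a user-supplied digitized waveform
    (2-column ``t, U``), for exact replication when the measured trace is
    available.  Returns a callable ``U(t)``."""
    t = np.asarray(t, dtype=float)
    U = np.asarray(U, dtype=float)
    if T is None:
        T = t[-1] - t[0] + (t[1] - t[0])
    from scipy.interpolate import CubicSpline

    tt = np.concatenate([t, [t[0] + T]])
    UU = np.concatenate([U, [U[0]]])
    cs = CubicSpline(tt, UU, bc_type="periodic")
    return lambda x: cs(np.asarray(x, dtype=float) % T + t[0])


@dataclass(frozen=True)
class ResistiveOutlet:
    """Resistive outlet boundary: pressure drop ``dp = R * Q``."""

    R: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("vascular resistance R must be non-negative")

    def pressure_drop(self, Q) -> np.ndarray:
        return self.R * np.asarray(Q, dtype=float)


#: Vascular resistances used for both geometries (Pa s / m^3).
ICA_OUTLET = ResistiveOutlet(R=1.5e6, label="ICA")
ECA_OUTLET = ResistiveOutlet(R=11e6, label="ECA")


def outlet_pressure(outlet: ResistiveOutlet, Q) -> np.ndarray:
    """Pressure drop over a resistive outlet, ``dp = R * Q`` (Pa)."""
    return outlet.pressure_drop(Q)


def flow_split(Q_cca, Q_ica):
    """ECA outflow by continuity: ``Q_eca = Q_cca - Q_ica``."""
    Q_cca = np.asarray(Q_cca, dtype=float)
    Q_ica = np.asarray(Q_ica, dtype=float)
    if np.any(Q_ica < 0) or np.any(Q_ica > Q_cca):
        raise ValueError("continuity violation: require 0 <= Q_ica <= Q_cca")
    return Q_cca - Q_ica


def cfl_number(u_max: float, dt: float, h: float) -> float:
    """Courant-Friedrichs-Lewy number ``u_max * dt / h``."""
    if h <= 0 or dt <= 0:
        raise ValueError("h and dt must be positive")
    return u_max * dt / h


def max_timestep(u_max: float, h: float, target_cfl: float = 1.0) -> float:
    """Largest time step keeping the CFL number below ``target_cfl``."""
    if h <= 0 or target_cfl <= 0:
        raise ValueError("h and target_cfl must be positive")
    if u_max <= 0:
        return np.inf
    return target_cfl * h / u_max
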