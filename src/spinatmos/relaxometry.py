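"""NV longitudinal relaxation model, two-point contrast, and assay arithmetic.

GHz-band magnetic noise with variance <Bperp^2> transverse to the NV axis and
Lorentzian spectrum shortens the NV longitudinal relaxation time:

    Gamma_1 = 1/T1 = 1/T1_int + 3 gamma_e^2 <Bperp^2> tau_c / (1 + omega0^2 tau_c^2)

where omega0 = 2 pi D samples the noise at the NV zero-field splitting
D = 2.87 GHz and tau_c is the autocorrelation decay time of the fluctuating
field (set by the paramagnetic-ion spin dynamics).  The spectral factor
tau_c/(1 + omega0^2 tau_c^2) peaks at tau_c = 1/omega0 ~ 55 ps.

The fluorescence decay is modelled as a single exponential with constant
baseline, F(tau) = 1 + A exp(-Gamma_1 tau); shallow NV ensembles are often
better described by stretched exponentials, but the single-exponential form
is invertible and sufficient for the two-point contrast proxy
C = F(tau1)/F(tau2) used here (tau1 = 10 us, tau2 = 400 us).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import GAMMA_E, NV_ZERO_FIELD_SPLITTING_HZ

__all__ = [
    "RelaxometryParams",
    "ContrastMeasurement",
    "spectral_factor",
    "gamma1",
    "decay_signal",
    "two_point_contrast",
    "temperature_correct",
    "lod_amount",
    "sensitivity_molecules",
]


@dataclass(frozen=True)
class RelaxometryParams:
    """Parameters of the relaxation-rate model (SI units)."""

    T1_int: float = 1e-3  # s, intrinsic relaxation time
    tau_c: float = 1e-10  # s, field autocorrelation time
    D: float = NV_ZERO_FIELD_SPLITTING_HZ  # Hz
    gamma_e: float = GAMMA_E  # rad s^-1 T^-1

    def __post_init__(self) -> None:
        if min(self.T1_int, self.tau_c, self.D, self.gamma_e) <= 0:
            raise ValueError("all relaxometry parameters must be positive")

    @property
    def omega0(self) -> float:
        """Angular sampling frequency, exactly 2 pi D (rad/s)."""
        return 2.0 * math.pi * self.D


@dataclass(frozen=True)
class ContrastMeasurement:
    """A two-point spin-contrast reading with its temperature."""

    C: float
    temperature: float = 25.0  # deg C
    tau1: float = 1e-5  # s
    tau2: float = 4e-4  # s

    def __post_init__(self) -> None:
        if self.tau1 >= self.tau2:
            raise ValueError("tau1 must be shorter than tau2")
        if self.C <= 0:
            raise ValueError("contrast must be positive")


def spectral_factor(tau_c, omega0: float):
    """Lorentzian spectral factor tau_c / (1 + omega0^2 tau_c^2), in seconds.

    Maximised at tau_c = 1/omega0, where it equals 1/(2 omega0).
    """
    tau_c = np.asarray(tau_c, dtype=float)
    if np.any(tau_c <= 0):
        raise ValueError("tau_c must be positive")
    out = tau_c / (1.0 + (omega0 * tau_c) ** 2)
    return float(out) if out.ndim == 0 else out


def gamma1(bperp2, params: RelaxometryParams):
    """Longitudinal relaxation rate Gamma_1 (s^-1) for noise variance bperp2 (T^2)."""
    bperp2 = np.asarray(bperp2, dtype=float)
    if np.any(bperp2 < 0):
        raise ValueError("bperp2 must be non-negative")
    out = (1.0 / params.T1_int
           + 3.0 * params.gamma_e**2 * bperp2 * spectral_factor(params.tau_c, params.omega0))
    return float(out) if out.ndim == 0 else out


def decay_signal(gamma_1: float, amplitude: float, tau):
    """Normalised fluorescence F(tau) = 1 + A exp(-Gamma_1 tau)."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    tau = np.asarray(tau, dtype=float)
    out = 1.0 + amplitude * np.exp(-gamma_1 * tau)
    return float(out) if out.ndim == 0 else out


def two_point_contrast(gamma_1: float, amplitude: float,
                       tau1: float = 1e-5, tau2: float = 4e-4) -> float:
    """Spin contrast C = F(tau1)/F(tau2) from two single-point readings."""
    if tau1 >= tau2:
        raise ValueError("tau1 must be shorter than tau2")
    return float(decay_signal(gamma_1, amplitude, tau1)
                 / decay_signal(gamma_1, amplitude, tau2))


def temperature_correct(C: float, temperature: float, slope: float = 0.0012,
                        T_ref: float = 25.0) -> float:
    """Refer a contrast reading to T_ref: C* = C - (T - T_ref) * dC/dT."""
    return C - (temperature - T_ref) * slope


def lod_amount(concentration: float, volume_mm3: float) -> float:
    """Amount (attomoles) of analyte at ``concentration`` (mol/L) in a channel
    of ``volume_mm3`` (mm^3).  1 mm^3 = 1e-6 L; 1 mol = 1e18 amol."""
    if concentration < 0 or volume_mm3 <= 0:
        raise ValueError("concentration must be >= 0 and volume positive")
    return concentration * volume_mm3 * 1e-6 * 1e18


def sensitivity_molecules(threshold_ions: int = 180, ions_per_molecule: int = 8) -> int:
    """Molecules needed to supply ``threshold_ions`` adsorbed paramagnetic ions.

    A fractional molecule cannot adsorb, so the ratio is rounded up.
    """
    if ions_per_molecule <= 0:
        raise ValueError("ions_per_molecule must be positive")
    return math.ceil(threshold_ions / ions_per_molecule)
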