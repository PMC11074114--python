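"""Dipolar magnetic-noise estimation at a buried NV site.

A paramagnetic ion of spin S at distance r from the NV centre contributes a
randomly oriented magnetic dipole field.  Averaging over the ion's spin
states, the variance of the k-th Cartesian field component produced by a set
of ions is

    <B_k^2> = C_S * sum_I (1 + 3 khat_I^2) / r_I^6,
    C_S = S(S+1)/3 * (mu0/(4 pi) * gamma_e * hbar)^2,

with r_I in nm, khat_I = k_I / r_I the direction cosine, and C_S in nm^6 T^2
(C_S = 1.00574e-5 nm^6 T^2 for Mn2+, S = 5/2).  For NV ensembles under a
{100} surface, averaging over the four NV orientations gives the transverse
variance <Bperp^2> = 2/3 (<Bx^2> + <By^2> + <Bz^2>).

Summing the direction factors, a single ion satisfies
<Bx^2>+<By^2>+<Bz^2> = 6 C_S / r^6 and <Bperp^2> = 4 C_S / r^6 regardless of
direction, so a uniform ion density rho filling the half space at distance d
from the NV yields the closed form <Bperp^2> = (2 pi / 3) C_S rho / d^3 —
used throughout the tests as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import GAMMA_E, HBAR, MU0, NM_PER_M
from .trajectory import Frame, SlabGeometry, Trajectory, min_image_shift

__all__ = [
    "SpinSpecies",
    "NVSite",
    "NoiseEstimate",
    "spin_prefactor",
    "frame_field_variance",
    "transverse_variance",
    "trajectory_noise",
    "noise_vs_distance",
    "coverage_extrapolation",
    "autocorrelation_tau_c",
    "MIN_ION_NV_DISTANCE",
]

#: sanity guard (nm): an ion closer than this to the NV indicates a corrupt
#: frame (the NV sits >= several nm inside the diamond lattice)
MIN_ION_NV_DISTANCE = 0.3


def spin_prefactor(S: float) -> float:
    """Dipolar variance prefactor C_S in nm^6 T^2 for spin quantum number S.

    C_S = S(S+1)/3 * (mu0/(4 pi) gamma_e hbar)^2; 1.00574e-5 nm^6 T^2 for
    S = 5/2 (Mn2+).
    """
    if S < 0:
        raise ValueError("spin quantum number must be >= 0")
    if abs(2 * S - round(2 * S)) > 1e-9:
        raise ValueError(f"spin quantum number must be half-integer, got {S}")
    moment = MU0 / (4 * math.pi) * GAMMA_E * HBAR  # T m^3
    return S * (S + 1) / 3.0 * (moment * NM_PER_M**3) ** 2  # -> nm^6 T^2


@dataclass(frozen=True)
class SpinSpecies:
    """A paramagnetic (or S=0 diamagnetic) ionic species."""

    label: str
    S: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "_C_S", spin_prefactor(self.S))

    @property
    def C_S(self) -> float:
        """Cached dipolar prefactor, nm^6 T^2."""
        return self._C_S


#: Mn2+ has a half-filled 3d shell, S = 5/2
MN2P = SpinSpecies("Mn", 2.5)


@dataclass(frozen=True)
class NVSite:
    """An NV centre buried below one of the slab surfaces."""

    position: tuple[float, float, float]  # nm
    depth: float = 7.0  # nm below the surface zero plane
    surface_tag: str = "{100}"

    @classmethod
    def below_surface(cls, geometry: SlabGeometry, side: str = "bottom",
                      lateral: tuple[float, float] = (0.0, 0.0),
                      depth: float = 7.0) -> "NVSite":
        """Place the NV ``depth`` nm inside the slab on the chosen side."""
        if side == "bottom":
            z = geometry.bottom_zero - depth
        elif side == "top":
            z = geometry.top_zero + depth
        else:
            raise ValueError(f"side must be 'bottom' or 'top', got {side!r}")
        return cls(position=(lateral[0], lateral[1], z), depth=depth)


@dataclass
class NoiseEstimate:
    """Frame-averaged field variances at an NV site (all in T^2)."""

    bx2: float
    by2: float
    bz2: float
    bperp2: float
    n_frames: int
    bperp2_std: float  # std across frames
    series: pd.DataFrame | None = field(default=None, repr=False)


def _species_prefactors(frame: Frame, species_map: dict) -> np.ndarray:
    """Per-atom C_S values; 0 for diamagnetic species."""
    cache: dict[str, float] = {}
    out = np.empty(frame.n_atoms)
    for i, lab in enumerate(frame.species):
        if lab not in cache:
            sp = species_map.get(lab)
            if sp is None:
                raise KeyError(f"species {lab!r} missing from species_map")
            if sp == "diamagnetic":
                cache[lab] = 0.0
            elif isinstance(sp, SpinSpecies):
                cache[lab] = sp.C_S
            else:
                cache[lab] = spin_prefactor(float(sp))
        out[i] = cache[lab]
    return out


def frame_field_variance(frame: Frame, nv: NVSite, species_map: dict,
                         periodic: bool = True,
                         guard: float = MIN_ION_NV_DISTANCE) -> tuple[float, float, float]:
    """Per-component dipolar field variances (Bx2, By2, Bz2) for one frame.

    Ion–NV displacements use the minimum-image convention in x/y only (the
    slab has no z periodicity).  Species with S=0 contribute nothing.
    """
    cs = _species_prefactors(frame, species_map)
    para = cs > 0
    if not para.any():
        return (0.0, 0.0, 0.0)
    d = frame.xyz[para] - np.asarray(nv.position)
    if periodic:
        d[:, :2] = min_image_shift(d[:, :2], frame.box[:2])
    r2 = np.einsum("ij,ij->i", d, d)
    bad = r2 < guard * guard
    if bad.any():
        ids = frame.ids[para][bad]
        raise ValueError(
            f"ion(s) {ids.tolist()} within guard distance {guard} nm of the NV "
            f"(min r = {math.sqrt(r2.min()):.3f} nm); corrupt frame?")
    inv_r6 = r2 ** -3
    khat2 = d * d / r2[:, None]  # (N, 3) direction cosines squared
    w = cs[para] * inv_r6
    comps = (w[:, None] * (1.0 + 3.0 * khat2)).sum(axis=0)
    return (float(comps[0]), float(comps[1]), float(comps[2]))


def transverse_variance(components: Sequence[float]) -> float:
    """<Bperp^2> = 2/3 (Bx2 + By2 + Bz2), the {100} orientation average."""
    bx2, by2, bz2 = components
    if min(bx2, by2, bz2) < 0:
        raise ValueError("variances must be non-negative")
    return 2.0 / 3.0 * (bx2 + by2 + bz2)


def trajectory_noise(traj: Trajectory, nv: NVSite, periodic: bool = True,
                     keep_series: bool = True) -> NoiseEstimate:
    """Average the per-frame field variances over a trajectory."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    rows = np.empty((traj.n_frames, 3))
    for i, f in enumerate(traj.frames):
        rows[i] = frame_field_variance(f, nv, traj.species_map, periodic=periodic)
    bperp = 2.0 / 3.0 * rows.sum(axis=1)
    series = None
    if keep_series:
        series = pd.DataFrame(
            {"time": traj.times, "bx2": rows[:, 0], "by2": rows[:, 1],
             "bz2": rows[:, 2], "bperp2": bperp})
    mean = rows.mean(axis=0)
    return NoiseEstimate(
        bx2=float(mean[0]), by2=float(mean[1]), bz2=float(mean[2]),
        bperp2=float(bperp.mean()), n_frames=traj.n_frames,
        bperp2_std=float(bperp.std(ddof=0)), series=series)


def noise_vs_distance(ensemble: Sequence[tuple[Trajectory, dict]],
                      geometry: SlabGeometry, side: str = "bottom",
                      depth: float = 7.0, periodic: bool = True) -> pd.DataFrame:
    """Per-replica (molecule COM distance, <Bperp^2>) table.

    Each ensemble member is a (trajectory, selection) pair; the selection is a
    dict of keyword arguments for :meth:`Frame.select` identifying the
    molecule (e.g. ``{"species": "P"}``).  The NV is placed ``depth`` nm below
    the chosen surface, laterally aligned with the molecule's mean centre of
    mass, mirroring an NV under a molecule-covered surface.
    """
    rows = []
    for k, (traj, sel) in enumerate(ensemble):
        if not sel:
            raise ValueError(f"replica {k}: missing molecule selection")
        coms = []
        for f in traj.frames:
            mask = f.select(**sel)
            if not mask.any():
                raise ValueError(f"replica {k}: molecule selection matched no atoms")
            coms.append(f.xyz[mask].mean(axis=0))
        com = np.mean(coms, axis=0)
        dist = (com[2] - geometry.bottom_zero) if side == "bottom" else (geometry.top_zero - com[2])
        nv = NVSite.below_surface(geometry, side=side, lateral=(com[0], com[1]), depth=depth)
        est = trajectory_noise(traj, nv, periodic=periodic, keep_series=False)
        rows.append({"replica": k, "com_distance": float(dist), "bperp2": est.bperp2,
                     "bperp2_std": est.bperp2_std})
    return pd.DataFrame(rows)


def coverage_extrapolation(per_molecule_delta: float, footprint_area: float,
                           nv_depth: float = 7.0, cutoff: float | None = None,
                           cluster_height: float = 0.5) -> float:
    """Extrapolate a single molecule's noise increment to full surface coverage.

    The adsorbed molecule's excess-ion cloud is represented as an effective
    point cluster at ``cluster_height`` above the surface; a 2D square lattice
    of such clusters with pitch sqrt(footprint_area) tiles the surface, and
    the r^-6 single-cluster transverse variance is summed over all lattice
    images out to ``cutoff`` (default 20x pitch; the sum converges as r^-6).
    """
    if footprint_area <= 0:
        raise ValueError("footprint_area must be positive")
    pitch = math.sqrt(footprint_area)
    if cutoff is None:
        cutoff = 20.0 * pitch
    n_img = max(1, int(math.ceil(cutoff / pitch)))
    r0_sq = (nv_depth + cluster_height) ** 2
    i = np.arange(-n_img, n_img + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    s2 = (ii.astype(float) ** 2 + jj.astype(float) ** 2) * pitch**2
    lattice_sum = float(((r0_sq / (r0_sq + s2)) ** 3).sum())
    return per_molecule_delta * lattice_sum


def _acf_biased(x: np.ndarray) -> np.ndarray:
    """Biased (1/N) autocovariance of a mean-removed series, via FFT."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    return acov / n


def autocorrelation_tau_c(series: np.ndarray, dt: float,
                          lag_window_factor: float = 5.0) -> tuple[float, float, dict]:
    """Fit <B(t)B(t+tau)> = <B^2> exp(-tau/tau_c) to a scalar time series.

    Returns (fitted variance, tau_c in the units of ``dt``, diagnostics).
    The empirical autocovariance uses the biased 1/N normalisation; the fit
    window is ``lag_window_factor`` times an initial 1/e-crossing estimate of
    tau_c and is refit once with the updated window.  Degenerate inputs are
    flagged in the diagnostics instead of returning silent NaNs.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("series must be 1-D with at least 4 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    fluct = x - x.mean()
    var0 = float(np.mean(fluct**2))
    diag: dict = {"flags": []}
    if var0 == 0.0:
        diag["flags"].append("constant_series")
        return (0.0, float("nan"), diag)
    acov = _acf_biased(fluct)
    rho = acov / acov[0]
    below = np.nonzero(rho < 1.0 / math.e)[0]
    k_e = int(below[0]) if below.size else len(rho) // 2
    if k_e <= 1:
        # decorrelated within one sample: tau_c unresolved at this dt
        diag["flags"].append("tau_c_below_dt")
        return (var0, dt, diag)

    def _fit(k_max: int):
        k_max = int(min(max(k_max, 3), len(rho) - 1))
        lags = np.arange(k_max + 1) * dt
        y = acov[: k_max + 1]
        p0 = (var0, k_e * dt)
        popt, pcov = curve_fit(lambda t, a, tc: a * np.exp(-t / tc), lags, y,
                               p0=p0, maxfev=10000)
        resid = y - popt[0] * np.exp(-lags / popt[1])
        return popt, float(np.sqrt(np.mean(resid**2))), k_max

    try:
        popt, rms, kw = _fit(int(lag_window_factor * k_e))
        popt, rms, kw = _fit(int(lag_window_factor * popt[1] / dt))
    except RuntimeError as exc:
        raise RuntimeError(f"autocorrelation fit failed: {exc}") from exc
    diag.update(fit_window_lags=kw, rms_residual=rms, one_over_e_lag=k_e)
    return (float(popt[0]), float(abs(popt[1])), diag)
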