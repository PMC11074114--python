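"""Ion-atmosphere analysis along the slab normal.

Time-averaged z density profiles per species, region-integrated ion numbers
(with standard deviations across frames), the excess accumulation of
paramagnetic counterions on the adsorption side relative to the bare surface
on the opposite side, and adsorption-event detection for the polyanion.

Conventions: z is measured from the surface zero plane of the slab involved
in adsorption (the bottom surface by default, and for non-adsorbed replicas).
The operational adsorption criterion — minimum bead-surface distance staying
below ``contact_cutoff`` continuously for at least ``persistence`` — is a
declared convention of this package; the defaults (0.35 nm, 1 ns) correspond
to a first-solvation-shell contact held long enough to exclude grazing
encounters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory import SlabGeometry, Trajectory

__all__ = [
    "DensityProfile",
    "RegionCounts",
    "AdsorptionRecord",
    "AdsorptionStatistics",
    "ExcessEstimate",
    "z_density_profile",
    "integrate_regions",
    "excess_accumulation",
    "detect_adsorption",
    "adsorption_statistics",
]


@dataclass
class DensityProfile:
    """Binned z-profile: per-species number density (nm^-3) vs distance."""

    bin_edges: np.ndarray  # nm, uniform, measured from the origin surface
    density: dict  # label -> (n_bins,) mean density nm^-3
    counts_per_frame: dict  # label -> (n_frames, n_bins) raw counts
    n_frames: int
    area_nm2: float  # Lx * Ly

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def integral(self, label: str) -> float:
        """Mean number of ions of ``label`` in the profiled slab (conservation check)."""
        return float(self.density[label].sum() * self.area_nm2 * self.bin_width)


@dataclass
class RegionCounts:
    """Mean ion number and across-frame std per z region, per species."""

    regions: tuple  # of (z_lo, z_hi) nm
    mean: dict  # label -> (n_regions,)
    std: dict  # label -> (n_regions,)
    n_frames: int


@dataclass
class ExcessEstimate:
    """Region-difference ion count with its standard error."""

    mean: float
    std_err: float
    n_frames: int


@dataclass
class AdsorptionRecord:
    """Outcome of adsorption detection for one replica."""

    replica_id: int
    adsorbed: bool
    onset_ns: float | None
    side: str | None
    min_distance_ns: np.ndarray  # times
    min_distance_nm: np.ndarray  # min bead-surface distance series


@dataclass
class AdsorptionStatistics:
    fraction: float
    fraction_std: float  # binomial
    n_replicas: int
    n_adsorbed: int
    onset_quartiles_ns: tuple | None  # (q25, q50, q75) over adsorbed replicas


def z_density_profile(traj: Trajectory, species: str | Sequence[str],
                      geometry: SlabGeometry, bin_width: float = 0.1,
                      origin_side: str = "bottom") -> DensityProfile:
    """Time-averaged number-density histogram along z for the given species.

    The histogram spans the solution region between the two zero planes;
    densities are counts / (Lx * Ly * bin_width), averaged over frames.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    labels = [species] if isinstance(species, str) else list(species)
    extent = geometry.extent
    n_bins = int(round(extent / bin_width))
    if n_bins < 1 or abs(n_bins * bin_width - extent) > bin_width:
        raise ValueError(
            f"bin_width {bin_width} does not divide the slab extent {extent} "
            "to within one bin")
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    box = traj.frames[0].box
    area = box[0] * box[1]
    counts = {lab: np.zeros((traj.n_frames, n_bins)) for lab in labels}
    for i, f in enumerate(traj.frames):
        if origin_side == "bottom":
            z = f.xyz[:, 2] - geometry.bottom_zero
        else:
            z = geometry.top_zero - f.xyz[:, 2]
        for lab in labels:
            mask = f.select(species=lab)
            if i == 0 and not mask.any():
                raise ValueError(f"species {lab!r} absent from trajectory")
            counts[lab][i], _ = np.histogram(z[mask], bins=edges)
    density = {lab: counts[lab].mean(axis=0) / (area * bin_width) for lab in labels}
    return DensityProfile(bin_edges=edges, density=density, counts_per_frame=counts,
                          n_frames=traj.n_frames, area_nm2=area)


def integrate_regions(profile: DensityProfile,
                      regions: Sequence[tuple[float, float]]) -> RegionCounts:
    """Mean ion number per region (partial bins split pro-rata) with std across frames."""
    edges = profile.bin_edges
    lo, hi = edges[0], edges[-1]
    regs = tuple((float(a), float(b)) for a, b in regions)
    prev_hi = -math.inf
    for a, b in regs:
        if a >= b:
            raise ValueError(f"empty region ({a}, {b})")
        if a < lo - 1e-9 or b > hi + 1e-9:
            raise ValueError(f"region ({a}, {b}) outside profile support [{lo}, {hi}]")
        if a < prev_hi:
            raise ValueError("regions must be non-overlapping and ordered")
        prev_hi = b
    # per-bin overlap weights for each region
    w = np.zeros((len(regs), len(edges) - 1))
    for r, (a, b) in enumerate(regs):
        left = np.clip(a, edges[:-1], edges[1:])
        right = np.clip(b, edges[:-1], edges[1:])
        w[r] = np.maximum(right - left, 0.0) / np.diff(edges)
    mean, std = {}, {}
    for lab, cpf in profile.counts_per_frame.items():
        per_frame = cpf @ w.T  # (n_frames, n_regions)
        mean[lab] = per_frame.mean(axis=0)
        std[lab] = per_frame.std(axis=0, ddof=0)
    return RegionCounts(regions=regs, mean=mean, std=std, n_frames=profile.n_frames)


def excess_accumulation(counts: RegionCounts, adsorption_region_idx: int,
                        reference_region_idx: int, species: str = "Mn") -> ExcessEstimate:
    """Excess ion number in the adsorption region relative to the reference.

    Both regions must have equal width, otherwise the comparison is invalid.
    The uncertainty is the standard error of the mean difference under the
    independent-frames assumption.
    """
    a = counts.regions[adsorption_region_idx]
    b = counts.regions[reference_region_idx]
    if abs((a[1] - a[0]) - (b[1] - b[0])) > 1e-9:
        raise ValueError(f"regions {a} and {b} have unequal widths; excess undefined")
    diff = counts.mean[species][adsorption_region_idx] - counts.mean[species][reference_region_idx]
    s = math.hypot(counts.std[species][adsorption_region_idx],
                   counts.std[species][reference_region_idx])
    return ExcessEstimate(mean=float(diff), std_err=s / math.sqrt(counts.n_frames),
                          n_frames=counts.n_frames)


def _first_persistent_run(below: np.ndarray, n_persist: int) -> int | None:
    """Index of the first frame opening a run of >= n_persist True values."""
    run = 0
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= n_persist:
            return i - n_persist + 1
    return None


def detect_adsorption(traj: Trajectory, selection: dict, geometry: SlabGeometry,
                      contact_cutoff: float = 0.35, persistence: float = 1.0,
                      replica_id: int = 0) -> AdsorptionRecord:
    """Classify a replica as adsorbed using the contact + persistence rule.

    Adsorbed iff the molecule's minimum atom-surface distance stays below
    ``contact_cutoff`` continuously for at least ``persistence`` (ns) on
    either surface; the onset is the first instant of that window and the
    side is the surface achieving it.  Excursions above the cutoff shorter
    than ``persistence`` before a later persistent window are ignored.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    if persistence < traj.dt:
        raise ValueError("persistence must be at least one frame interval")
    d_bot = np.empty(traj.n_frames)
    d_top = np.empty(traj.n_frames)
    for i, f in enumerate(traj.frames):
        mask = f.select(**selection)
        if not mask.any():
            raise ValueError("molecule selection matched no atoms")
        z = f.xyz[mask, 2]
        d_bot[i] = z.min() - geometry.bottom_zero
        d_top[i] = geometry.top_zero - z.max()
    n_persist = max(1, int(math.ceil(persistence / traj.dt)))
    times = traj.times
    best: tuple[float, str] | None = None
    for side, d in (("bottom", d_bot), ("top", d_top)):
        i0 = _first_persistent_run(d < contact_cutoff, n_persist)
        if i0 is not None and (best is None or times[i0] < best[0]):
            best = (float(times[i0]), side)
    min_d = np.minimum(d_bot, d_top)
    if best is None:
        return AdsorptionRecord(replica_id, False, None, None, times, min_d)
    return AdsorptionRecord(replica_id, True, best[0], best[1], times, min_d)


def adsorption_statistics(records: Sequence[AdsorptionRecord]) -> AdsorptionStatistics:
    """Fraction adsorbed (with binomial std) and onset-time quartiles."""
    if not records:
        raise ValueError("need at least one adsorption record")
    n = len(records)
    onsets = [r.onset_ns for r in records if r.adsorbed]
    k = len(onsets)
    p = k / n
    quartiles = tuple(np.percentile(onsets, [25, 50, 75])) if onsets else None
    return AdsorptionStatistics(fraction=p, fraction_std=math.sqrt(p * (1 - p) / n),
                                n_replicas=n, n_adsorbed=k,
                                onset_quartiles_ns=quartiles)
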