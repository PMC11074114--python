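"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here without any
external data: an Ornstein-Uhlenbeck magnetic-field generator (exponential
autocorrelation, Lorentzian spectrum), Poisson samplers of static ion
configurations with closed-form noise answers, planted-truth accumulation
fixtures, a functional-group surface model, and an overdamped Brownian-
dynamics (BD) surrogate of a polyanion plus its ion atmosphere between two
functionalized slabs.

The BD surrogate deliberately replaces all-atom replica-exchange MD: there is
no explicit water, no atomistic force field and no replica exchange.  Ions
and chain beads interact through screened-Coulomb (Debye-Huckel/Yukawa)
pair potentials consistent with the mean-field electrolyte module, soft-core
excluded volume, harmonic chain bonds, and a short-range attraction well at
each surface standing in for the adsorption chemistry.  It exists to exercise
the analysis stages on data with planted, recoverable truth — not to
re-derive all-atom observables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .atmosphere import AdsorptionRecord, detect_adsorption
from .constants import AVOGADRO, E_CHARGE, EPS0, KB, molar_to_per_nm3
from .dipolar import MN2P, SpinSpecies
from .electrolyte import ChargedPlane, ElectrolyteComposition, IonBudget, box_ion_budget, debye_length
from .trajectory import Frame, SlabGeometry, Trajectory, min_image_shift

__all__ = [
    "OUFieldParams",
    "generate_ou_field",
    "sample_static_ions",
    "SurrogateSystem",
    "SurfaceSiteMap",
    "build_surface_model",
    "plant_accumulation",
    "BDResult",
    "run_brownian_dynamics",
    "DEFAULT_SURFACE_FRACTIONS",
    "bjerrum_length",
]

#: XPS-derived area fractions of oxygen functional groups on the oxygenated
#: {100} diamond face
DEFAULT_SURFACE_FRACTIONS = {
    "hydroxyl/epoxy": 0.645,
    "carbonyl": 0.202,
    "ether": 0.137,
    "carboxyl": 0.016,
}

_DEFAULT_SPECIES_MAP = {"Mn": MN2P, "Na": "diamagnetic", "Cl": "diamagnetic",
                        "P": "diamagnetic"}


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck field generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OUFieldParams:
    """Parameters of a stationary OU process with <B(t)B(t+tau)> = var*exp(-|tau|/tau_c)."""

    variance: float  # T^2
    tau_c: float  # ns
    dt: float  # ns
    n_steps: int
    n_components: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.variance, self.tau_c, self.dt) <= 0 or self.n_steps < 1:
            raise ValueError("OU parameters must be positive")
        if self.n_components not in (1, 3):
            raise ValueError("n_components must be 1 or 3")


def generate_ou_field(params: OUFieldParams) -> np.ndarray:
    """Exact-discretization OU sample path, stationary from the first sample.

    x_{n+1} = x_n e^{-dt/tau_c} + sigma sqrt(1 - e^{-2 dt/tau_c}) xi_n.
    Returns shape (n_steps,) or (n_steps, 3).
    """
    rng = np.random.default_rng(params.seed)
    sigma = math.sqrt(params.variance)
    a = math.exp(-params.dt / params.tau_c)
    b = sigma * math.sqrt(1.0 - a * a)
    shape = (params.n_steps,) if params.n_components == 1 else (params.n_steps, 3)
    xi = rng.standard_normal(shape)
    out = np.empty(shape)
    out[0] = sigma * xi[0]
    for n in range(1, params.n_steps):
        out[n] = a * out[n - 1] + b * xi[n]
    return out


# ---------------------------------------------------------------------------
# static ion samplers (closed-form oracles)
# ---------------------------------------------------------------------------

def sample_static_ions(density: float, region: str = "halfspace",
                       box: Sequence[float] = (200.0, 200.0, 100.0),
                       n_frames: int = 100, seed: int = 0,
                       species: str = "Mn", dt: float = 1.0) -> Trajectory:
    """Independent frames of Poisson-count, uniformly placed ions.

    ``region="halfspace"`` fills the box above the surface zero plane at z=0
    (use a laterally large box so minimum-imaging does not truncate the
    half-space integral an oracle compares against); ``region="box"`` fills
    the whole box.  Ion counts are Poisson with mean density*volume per frame.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if region not in ("halfspace", "box"):
        raise ValueError(f"unknown region {region!r}")
    rng = np.random.default_rng(seed)
    lx, ly, lz = (float(b) for b in box)
    vol = lx * ly * lz
    frames = []
    for k in range(n_frames):
        n = rng.poisson(density * vol)
        xyz = rng.uniform(0.0, 1.0, size=(n, 3)) * np.array([lx, ly, lz])
        frames.append(Frame(time=k * dt, ids=np.arange(n),
                            species=np.array([species] * n, dtype=object),
                            xyz=xyz, box=(lx, ly, lz)))
    smap = dict(_DEFAULT_SPECIES_MAP)
    if species not in smap:
        smap[species] = MN2P if species == "Mn" else "diamagnetic"
    return Trajectory(frames=frames, dt=dt, species_map=smap)


# ---------------------------------------------------------------------------
# surface model
# ---------------------------------------------------------------------------

@dataclass
class SurfaceSiteMap:
    """Deterministic placement of functional-group labels on one slab face."""

    positions: np.ndarray  # (N, 2) nm
    labels: np.ndarray  # (N,) str
    charges: np.ndarray  # (N,) e
    area_nm2: float
    charge_state: str

    @property
    def total_charge_e(self) -> float:
        return float(self.charges.sum())

    def count(self, label: str) -> int:
        return int((self.labels == label).sum())


def _apportion(fractions: dict, n: int) -> dict:
    """Largest-remainder apportionment of n sites to the given fractions."""
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def build_surface_model(fractions: dict | None = None, area_nm2: float = 100.0,
                        charge_state: str = "protonated",
                        site_density: float = 10.0, seed: int = 0) -> SurfaceSiteMap:
    """Scatter functional-group labels on a lattice over one slab face.

    ``charge_state`` sets the carboxyl protonation: ``"protonated"`` (neutral
    surface), ``"half"`` (half the carboxyls deprotonated, rounded down) or
    ``"deprotonated"`` (every carboxyl carries -1 e).  Same seed, same map.
    """
    fractions = dict(fractions or DEFAULT_SURFACE_FRACTIONS)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total}")
    if charge_state not in ("protonated", "half", "deprotonated"):
        raise ValueError(f"unknown charge_state {charge_state!r}")
    n_sites = int(round(area_nm2 * site_density))
    counts = _apportion(fractions, n_sites)
    labels = np.array([lab for lab, c in counts.items() for _ in range(c)], dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    side = math.sqrt(area_nm2)
    m = int(math.ceil(math.sqrt(n_sites)))
    gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    grid = (np.stack([gx.ravel(), gy.ravel()], axis=1)[:n_sites] + 0.5) * (side / m)
    charges = np.zeros(n_sites)
    carb = np.nonzero(labels == "carboxyl")[0]
    if charge_state == "deprotonated":
        charges[carb] = -1.0
    elif charge_state == "half":
        charges[carb[: len(carb) // 2]] = -1.0
    return SurfaceSiteMap(positions=grid, labels=labels, charges=charges,
                          area_nm2=area_nm2, charge_state=charge_state)


# ---------------------------------------------------------------------------
# surrogate system
# ---------------------------------------------------------------------------

def bjerrum_length(temperature: float = 298.15, eps_r: float = 78.4) -> float:
    """Bjerrum length in nm (~0.7 nm in water at 298 K)."""
    return E_CHARGE**2 / (4 * math.pi * eps_r * EPS0 * KB * temperature) * 1e9


@dataclass
class SurrogateSystem:
    """Full parameterization of the BD surrogate of a slab assay cell.

    Defaults mirror the simulated study conditions: a 10 x 10 x 20 nm^3 box,
    5 mM MnCl2 + 10 mM NaCl, a 22-bead polyanion carrying -21 e, two
    identical functionalized surfaces that are neutral or negatively charged,
    and ion numbers chosen by the electrolyte bookkeeping so the cell is
    exactly electroneutral.
    """

    box: tuple[float, float, float] = (10.0, 10.0, 20.0)
    slab_margin: float = 0.5  # nm between box edge and surface zero plane
    planes: tuple[ChargedPlane, ChargedPlane] = (
        ChargedPlane(0.0, 100.0), ChargedPlane(0.0, 100.0))
    surface_fractions: dict = field(default_factory=lambda: dict(DEFAULT_SURFACE_FRACTIONS))
    composition: ElectrolyteComposition = field(
        default_factory=ElectrolyteComposition.from_salts)
    ion_budget: IonBudget | None = None
    n_beads: int = 22
    chain_charge: int = -21
    bond_length: float = 0.6  # nm
    diffusion: dict = field(default_factory=lambda: {"Mn": 0.7, "Na": 1.3, "Cl": 2.0})
    bead_diffusion: float = 0.4  # nm^2/ns per bead (monomer-like; Rouse COM scaling)
    timestep_ps: float = 1.0
    temperature: float = 298.15  # K
    well_depth_kT: float = 4.0  # adsorption well per bead
    well_width_nm: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        fr_total = sum(self.surface_fractions.values())
        if abs(fr_total - 1.0) > 1e-9:
            raise ValueError("surface fractions must sum to 1")
        if self.ion_budget is None:
            lx, ly, lz = self.box
            water = (lx, ly, lz - 2 * self.slab_margin)
            self.ion_budget = box_ion_budget(
                water, self.composition, planes=self.planes,
                molecule_charge=self.chain_charge if self.n_beads else 0)
        if self.ion_budget.net_charge_e + sum(p.charge_e for p in self.planes) + (
                self.chain_charge if self.n_beads else 0) != 0:
            raise ValueError("surrogate system is not electroneutral")

    @property
    def geometry(self) -> SlabGeometry:
        return SlabGeometry(bottom_zero=self.slab_margin,
                            top_zero=self.box[2] - self.slab_margin)

    @classmethod
    def neutral(cls, **kw) -> "SurrogateSystem":
        return cls(**kw)

    @classmethod
    def charged(cls, surface_charge_e: float = -32.0, **kw) -> "SurrogateSystem":
        """Both faces carry the given total charge (e.g. -32 e or -65 e)."""
        area = kw.pop("area", 100.0)
        return cls(planes=(ChargedPlane(surface_charge_e, area),
                           ChargedPlane(surface_charge_e, area)), **kw)


# ---------------------------------------------------------------------------
# planted-truth fixtures
# ---------------------------------------------------------------------------

def plant_accumulation(base: SurrogateSystem, n_excess: int,
                       region: tuple[float, float] = (0.0, 4.0),
                       lateral_sigma: float = 1.5, n_frames: int = 200,
                       molecule_height: float | None = None,
                       seed: int = 0, dt: float = 1.0) -> Trajectory:
    """Equilibrium-like background plus a planted excess of Mn near one surface.

    Background ions (the system's full ion budget) are placed uniformly in
    the solution slab, independently per frame; ``n_excess`` additional Mn
    ions are placed with a lateral Gaussian (sigma = ``lateral_sigma``)
    around the polyanion footprint at the box centre, z uniform inside
    ``region`` (measured from the bottom zero plane), resampled per frame.
    The chain beads sit as a static blob at ``molecule_height`` (default:
    region midpoint) so molecule selections and COM distances are defined.
    """
    if n_excess < 0:
        raise ValueError("n_excess must be >= 0")
    geom = base.geometry
    if region[0] < 0 or region[1] > geom.extent or region[0] >= region[1]:
        raise ValueError(f"region {region} outside the solution slab [0, {geom.extent}]")
    rng = np.random.default_rng(seed)
    lx, ly, lz = base.box
    cx, cy = lx / 2, ly / 2
    zb, zt = geom.bottom_zero, geom.top_zero
    if molecule_height is None:
        molecule_height = 0.5 * (region[0] + region[1])
    # static chain blob around the footprint centre
    bead_xyz = np.column_stack([
        cx + 0.4 * rng.standard_normal(base.n_beads),
        cy + 0.4 * rng.standard_normal(base.n_beads),
        np.clip(zb + molecule_height + 0.2 * rng.standard_normal(base.n_beads), zb, zt)])
    labels_bg = [lab for lab, n in base.ion_budget.counts.items() for _ in range(n)]
    frames = []
    for k in range(n_frames):
        bg = rng.uniform(0.0, 1.0, size=(len(labels_bg), 3)) * np.array(
            [lx, ly, zt - zb]) + np.array([0.0, 0.0, zb])
        ex = np.column_stack([
            cx + lateral_sigma * rng.standard_normal(n_excess),
            cy + lateral_sigma * rng.standard_normal(n_excess),
            zb + rng.uniform(region[0], region[1], size=n_excess)])
        xyz = np.vstack([bead_xyz, bg, ex])
        species = np.array(["P"] * base.n_beads + labels_bg + ["Mn"] * n_excess,
                           dtype=object)
        frames.append(Frame(time=k * dt, ids=np.arange(len(xyz)), species=species,
                            xyz=xyz, box=base.box))
    return Trajectory(frames=frames, dt=dt, species_map=dict(_DEFAULT_SPECIES_MAP))


# ---------------------------------------------------------------------------
# Brownian-dynamics surrogate
# ---------------------------------------------------------------------------

@dataclass
class BDResult:
    """Output of a BD run: recorded trajectory plus adsorption bookkeeping."""

    trajectory: Trajectory
    adsorption: AdsorptionRecord | None
    unwrapped: np.ndarray  # (n_records, n_mobile, 3), never wrapped or reflected-corrected
    species: np.ndarray  # mobile-particle labels
    geometry: SlabGeometry


def _init_chain(rng, box, start_height, bond_length, n_beads, zb, zt):
    """Self-avoiding-ish random walk blob around the start point."""
    pos = np.empty((n_beads, 3))
    pos[0] = (box[0] / 2, box[1] / 2, zb + start_height)
    for i in range(1, n_beads):
        step = rng.standard_normal(3)
        step *= bond_length / np.linalg.norm(step)
        pos[i] = pos[i - 1] + step
        pos[i, 2] = min(max(pos[i, 2], zb + 0.2), zt - 0.2)
    return pos


def run_brownian_dynamics(system: SurrogateSystem, duration_ns: float,
                          seed: int | None = None,
                          record_interval_ps: float = 10.0,
                          include_chain: bool = True,
                          include_ions: bool = True,
                          chain_start_height: float | None = None,
                          external_potential: tuple[Callable, Callable] | None = None,
                          external_species: str = "Mn",
                          pair_interactions: bool = True,
                          surface_well: bool = True,
                          walls: bool = True,
                          contact_cutoff: float = 0.35,
                          persistence: float = 1.0,
                          replica_id: int = 0,
                          displacement_guard: float = 0.25) -> BDResult:
    """Overdamped Langevin dynamics of the surrogate system.

    Position update per particle: dx = (D/kB T) F dt + sqrt(2 D dt) xi, with
    screened-Coulomb pair forces between all charges (ions, chain beads and
    the discrete deprotonated-carboxyl sites of each surface), harmonic chain
    bonds, soft-core excluded volume, a Gaussian attraction well of depth
    ``well_depth_kT`` per bead at each surface, reflective z walls at the
    surface zero planes and x/y periodicity.  An optional external 1-D
    potential ``(U(z), F(z))`` (kB T, kB T/nm) acts on ``external_species``
    for stationarity checks.  A deterministic displacement larger than
    ``displacement_guard`` per step aborts the run with diagnostics.
    """
    rng = np.random.default_rng(system.seed if seed is None else seed)
    lx, ly, lz = system.box
    geom = system.geometry
    zb, zt = geom.bottom_zero, geom.top_zero
    dt = system.timestep_ps * 1e-3  # ns
    n_steps = max(1, int(round(duration_ns / dt)))
    every = max(1, int(round(record_interval_ps / system.timestep_ps)))

    labels: list[str] = []
    charges: list[float] = []
    diffus: list[float] = []
    positions: list[np.ndarray] = []

    if include_chain and system.n_beads:
        if chain_start_height is None:
            chain_start_height = geom.extent / 2
        chain = _init_chain(rng, system.box, chain_start_height,
                            system.bond_length, system.n_beads, zb, zt)
        positions.append(chain)
        labels += ["P"] * system.n_beads
        # spread the chain charge over the first |q| beads (backbone phosphates)
        qc = [0.0] * system.n_beads
        for i in range(min(abs(system.chain_charge), system.n_beads)):
            qc[i] = math.copysign(1.0, system.chain_charge)
        charges += qc
        diffus += [system.bead_diffusion] * system.n_beads

    valence = system.ion_budget.valences
    counts = system.ion_budget.counts if include_ions else {}
    for lab, n in counts.items():
        if n == 0:
            continue
        pos = rng.uniform(0.0, 1.0, size=(n, 3)) * np.array([lx, ly, zt - zb - 0.4])
        pos[:, 2] += zb + 0.2
        positions.append(pos)
        labels += [lab] * n
        charges += [float(valence[lab])] * n
        diffus += [float(system.diffusion.get(lab, 1.0))] * n

    n_mobile = len(labels)
    if n_mobile == 0:
        raise ValueError("no mobile particles in the system")
    x = np.vstack(positions)
    q = np.array(charges)
    D = np.array(diffus)
    spec = np.array(labels, dtype=object)

    # static charged surface sites (deprotonated carboxyls as discrete -1 e)
    static_pos, static_q = [], []
    for plane, z0 in zip(system.planes, (zb, zt)):
        n_sites = int(round(abs(plane.charge_e)))
        if n_sites == 0 or not pair_interactions:
            continue
        m = int(math.ceil(math.sqrt(n_sites)))
        gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        grid = (np.stack([gx.ravel(), gy.ravel()], axis=1)[:n_sites] + 0.5)
        grid = grid * (math.sqrt(plane.area_nm2) / m)
        static_pos.append(np.column_stack([grid, np.full(n_sites, z0)]))
        static_q.append(np.full(n_sites, math.copysign(1.0, plane.charge_e)))
    xs = np.vstack(static_pos) if static_pos else np.empty((0, 3))
    qs = np.concatenate(static_q) if static_q else np.empty(0)

    kappa = 1.0 / debye_length(system.composition)  # nm^-1
    lB = bjerrum_length(system.temperature, system.composition.eps_r)
    r_ex, eps_ex = 0.35, 5.0  # soft-core radius (nm) and height (kT)
    k_bond, r0 = 100.0, system.bond_length  # kT/nm^2
    eps_w, w = system.well_depth_kT, system.well_width_nm
    n_beads = system.n_beads if include_chain else 0
    bead_idx = np.arange(n_beads)
    ext_mask = spec == external_species

    def forces(pos: np.ndarray) -> np.ndarray:
        f = np.zeros_like(pos)
        if pair_interactions:
            all_pos = np.vstack([pos, xs]) if len(xs) else pos
            all_q = np.concatenate([q, qs]) if len(xs) else q
            d = pos[:, None, :] - all_pos[None, :, :]
            d[..., :2] = min_image_shift(d[..., :2], (lx, ly))
            r2 = np.einsum("ijk,ijk->ij", d, d)
            np.fill_diagonal(r2[:, :len(pos)], np.inf)
            r = np.sqrt(r2)
            # Yukawa: F = lB qi qj e^{-kr} (1 + kr) / r^2 along rhat
            qq = q[:, None] * all_q[None, :]
            # Yukawa force, linearly capped inside the soft-core radius so
            # opposite charges cannot collapse onto point sites
            re = np.maximum(r, r_ex)
            with np.errstate(over="ignore", invalid="ignore"):
                mag = lB * qq * np.exp(-kappa * re) * (1.0 + kappa * re) / (re * re)
            # soft-core excluded volume for r < r_ex
            close = r < r_ex
            mag = np.where(close, mag + 2.0 * eps_ex * (1.0 - r / r_ex) / r_ex, mag)
            mag = np.where(np.isfinite(mag), mag, 0.0)
            f += np.einsum("ij,ijk->ik", mag / np.maximum(r, 1e-6), d)
        if n_beads > 1:
            db = pos[bead_idx[:-1]] - pos[bead_idx[1:]]
            db[:, :2] = min_image_shift(db[:, :2], (lx, ly))
            rb = np.linalg.norm(db, axis=1)
            fb = -k_bond * (rb - r0)[:, None] * db / rb[:, None]
            f[bead_idx[:-1]] += fb
            f[bead_idx[1:]] -= fb
        if surface_well and n_beads:
            zbead = pos[bead_idx, 2]
            for z0, sgn in ((zb, 1.0), (zt, -1.0)):
                u = (zbead - z0) / w
                f[bead_idx, 2] += -sgn * eps_w * np.abs(u) * np.exp(-0.5 * u * u) / w * np.sign(u * sgn)
        if external_potential is not None:
            _, fz = external_potential
            f[ext_mask, 2] += fz(pos[ext_mask, 2])
        return f

    sq = np.sqrt(2.0 * D * dt)[:, None]
    mob = (D * dt)[:, None]
    frames = []
    unwrapped = []
    xu = x.copy()
    smap = dict(_DEFAULT_SPECIES_MAP)
    for lab in set(labels) - set(smap):
        smap[lab] = "diamagnetic"

    for step in range(n_steps + 1):
        if step % every == 0:
            frames.append(Frame(time=step * dt, ids=np.arange(n_mobile),
                                species=spec.copy(), xyz=x.copy(), box=system.box))
            unwrapped.append(xu.copy())
        if step == n_steps:
            break
        F = forces(x)
        det = mob * F
        worst = float(np.abs(det).max())
        if worst > displacement_guard:
            i = int(np.abs(det).max(axis=1).argmax())
            raise RuntimeError(
                f"BD instability at step {step}: particle {i} ({spec[i]}) "
                f"deterministic displacement {worst:.3f} nm exceeds the "
                f"{displacement_guard} nm guard; reduce the timestep")
        noise = sq * rng.standard_normal((n_mobile, 3))
        x = x + det + noise
        xu = xu + det + noise
        x[:, 0] %= lx
        x[:, 1] %= ly
        if walls:
            z = x[:, 2]
            z[:] = np.where(z < zb, 2 * zb - z, z)
            z[:] = np.where(z > zt, 2 * zt - z, z)
            np.clip(z, zb, zt, out=z)

    dt_rec = every * dt
    traj = Trajectory(frames=frames, dt=dt_rec, species_map=smap)
    record = None
    if include_chain and system.n_beads:
        record = detect_adsorption(traj, {"species": "P"}, geom,
                                   contact_cutoff=contact_cutoff,
                                   persistence=max(persistence, dt_rec),
                                   replica_id=replica_id)
    return BDResult(trajectory=traj, adsorption=record,
                    unwrapped=np.array(unwrapped), species=spec, geometry=geom)
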