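"""Mean-field electrolyte theory for slab-system setup.

Covers the Debye screening length of a mixed electrolyte, the Grahame
relation between surface charge density and surface potential for an
arbitrary ion mixture (solved numerically; exact within Poisson-Boltzmann),
1-D Poisson-Boltzmann ion profiles next to a uniformly charged plane, the
resulting excess ion numbers (which obey the screening sum rule
sum_i z_i N_i^excess = -sigma A exactly in PB theory), the backbone charge of
a synthetic RNA oligo, and the integer ion bookkeeping used to populate a
simulation box at prescribed bulk concentrations while keeping the total
system exactly electroneutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .constants import AVOGADRO, E_CHARGE, EPS0, KB, molar_to_per_nm3

__all__ = [
    "ElectrolyteComposition",
    "ChargedPlane",
    "IonBudget",
    "PBProfiles",
    "debye_length",
    "grahame_potential",
    "pb_ion_profiles",
    "excess_ion_numbers",
    "backbone_charge",
    "box_ion_budget",
]


@dataclass(frozen=True)
class ElectrolyteComposition:
    """Bulk electrolyte: list of (label, valence, concentration in mM)."""

    species: tuple  # of (label, z, c_mM)
    temperature: float = 298.15  # K
    eps_r: float = 78.4  # relative permittivity of water

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(
            (str(l), int(z), float(c)) for l, z, c in self.species))
        if any(c < 0 for _, _, c in self.species):
            raise ValueError("concentrations must be non-negative")
        net = sum(z * c for _, z, c in self.species)
        if abs(net) > 1e-9 * max(1.0, sum(c for _, _, c in self.species)):
            raise ValueError(f"bulk electrolyte not electroneutral: sum z*c = {net} mM")

    @classmethod
    def from_salts(cls, mncl2_mM: float = 5.0, nacl_mM: float = 10.0,
                   temperature: float = 298.15, eps_r: float = 78.4) -> "ElectrolyteComposition":
        """The assay buffer: MnCl2 (2:1) plus NaCl (1:1)."""
        return cls(species=(("Mn", 2, mncl2_mM), ("Na", 1, nacl_mM),
                            ("Cl", -1, 2 * mncl2_mM + nacl_mM)),
                   temperature=temperature, eps_r=eps_r)

    @property
    def ionic_strength_mM(self) -> float:
        return 0.5 * sum(c * z * z for _, z, c in self.species)


@dataclass(frozen=True)
class ChargedPlane:
    """A uniformly charged planar surface: total charge (e) over an area (nm^2)."""

    charge_e: float
    area_nm2: float

    def __post_init__(self) -> None:
        if self.area_nm2 <= 0:
            raise ValueError("area must be positive")

    @property
    def sigma_e_per_nm2(self) -> float:
        return self.charge_e / self.area_nm2

    @property
    def sigma_si(self) -> float:
        """Charge density in C/m^2."""
        return self.sigma_e_per_nm2 * E_CHARGE * 1e18


@dataclass
class IonBudget:
    """Integer per-species ion counts for a box, with provenance notes."""

    counts: dict  # label -> int
    valences: dict  # label -> int
    provenance: list = field(default_factory=list)

    @property
    def net_charge_e(self) -> int:
        return sum(self.valences[l] * n for l, n in self.counts.items())


def debye_length(comp: ElectrolyteComposition) -> float:
    """Debye screening length kappa^-1 in nm.

    kappa^2 = e^2 sum_i n_i z_i^2 / (eps eps0 kB T) with n_i the bulk number
    densities.  ~0.78 nm for 150 mM 1:1 at 298 K; physiological screening is
    sub-nanometre.
    """
    sum_cz2 = sum(c * z * z for _, z, c in comp.species)  # mM = mol/m^3
    if sum_cz2 <= 0:
        raise ValueError("zero ionic strength: Debye length undefined")
    n_z2 = sum_cz2 * AVOGADRO  # m^-3
    kappa2 = E_CHARGE**2 * n_z2 / (comp.eps_r * EPS0 * KB * comp.temperature)
    return 1e9 / math.sqrt(kappa2)


def _grahame_residual(psi: float, comp: ElectrolyteComposition) -> float:
    """2 eps eps0 kB T sum_i n_i (exp(-z_i e psi / kB T) - 1), SI (psi in V)."""
    kT = KB * comp.temperature
    total = 0.0
    for _, z, c in comp.species:
        n = c * AVOGADRO  # m^-3
        total += n * math.expm1(-z * E_CHARGE * psi / kT)
    return 2.0 * comp.eps_r * EPS0 * kT * total


def grahame_potential(plane: ChargedPlane, comp: ElectrolyteComposition) -> float:
    """Surface potential psi0 (mV) solving the Grahame relation.

    sigma^2 = 2 eps eps0 kB T sum_i n_i (exp(-z_i e psi0/kB T) - 1), with
    sign(psi0) = sign(sigma).  Solved by bracketing; reduces to the linear
    Debye-Huckel result psi0 = sigma/(eps eps0 kappa) at low charge.
    """
    sigma = plane.sigma_si
    if sigma == 0.0:
        return 0.0
    sgn = math.copysign(1.0, sigma)
    target = sigma * sigma

    def f(psi_mag: float) -> float:
        return _grahame_residual(sgn * psi_mag, comp) - target

    hi = 0.025
    while f(hi) < 0:
        hi *= 2.0
        if hi > 100.0:
            raise RuntimeError(
                f"Grahame root not bracketed up to {hi} V for sigma={sigma} C/m^2; "
                "pathological surface charge or composition")
    psi_mag = brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-14)
    return sgn * psi_mag * 1e3


@dataclass
class PBProfiles:
    """1-D Poisson-Boltzmann solution next to a charged plane."""

    z_nm: np.ndarray
    psi_mV: np.ndarray
    densities_mM: dict  # label -> ndarray
    comp: ElectrolyteComposition

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"z_nm": self.z_nm, "psi_mV": self.psi_mV})
        for lab, d in self.densities_mM.items():
            df[f"c_{lab}_mM"] = d
        return df


def pb_ion_profiles(psi0_mV: float, comp: ElectrolyteComposition,
                    z_max: float = 20.0, n_points: int = 800) -> PBProfiles:
    """Integrate the 1-D PB equation outward from a plane at potential psi0.

    Uses the first integral dpsi/dz = -sign(psi0) sqrt(2 kB T / (eps eps0)
    sum_i n_i (exp(-z_i e psi/kB T) - 1)), which decays to zero in the bulk.
    Densities follow the Boltzmann relation c_i(z) = c_i exp(-z_i e psi/kB T).
    """
    kT = KB * comp.temperature
    z_nm = np.linspace(0.0, z_max, n_points)
    psi0 = psi0_mV * 1e-3
    if psi0 == 0.0:
        psi = np.zeros_like(z_nm)
    else:
        sgn = math.copysign(1.0, psi0)
        pref = 2.0 * kT / (comp.eps_r * EPS0)

        def rhs(_z, y):
            s = sum(c * AVOGADRO * math.expm1(-zi * E_CHARGE * y[0] / kT)
                    for _, zi, c in comp.species)
            return [-sgn * math.sqrt(max(pref * s, 0.0)) * 1e-9]  # V per nm

        sol = solve_ivp(rhs, (0.0, z_max), [psi0], t_eval=z_nm,
                        rtol=1e-10, atol=1e-14, max_step=z_max / 200)
        if not sol.success:
            raise RuntimeError(f"PB integration failed: {sol.message}")
        psi = sol.y[0]
    dens = {}
    for lab, zi, c in comp.species:
        dens[lab] = c * np.exp(-zi * E_CHARGE * psi / kT)
    return PBProfiles(z_nm=z_nm, psi_mV=psi * 1e3, densities_mM=dens, comp=comp)


def excess_ion_numbers(profiles: PBProfiles, area_nm2: float) -> dict:
    """Per-species excess ion counts over bulk, area * integral(c(z)-c_bulk)dz.

    In PB theory the valence-weighted total equals minus the surface charge
    (screening sum rule); integration is by the trapezoid rule on the solved
    grid.
    """
    if area_nm2 <= 0:
        raise ValueError("area must be positive")
    tail = abs(profiles.psi_mV[-1])
    if tail > 1e-3 * max(abs(profiles.psi_mV[0]), 1.0):
        raise RuntimeError(
            f"PB profile not converged to bulk at z_max (psi tail {tail:.3g} mV); "
            "increase z_max")
    out = {}
    bulk = {lab: c for lab, _, c in profiles.comp.species}
    for lab, dens in profiles.densities_mM.items():
        excess_per_nm2 = np.trapezoid(
            (dens - bulk[lab]) * molar_to_per_nm3(1.0), profiles.z_nm)
        out[lab] = float(excess_per_nm2 * area_nm2)
    return out


_RNA_ALPHABET = set("ACGU")


def backbone_charge(sequence: str) -> int:
    """Net backbone charge (e) of a synthetic RNA oligo.

    L nucleotides are joined by L-1 phosphodiester groups, each carrying -1 e
    at neutral-ish pH; synthetic oligos carry no terminal phosphate, so the
    charge is -(L-1).  The printed 22-mer assayed here is therefore -21 e.
    """
    seq = sequence.strip().upper()
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    if len(seq) < 2:
        raise ValueError("sequence must have at least 2 nucleotides")
    return -(len(seq) - 1)


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def box_ion_budget(water_volume_nm3: float | Sequence[float],
                   comp: ElectrolyteComposition,
                   planes: Sequence[ChargedPlane] = (),
                   molecule_charge: int = 0,
                   pb_z_max: float = 20.0) -> IonBudget:
    """Integer ion counts for a slab box at prescribed bulk conditions.

    Bulk term: round(c_i * V) per species (round-half-to-even).  Surface
    term: rounded PB excess counts per charged plane.  Molecule term: the
    polyanion's charge is neutralised divalent-first, remainder monovalent.
    Any residual +-1 e from rounding is absorbed into the most abundant
    monovalent species and logged; the emitted budget is exactly neutral
    against surfaces + molecule.
    """
    if not isinstance(water_volume_nm3, (int, float)):
        lx, ly, lz = water_volume_nm3
        water_volume_nm3 = lx * ly * lz
    if water_volume_nm3 <= 0:
        raise ValueError("water volume must be positive")
    labels = [l for l, _, _ in comp.species]
    valences = {l: z for l, z, _ in comp.species}
    counts = {l: 0 for l in labels}
    notes: list[str] = []

    for lab, _z, c in comp.species:
        n = _round_half_even(molar_to_per_nm3(c) * water_volume_nm3)
        counts[lab] += n
        notes.append(f"bulk: {n} {lab} from {c} mM x {water_volume_nm3:.1f} nm^3")

    # the diffuse layer must have decayed by z_max: scale with the Debye length
    z_max = max(pb_z_max, 12.0 * debye_length(comp))
    for k, plane in enumerate(planes):
        if plane.charge_e == 0:
            continue
        psi0 = grahame_potential(plane, comp)
        prof = pb_ion_profiles(psi0, comp, z_max=z_max)
        for lab, x in excess_ion_numbers(prof, plane.area_nm2).items():
            n = _round_half_even(x)
            counts[lab] = max(0, counts[lab] + n)
            notes.append(f"surface {k} ({plane.charge_e:+.0f} e): {n:+d} {lab} (PB excess {x:.2f})")

    if molecule_charge != 0:
        need = -molecule_charge  # cations to add for a polyanion
        if need < 0:
            raise ValueError("only anionic molecules are supported")
        divalents = sorted((l for l in labels if valences[l] == 2),
                           key=lambda l: -counts[l])
        monovalents = sorted((l for l in labels if valences[l] == 1),
                             key=lambda l: -counts[l])
        if divalents:
            n2 = need // 2
            counts[divalents[0]] += n2
            notes.append(f"molecule ({molecule_charge:+d} e): +{n2} {divalents[0]}")
            need -= 2 * n2
        if need:
            if not monovalents:
                raise ValueError("cannot neutralize molecule: no monovalent cations")
            counts[monovalents[0]] += need
            notes.append(f"molecule remainder: +{need} {monovalents[0]}")

    external = int(round(sum(p.charge_e for p in planes))) + molecule_charge
    residual = sum(valences[l] * counts[l] for l in labels) + external
    if residual != 0:
        monos = sorted((l for l in labels if abs(valences[l]) == 1),
                       key=lambda l: -counts[l])
        fixed = False
        for lab in monos:
            delta = -int(residual) // valences[lab] if abs(residual) % abs(valences[lab]) == 0 else None
            if delta is None:
                continue
            if counts[lab] + delta >= 0:
                counts[lab] += delta
                notes.append(f"neutrality fix: {delta:+d} {lab} (residual {residual:+d} e)")
                fixed = True
                break
        if not fixed:
            raise ValueError(f"cannot neutralize residual charge {residual:+d} e")
    return IonBudget(counts=counts, valences=valences, provenance=notes)
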