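"""Trajectory containers, slab-geometry conventions, and coordinate I/O.

The slab systems analysed here are periodic in x/y only; the z axis is normal
to the two functionalized surfaces and carries no periodic images (the
simulated cells keep a vacuum buffer along z).  The "surface zero" plane of
each slab sits ``carbon_offset`` (0.2 nm by default) above the topmost plane
of bulk carbon atoms, which is where the oxygen adlayer of an oxygenated
diamond face sits on average; all surface distances are measured from that
plane, positive into the solution.

Formats: an extended XYZ dialect whose comment line carries
``time=<ns> box=<Lx,Ly,Lz>`` (nm), single- or multi-frame GRO, and multi-model
PDB.  GRO and PDB parsing/writing is delegated to MDAnalysis; coordinates are
converted to nm on the way in (MDAnalysis uses Angstrom internally).
"""

from __future__ import annotations

import io
import os
import re
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Frame",
    "Trajectory",
    "SlabGeometry",
    "TrajectoryParseError",
    "read_trajectory",
    "write_trajectory",
    "write_trajectory_batch",
    "surface_distance",
    "min_image_shift",
]


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file cannot be parsed."""


def min_image_shift(dxy: np.ndarray, box_xy: Sequence[float]) -> np.ndarray:
    """Apply the minimum-image convention to x/y displacement components.

    ``dxy`` has shape (..., 2); ``box_xy`` is (Lx, Ly).  z is never imaged.
    """
    dxy = np.asarray(dxy, dtype=float).copy()
    for k in range(2):
        L = float(box_xy[k])
        dxy[..., k] -= L * np.round(dxy[..., k] / L)
    return dxy


@dataclass
class Frame:
    """One time-stamped configuration of ions/beads in a slab box.

    Coordinates are in nm; x/y are wrapped into [0, Lx) x [0, Ly) on
    construction.  atom ids must be unique within the frame.
    """

    time: float  # ns
    ids: np.ndarray  # (N,) int
    species: np.ndarray  # (N,) str labels
    xyz: np.ndarray  # (N, 3) nm
    box: tuple[float, float, float]  # nm

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates in frame")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate atom ids within a frame")
        if len(self.ids) != len(self.xyz) or len(self.species) != len(self.xyz):
            raise ValueError("ids/species/xyz length mismatch")
        self.box = tuple(float(b) for b in self.box)
        if any(b <= 0 for b in self.box):
            raise ValueError(f"non-positive box: {self.box}")
        # wrap x/y only; the z axis is non-periodic (vacuum buffer)
        for k in range(2):
            self.xyz[:, k] = np.mod(self.xyz[:, k], self.box[k])

    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    def select(self, species: str | Iterable[str] | None = None,
               ids: Iterable[int] | None = None) -> np.ndarray:
        """Boolean mask of atoms matching a species label (or set) and/or ids."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if species is not None:
            wanted = {species} if isinstance(species, str) else set(species)
            mask &= np.array([s in wanted for s in self.species])
        if ids is not None:
            wanted_ids = set(int(i) for i in ids)
            mask &= np.array([int(i) in wanted_ids for i in self.ids])
        return mask


@dataclass
class Trajectory:
    """An ordered, uniformly spaced sequence of frames.

    ``species_map`` resolves each species label to a spin-carrying species
    (a :class:`spinatmos.dipolar.SpinSpecies`) or the string ``"diamagnetic"``.
    """

    frames: list[Frame]
    dt: float  # ns, uniform frame spacing
    species_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(steps, self.dt, rtol=1e-6, atol=1e-9):
                raise ValueError(
                    "non-uniform frame spacing: trajectory analysis assumes a "
                    f"constant dt={self.dt} ns but observed steps "
                    f"[{steps.min():.6g}, {steps.max():.6g}] ns"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def labels(self) -> set:
        out: set = set()
        for f in self.frames:
            out.update(f.species.tolist())
        return out

    def validate_species(self) -> None:
        unresolved = self.labels() - set(self.species_map)
        if unresolved:
            raise ValueError(f"species labels without species_map entry: {sorted(unresolved)}")


@dataclass
class SlabGeometry:
    """z-positions of the two surface zero planes of a slab cell.

    The zero plane of each surface sits ``carbon_offset`` above (below, for
    the top slab) the topmost plane of bulk atoms of that slab.
    """

    bottom_zero: float  # nm
    top_zero: float  # nm
    carbon_offset: float = 0.2  # nm
    normal_axis: int = 2  # fixed: z

    def __post_init__(self) -> None:
        if self.bottom_zero >= self.top_zero:
            raise ValueError("bottom_zero must lie below top_zero")
        if self.normal_axis != 2:
            raise ValueError("slab normal is fixed to the z axis")

    @classmethod
    def from_carbon_planes(cls, bottom_carbon: float, top_carbon: float,
                           carbon_offset: float = 0.2) -> "SlabGeometry":
        """Build from the topmost bulk-atom planes of the two slabs."""
        return cls(bottom_zero=bottom_carbon + carbon_offset,
                   top_zero=top_carbon - carbon_offset,
                   carbon_offset=carbon_offset)

    @property
    def extent(self) -> float:
        """Width of the solution region between the two zero planes (nm)."""
        return self.top_zero - self.bottom_zero


def surface_distance(frame: Frame, geometry: SlabGeometry, side: str = "bottom",
                     species: str | Iterable[str] | None = None,
                     ids: Iterable[int] | None = None,
                     reduce: str = "none") -> np.ndarray | float:
    """Distance of selected atoms (or their centre of mass) from a zero plane.

    Distances are positive into the solution.  ``reduce="com"`` returns the
    scalar distance of the selection's unweighted centre of mass.
    """
    mask = frame.select(species=species, ids=ids)
    if not mask.any():
        raise ValueError("empty selection for surface_distance")
    z = frame.xyz[mask, 2]
    if reduce == "com":
        z = np.array([z.mean()])
    elif reduce != "none":
        raise ValueError(f"unknown reduce mode {reduce!r}")
    if side == "bottom":
        d = z - geometry.bottom_zero
    elif side == "top":
        d = geometry.top_zero - z
    else:
        raise ValueError(f"side must be 'bottom' or 'top', got {side!r}")
    return float(d[0]) if reduce == "com" else d


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_BOX_RE = re.compile(r"box=([0-9eE+.\-]+),([0-9eE+.\-]+),([0-9eE+.\-]+)")
_TIME_RE = re.compile(r"time=([0-9eE+.\-]+)")


def _read_xyz(path: str, box, dt) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryParseError(
                f"frame {idx}: expected atom count, got {lines[i]!r}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        mbox = _BOX_RE.search(comment)
        if mbox:
            fbox = tuple(float(g) for g in mbox.groups())
        elif box is not None:
            fbox = tuple(box)
        else:
            raise TrajectoryParseError(
                f"frame {idx}: no box metadata in comment line and no box "
                "supplied; refusing to guess")
        mtime = _TIME_RE.search(comment)
        if mtime:
            t = float(mtime.group(1))
        elif dt is not None:
            t = idx * dt
        else:
            raise TrajectoryParseError(
                f"frame {idx}: no time metadata and no dt supplied")
        body = lines[i + 2: i + 2 + n]
        if len(body) < n:
            raise TrajectoryParseError(f"frame {idx}: truncated ({len(body)}/{n} atoms)")
        species, xyz = [], []
        for j, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise TrajectoryParseError(f"frame {idx}: malformed atom line {j}: {ln!r}")
            species.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(Frame(time=t, ids=np.arange(n), species=np.array(species, dtype=object),
                            xyz=np.array(xyz), box=fbox))
        i += 2 + n
        idx += 1
    return frames


def _write_xyz(traj: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{f.n_atoms}\n")
            fh.write(f"time={f.time:.6f} box={f.box[0]:.6f},{f.box[1]:.6f},{f.box[2]:.6f}\n")
            for s, (x, y, z) in zip(f.species, f.xyz):
                fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# GRO / PDB via MDAnalysis
# ---------------------------------------------------------------------------

def _mda():
    import MDAnalysis as mda
    return mda


def _frames_from_universe(u, scale: float, box, dt, times=None) -> list[Frame]:
    frames = []
    names = [n.strip() for n in u.atoms.names]
    for k, ts in enumerate(u.trajectory):
        if ts.dimensions is not None and ts.dimensions[:3].min() > 0:
            fbox = tuple(float(d) * scale for d in ts.dimensions[:3])
        elif box is not None:
            fbox = tuple(box)
        else:
            raise TrajectoryParseError(
                f"frame {k}: no box metadata in file and no box supplied")
        if times is not None:
            t = times[k]
        elif dt is not None:
            t = k * dt
        else:
            raise TrajectoryParseError(f"frame {k}: no dt supplied for this format")
        frames.append(Frame(time=t, ids=np.arange(u.atoms.n_atoms),
                            species=np.array(names, dtype=object),
                            xyz=u.atoms.positions.astype(float) * scale, box=fbox))
    return frames


def _split_gro_frames(path: str) -> list[str]:
    """Split a (possibly multi-frame) GRO file into per-frame chunks."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    chunks, i = [], 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i + 1].split()[0])
        except (IndexError, ValueError) as exc:
            raise TrajectoryParseError(
                f"gro frame {len(chunks)}: bad atom-count line") from exc
        end = i + 2 + n + 1  # title, count, atoms, box line
        if end > len(lines):
            raise TrajectoryParseError(f"gro frame {len(chunks)}: truncated")
        chunks.append("\n".join(lines[i:end]) + "\n")
        i = end
    return chunks


def _read_gro(path: str, box, dt) -> list[Frame]:
    mda = _mda()
    frames = []
    for k, chunk in enumerate(_split_gro_frames(path)):
        title = chunk.splitlines()[0]
        mt = re.search(r"\bt=\s*([0-9eE+.\-]+)", title)
        with tempfile.NamedTemporaryFile("w", suffix=".gro", delete=False) as tf:
            tf.write(chunk)
            tmp = tf.name
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(tmp)
            t = float(mt.group(1)) if mt else (k * dt if dt is not None else None)
            if t is None:
                raise TrajectoryParseError(f"gro frame {k}: no time metadata and no dt")
            # GRO is natively nm but MDAnalysis converts to Angstrom
            frames.extend(_frames_from_universe(u, 0.1, box, dt, times=[t]))
        finally:
            os.unlink(tmp)
    return frames


def _read_pdb(path: str, box, dt) -> list[Frame]:
    mda = _mda()
    if box is None:
        # CRYST1 is file-global; some reader versions do not propagate it to
        # every model's timestep, so parse it directly (Angstrom -> nm)
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    box = (float(line[6:15]) / 10, float(line[15:24]) / 10,
                           float(line[24:33]) / 10)
                    break
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    return _frames_from_universe(u, 0.1, box, dt)  # Angstrom -> nm


def _universe_for_frame(f: Frame):
    mda = _mda()
    u = mda.Universe.empty(f.n_atoms, n_residues=f.n_atoms, atom_resindex=np.arange(f.n_atoms),
                           trajectory=True)
    names = [str(s)[:5] for s in f.species]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", ["ION"] * f.n_atoms)
    u.add_TopologyAttr("resids", np.arange(1, f.n_atoms + 1))
    u.atoms.positions = f.xyz * 10.0  # nm -> Angstrom
    u.dimensions = [f.box[0] * 10, f.box[1] * 10, f.box[2] * 10, 90.0, 90.0, 90.0]
    return u


def _write_gro(traj: Trajectory, path: str) -> None:
    buf = io.StringIO()
    for f in traj.frames:
        u = _universe_for_frame(f)
        with tempfile.NamedTemporaryFile("r", suffix=".gro", delete=False) as tf:
            tmp = tf.name
        try:
            u.atoms.write(tmp)
            with open(tmp) as fh:
                lines = fh.read().splitlines()
            lines[0] = f"spinatmos frame t= {f.time:.6f}"
            buf.write("\n".join(lines) + "\n")
        finally:
            os.unlink(tmp)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _write_pdb(traj: Trajectory, path: str) -> None:
    mda = _mda()
    counts = {f.n_atoms for f in traj.frames}
    if len(counts) > 1:
        raise ValueError(
            "multi-model PDB requires a constant atom count across frames "
            f"(got counts {sorted(counts)}); use the xyz format for "
            "variable-count trajectories")
    u = _universe_for_frame(traj.frames[0])
    coords = np.stack([f.xyz * 10.0 for f in traj.frames])
    u.load_new(coords, format="memory")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, multiframe=True) as w:
            for f, ts in zip(traj.frames, u.trajectory):
                u.dimensions = [f.box[0] * 10, f.box[1] * 10, f.box[2] * 10,
                                90.0, 90.0, 90.0]
                w.write(u.atoms)


_FORMATS = ("xyz", "gro", "pdb-frames")


def read_trajectory(path: str, format: str = "xyz", *, dt: float | None = None,
                    box: Sequence[float] | None = None,
                    species_map: dict | None = None) -> Trajectory:
    """Read a trajectory file into internal nm/ns units.

    ``dt`` (ns) is required whenever the file does not carry per-frame times;
    ``box`` (nm) is required whenever the file carries no box metadata.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "xyz":
        frames = _read_xyz(path, box, dt)
    elif format == "gro":
        frames = _read_gro(path, box, dt)
    else:
        frames = _read_pdb(path, box, dt)
    if dt is None:
        if len(frames) > 1:
            dt = frames[1].time - frames[0].time
        else:
            dt = 1.0
    return Trajectory(frames=frames, dt=dt, species_map=species_map or {})


def write_trajectory(traj: Trajectory, path: str, format: str = "xyz") -> str:
    """Write a trajectory; round-trips coordinates to the format's precision."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "xyz":
        _write_xyz(traj, path)
    elif format == "gro":
        if not traj.frames:
            open(path, "w").close()
        else:
            _write_gro(traj, path)
    else:
        if not traj.frames:
            open(path, "w").close()
        else:
            _write_pdb(traj, path)
    return path


def write_trajectory_batch(trajs: Sequence[Trajectory], directory: str,
                           prefix: str = "replica", format: str = "xyz") -> list[str]:
    """Write an ensemble of replicas as ``<prefix>_<k>.<ext>`` files."""
    os.makedirs(directory, exist_ok=True)
    ext = {"xyz": "xyz", "gro": "gro", "pdb-frames": "pdb"}[format]
    paths = []
    for k, t in enumerate(trajs):
        p = os.path.join(directory, f"{prefix}_{k:02d}.{ext}")
        write_trajectory(t, p, format=format)
        paths.append(p)
    return paths
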