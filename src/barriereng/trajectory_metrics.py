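"""Trajectory-derived observables for barrier identification and verification.

Works on frame series with constant topology (multi-model PDB or in-memory
:class:`Trajectory`): Kabsch superposition and RMSD, radius of gyration,
per-residue RMSF over an analysis window, Shrake–Rupley SASA,
substrate/water occupancy at the binding site, Ser OG–carbonyl distance
series, and spatial occupancy grids (SDF).

The substrate binding site is defined operationally as the sphere of
``cutoff`` Å (default 6.0) around the catalytic Ser OG atom: a molecule is
"in" the site on a frame when at least one of its heavy atoms lies inside.
Analysis windows are specified in nanoseconds and filter frames by time, so
"the last 40 ns" maps onto any storage interval.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    CatalyticSite,
    Residue,
    Structure,
    atomic_mass,
    coords_of,
    read_structure,
    vdw_radius,
)

log = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]


@dataclass
class Trajectory:
    """Frame series with uniform time stamps and tagged ligand/water residues."""

    structure: Structure
    times: np.ndarray  # ns, one per frame
    ligand_ids: list[ResidueKey] = field(default_factory=list)
    water_ids: list[ResidueKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.structure.n_models:
            raise ValueError(
                f"{len(self.times)} times for {self.structure.n_models} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.structure.n_models

    def frame(self, i: int) -> list[Residue]:
        return self.structure.models[i]

    def protein_keys(self) -> list[ResidueKey]:
        skip = set(self.ligand_ids) | set(self.water_ids)
        return [r.key for r in self.frame(0) if r.key not in skip]

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        frame_interval_ns: float = 0.5,
        ligand_resname: str = "BHT",
        water_resname: str = "HOH",
    ) -> "Trajectory":
        """Load a multi-model PDB; frame i gets time i × interval."""
        s = read_structure(path)
        times = np.arange(s.n_models) * frame_interval_ns
        ligand_ids = [r.key for r in s.residues(0) if r.res_name == ligand_resname]
        water_ids = [r.key for r in s.residues(0) if r.res_name == water_resname]
        return cls(structure=s, times=times, ligand_ids=ligand_ids, water_ids=water_ids)


@dataclass(frozen=True)
class AnalysisWindow:
    """Inclusive [start_ns, end_ns] time window."""

    start_ns: float
    end_ns: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_ns < self.end_ns):
            raise ValueError(f"invalid window [{self.start_ns}, {self.end_ns}]")

    def mask(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.start_ns) & (times <= self.end_ns)


@dataclass
class OccupancySeries:
    """Per-frame molecule counts at the binding site for one species."""

    times: np.ndarray
    counts: np.ndarray
    species: str
    cutoff: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("occupancy counts must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    def bin_means(self, bin_ns: float = 10.0) -> pd.DataFrame:
        """Mean count per time bin (e.g. per 10 ns block)."""
        start = math.floor(self.times.min() / bin_ns) * bin_ns
        edges = np.arange(start, self.times.max() + bin_ns, bin_ns)
        rows = []
        for lo in edges:
            hi = lo + bin_ns
            m = (self.times >= lo) & (self.times < hi)
            if m.any():
                rows.append({"bin_start_ns": lo, "bin_end_ns": hi,
                             "mean_count": float(self.counts[m].mean())})
        return pd.DataFrame(rows)


@dataclass
class Grid3D:
    """Regular grid of per-voxel occupancy fractions in [0, 1]."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # shape (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a non-empty 3D array")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("occupancy fractions must lie in [0, 1]")

    def write_cube(self, path: str | Path, comment: str = "occupancy fraction") -> None:
        """Gaussian cube output (grid in Å converted to Bohr, no atoms)."""
        bohr = 1.0 / 0.529177210903
        nx, ny, nz = self.values.shape
        with open(path, "w") as fh:
            fh.write("barriereng spatial distribution\n")
            fh.write(comment + "\n")
            ox, oy, oz = self.origin * bohr
            fh.write(f"{1:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
            s = self.spacing * bohr
            fh.write(f"{nx:5d}{s:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
            fh.write(f"{ny:5d}{0.0:12.6f}{s:12.6f}{0.0:12.6f}\n")
            fh.write(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{s:12.6f}\n")
            fh.write(f"{1:5d}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
            flat = self.values.reshape(nx * ny, nz)
            for row in flat:
                for i in range(0, nz, 6):
                    fh.write("".join(f"{v:13.5E}" for v in row[i : i + 6]) + "\n")


# ---------------------------------------------------------------------------
# Superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid fit of ``mobile`` onto ``reference`` (paired rows).

    Returns (rotation R, translation t, post-fit RMSD); the fitted
    coordinates are ``mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (N, 3) arrays")
    if len(mobile) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = rc - R @ mc
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return R, t, rmsd


def _selection_coords(
    model: list[Residue], keys: list[ResidueKey] | None, atom_names: list[str] | None
) -> np.ndarray:
    """Heavy-atom coordinates in topology order, optionally filtered."""
    keyset = set(keys) if keys is not None else None
    pts = []
    for res in model:
        if keyset is not None and res.key not in keyset:
            continue
        for a in res.heavy_atoms():
            if atom_names is None or a.name in atom_names:
                pts.append(a.coords)
    if not pts:
        raise ValueError("empty superposition selection")
    return np.vstack(pts)


def superpose(
    frame: Structure,
    reference: Structure,
    selection_keys: list[ResidueKey] | None = None,
    atom_names: list[str] | None = None,
) -> tuple[Structure, float]:
    """Least-squares superpose (single-model) ``frame`` onto ``reference``.

    The fit is computed on the selection; the returned structure has *all*
    atoms transformed.  Also returns the post-fit RMSD over the selection.
    """
    P = _selection_coords(frame.residues(0), selection_keys, atom_names)
    Q = _selection_coords(reference.residues(0), selection_keys, atom_names)
    R, t, rmsd = kabsch(P, Q)
    moved = copy.deepcopy(frame)
    for res in moved.residues(0):
        for a in res.atoms:
            a.coords = R @ a.coords + t
    return moved, rmsd


def radius_of_gyration(frame: Structure, selection_keys: list[ResidueKey] | None = None) -> float:
    """Mass-weighted radius of gyration (Å) over heavy atoms."""
    keyset = set(selection_keys) if selection_keys is not None else None
    pts, masses = [], []
    for res in frame.residues(0):
        if keyset is not None and res.key not in keyset:
            continue
        for a in res.heavy_atoms():
            pts.append(a.coords)
            masses.append(atomic_mass(a.element))
    if not pts:
        raise ValueError("empty selection for radius of gyration")
    if len(pts) == 1:
        return 0.0
    xyz = np.vstack(pts)
    m = np.asarray(masses)
    com = (xyz * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((xyz - com) ** 2, axis=1)).sum() / m.sum()))


# ---------------------------------------------------------------------------
# RMSF


def _representative_coords(
    model: list[Residue], keys: list[ResidueKey], atom_name: str = "CA"
) -> np.ndarray:
    """One representative heavy atom per residue (CA, else first heavy)."""
    pts = []
    lookup = {r.key: r for r in model}
    for key in keys:
        res = lookup[key]
        if res.has_atom(atom_name):
            pts.append(res.atom(atom_name).coords)
        else:
            pts.append(res.heavy_atoms()[0].coords)
    return np.vstack(pts)


def rmsf(
    traj: Trajectory,
    window: AnalysisWindow,
    selection_keys: list[ResidueKey] | None = None,
    atom_name: str = "CA",
    fit_keys: list[ResidueKey] | None = None,
) -> pd.DataFrame:
    """Per-residue RMSF (Å) about the window-mean structure.

    Frames are first superposed onto the first window frame, averaged, then
    re-superposed onto that mean; RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|²).
    The superposition fit uses ``fit_keys`` (default: the analysed
    selection); pass a rigid subset to keep a mobile region's fluctuation
    from leaking into the fit.
    """
    keys = selection_keys if selection_keys is not None else traj.protein_keys()
    if not keys:
        raise ValueError("no residues selected for RMSF")
    fit = fit_keys if fit_keys is not None else keys
    idx = np.nonzero(window.mask(traj.times))[0]
    if len(idx) < 2:
        raise ValueError("RMSF window must contain at least 2 frames")
    raw = np.stack([_representative_coords(traj.frame(i), keys, atom_name) for i in idx])
    raw_fit = np.stack(
        [_representative_coords(traj.frame(i), fit, atom_name) for i in idx]
    )
    fitted = np.empty_like(raw)

    def _apply(ref_fit: np.ndarray) -> None:
        for k in range(len(idx)):
            R, t, _ = kabsch(raw_fit[k], ref_fit)
            fitted[k] = raw[k] @ R.T + t

    _apply(raw_fit[0])
    fitted_fit = np.empty_like(raw_fit)
    for k in range(len(idx)):
        R, t, _ = kabsch(raw_fit[k], raw_fit[0])
        fitted_fit[k] = raw_fit[k] @ R.T + t
    _apply(fitted_fit.mean(axis=0))  # second pass: fit to the window mean
    mean = fitted.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    return pd.DataFrame(
        {
            "chain": [k[0] for k in keys],
            "seq_id": [k[1] for k in keys],
            "rmsf": fluct,
        }
    )


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def sasa(
    frame: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    model: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Shrake–Rupley solvent-accessible surface area (Å²).

    Test points on each atom's solvent-expanded sphere (radius r_vdw +
    probe) count as accessible when inside no other atom's expanded sphere;
    per-atom area = exposed fraction × 4π(r+p)².  Deterministic for a given
    ``n_points``.  Returns (total, per-residue table).
    """
    if n_points < 16:
        raise ValueError("n_points must be at least 16")
    atoms: list[tuple[ResidueKey, Atom]] = []
    for res in frame.residues(model):
        for a in res.heavy_atoms():
            atoms.append((res.key, a))
    if not atoms:
        raise ValueError("no heavy atoms")
    centers = np.vstack([a.coords for _, a in atoms])
    radii = np.array([vdw_radius(a.element) for _, a in atoms]) + probe
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(centers)
    per_atom = np.zeros(len(atoms))
    rmax = radii.max()
    for i in range(len(atoms)):
        pts = centers[i] + radii[i] * unit
        # coincident duplicates: the first keeps its area, the rest are buried
        neighbors = []
        duplicated = False
        for j in tree.query_ball_point(centers[i], radii[i] + rmax):
            if j == i:
                continue
            if radii[j] == radii[i] and np.linalg.norm(centers[j] - centers[i]) < 1e-9:
                if j < i:
                    duplicated = True
                    break
                continue
            neighbors.append(j)
        if duplicated:
            per_atom[i] = 0.0
            continue
        if neighbors:
            nb_c = centers[neighbors]
            nb_r = radii[neighbors]
            d2 = np.sum((pts[:, None, :] - nb_c[None, :, :]) ** 2, axis=2)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        per_atom[i] = 4 * np.pi * radii[i] ** 2 * exposed / n_points
    rows: dict[ResidueKey, float] = {}
    for (key, _), area in zip(atoms, per_atom):
        rows[key] = rows.get(key, 0.0) + area
    table = pd.DataFrame(
        {
            "chain": [k[0] for k in rows],
            "seq_id": [k[1] for k in rows],
            "sasa": list(rows.values()),
        }
    )
    return float(per_atom.sum()), table


# ---------------------------------------------------------------------------
# Site occupancy and distance series


def _species_keys(traj: Trajectory, species: str) -> list[ResidueKey]:
    if species == "ligand":
        keys = traj.ligand_ids
    elif species == "water":
        keys = traj.water_ids
    else:
        raise ValueError(f"unknown species {species!r}")
    if not keys:
        raise ValueError(f"trajectory contains no {species} molecules")
    return keys


def _site_og_coords(traj: Trajectory, site: CatalyticSite, i_frame: int) -> np.ndarray:
    res = traj.structure.find_residue(*site.ser.key, model=i_frame)
    return res.atom("OG").coords


def site_occupancy(
    traj: Trajectory,
    window: AnalysisWindow,
    site: CatalyticSite,
    species: str = "ligand",
    cutoff: float = 6.0,
) -> OccupancySeries:
    """Per-frame count of molecules with ≥1 heavy atom within ``cutoff`` of Ser OG."""
    keys = _species_keys(traj, species)
    idx = np.nonzero(window.mask(traj.times))[0]
    if len(idx) == 0:
        raise ValueError("analysis window contains no frames")
    counts = np.zeros(len(idx), dtype=int)
    for out_i, i in enumerate(idx):
        og = _site_og_coords(traj, site, i)
        model = traj.frame(i)
        lookup = {r.key: r for r in model}
        n = 0
        for key in keys:
            heavy = lookup[key].heavy_atoms()
            d = np.linalg.norm(coords_of(heavy) - og, axis=1)
            if (d <= cutoff).any():
                n += 1
        counts[out_i] = n
    return OccupancySeries(
        times=traj.times[idx], counts=counts, species=species, cutoff=cutoff
    )


def distance_series(
    traj: Trajectory,
    site: CatalyticSite,
    ligand_id: ResidueKey,
    smooth_width: int = 0,
) -> pd.DataFrame:
    """Per-frame OG–C7 and OG–C10 distances (Å) for one ligand copy.

    ``smooth_width`` > 1 applies a centered running mean of that window.
    """
    d7, d10 = [], []
    for i in range(traj.n_frames):
        og = _site_og_coords(traj, site, i)
        lig = traj.structure.find_residue(*ligand_id, model=i)
        d7.append(float(np.linalg.norm(lig.atom("C7").coords - og)))
        d10.append(float(np.linalg.norm(lig.atom("C10").coords - og)))
    df = pd.DataFrame({"time_ns": traj.times, "d_og_c7": d7, "d_og_c10": d10})
    if smooth_width > 1:
        for col in ("d_og_c7", "d_og_c10"):
            df[col] = df[col].rolling(smooth_width, center=True, min_periods=1).mean()
    return df


def spatial_distribution(
    traj: Trajectory,
    window: AnalysisWindow,
    species: str = "ligand",
    spacing: float = 1.0,
    superpose_protein: bool = True,
) -> Grid3D:
    """Occupancy-fraction grid (SDF): per voxel, the fraction of window
    frames in which ≥1 heavy atom of the species falls inside the voxel.

    Frames are first superposed onto the first window frame on protein
    heavy atoms, and the same rigid transform is applied to the species.
    """
    keys = _species_keys(traj, species)
    idx = np.nonzero(window.mask(traj.times))[0]
    if len(idx) == 0:
        raise ValueError("analysis window contains no frames")
    prot_keys = traj.protein_keys()
    ref = _selection_coords(traj.frame(idx[0]), prot_keys, None) if superpose_protein else None
    frames_pts: list[np.ndarray] = []
    for i in idx:
        model = traj.frame(i)
        lookup = {r.key: r for r in model}
        pts = np.vstack(
            [coords_of(lookup[key].heavy_atoms()) for key in keys]
        )
        if superpose_protein and ref is not None:
            P = _selection_coords(model, prot_keys, None)
            R, t, _ = kabsch(P, ref)
            pts = pts @ R.T + t
        frames_pts.append(pts)
    allpts = np.vstack(frames_pts)
    origin = np.floor(allpts.min(axis=0) / spacing) * spacing
    shape = np.floor((allpts.max(axis=0) - origin) / spacing).astype(int) + 1
    hits = np.zeros(tuple(shape), dtype=int)
    for pts in frames_pts:
        vox = np.floor((pts - origin) / spacing).astype(int)
        vox = np.unique(vox, axis=0)
        hits[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return Grid3D(origin=origin, spacing=spacing, values=hits / len(idx))
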