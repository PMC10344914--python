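"""Geometric factors of a protein–ligand complex.

Three of the four factors entering the weighted variant score are computed
here on a docked complex: the number of protein–ligand hydrogen bonds (B),
the serine nucleophilic-attack distance to the ligand's ester carbonyl
carbons C7/C10 (C), and the cavity volume enclosed between the ligand and
its 4 Å residue shell (D).  The fourth factor, the docking binding energy
(A), is ingested from an external docking run via a delimited table.

Hydrogen-bond detection is heavy-atom based by default (donor–acceptor
distance ≤ 3.5 Å between N/O atoms); when the input carries hydrogens, the
D–H···A angle criterion applies in addition.  The cavity detector is a
dual-probe grid method: cavity voxels are reachable by a small probe
(1.4 Å, water-sized) but not by a large probe (4.0 Å, bulk solvent), and do
not overlap any heavy-atom van der Waals sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    CatalyticSite,
    LigandPose,
    Structure,
    coords_of,
    select_within,
    vdw_radius,
)

log = logging.getLogger(__name__)

_POLAR_ELEMENTS = {"N", "O"}
_COVALENT_H_CUTOFF = 1.3  # Å; X-H bond detection


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``min_dha_angle`` (degrees, at the hydrogen) is applied only when
    hydrogens are present in the input; docking poses typically lack them.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("min_dha_angle must lie in (0, 180]")


@dataclass(frozen=True)
class CavityGrid:
    """Dual-probe grid parameters (Å)."""

    spacing: float = 0.6
    probe_in: float = 1.4
    probe_out: float = 4.0
    padding: float = 6.0
    min_cavity_volume: float = 5.0  # Å³; drops sliver components in surface crevices

    def __post_init__(self) -> None:
        if not (0 < self.spacing <= self.probe_in):
            raise ValueError("require 0 < spacing <= probe_in")
        if self.probe_out <= self.probe_in:
            raise ValueError("probe_out must exceed probe_in")


@dataclass
class FactorRecord:
    """The four per-variant factors feeding the weighted score."""

    variant_id: str
    A_binding_energy: float
    B_hbond_count: int
    C_attack_distance: float
    D_cavity_volume: float

    def __post_init__(self) -> None:
        if self.C_attack_distance < 0 or self.D_cavity_volume < 0:
            raise ValueError(f"{self.variant_id}: negative distance or volume")


# ---------------------------------------------------------------------------
# Hydrogen bonds


def _polar_heavy(atoms: list[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element.upper() in _POLAR_ELEMENTS]


def _attached_hydrogens(atom: Atom, pool: list[Atom]) -> list[Atom]:
    return [
        h
        for h in pool
        if h.is_hydrogen
        and np.linalg.norm(h.coords - atom.coords) <= _COVALENT_H_CUTOFF
    ]


def _angle_deg(at_vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    u, v = a - at_vertex, b - at_vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def count_hbonds(
    protein: Structure,
    ligand: LigandPose,
    criteria: HBondCriteria = HBondCriteria(),
    model: int = 0,
) -> int:
    """Count unique protein-atom/ligand-atom hydrogen-bond pairs.

    Both N and O heavy atoms are treated as donor/acceptor capable; a pair
    counts once regardless of direction.  With hydrogens present on either
    partner, at least one X-H must point at the other atom with a D-H···A
    angle ≥ the criterion; a pair where neither partner carries hydrogens
    falls back to the distance-only rule.
    """
    lig_res = ligand.residue
    lig_polar = _polar_heavy(lig_res.atoms)
    if not lig_polar:
        log.warning("ligand %s has no polar heavy atoms; 0 hydrogen bonds", ligand.pose_id)
        return 0
    prot_residues = [r for r in protein.residues(model) if r.key != lig_res.key]
    prot_polar: list[Atom] = []
    prot_atoms_all: list[Atom] = []
    for res in prot_residues:
        prot_atoms_all.extend(res.atoms)
        prot_polar.extend(_polar_heavy(res.atoms))
    if not prot_polar:
        return 0
    have_h = any(a.is_hydrogen for a in prot_atoms_all) or any(
        a.is_hydrogen for a in lig_res.atoms
    )
    tree = cKDTree(coords_of(prot_polar))
    count = 0
    for la in lig_polar:
        for idx in tree.query_ball_point(la.coords, criteria.max_da_distance):
            pa = prot_polar[idx]
            if not have_h:
                count += 1
                continue
            hs = _attached_hydrogens(pa, prot_atoms_all) + _attached_hydrogens(
                la, lig_res.atoms
            )
            if not hs:
                count += 1  # neither partner protonated: distance-only rule
                continue
            ok = False
            for h in hs:
                donor = pa if np.linalg.norm(h.coords - pa.coords) <= _COVALENT_H_CUTOFF else la
                acceptor = la if donor is pa else pa
                if _angle_deg(h.coords, donor.coords, acceptor.coords) >= criteria.min_dha_angle:
                    ok = True
                    break
            if ok:
                count += 1
    return count


# ---------------------------------------------------------------------------
# Serine attack distance


def attack_distance(
    protein: Structure,
    ligand: LigandPose,
    site: CatalyticSite,
    mode: str = "min",
) -> float | tuple[float, float]:
    """Distance from the catalytic Ser OG to the ligand carbonyl carbons.

    ``mode='both'`` returns the (OG–C7, OG–C10) pair; ``mode='min'`` (the
    scoring default) returns the smaller — nucleophilic attack proceeds on
    whichever ester carbonyl is closer.
    """
    og = site.og.coords
    try:
        c7 = ligand.residue.atom("C7").coords
    except KeyError:
        raise KeyError("ligand pose lacks atom C7") from None
    try:
        c10 = ligand.residue.atom("C10").coords
    except KeyError:
        raise KeyError("ligand pose lacks atom C10") from None
    d7 = float(np.linalg.norm(og - c7))
    d10 = float(np.linalg.norm(og - c10))
    if mode == "both":
        return (d7, d10)
    if mode == "min":
        return min(d7, d10)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Cavity volume


def _surface_distance(
    points: np.ndarray, centers: np.ndarray, radii: np.ndarray, chunk: int = 20000
) -> np.ndarray:
    """min over atoms of (||p - c|| - r): signed distance to the vdW surface."""
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        block = points[lo : lo + chunk]
        d = np.linalg.norm(block[:, None, :] - centers[None, :, :], axis=2) - radii[None, :]
        out[lo : lo + chunk] = d.min(axis=1)
    return out


def _covered_by_centers(
    points: np.ndarray, d_surf: np.ndarray, center_mask: np.ndarray, probe: float
) -> np.ndarray:
    """Voxels swept by a probe sphere whose center stays in the center set.

    A grid center ``c`` with clearance ``d_surf(c) >= probe`` certifies not
    just the dilation ball of radius ``probe`` but — because the surface
    distance field is 1-Lipschitz — every point within ``d_surf(c)`` of it:
    sliding the probe from ``c`` toward such a point keeps its clearance
    >= probe throughout.  Using the larger certified radius per center
    removes the quantization slivers a plain fixed-radius dilation leaves
    along curved boundaries.
    """
    centers = points[center_mask]
    if len(centers) == 0:
        return np.zeros(len(points), dtype=bool)
    tree = cKDTree(centers)
    dist, idx = tree.query(points, k=1)
    certified = d_surf[center_mask][idx]
    return (dist <= probe) | (dist <= certified)


def _bulk_mask(
    points: np.ndarray,
    d_surf: np.ndarray,
    probe: float,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Space the bulk-solvent probe can reach rolling in from the box edge.

    Probe centers (surface distance ≥ probe) are flood-filled from the grid
    boundary; only components touching the boundary count as bulk, so fully
    enclosed voids that happen to fit the probe remain cavities.  The bulk
    region is the boundary-connected centers dilated by their certified
    clearance radii (see :func:`_covered_by_centers`).
    """
    from scipy import ndimage

    centers3d = (d_surf >= probe).reshape(shape)
    labels, n = ndimage.label(centers3d)
    if n == 0:
        return np.zeros(len(points), dtype=bool)
    edge_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            edge_labels.update(np.unique(face[face > 0]).tolist())
    if not edge_labels:
        return np.zeros(len(points), dtype=bool)
    connected = np.isin(labels, sorted(edge_labels)).ravel()
    return _covered_by_centers(points, d_surf, connected, probe)


def cavity_volume(
    protein: Structure,
    ligand: LigandPose,
    grid: CavityGrid = CavityGrid(),
    shell_cutoff: float = 4.0,
    model: int = 0,
) -> float:
    """Cavity volume (Å³) between the ligand and its residue shell.

    The grid is restricted to the sub-box enclosing the ligand plus the
    protein residues within ``shell_cutoff`` of it.  A voxel belongs to the
    cavity when the small probe can sweep it, the large (bulk) probe cannot
    reach it rolling in from outside the box, and it overlaps no heavy-atom
    van der Waals sphere.  Volume is voxel count × spacing³ and is monotone
    non-increasing in ``probe_in``.
    """
    lig_heavy = ligand.residue.heavy_atoms()
    shell = select_within(
        protein, lig_heavy, shell_cutoff, model=model, exclude=[ligand.residue.key]
    )
    if not shell:
        log.warning("no protein residues within %.1f Å of ligand; cavity 0", shell_cutoff)
        return 0.0
    atoms = list(lig_heavy)
    for res in shell:
        atoms.extend(res.heavy_atoms())
    centers = coords_of(atoms)
    radii = np.array([vdw_radius(a.element) for a in atoms])
    lo = centers.min(axis=0) - grid.padding
    hi = centers.max(axis=0) + grid.padding
    axes = [np.arange(lo[i], hi[i] + grid.spacing / 2, grid.spacing) for i in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    d_surf = _surface_distance(points, centers, radii)
    free = d_surf > 0
    shape = tuple(len(ax) for ax in axes)
    open_in = _covered_by_centers(points, d_surf, d_surf >= grid.probe_in, grid.probe_in)
    bulk = _bulk_mask(points, d_surf, grid.probe_out, shape)
    cavity = (free & open_in & ~bulk).reshape(shape)
    # The probe-size differential leaves thin slivers along surface crevices;
    # a minimum-volume filter on connected components keeps real cavities only.
    from scipy import ndimage

    labels, n = ndimage.label(cavity)
    if n == 0:
        return 0.0
    voxel = grid.spacing**3
    sizes = ndimage.sum_labels(cavity, labels, index=np.arange(1, n + 1))
    keep = sizes * voxel >= grid.min_cavity_volume
    return float(sizes[keep].sum()) * voxel


# ---------------------------------------------------------------------------
# Assembly


def read_binding_energies(table: str | Path | pd.DataFrame) -> pd.Series:
    """Binding-energy table keyed by ``variant_id`` (kcal/mol)."""
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table)
    if not {"variant_id", "binding_energy_kcal_mol"} <= set(table.columns):
        raise ValueError(
            "binding-energy table needs columns variant_id, binding_energy_kcal_mol"
        )
    if table["variant_id"].duplicated().any():
        dup = table.loc[table["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant_id in binding-energy table: {dup}")
    return table.set_index("variant_id")["binding_energy_kcal_mol"]


def assemble_factors(
    variant_id: str,
    protein: Structure,
    ligand: LigandPose,
    site: CatalyticSite,
    criteria: HBondCriteria = HBondCriteria(),
    grid: CavityGrid = CavityGrid(),
    binding_energy_table: str | Path | pd.DataFrame | pd.Series | None = None,
    shell_cutoff: float = 4.0,
) -> FactorRecord:
    """Combine computed B, C, D with the ingested binding energy A."""
    if binding_energy_table is None:
        if ligand.binding_energy is None:
            raise ValueError(f"{variant_id}: no binding energy on pose or in table")
        energy = float(ligand.binding_energy)
    else:
        energies = (
            binding_energy_table
            if isinstance(binding_energy_table, pd.Series)
            else read_binding_energies(binding_energy_table)
        )
        if variant_id not in energies.index:
            raise KeyError(
                f"variant {variant_id!r} missing from binding-energy table; "
                f"available: {list(energies.index)}"
            )
        energy = float(energies.loc[variant_id])
    return FactorRecord(
        variant_id=variant_id,
        A_binding_energy=energy,
        B_hbond_count=count_hbonds(protein, ligand, criteria),
        C_attack_distance=float(attack_distance(protein, ligand, site, mode="min")),
        D_cavity_volume=cavity_volume(protein, ligand, grid, shell_cutoff),
    )
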