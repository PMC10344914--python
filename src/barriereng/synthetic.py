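"""Seeded synthetic fixtures for every stage of the pipeline.

No deposited data is required anywhere in the package: this module builds a
pocket-bearing toy protein with a designated catalytic serine, an idealized
BHET ligand with named ester carbonyl carbons C7/C10, trajectories with a
prescribed number of substrate copies whose binding-site occupancy follows a
known schedule, per-variant factor tables with a designated dominating
variant, and noisy exponential-decay / Michaelis–Menten datasets with known
parameters.

Defaults mirror the simulated study conditions the analyses assume: 30
substrate copies, frames stored every 0.5 ns over 100 ns (so "the last
40 ns" is the window 60–100 ns), decay sampled every 0.5 h, and a kinetics
design spanning 0.8–15 mM.  Every generator is a pure function of its
configuration: the same seed yields byte-identical output.  Physical realism
is deliberately minimal — geometry, names and numbering are what downstream
operations consume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .assay_models import DecayDataset, KineticsDataset
from .pocket_metrics import FactorRecord
from .structure_io import Atom, CatalyticSite, LigandPose, Residue, Structure
from .trajectory_metrics import Trajectory

log = logging.getLogger(__name__)

DEFAULT_KINETICS_DESIGN = (0.8, 1.5, 3.0, 6.0, 10.0, 15.0)  # mM


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic builders; the seed fixes all randomness."""

    seed: int = 0
    n_residues: int = 60
    n_ligands: int = 30
    n_waters: int = 60
    frame_interval_ns: float = 0.5
    duration_ns: float = 100.0
    occupancy_schedule: list[tuple[float, float, int]] = field(default_factory=list)
    site_cutoff: float = 6.0
    protein_sigma: float = 0.1     # Å, per-frame Gaussian jitter on protein atoms
    ligand_step: float = 1.0       # Å, rigid random-walk step per frame
    box_margin: float = 8.0        # Å, box beyond the protein bounding box

    def __post_init__(self) -> None:
        windows = sorted(self.occupancy_schedule)
        for (s0, e0, _), (s1, e1, _) in zip(windows, windows[1:]):
            if s1 < e0:
                raise ValueError("occupancy schedule windows overlap")
        for s, e, count in self.occupancy_schedule:
            if not (0 <= s < e):
                raise ValueError(f"bad schedule window ({s}, {e})")
            if e > self.duration_ns:
                raise ValueError("schedule window exceeds trajectory duration")
            if count > self.n_ligands:
                raise ValueError("scheduled count exceeds number of ligands")


# ---------------------------------------------------------------------------
# Toy protein


def build_toy_protein(cfg: GeneratorConfig = GeneratorConfig()) -> Structure:
    """Pocket-bearing toy protein: a solenoid wall around a central cavity.

    Backbone positions follow a local α-helix parameterization (1.5 Å rise,
    100° phase per residue) whose axis is wound around a circle, so the
    coiled wall encloses a pocket at the origin.  One mid-wall residue is a
    SER whose OG atom points into the pocket mouth; every other residue is
    ALA.  Deterministic per seed (a small seeded jitter distinguishes seeds).
    """
    if cfg.n_residues < 20:
        raise ValueError("need at least 20 residues for a pocket-bearing protein")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_residues
    rise, phase_step = 1.5, np.deg2rad(100.0)
    helix_r = 2.3
    axis_r0 = 7.0
    theta = 0.0
    ca = np.empty((n, 3))
    for i in range(n):
        axis_r = axis_r0 + 0.8 * theta / (2 * np.pi)  # slight outward drift per turn
        nhat = np.array([np.cos(theta), np.sin(theta), 0.0])
        axis_pt = axis_r * nhat
        phi = i * phase_step
        ca[i] = axis_pt + helix_r * (np.cos(phi) * nhat + np.sin(phi) * np.array([0, 0, 1.0]))
        theta += rise / axis_r
    ca += rng.normal(0.0, 0.05, size=ca.shape)

    ser_index = n // 2
    residues: list[Residue] = []
    serial = 1
    for i in range(n):
        base = ca[i]
        outward = base / max(np.linalg.norm(base), 1e-9)
        atoms = [
            Atom("N", "N", base + np.array([-1.2, 0.3, 0.4]), serial),
            Atom("CA", "C", base, serial + 1),
            Atom("C", "C", base + np.array([1.3, 0.2, -0.3]), serial + 2),
            Atom("O", "O", base + np.array([1.8, 1.2, -0.5]), serial + 3),
        ]
        serial += 4
        name = "ALA"
        if i == ser_index:
            name = "SER"
            og = base - 3.0 * outward  # into the pocket mouth
            og[2] = base[2]
            atoms.append(Atom("OG", "O", og, serial))
            serial += 1
        residues.append(Residue(chain="A", seq_id=i + 1, res_name=name, atoms=atoms))
    return Structure(models=[residues], header=f"toy solenoid protein seed={cfg.seed}")


def toy_catalytic_site(protein: Structure) -> CatalyticSite:
    """The designated SER of a toy protein."""
    for res in protein.residues(0):
        if res.res_name == "SER" and res.has_atom("OG"):
            return CatalyticSite(ser=res, label=f"SER{res.seq_id}")
    raise ValueError("toy protein has no SER with OG")


# ---------------------------------------------------------------------------
# BHET ligand


def _bhet_template() -> list[tuple[str, str, np.ndarray]]:
    """Idealized planar BHET (C12H14O6: 18 heavy atoms), centered on the ring.

    The terephthalate ring lies in the xy-plane; C7 and C10 are the two
    ester carbonyl carbons on the para axis (through-space span ≈ 5.76 Å).
    Hydroxyethyl tails are bent out of plane with chemically normal bond
    lengths (1.2–1.6 Å).
    """
    rb = 1.39  # aromatic C-C
    ring = []
    for i in range(6):
        ang = np.deg2rad(60 * i)
        ring.append((f"C{i+1}", "C", np.array([rb * np.cos(ang), rb * np.sin(ang), 0.0])))
    # ring: C1 at (+1.39, 0, 0), C4 at (-1.39, 0, 0) -- the para axis is x.
    x1, x4 = ring[0][2], ring[3][2]

    def tail(attach: np.ndarray, sign: float, c_carbonyl: str, names: tuple[str, ...]):
        ax = np.array([sign, 0.0, 0.0])
        c = attach + 1.49 * ax                                  # carbonyl carbon
        o_dbl = c + 1.22 * np.array([sign * 0.5, 0.866, 0.0])   # C=O
        o_est = c + 1.34 * np.array([sign * 0.5, -0.866, 0.0])  # ester O
        ch2a = o_est + 1.43 * np.array([sign * 0.94, -0.2, 0.28])
        ch2b = ch2a + 1.52 * np.array([sign * 0.64, 0.5, 0.59])
        o_h = ch2b + 1.43 * np.array([sign * 0.8, -0.3, 0.52])
        return [
            (c_carbonyl, "C", c),
            (names[0], "O", o_dbl),
            (names[1], "O", o_est),
            (names[2], "C", ch2a),
            (names[3], "C", ch2b),
            (names[4], "O", o_h),
        ]

    atoms = list(ring)
    atoms += tail(x1, +1.0, "C7", ("O1", "O2", "C8", "C9", "O3"))
    atoms += tail(x4, -1.0, "C10", ("O4", "O5", "C11", "C12", "O6"))
    return atoms


def build_bhet_ligand(
    center: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    seq_id: int = 1,
    chain: str = "L",
    binding_energy: float | None = None,
) -> LigandPose:
    """Idealized BHET pose translated so its ring centroid sits at ``center``."""
    center = np.asarray(center, float)
    template = _bhet_template()
    centroid = np.mean([xyz for _, _, xyz in template[:6]], axis=0)
    atoms = [
        Atom(name, element, xyz - centroid + center, serial=i + 1)
        for i, (name, element, xyz) in enumerate(template)
    ]
    res = Residue(chain=chain, seq_id=seq_id, res_name="BHT", atoms=atoms, is_hetatm=True)
    return LigandPose(residue=res, binding_energy=binding_energy, pose_id=f"BHT:{seq_id}")


# ---------------------------------------------------------------------------
# Trajectory


def _scheduled_count(cfg: GeneratorConfig, t: float) -> int:
    for s, e, count in cfg.occupancy_schedule:
        if s <= t <= e:
            return count
    return 0


def simulate_trajectory(
    protein: Structure, cfg: GeneratorConfig = GeneratorConfig()
) -> tuple[Trajectory, dict]:
    """Frame series with scheduled substrate occupancy at the Ser site.

    Substrate copies perform seeded rigid random walks inside a reflective
    box around the protein; during each schedule window the first ``count``
    copies are parked inside the site cutoff of the Ser OG while all free
    copies are kept out of an exclusion zone around it, so the analysis-side
    occupancy count reproduces the schedule exactly.  Waters (single-oxygen
    molecules) walk freely.  Protein atoms receive per-frame Gaussian jitter
    of ``protein_sigma`` Å for RMSF testing.  Returns the trajectory and a
    ground-truth manifest.
    """
    rng = np.random.default_rng(cfg.seed)
    site = toy_catalytic_site(protein)
    og0 = site.og.coords.copy()
    prot_xyz = np.vstack([a.coords for r in protein.residues(0) for a in r.atoms])
    lo = prot_xyz.min(axis=0) - cfg.box_margin
    hi = prot_xyz.max(axis=0) + cfg.box_margin
    times = np.arange(0.0, cfg.duration_ns + cfg.frame_interval_ns / 2, cfg.frame_interval_ns)

    template = build_bhet_ligand().residue  # reused geometry, translated per copy
    ligand_extent = max(
        float(np.linalg.norm(a.coords)) for a in template.heavy_atoms()
    )
    # Free walkers keep their *center* outside this radius of the OG so that
    # no heavy atom of an unscheduled copy can cross the site cutoff.
    exclusion = cfg.site_cutoff + ligand_extent + 0.5

    def random_far_point() -> np.ndarray:
        while True:
            p = rng.uniform(lo, hi)
            if np.linalg.norm(p - og0) > exclusion + 2.0:
                return p

    lig_centers = np.vstack([random_far_point() for _ in range(cfg.n_ligands)])
    wat_centers = rng.uniform(lo, hi, size=(cfg.n_waters, 3))

    models: list[list[Residue]] = []
    serial_base = max(a.serial for r in protein.residues(0) for a in r.atoms)
    for t in times:
        count = _scheduled_count(cfg, t)
        # advance free walkers; re-reflect out of the exclusion zone
        step = rng.normal(0.0, cfg.ligand_step, size=lig_centers.shape)
        lig_centers = np.clip(lig_centers + step, lo, hi)
        for j in range(cfg.n_ligands):
            if j >= count:
                d = lig_centers[j] - og0
                r = np.linalg.norm(d)
                if r < exclusion:
                    lig_centers[j] = og0 + d / max(r, 1e-9) * (exclusion + 1.0)
        wat_centers = np.clip(wat_centers + rng.normal(0.0, cfg.ligand_step, wat_centers.shape), lo, hi)

        frame: list[Residue] = []
        for res in protein.residues(0):
            atoms = [
                Atom(a.name, a.element,
                     a.coords + rng.normal(0.0, cfg.protein_sigma, 3) if cfg.protein_sigma > 0 else a.coords.copy(),
                     a.serial)
                for a in res.atoms
            ]
            frame.append(Residue(res.chain, res.seq_id, res.res_name, atoms,
                                 res.insertion_code, res.is_hetatm))
        serial = serial_base
        for j in range(cfg.n_ligands):
            if j < count:  # parked inside the site this frame
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                center = og0 + u * (0.3 * cfg.site_cutoff * rng.uniform(0.2, 1.0))
            else:
                center = lig_centers[j]
            atoms = [
                Atom(a.name, a.element, a.coords + center, serial := serial + 1)
                for a in template.atoms
            ]
            frame.append(Residue("L", j + 1, "BHT", atoms, is_hetatm=True))
        for j in range(cfg.n_waters):
            frame.append(
                Residue("W", j + 1, "HOH",
                        [Atom("O", "O", wat_centers[j].copy(), serial := serial + 1)],
                        is_hetatm=True)
            )
        models.append(frame)

    structure = Structure(models=models, header=f"synthetic trajectory seed={cfg.seed}")
    traj = Trajectory(
        structure=structure,
        times=times,
        ligand_ids=[("L", j + 1, "") for j in range(cfg.n_ligands)],
        water_ids=[("W", j + 1, "") for j in range(cfg.n_waters)],
    )
    manifest = {
        "seed": cfg.seed,
        "ser_seq_id": site.ser.seq_id,
        "site_cutoff": cfg.site_cutoff,
        "frame_interval_ns": cfg.frame_interval_ns,
        "duration_ns": cfg.duration_ns,
        "n_ligands": cfg.n_ligands,
        "n_waters": cfg.n_waters,
        "occupancy_schedule": [list(w) for w in cfg.occupancy_schedule],
    }
    return traj, manifest


# ---------------------------------------------------------------------------
# Factor tables and assay datasets


def simulate_factor_table(
    n_variants: int, cfg: GeneratorConfig = GeneratorConfig(), labels: list[str] | None = None
) -> tuple[list[FactorRecord], str]:
    """Random factor records with one designated variant dominating all four
    factors (most negative energy, most hydrogen bonds, shortest attack
    distance, largest cavity).  Returns (records, dominator id)."""
    if n_variants < 2:
        raise ValueError("need at least 2 variants")
    rng = np.random.default_rng(cfg.seed)
    ids = labels if labels is not None else [f"V{i+1}" for i in range(n_variants)]
    if len(ids) != n_variants:
        raise ValueError("labels length must equal n_variants")
    A = rng.uniform(-8.0, -5.0, n_variants)
    B = rng.integers(1, 6, n_variants).astype(float)
    C = rng.uniform(3.5, 8.0, n_variants)
    D = rng.uniform(150.0, 400.0, n_variants)
    best = int(rng.integers(0, n_variants))
    A[best] = A.min() - 0.5
    B[best] = B.max() + 1
    C[best] = max(C.min() - 0.4, 0.1)
    D[best] = D.max() + 25.0
    records = [
        FactorRecord(ids[i], float(A[i]), int(B[i]), float(C[i]), float(D[i]))
        for i in range(n_variants)
    ]
    return records, ids[best]


def simulate_decay(
    k: float,
    noise: float = 0.0,
    seed: int = 0,
    t_max_h: float = 10.0,
    dt_h: float = 0.5,
    e0: float = 1.0,
) -> DecayDataset:
    """Exponential decay sampled every ``dt_h`` hours with multiplicative
    log-normal noise; ``noise=0`` returns exact model values."""
    if k <= 0:
        raise ValueError("k must be positive")
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max_h + dt_h / 2, dt_h)
    act = e0 * np.exp(-k * t)
    if noise > 0:
        act = act * np.exp(rng.normal(0.0, noise, size=t.shape))
    return DecayDataset(times=t, activities=act)


def simulate_kinetics(
    K_M: float,
    Vmax: float,
    design: tuple[float, ...] = DEFAULT_KINETICS_DESIGN,
    noise: float = 0.0,
    seed: int = 0,
) -> KineticsDataset:
    """Michaelis–Menten rates over a substrate design (default 0.8–15 mM)
    with multiplicative log-normal noise; ``noise=0`` is exact."""
    if K_M <= 0 or Vmax <= 0:
        raise ValueError("K_M and Vmax must be positive")
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    rng = np.random.default_rng(seed)
    s = np.asarray(design, float)
    v = Vmax * s / (K_M + s)
    if noise > 0:
        v = v * np.exp(rng.normal(0.0, noise, size=s.shape))
    return KineticsDataset(substrate=s, rates=v)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
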