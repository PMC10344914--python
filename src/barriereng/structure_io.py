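"""Minimal structural data model with PDB readers/writers and selections.

The package works on heavy-atom geometry only: hydrogens are tolerated on
input but ignored by every distance-based operation.  Author residue
numbering (the numbers printed in PDB columns 23-26) is authoritative
throughout; internal indices are never exposed.

Parsing is delegated to :mod:`gemmi`; the result is converted into a small
immutable-ish data model (`Atom`/`Residue`/`Structure`) that the rest of the
package consumes.  Multi-model files (MODEL/ENDMDL blocks) become the frame
list of a trajectory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

#: Fixed internal van der Waals radii (Å); deterministic, no external dependency.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW_RADIUS = 1.70

#: Atomic masses (u) for the elements the toy systems contain.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06,
}
DEFAULT_MASS = 12.011

_HYDROGEN_ELEMENTS = {"H", "D"}


class StructureError(ValueError):
    """Invalid structural data."""


class StructureParseError(StructureError):
    """A file could not be parsed as the requested format."""


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


@dataclass
class Atom:
    """A single atom: label, element, Å coordinates and PDB bookkeeping."""

    name: str
    element: str
    coords: np.ndarray
    serial: int = 1
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise StructureError(f"atom {self.name!r}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: non-finite coordinates")
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if self.serial <= 0:
            raise StructureError(f"atom {self.name!r}: serial must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """A residue keyed by (chain, author seq_id, insertion code)."""

    chain: str
    seq_id: int
    res_name: str
    atoms: list[Atom]
    insertion_code: str = ""
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(
                f"residue {self.res_name} {self.chain}{self.seq_id}: no atoms"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_id, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"residue {self.res_name} {self.chain}{self.seq_id} has no atom {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Structure:
    """One or more models sharing residue topology (frames of a trajectory)."""

    models: list[list[Residue]]
    header: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise StructureError("a Structure needs at least one model")
        for model in self.models:
            seen: set[tuple[str, int, str]] = set()
            for res in model:
                if res.key in seen:
                    raise StructureError(f"duplicate residue key {res.key}")
                seen.add(res.key)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residues(self, model: int = 0) -> list[Residue]:
        return self.models[model]

    def chains(self, model: int = 0) -> list[str]:
        out: list[str] = []
        for res in self.models[model]:
            if res.chain not in out:
                out.append(res.chain)
        return out

    def find_residue(
        self, chain: str, seq_id: int, insertion_code: str = "", model: int = 0
    ) -> Residue:
        for res in self.models[model]:
            if res.key == (chain, seq_id, insertion_code):
                return res
        raise KeyError(f"no residue {chain}{seq_id}{insertion_code!r} in model {model}")


@dataclass
class LigandPose:
    """A single-residue ligand instance, optionally with a docking energy.

    Binding energies (kcal/mol) are ingested from an external docking run;
    this package never computes them.  Poses that feed the serine attack
    distance must carry atoms named C7 and C10 (the two ester carbonyl
    carbons of BHET).
    """

    residue: Residue
    binding_energy: float | None = None
    pose_id: str = ""


@dataclass
class CatalyticSite:
    """The nucleophilic serine (with its OG hydroxyl oxygen) and optional triad."""

    ser: Residue
    other_triad: tuple[Residue, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if not self.ser.has_atom("OG"):
            raise StructureError(
                f"catalytic Ser {self.ser.chain}{self.ser.seq_id} has no OG atom"
            )

    @property
    def og(self) -> Atom:
        return self.ser.atom("OG")


# ---------------------------------------------------------------------------
# Reading / writing


def _prevalidate_pdb(path: Path) -> None:
    """Cheap line scan so malformed coordinate records fail with a line number."""
    text = path.read_text()
    if not text.strip():
        raise StructureParseError(f"{path}: empty file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise StructureParseError(
                    f"{path}: line {lineno}: truncated coordinate record"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}: line {lineno}: unparseable coordinates ({exc})"
                ) from None


def _dedup_altlocs(atoms: list[tuple[str, gemmi.Atom]]) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name; warn when dropping."""
    by_name: dict[str, gemmi.Atom] = {}
    dropped = False
    for name, atom in atoms:
        prev = by_name.get(name)
        if prev is None:
            by_name[name] = atom
        else:
            dropped = True
            if atom.occ > prev.occ:
                by_name[name] = atom
    if dropped:
        log.warning("alternate conformers present; kept highest-occupancy atoms")
    return list(by_name.values())


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    MODEL/ENDMDL blocks map to models; HETATM records become ligand-capable
    residues (``is_hetatm=True``); author numbering is kept verbatim.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise StructureParseError(f"{path}: {exc}") from exc
    models: list[list[Residue]] = []
    for g_model in st:
        residues: list[Residue] = []
        for g_chain in g_model:
            for g_res in g_chain:
                raw = [(a.name, a) for a in g_res]
                kept = _dedup_altlocs(raw)
                atoms = [
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        serial=max(a.serial, 1),
                        occupancy=a.occ,
                        b_factor=a.b_iso,
                    )
                    for a in kept
                ]
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        chain=g_chain.name,
                        seq_id=g_res.seqid.num,
                        res_name=g_res.name,
                        atoms=atoms,
                        insertion_code=(g_res.seqid.icode or "").strip(),
                        is_hetatm=g_res.het_flag == "H",
                    )
                )
        models.append(residues)
    if not models or not any(models):
        raise StructureParseError(f"{path}: no coordinate records")
    return Structure(models=models, header=st.name or "")


def _format_atom_line(
    record: str, serial: int, atom: Atom, res: Residue
) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) < 2:
        name = " " + name
    return (
        f"{record:<6s}{serial:>5d} {name:<4s} {res.res_name:>3s} "
        f"{res.chain[:1]:1s}{res.seq_id:>4d}{(res.insertion_code or ' '):1s}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
        f"{atom.element.upper():>2s}"
    )


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as PDB; multi-model structures get MODEL/ENDMDL blocks.

    Round-trips through :func:`read_structure` preserve coordinates to the
    0.001 Å precision of the format.
    """
    path = Path(path)
    lines: list[str] = []
    multi = s.n_models > 1
    for i_model, model in enumerate(s.models, start=1):
        if multi:
            lines.append(f"MODEL     {i_model:>4d}")
        serial = 0
        for res in model:
            record = "HETATM" if res.is_hetatm else "ATOM"
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line(record, serial, atom, res))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence and geometry helpers


def extract_sequence(s: Structure, chain: str, model: int = 0) -> tuple[str, list[int]]:
    """One-letter sequence and parallel author-number list for a polymer chain.

    Unknown residue names map to ``'X'``; HETATM residues (ligands, waters)
    are excluded.
    """
    from Bio.SeqUtils import seq1

    residues = [
        r for r in s.residues(model) if r.chain == chain and not r.is_hetatm
    ]
    if not residues:
        raise KeyError(f"no polymer chain {chain!r} in model {model}")
    seq = "".join(seq1(r.res_name, undef_code="X") or "X" for r in residues)
    numbering = [r.seq_id for r in residues]
    return seq, numbering


def coords_of(atoms: Iterable[Atom]) -> np.ndarray:
    pts = [a.coords for a in atoms]
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def select_within(
    s: Structure,
    center: Sequence[Atom],
    cutoff: float,
    model: int = 0,
    exclude: Iterable[tuple[str, int, str]] = (),
) -> list[Residue]:
    """Residues with ≥1 heavy atom within ``cutoff`` Å of any center atom.

    ``exclude`` drops residues by key (typically the ligand itself).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    center = list(center)
    if not center:
        raise ValueError("center atom set is empty")
    excluded = set(exclude)
    center_xyz = coords_of(center)
    tree = cKDTree(center_xyz)
    out: list[Residue] = []
    for res in s.residues(model):
        if res.key in excluded:
            continue
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        d, _ = tree.query(coords_of(heavy), k=1)
        if np.min(d) <= cutoff:
            out.append(res)
    return out


def extract_ligand(
    s: Structure, res_name: str, model: int = 0, seq_id: int | None = None
) -> LigandPose:
    """Pull a single-residue ligand out of a structure.

    A ligand is exactly one residue; multiple matches require ``seq_id``.
    """
    matches = [
        r
        for r in s.residues(model)
        if r.res_name == res_name and (seq_id is None or r.seq_id == seq_id)
    ]
    if not matches:
        raise KeyError(f"no ligand residue named {res_name!r} in model {model}")
    if len(matches) > 1:
        raise StructureError(
            f"{len(matches)} residues named {res_name!r}; pass seq_id to pick one"
        )
    return LigandPose(residue=matches[0], pose_id=f"{res_name}:{matches[0].seq_id}")


def find_serine_sites(s: Structure, model: int = 0) -> list[CatalyticSite]:
    """All SER residues carrying an OG atom (candidate nucleophiles)."""
    sites = []
    for res in s.residues(model):
        if res.res_name == "SER" and res.has_atom("OG"):
            sites.append(CatalyticSite(ser=res, label=f"SER{res.seq_id}"))
    return sites
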