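"""Structure I/O and geometric primitives.

Reads and writes multi-model PDB (and reads mmCIF) coordinate files for
conformational ensembles, provides deterministic atom selections, Kabsch
least-squares superposition, fit-free RMSD, and buried solvent-accessible
surface area between two chains via Shrake-Rupley sphere sampling on a
deterministic Fibonacci lattice.

Conventions: coordinates in Angstrom; residue numbers are author numbering
as read (no renumbering); insertion codes are rejected; for alternate
locations the highest-occupancy conformer is kept (tie: first in file).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("gatescape")

__all__ = [
    "AtomRecord",
    "StructureModel",
    "GroupSpec",
    "SuperpositionResult",
    "StructureError",
    "ReadError",
    "SelectionError",
    "DegenerateGeometryError",
    "read_models",
    "write_models",
    "select_atoms",
    "select_coords",
    "superpose",
    "apply_transform",
    "rmsd_unaligned",
    "sasa",
    "buried_interface_area",
    "fibonacci_sphere",
    "VDW_RADII",
]


class StructureError(Exception):
    """Base class for structural errors."""


class ReadError(StructureError):
    """A coordinate file could not be parsed into valid models."""


class SelectionError(StructureError):
    """A residue selection could not be resolved on a model."""


class DegenerateGeometryError(StructureError):
    """Geometry too degenerate for the requested operation."""


# Van der Waals radii (Angstrom) keyed by element symbol, from the widely
# used Bondi compilation. Unknown elements are an error, never a default.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structural model.

    ``het`` marks atoms read from (or to be written as) HETATM records so
    that ligand poses survive a PDB round trip.
    """

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    het: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise StructureError(
                f"non-finite coordinates for atom {self.key()}: {self.coords}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def key(self) -> tuple[str, int, str]:
        """Identity key (chain, residue number, atom name); unique per model."""
        return (self.chain_id, self.res_seq, self.atom_name)


@dataclass
class StructureModel:
    """One conformer: an ordered list of atoms plus free-form metadata."""

    model_id: str
    atoms: list[AtomRecord]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"model {self.model_id!r} has no atoms")

    def validate_unique(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            k = a.key()
            if k in seen:
                raise ReadError(
                    f"model {self.model_id!r}: duplicate atom {k}"
                )
            seen.add(k)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray, model_id: str | None = None) -> "StructureModel":
        """Copy of this model with replaced coordinates (same atom identities)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(a.chain_id, a.res_seq, a.res_name, a.atom_name,
                       a.element, (float(x), float(y), float(z)), a.het)
            for a, (x, y, z) in zip(self.atoms, xyz)
        ]
        return StructureModel(model_id or self.model_id, atoms, dict(self.meta))


@dataclass(frozen=True)
class GroupSpec:
    """A residue-group selection: one chain, a set of residue numbers.

    ``heavy_only`` (default) drops hydrogens/deuteriums. Selecting a group
    on a model missing any listed residue is an error, never an empty set.
    """

    chain_id: str
    residues: frozenset[int]
    heavy_only: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", frozenset(int(r) for r in self.residues))
        if not self.residues:
            raise SelectionError("GroupSpec requires a non-empty residue set")


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform x -> R @ x + t mapping mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or abs(np.linalg.det(R) - 1) > 1e-8:
            raise StructureError("rotation is not a proper orthonormal matrix")
        if self.rmsd < 0:
            raise StructureError("negative RMSD")


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _convert_gemmi_model(gmodel: gemmi.Model, model_id: str) -> StructureModel:
    atoms: list[AtomRecord] = []
    for chain in gmodel:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise ReadError(
                    f"model {model_id!r}: insertion code {res.seqid.icode!r} at "
                    f"{chain.name}/{res.seqid.num} is not supported"
                )
            het = res.het_flag == "H"
            # altloc collapse: keep the highest-occupancy conformer per atom
            # name; ties resolved to the first occurrence in file order.
            # Repeated atom names WITHOUT altloc codes are true duplicates.
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif not atom.has_altloc() and not prev.has_altloc():
                    raise ReadError(
                        f"model {model_id!r}: duplicate atom "
                        f"{(chain.name, res.seqid.num, atom.name)}"
                    )
                elif atom.occ > prev.occ:
                    logger.debug(
                        "altloc: keeping occ=%.2f over %.2f for %s/%s/%s",
                        atom.occ, prev.occ, chain.name, res.seqid.num, atom.name,
                    )
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                el = atom.element.name.upper()
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        res_name=res.name,
                        atom_name=name,
                        element=el,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        het=het,
                    )
                )
    model = StructureModel(model_id, atoms)
    model.validate_unique()
    return model


def read_models(path: str | Path, format: str | None = None) -> list[StructureModel]:
    """Read all models from a PDB or mmCIF file.

    MODEL/ENDMDL blocks delimit models; a single-model file yields one
    model. HETATM records are retained with their residue names. Model ids
    are ``<stem>#<index>`` (1-based, matching PDB MODEL serials where given).
    """
    path = Path(path)
    if not path.exists():
        raise ReadError(f"no such file: {path}")
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ReadError(f"{path}: {exc}") from exc
    models: list[StructureModel] = []
    for i, gmodel in enumerate(st, start=1):
        mid = f"{path.stem}#{i}"
        models.append(_convert_gemmi_model(gmodel, mid))
    if not models:
        raise ReadError(f"{path}: no models found")
    return models


def _pdb_atom_line(serial: int, a: AtomRecord) -> str:
    record = "HETATM" if a.het else "ATOM  "
    name = a.atom_name
    # PDB atom-name column convention: element right-justified in cols 13-14
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.coords
    return (
        f"{record}{serial:5d} {name:<4s}{'':1s}{a.res_name:>3s} {a.chain_id:1s}"
        f"{a.res_seq:4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_models(models: Sequence[StructureModel], path: str | Path) -> None:
    """Write models as a multi-model PDB file (deterministic byte output)."""
    path = Path(path)
    multi = len(models) > 1
    lines: list[str] = []
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        serial = 0
        for a in model.atoms:
            serial += 1
            lines.append(_pdb_atom_line(serial, a))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_atoms(model: StructureModel, spec: GroupSpec) -> list[AtomRecord]:
    """All atoms of the listed residues, deterministically ordered.

    Order is by residue number, then file order within a residue. A residue
    listed in the group but absent from the model is an error listing the
    missing numbers.
    """
    by_res: dict[int, list[AtomRecord]] = {r: [] for r in sorted(spec.residues)}
    for a in model.atoms:
        if a.chain_id == spec.chain_id and a.res_seq in by_res:
            if spec.heavy_only and a.is_hydrogen:
                continue
            by_res[a.res_seq].append(a)
    missing = sorted(r for r, atoms in by_res.items() if not atoms)
    if missing:
        raise SelectionError(
            f"model {model.model_id!r}: chain {spec.chain_id!r} is missing "
            f"residues {missing}"
        )
    return [a for r in sorted(by_res) for a in by_res[r]]


def select_coords(model: StructureModel, specs: GroupSpec | Iterable[GroupSpec]) -> np.ndarray:
    """Concatenated (n, 3) coordinates for one or more GroupSpecs."""
    if isinstance(specs, GroupSpec):
        specs = [specs]
    atoms: list[AtomRecord] = []
    for spec in specs:
        atoms.extend(select_atoms(model, spec))
    return np.array([a.coords for a in atoms], dtype=float)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares superposition of paired coordinate sets.

    Returns the proper rigid transform minimizing the RMSD of
    ``R @ mobile + t`` to ``reference``. Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"paired (n, 3) coordinate sets required, got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the line undetermined
    spread = np.linalg.svd(P, compute_uv=False)
    if spread[1] <= 1e-8 * max(spread[0], 1.0):
        raise DegenerateGeometryError("collinear or degenerate coordinate set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def rmsd_unaligned(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of paired coordinates with no superposition ("without fitting")."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired coordinate sets required, got {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit-sphere points from the golden-angle lattice (no RNG)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(atoms: Sequence[AtomRecord]) -> np.ndarray:
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in VDW_RADII:
            raise StructureError(f"no van der Waals radius for element {el!r}")
        radii[i] = VDW_RADII[el]
    return radii


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area (Angstrom^2).

    Sphere points come from a fixed Fibonacci lattice, so the result is
    bit-stable for a given ``n_points``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(coords) != len(radii):
        raise ValueError("coords/radii length mismatch")
    unit = fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    rmax = float(expanded.max())
    total = 0.0
    for i in range(len(coords)):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        neigh = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        total += 4.0 * math.pi * ri * ri * exposed.sum() / n_points
    return total


def buried_interface_area(model: StructureModel, chain_a: str, chain_b: str,
                          probe: float = 1.4, n_points: int = 960,
                          atoms: str = "heavy") -> float:
    """Buried SASA between two chains: (SASA_A + SASA_B - SASA_AB) / 2.

    ``atoms`` selects which atoms enter the computation: ``"heavy"`` (all
    non-hydrogen atoms, default) or ``"ca"`` (Calpha trace only).
    """
    if atoms not in ("heavy", "ca"):
        raise ValueError(f"atoms must be 'heavy' or 'ca', got {atoms!r}")

    def pick(chain: str) -> list[AtomRecord]:
        sel = [a for a in model.atoms if a.chain_id == chain and not a.is_hydrogen]
        if atoms == "ca":
            sel = [a for a in sel if a.atom_name == "CA"]
        if not sel:
            raise SelectionError(f"model {model.model_id!r}: no chain {chain!r}")
        return sel

    sel_a = pick(chain_a)
    sel_b = pick(chain_b)
    ca = np.array([a.coords for a in sel_a])
    cb = np.array([a.coords for a in sel_b])
    ra = _radii_for(sel_a)
    rb = _radii_for(sel_b)
    s_a = sasa(ca, ra, probe, n_points)
    s_b = sasa(cb, rb, probe, n_points)
    s_ab = sasa(np.vstack([ca, cb]), np.concatenate([ra, rb]), probe, n_points)
    return max(0.0, (s_a + s_b - s_ab) / 2.0)
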