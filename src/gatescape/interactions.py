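"""Geometric protein-ligand interaction profiling and pose clustering.

Interaction typing follows the conventions of geometric profilers used in
structural pharmacology: hydrogen bonds, ionic (salt-bridge) contacts,
parallel and perpendicular pi-stacking, and hydrophobic carbon-carbon
contacts, each with distance/angle cutoffs that are config-overridable.
Ligand chemistry (donors, acceptors, charged groups, rings, apolar
carbons) is declared in a :class:`LigandSpec` rather than perceived from
connectivity; protein chemistry comes from a built-in standard-residue
dictionary. Per-pose interaction fingerprints — canonical sets of
(interaction kind, protein residue) tokens — feed the docking-pose
convergence statistic, and pose geometry feeds average-linkage clustering
"without fitting" with the cluster count chosen at the minimum of the
Kelley penalty.

Default cutoffs (Angstrom / degrees):

- hbond: donor-acceptor heavy distance <= 3.5 (distance-only when the
  model carries no hydrogens; with hydrogens, <= 3.6 and D-H...A >= 100)
- ionic: opposite-charge group-centroid distance <= 5.5
- pi-parallel: ring-centroid distance <= 5.5, interplanar angle <= 30,
  lateral offset <= 2.0
- pi-perpendicular: centroid distance <= 6.0, interplanar angle 60-90
- hydrophobic: apolar C...C <= 4.0, collapsed to one record per residue
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import cdist, squareform

from .structures import (
    AtomRecord,
    GroupSpec,
    SelectionError,
    StructureModel,
    rmsd_unaligned,
    select_atoms,
)

__all__ = [
    "LigandSpec",
    "InteractionCriteria",
    "InteractionRecord",
    "PoseClusterResult",
    "load_ligand_spec",
    "builtin_ligand_spec",
    "detect_interactions",
    "fingerprint",
    "pose_convergence",
    "cluster_poses",
    "kelley_penalty",
    "PROTEIN_CHEMISTRY",
]


# ---------------------------------------------------------------------------
# Chemistry dictionaries
# ---------------------------------------------------------------------------

def _chem(donors=(), acceptors=(), charged=(), rings=(), apolar=()):
    return {
        "donors": tuple(donors),
        "acceptors": tuple(acceptors),
        "charged": tuple(charged),   # (group label, atom names, sign)
        "rings": tuple(tuple(r) for r in rings),
        "apolar": tuple(apolar),
    }


# Side-chain chemistry of the standard residues; every residue also has the
# backbone amide N as donor and carbonyl O as acceptor (PRO lacks the N-H).
PROTEIN_CHEMISTRY: dict[str, dict] = {
    "ALA": _chem(apolar=("CB",)),
    "GLY": _chem(),
    "VAL": _chem(apolar=("CB", "CG1", "CG2")),
    "LEU": _chem(apolar=("CB", "CG", "CD1", "CD2")),
    "ILE": _chem(apolar=("CB", "CG1", "CG2", "CD1")),
    "MET": _chem(apolar=("CB", "CG", "CE")),
    "PRO": _chem(apolar=("CB", "CG", "CD")),
    "PHE": _chem(rings=[("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
                 apolar=("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "TRP": _chem(donors=("NE1",),
                 rings=[("CG", "CD1", "NE1", "CE2", "CD2"),
                        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
                 apolar=("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2")),
    "TYR": _chem(donors=("OH",), acceptors=("OH",),
                 rings=[("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
                 apolar=("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "SER": _chem(donors=("OG",), acceptors=("OG",)),
    "THR": _chem(donors=("OG1",), acceptors=("OG1",), apolar=("CG2",)),
    "CYS": _chem(donors=("SG",), acceptors=("SG",), apolar=("CB",)),
    "ASN": _chem(donors=("ND2",), acceptors=("OD1",)),
    "GLN": _chem(donors=("NE2",), acceptors=("OE1",)),
    "ASP": _chem(acceptors=("OD1", "OD2"),
                 charged=(("carboxylate", ("OD1", "OD2"), -1),)),
    "GLU": _chem(acceptors=("OE1", "OE2"),
                 charged=(("carboxylate", ("OE1", "OE2"), -1),)),
    "LYS": _chem(donors=("NZ",), charged=(("ammonium", ("NZ",), +1),),
                 apolar=("CB", "CG", "CD")),
    "ARG": _chem(donors=("NE", "NH1", "NH2"),
                 charged=(("guanidinium", ("NE", "NH1", "NH2", "CZ"), +1),),
                 apolar=("CB", "CG")),
    "HIS": _chem(donors=("ND1", "NE2"), acceptors=("ND1", "NE2"),
                 rings=[("CG", "ND1", "CD2", "CE1", "NE2")]),
}

_HIS_PROTONATED_CHARGE = ("imidazolium", ("ND1", "NE2", "CE1"), +1)


@dataclass(frozen=True)
class LigandSpec:
    """Declared chemistry of a ligand residue.

    ``charged_groups`` maps a group label to (atom names, sign); ``rings``
    are planar ring atom-name lists (>= 5 atoms each).
    """

    res_name: str
    donors: tuple[str, ...] = ()
    acceptors: tuple[str, ...] = ()
    charged_groups: tuple[tuple[str, tuple[str, ...], int], ...] = ()
    rings: tuple[tuple[str, ...], ...] = ()
    apolar: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for ring in self.rings:
            if len(ring) < 5:
                raise ValueError(
                    f"ligand {self.res_name}: ring {ring} has fewer than 5 atoms"
                )


def load_ligand_spec(path: str | Path) -> LigandSpec:
    """Read a LigandSpec from its YAML declaration."""
    data = yaml.safe_load(Path(path).read_text())
    charged = tuple(
        (g["name"], tuple(g["atoms"]), int(g["sign"]))
        for g in data.get("charged_groups", [])
    )
    return LigandSpec(
        res_name=data["res_name"],
        donors=tuple(data.get("donors", [])),
        acceptors=tuple(data.get("acceptors", [])),
        charged_groups=charged,
        rings=tuple(tuple(r) for r in data.get("rings", [])),
        apolar=tuple(data.get("apolar", [])),
    )


def builtin_ligand_spec(name: str) -> LigandSpec:
    """A ligand spec shipped with the package (e.g. 'pyruvate', 'c7')."""
    from importlib.resources import files

    path = files("gatescape").joinpath(f"data/ligands/{name}.yaml")
    if not path.is_file():
        raise FileNotFoundError(f"no built-in ligand spec {name!r}")
    data = yaml.safe_load(path.read_text())
    charged = tuple(
        (g["name"], tuple(g["atoms"]), int(g["sign"]))
        for g in data.get("charged_groups", [])
    )
    return LigandSpec(
        res_name=data["res_name"],
        donors=tuple(data.get("donors", [])),
        acceptors=tuple(data.get("acceptors", [])),
        charged_groups=charged,
        rings=tuple(tuple(r) for r in data.get("rings", [])),
        apolar=tuple(data.get("apolar", [])),
    )


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance (A) and angle (deg) cutoffs for each interaction kind."""

    hbond_dist: float = 3.5
    hbond_dist_with_h: float = 3.6
    hbond_angle_min: float = 100.0
    ionic_dist: float = 5.5
    pi_parallel_dist: float = 5.5
    pi_parallel_angle_max: float = 30.0
    pi_parallel_offset_max: float = 2.0
    pi_perp_dist: float = 6.0
    pi_perp_angle_min: float = 60.0
    pi_perp_angle_max: float = 90.0
    hydrophobic_dist: float = 4.0
    his_protonated: bool = False


_KIND_ORDER = ("hbond", "hydrophobic", "ionic", "pi_parallel", "pi_perpendicular")


@dataclass(frozen=True)
class InteractionRecord:
    """One typed protein-ligand contact."""

    kind: str
    chain_id: str
    res_seq: int
    res_name: str
    protein_atom: str      # atom name or ring/group label
    ligand_atom: str       # atom name or ring/group label
    distance: float
    angle: float | None = None

    def token(self) -> tuple[str, str, int, str]:
        """Fingerprint token: interaction kind + protein residue identity."""
        return (self.kind, self.chain_id, self.res_seq, self.res_name)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _residue_atoms(model: StructureModel, chain: str, res_seq: int) -> dict[str, AtomRecord]:
    return {a.atom_name: a for a in model.atoms
            if a.chain_id == chain and a.res_seq == res_seq}


def _ligand_atoms(model: StructureModel, res_name: str) -> dict[str, AtomRecord]:
    atoms = {a.atom_name: a for a in model.atoms if a.res_name == res_name}
    if not atoms:
        raise SelectionError(f"model {model.model_id!r}: no ligand residue {res_name!r}")
    return atoms


def _coords(atom_map: Mapping[str, AtomRecord], names: Iterable[str],
            context: str) -> np.ndarray:
    missing = [n for n in names if n not in atom_map]
    if missing:
        raise SelectionError(f"{context}: missing atoms {missing}")
    return np.array([atom_map[n].coords for n in names], dtype=float)


def _ring_frame(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal (least-squares plane) of a ring."""
    centroid = xyz.mean(axis=0)
    _, _, Vt = np.linalg.svd(xyz - centroid)
    return centroid, Vt[2]


def _hydrogens_near(model: StructureModel, donor: AtomRecord,
                    max_dh: float = 1.3) -> list[np.ndarray]:
    d = np.asarray(donor.coords)
    out = []
    for a in model.atoms:
        if a.is_hydrogen and a.chain_id == donor.chain_id and a.res_seq == donor.res_seq:
            h = np.asarray(a.coords)
            if np.linalg.norm(h - d) <= max_dh:
                out.append(h)
    return out


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, float(cosang)))))


def _residue_chemistry(res_name: str, criteria: InteractionCriteria) -> dict:
    if res_name not in PROTEIN_CHEMISTRY:
        raise SelectionError(f"unknown protein residue name {res_name!r}")
    chem = dict(PROTEIN_CHEMISTRY[res_name])
    donors = set(chem["donors"])
    acceptors = set(chem["acceptors"]) | {"O"}  # backbone carbonyl
    if res_name != "PRO":
        donors.add("N")  # backbone amide
    charged = list(chem["charged"])
    if res_name == "HIS" and criteria.his_protonated:
        charged.append(_HIS_PROTONATED_CHARGE)
    return {**chem, "donors": tuple(sorted(donors)),
            "acceptors": tuple(sorted(acceptors)), "charged": tuple(charged)}


def _check_hbond(model, donor_atom, acceptor_xyz, criteria, has_h):
    """Distance (and, with hydrogens, D-H...A angle) test for one H bond."""
    d = float(np.linalg.norm(np.asarray(donor_atom.coords) - acceptor_xyz))
    if has_h:
        if d > criteria.hbond_dist_with_h:
            return None
        hs = _hydrogens_near(model, donor_atom)
        if not hs:
            return None
        best = max(_angle_deg(np.asarray(donor_atom.coords), h, acceptor_xyz)
                   for h in hs)
        if best < criteria.hbond_angle_min:
            return None
        return d, best
    if d > criteria.hbond_dist:
        return None
    return d, None


def detect_interactions(model: StructureModel, ligand: LigandSpec,
                        site: Sequence[GroupSpec],
                        criteria: InteractionCriteria = InteractionCriteria()) -> list[InteractionRecord]:
    """Typed protein-ligand contacts between the ligand and the site residues.

    Deterministic: records are sorted by (kind, chain, residue, partner
    atoms). Hydrophobic contacts are collapsed to one record per protein
    residue, reporting the closest carbon pair.
    """
    lig = _ligand_atoms(model, ligand.res_name)
    has_h = any(a.is_hydrogen for a in model.atoms)

    lig_rings = [(f"ring{i + 1}", _coords(lig, names, f"ligand {ligand.res_name}"))
                 for i, names in enumerate(ligand.rings)]
    lig_charges = [(label, _coords(lig, names, f"ligand {ligand.res_name}"), sign)
                   for label, names, sign in ligand.charged_groups]

    records: list[InteractionRecord] = []
    for spec in site:
        for atom in select_atoms(model, spec):
            pass  # selection errors surface before any typing below
        for res_seq in sorted(spec.residues):
            res_atoms = {a.atom_name: a for a in select_atoms(
                model, GroupSpec(spec.chain_id, frozenset({res_seq}), heavy_only=False))}
            res_name = next(iter(res_atoms.values())).res_name
            chem = _residue_chemistry(res_name, criteria)
            ident = (spec.chain_id, res_seq, res_name)

            # hydrogen bonds: protein donor -> ligand acceptor
            for dname in chem["donors"]:
                if dname not in res_atoms:
                    continue
                for aname in ligand.acceptors:
                    hit = _check_hbond(model, res_atoms[dname],
                                       np.asarray(lig[aname].coords), criteria, has_h)
                    if hit:
                        records.append(InteractionRecord(
                            "hbond", *ident, dname, aname, hit[0], hit[1]))
            # hydrogen bonds: ligand donor -> protein acceptor
            for aname in chem["acceptors"]:
                if aname not in res_atoms:
                    continue
                for dname in ligand.donors:
                    hit = _check_hbond(model, lig[dname],
                                       np.asarray(res_atoms[aname].coords),
                                       criteria, has_h)
                    if hit:
                        records.append(InteractionRecord(
                            "hbond", *ident, aname, dname, hit[0], hit[1]))

            # ionic: opposite-sign charged-group centroids
            for plabel, pnames, psign in chem["charged"]:
                if not all(n in res_atoms for n in pnames):
                    continue
                pc = np.array([res_atoms[n].coords for n in pnames]).mean(axis=0)
                for llabel, lxyz, lsign in lig_charges:
                    if psign * lsign >= 0:
                        continue
                    d = float(np.linalg.norm(pc - lxyz.mean(axis=0)))
                    if d <= criteria.ionic_dist:
                        records.append(InteractionRecord(
                            "ionic", *ident, plabel, llabel, d))

            # pi stacking: protein ring vs ligand ring
            for ri, rnames in enumerate(chem["rings"]):
                if not all(n in res_atoms for n in rnames):
                    continue
                pcen, pnorm = _ring_frame(
                    np.array([res_atoms[n].coords for n in rnames]))
                for llabel, lxyz in lig_rings:
                    lcen, lnorm = _ring_frame(lxyz)
                    d = float(np.linalg.norm(pcen - lcen))
                    ang = math.degrees(math.acos(
                        max(-1.0, min(1.0, abs(float(np.dot(pnorm, lnorm)))))))
                    sep = lcen - pcen
                    offset = float(np.linalg.norm(sep - np.dot(sep, pnorm) * pnorm))
                    if (d <= criteria.pi_parallel_dist
                            and ang <= criteria.pi_parallel_angle_max
                            and offset <= criteria.pi_parallel_offset_max):
                        records.append(InteractionRecord(
                            "pi_parallel", *ident, f"ring{ri + 1}", llabel, d, ang))
                    elif (d <= criteria.pi_perp_dist
                          and criteria.pi_perp_angle_min <= ang <= criteria.pi_perp_angle_max):
                        records.append(InteractionRecord(
                            "pi_perpendicular", *ident, f"ring{ri + 1}", llabel, d, ang))

            # hydrophobic: closest apolar C...C pair, one record per residue
            pnames = [n for n in chem["apolar"] if n in res_atoms]
            lnames = [n for n in ligand.apolar if n in lig]
            if pnames and lnames:
                pd_xyz = np.array([res_atoms[n].coords for n in pnames])
                ld_xyz = np.array([lig[n].coords for n in lnames])
                dmat = cdist(pd_xyz, ld_xyz)
                i, j = np.unravel_index(int(np.argmin(dmat)), dmat.shape)
                if dmat[i, j] <= criteria.hydrophobic_dist:
                    records.append(InteractionRecord(
                        "hydrophobic", *ident, pnames[i], lnames[j],
                        float(dmat[i, j])))

    records.sort(key=lambda r: (r.kind, r.chain_id, r.res_seq,
                                r.protein_atom, r.ligand_atom))
    return records


# ---------------------------------------------------------------------------
# Fingerprints and convergence
# ---------------------------------------------------------------------------

def fingerprint(records: Iterable[InteractionRecord]) -> frozenset:
    """Canonical, order-independent set of (kind, protein residue) tokens."""
    return frozenset(r.token() for r in records)


@dataclass
class PoseClusterResult:
    linkage: np.ndarray | None
    kelley_penalty: dict[int, float]
    chosen_k: int | None
    assignment: dict[str, int]
    degenerate: bool = False
    modal_fingerprint: frozenset | None = None
    convergence_fraction: float | None = None
    fingerprints: dict[str, frozenset] = field(default_factory=dict)


def pose_convergence(poses: Sequence[StructureModel], ligand: LigandSpec,
                     site: Sequence[GroupSpec],
                     criteria: InteractionCriteria = InteractionCriteria()) -> PoseClusterResult:
    """Modal interaction fingerprint and the fraction of poses sharing it.

    The modal fingerprint is the most frequent one across poses (ties:
    more tokens, then lexicographically smallest). The convergence
    fraction counts poses whose fingerprint contains the modal one.
    """
    if not poses:
        raise ValueError("at least one pose required")
    fps = {p.model_id: fingerprint(detect_interactions(p, ligand, site, criteria))
           for p in poses}
    counts: dict[frozenset, int] = {}
    for fp in fps.values():
        counts[fp] = counts.get(fp, 0) + 1
    modal = min(counts, key=lambda fp: (-counts[fp], -len(fp), sorted(fp)))
    frac = sum(1 for fp in fps.values() if fp >= modal) / len(poses)
    return PoseClusterResult(
        linkage=None, kelley_penalty={}, chosen_k=None, assignment={},
        modal_fingerprint=modal, convergence_fraction=frac, fingerprints=fps,
    )


# ---------------------------------------------------------------------------
# Average-linkage pose clustering with the Kelley criterion
# ---------------------------------------------------------------------------

def kelley_penalty(D: np.ndarray, labels_by_k: Mapping[int, np.ndarray]) -> dict[int, float]:
    """Kelley penalty over clustering levels.

    For each level with k clusters, the average spread is the mean over
    multi-member clusters of their mean pairwise distance. Spreads are
    normalized across levels to the range [1, n-1] and the cluster count k
    is added; the minimum of the resulting penalty selects k. If all
    spreads are equal (e.g. identical poses) the normalized value is 1
    everywhere and the penalty reduces to 1 + k.
    """
    n = D.shape[0]
    spreads: dict[int, float] = {}
    for k, labels in labels_by_k.items():
        vals = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if idx.size >= 2:
                sub = D[np.ix_(idx, idx)]
                vals.append(float(sub[np.triu_indices(idx.size, 1)].mean()))
        spreads[k] = float(np.mean(vals)) if vals else 0.0
    smin = min(spreads.values())
    smax = max(spreads.values())
    out: dict[int, float] = {}
    for k, s in spreads.items():
        norm = 1.0 if smax - smin < 1e-12 else (s - smin) / (smax - smin) * (n - 2) + 1.0
        out[k] = norm + k
    return out


def _pose_coords(pose: StructureModel, site: Sequence[GroupSpec]) -> np.ndarray:
    """Ligand (HETATM) plus binding-site non-hydrogen coordinates, fixed order."""
    lig = sorted((a for a in pose.atoms if a.het and not a.is_hydrogen),
                 key=lambda a: (a.res_name, a.chain_id, a.res_seq, a.atom_name))
    coords = [a.coords for a in lig]
    for spec in site:
        coords.extend(a.coords for a in select_atoms(pose, spec))
    return np.array(coords, dtype=float)


def cluster_poses(poses: Sequence[StructureModel],
                  site: Sequence[GroupSpec]) -> PoseClusterResult:
    """Average-linkage pose clustering without fitting, k at the Kelley minimum.

    Pairwise pose distance is the fit-free RMSD over the ligand's
    non-hydrogen atoms plus the binding-site atoms. All poses must share
    the same atom composition. The merge tree is cut at every k in
    [2, n-1]; the reported ``chosen_k`` minimizes the Kelley penalty
    (ties: smallest k). Fully degenerate inputs (all distances ~0) are
    flagged and fall back to k = 2 by the tie rule.
    """
    if len(poses) < 3:
        raise ValueError("pose clustering requires at least 3 poses")
    coords = [_pose_coords(p, site) for p in poses]
    shape = coords[0].shape
    comps = [
        tuple(a.key() for a in sorted(
            (x for x in p.atoms if x.het and not x.is_hydrogen),
            key=lambda a: (a.res_name, a.chain_id, a.res_seq, a.atom_name)))
        for p in poses
    ]
    if any(c.shape != shape for c in coords) or len(set(comps)) != 1:
        raise ValueError("poses differ in atom composition")
    n = len(poses)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = rmsd_unaligned(coords[i], coords[j])
    Z = linkage(squareform(D, checks=False), method="average")
    ks = list(range(2, n))
    cuts = cut_tree(Z, n_clusters=ks)
    labels_by_k = {k: cuts[:, i] for i, k in enumerate(ks)}
    penalty = kelley_penalty(D, labels_by_k)
    degenerate = float(D.max()) < 1e-9
    chosen_k = min(penalty, key=lambda k: (penalty[k], k))
    labels = labels_by_k[chosen_k]
    assignment = {p.model_id: int(labels[i]) for i, p in enumerate(poses)}
    return PoseClusterResult(
        linkage=Z, kelley_penalty=penalty, chosen_k=int(chosen_k),
        assignment=assignment, degenerate=degenerate,
    )
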