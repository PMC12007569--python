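"""Synthetic rocker-switch ensembles and docking pose sets with ground truth.

The generator emulates the data regime of an AlphaFold-style conformational
ensemble of a two-protomer, three-transmembrane-helix transporter: chain A
(an MPC1L-like protomer) and chain B (an MPC2-like protomer), each built
from three idealized straight alpha-helical backbones (N, CA, C, O per
residue) arranged around a pseudo-twofold axis along the membrane normal
(z). The H2-H3 bundle of each protomer rotates rigidly about a hinge axis
(through the hinge residue's Calpha, perpendicular to the membrane normal)
between an outward-open endpoint (progress t = 0, the template) and an
inward-open endpoint (t = 1), by default through 16.5 deg on chain A and
19.0 deg on chain B. As t grows the N-terminal gate closes and the
C-terminal gate opens, so the generated ensemble traces the outward ->
occluded -> inward arc of a rocker-switch landscape with exactly known
per-model progress, applied angles, and pseudo-quality scores.

Residue numbering is chosen so the default MPC1L/MPC2 gate definitions
select real residues: chain A carries 20-96 (H1 20-44, H2 45-70, H3
71-96), chain B carries 34-110 (H1 34-58, H2 59-84, H3 85-110).

Pose sets: a hand-built binding-site scaffold (K49-, N100-, L96-, Y64- and
F68-analog residues) plus a pyruvate-like ligand placed either in a
designated modal geometry (ionic + hydrogen bond to the K49 analog,
hydrogen bond to the N100 analog, hydrophobic contact to the L96 analog)
or rigidly displaced to break the ionic contact, with margin-safe jitter
so interaction typing recovers the labels exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import LigandSpec, builtin_ligand_spec
from .structures import AtomRecord, GroupSpec, StructureModel

__all__ = [
    "SyntheticEnsembleParams",
    "HELIX_RANGES",
    "DEFAULT_HINGES",
    "MOBILE_BUNDLES",
    "FIXED_SELECTIONS",
    "build_template",
    "generate_ensemble",
    "build_binding_site",
    "generate_pose_set",
]

# Helix residue ranges (inclusive) per chain; H2/H3 form the mobile bundle.
# The spans place the N-gate residues in a tight band near the top of the
# bundle (z ~ +11..+22) and the C-gate residues near the bottom
# (z ~ -19..-7), so each hinge can sit between the bands.
HELIX_RANGES: dict[str, dict[str, tuple[int, int]]] = {
    "A": {"H1": (20, 44), "H2": (45, 74), "H3": (75, 104)},
    "B": {"H1": (34, 58), "H2": (59, 88), "H3": (89, 118)},
}
# Hinge Calphas sit between the two gate bands, each close to the gate its
# chain should disturb least: chain A pivots just above its C-gate (so its
# rotation mostly drives N-gate closure), chain B just below its N-gate
# (so its rotation mostly drives C-gate opening).
DEFAULT_HINGES: dict[str, int] = {"A": 98, "B": 84}

MOBILE_BUNDLES: dict[str, GroupSpec] = {
    "A": GroupSpec("A", frozenset(range(45, 105))),
    "B": GroupSpec("B", frozenset(range(59, 119))),
}
FIXED_SELECTIONS: list[GroupSpec] = [
    GroupSpec("A", frozenset(range(20, 45))),
    GroupSpec("B", frozenset(range(34, 59))),
]

# Idealized alpha-helix parameters: 1.5 A rise and 100 deg twist per
# residue; backbone atoms on co-axial helices with fixed radius/phase/rise
# offsets relative to Calpha.
_RISE = 1.5
_TWIST = math.radians(100.0)
_ATOM_OFFSETS = {  # name -> (radius, phase offset rad, z offset)
    "N": (1.55, math.radians(-29.0), -0.55),
    "CA": (2.27, 0.0, 0.0),
    "C": (1.67, math.radians(26.0), 0.53),
    "O": (2.00, math.radians(26.0), 1.73),
}
# Bundle x offset and the small inter-protomer stagger in y: staggering the
# two chains caps the closest cross-chain approach when a gate closes, so
# the gate coordination saturates instead of diverging.
_BUNDLE_X = 4.6
_STAGGER_Y = 2.6
# Small linear leakage mixed into the phase-staggered schedules keeps both
# bundles strictly moving at every t (strict gate-metric monotonicity).
_SCHEDULE_LINEAR_MIX = 0.05
_HELIX_AXES = {  # (chain, helix) -> (x, y) axis position; z is the axis
    ("A", "H1"): (-_BUNDLE_X - 7.0, 0.0),
    ("A", "H2"): (-_BUNDLE_X, -4.0),
    ("A", "H3"): (-_BUNDLE_X, 4.0),
    ("B", "H1"): (_BUNDLE_X + 7.0, _STAGGER_Y),
    ("B", "H2"): (_BUNDLE_X, -4.0 + _STAGGER_Y),
    ("B", "H3"): (_BUNDLE_X, 4.0 + _STAGGER_Y),
}
_Z_BOTTOM = -21.75  # bundle helices span z in [-21.75, +21.75]


@dataclass(frozen=True)
class SyntheticEnsembleParams:
    """Generator settings; identical params + seed give bit-identical output.

    ``t_distribution`` is ``"uniform"``, ``"two_modes"`` (mixture of Beta
    peaks near the endpoints) or ``("beta", a, b)``; ``t_values``
    overrides the draw with explicit progress values. The quality model
    is ``"unbiased"`` (score independent of t) or ``"biased"`` (mid-path
    models score lower, to exercise filter/landscape interplay).
    """

    n_models: int = 100
    t_distribution: object = "uniform"
    theta_max_a: float = 16.5
    theta_max_b: float = 19.0
    hinge_residues: tuple[tuple[str, int], ...] = (("A", 98), ("B", 84))
    noise_sigma: float = 0.2
    seed: int = 0
    quality_model: str = "unbiased"
    t_values: tuple[float, ...] | None = None
    phase_sharpness: float = 7.0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for theta in (self.theta_max_a, self.theta_max_b):
            if not (0.0 < theta < 90.0):
                raise ValueError(f"theta {theta} outside (0, 90) degrees")
        if self.quality_model not in ("unbiased", "biased"):
            raise ValueError(f"unknown quality model {self.quality_model!r}")
        if self.phase_sharpness < 1.0:
            raise ValueError("phase_sharpness must be >= 1")
        if self.t_values is not None:
            object.__setattr__(self, "t_values",
                               tuple(float(t) for t in self.t_values))
            if len(self.t_values) != self.n_models:
                raise ValueError("t_values length must equal n_models")
            if any(not (0.0 <= t <= 1.0) for t in self.t_values):
                raise ValueError("t values must lie in [0, 1]")

    @property
    def hinges(self) -> dict[str, int]:
        return dict(self.hinge_residues)


def _helix_backbone(chain: str, helix: str) -> list[AtomRecord]:
    lo, hi = HELIX_RANGES[chain][helix]
    ax, ay = _HELIX_AXES[(chain, helix)]
    n_res = hi - lo + 1
    down = helix == "H3"  # H3 is antiparallel: N-terminus at the top
    z0 = _Z_BOTTOM if helix != "H1" else -(n_res - 1) * _RISE / 2.0
    atoms: list[AtomRecord] = []
    for k in range(n_res):
        res = lo + k
        z_ca = (z0 + (n_res - 1 - k) * _RISE) if down else (z0 + k * _RISE)
        phase = k * _TWIST
        for name, (radius, dphi, dz) in _ATOM_OFFSETS.items():
            phi = phase + dphi
            dz_signed = -dz if down else dz
            atoms.append(AtomRecord(
                chain_id=chain,
                res_seq=res,
                res_name="GLY",
                atom_name=name,
                element=name[0],
                coords=(ax + radius * math.cos(phi),
                        ay + radius * math.sin(phi),
                        z_ca + dz_signed),
            ))
    return atoms


def _rotation_about_y(theta_deg: float, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation by theta about the axis through ``point`` along +y."""
    th = math.radians(theta_deg)
    R = np.array([[math.cos(th), 0.0, math.sin(th)],
                  [0.0, 1.0, 0.0],
                  [-math.sin(th), 0.0, math.cos(th)]])
    t = point - R @ point
    return R, t


def _bundle_mask(model: StructureModel, chain: str) -> np.ndarray:
    lo = HELIX_RANGES[chain]["H2"][0]
    hi = HELIX_RANGES[chain]["H3"][1]
    return np.array([a.chain_id == chain and lo <= a.res_seq <= hi
                     for a in model.atoms])


def _hinge_ca(model: StructureModel, chain: str, res: int) -> np.ndarray:
    for a in model.atoms:
        if a.chain_id == chain and a.res_seq == res and a.atom_name == "CA":
            return np.asarray(a.coords)
    raise ValueError(f"hinge residue {chain}/{res} has no Calpha")


def _rotate_bundles(model: StructureModel, angles: dict[str, float],
                    hinges: dict[str, int], model_id: str) -> StructureModel:
    """Rigidly rotate each chain's H2-H3 bundle about its hinge axis."""
    xyz = model.coords_array()
    for chain, theta in angles.items():
        if theta == 0.0:
            continue
        mask = _bundle_mask(model, chain)
        R, t = _rotation_about_y(theta, _hinge_ca(model, chain, hinges[chain]))
        xyz[mask] = xyz[mask] @ R.T + t
    return model.with_coords(xyz, model_id)


def build_template(theta_max_a: float = 16.5, theta_max_b: float = 19.0,
                   hinges: dict[str, int] | None = None) -> StructureModel:
    """Deterministic outward-open (t = 0) template heterodimer.

    Helices are built vertical and the two H2-H3 bundles are pre-tilted
    outward by half the endpoint rotation, so that applying the full
    rotation (t = 1) tilts them inward symmetrically: the template has an
    open N-gate and a closed C-gate, the t = 1 endpoint the reverse.
    """
    hinges = dict(DEFAULT_HINGES if hinges is None else hinges)
    atoms: list[AtomRecord] = []
    for chain in ("A", "B"):
        for helix in ("H1", "H2", "H3"):
            atoms.extend(_helix_backbone(chain, helix))
    vertical = StructureModel("template", atoms, {"t": 0.0})
    vertical.validate_unique()
    # outward pre-tilt: chain A top leans to -x, chain B top leans to +x
    return _rotate_bundles(
        vertical,
        {"A": -theta_max_a / 2.0, "B": theta_max_b / 2.0},
        hinges,
        "template",
    )


def _draw_t(params: SyntheticEnsembleParams, rng: np.random.Generator) -> np.ndarray:
    if params.t_values is not None:
        return np.asarray(params.t_values, dtype=float)
    dist = params.t_distribution
    n = params.n_models
    if dist == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if dist == "two_modes":
        lo = rng.beta(2.0, 8.0, size=n)
        hi = rng.beta(8.0, 2.0, size=n)
        pick = rng.uniform(size=n) < 0.5
        return np.where(pick, lo, hi)
    if isinstance(dist, (tuple, list)) and len(dist) == 3 and dist[0] == "beta":
        _, a, b = dist
        if a <= 0 or b <= 0:
            raise ValueError("beta shape parameters must be positive")
        return rng.beta(float(a), float(b), size=n)
    raise ValueError(f"unknown t_distribution {dist!r}")


def _pseudo_scores(t: np.ndarray, params: SyntheticEnsembleParams,
                   rng: np.random.Generator) -> np.ndarray:
    base = np.clip(1.0 - np.abs(rng.normal(0.0, 0.15, size=len(t))), 0.0, 1.0)
    if params.quality_model == "biased":
        base = np.clip(base - 0.4 * (1.0 - np.abs(2.0 * t - 1.0)), 0.0, 1.0)
    return base


def generate_ensemble(params: SyntheticEnsembleParams) -> tuple[list[StructureModel], pd.DataFrame]:
    """Seeded ensemble of rocker-switch conformers plus its ground truth.

    Each model draws a progress t and rotates the two H2-H3 bundles about
    their hinge axes along monotone phase-staggered schedules (chain A by
    (1-(1-t)^gamma) * theta_max_a, chain B by t^gamma * theta_max_b, with
    gamma = ``phase_sharpness``), closing the N-gate early and opening
    the C-gate late so that mid-path models are occluded; isotropic
    Gaussian coordinate noise is added last. The ground-truth table has
    one row per model: model_id, t, applied angles, pseudo_score.
    """
    rng = np.random.default_rng(params.seed)
    hinges = params.hinges
    template = build_template(params.theta_max_a, params.theta_max_b, hinges)
    t_arr = _draw_t(params, rng)
    scores = _pseudo_scores(t_arr, params, rng)
    width = max(4, len(str(params.n_models)))
    gamma = params.phase_sharpness
    models: list[StructureModel] = []
    rows = []
    for i, t in enumerate(t_arr):
        mid = f"synth_{i:0{width}d}"
        # phase-staggered monotone schedules: the chain-A rotation (N-gate
        # closure) completes early, the chain-B rotation (C-gate opening)
        # late, so the mid-path models are occluded (both gates shut)
        # rather than half-open channels; endpoints carry the full
        # rotations regardless of gamma, and gamma = 1 makes both linear.
        lam = _SCHEDULE_LINEAR_MIX
        frac_a = (1.0 - lam) * (1.0 - (1.0 - float(t)) ** gamma) + lam * float(t)
        frac_b = (1.0 - lam) * float(t) ** gamma + lam * float(t)
        angle_a = frac_a * params.theta_max_a
        angle_b = frac_b * params.theta_max_b
        model = _rotate_bundles(
            template, {"A": angle_a, "B": -angle_b}, hinges, mid)
        if params.noise_sigma > 0:
            xyz = model.coords_array()
            xyz += rng.normal(0.0, params.noise_sigma, size=xyz.shape)
            model = model.with_coords(xyz, mid)
        model.meta.update(t=float(t), pseudo_score=float(scores[i]),
                          seed=params.seed)
        models.append(model)
        rows.append({"model_id": mid, "t": float(t), "angle_a": angle_a,
                     "angle_b": angle_b, "pseudo_score": float(scores[i])})
    truth = pd.DataFrame(rows, columns=["model_id", "t", "angle_a", "angle_b",
                                        "pseudo_score"])
    return models, truth


# ---------------------------------------------------------------------------
# Pose sets
# ---------------------------------------------------------------------------

# Hand-placed binding-site scaffold: analogs of the pyruvate-site residues,
# with the contact-forming side-chain atoms positioned relative to the
# modal ligand placement (below) and everything else pushed well outside
# every cutoff.
_SITE_RESIDUES: list[tuple[str, int, str, list[tuple[str, tuple[float, float, float]]]]] = [
    ("B", 49, "LYS", [
        ("N", (1.0, 11.6, 0.0)), ("CA", (0.0, 10.9, 0.0)),
        ("C", (-1.2, 11.6, 0.0)), ("O", (-1.3, 12.8, 0.0)),
        ("CB", (0.0, 9.4, 0.0)), ("CG", (0.0, 7.9, 0.0)),
        ("CD", (0.0, 6.4, 0.0)), ("CE", (0.0, 4.9, 0.0)),
        ("NZ", (0.0, 3.4, 0.0)),
    ]),
    ("B", 100, "ASN", [
        ("N", (1.7, 0.2, 7.1)), ("CA", (1.7, -1.0, 6.3)),
        ("C", (2.9, -1.6, 7.0)), ("O", (2.9, -2.8, 7.2)),
        ("CB", (1.7, -2.2, 5.5)), ("CG", (1.7, -2.2, 4.0)),
        ("OD1", (2.3, -1.2, 3.6)), ("ND2", (1.1, -2.2, 3.0)),
    ]),
    ("B", 96, "LEU", [
        ("N", (-2.8, -3.9, -7.3)), ("CA", (-1.6, -3.3, -7.6)),
        ("C", (-1.7, -3.3, -9.1)), ("O", (-0.7, -3.0, -9.8)),
        ("CB", (-1.6, -3.3, -6.1)), ("CG", (-1.6, -3.3, -4.6)),
        ("CD1", (-1.2, -2.3, -3.6)), ("CD2", (-2.4, -2.9, -4.2)),
    ]),
    ("A", 64, "TYR", [
        ("N", (-8.4, 3.0, 8.6)), ("CA", (-7.6, 3.0, 7.8)),
        ("C", (-8.4, 3.0, 6.6)), ("O", (-9.6, 3.0, 6.6)),
        ("CB", (-6.8, 3.0, 6.8)), ("CG", (-6.4, 3.0, 5.4)),
        ("CD1", (-6.9, 2.0, 4.6)), ("CD2", (-5.5, 3.9, 4.8)),
        ("CE1", (-6.5, 1.9, 3.3)), ("CE2", (-5.1, 3.9, 3.5)),
        ("CZ", (-5.6, 2.9, 2.7)), ("OH", (-5.2, 2.9, 1.4)),
    ]),
    ("A", 68, "PHE", [
        ("N", (5.6, -1.0, -8.9)), ("CA", (5.0, -1.0, -7.7)),
        ("C", (5.9, -1.0, -6.5)), ("O", (7.1, -1.0, -6.6)),
        ("CB", (4.1, -2.2, -7.6)), ("CG", (4.0, -1.0, -5.5)),
        ("CD1", (4.6, -2.0, -4.8)), ("CD2", (3.4, 0.0, -4.8)),
        ("CE1", (4.6, -2.0, -3.4)), ("CE2", (3.4, 0.0, -3.4)),
        ("CZ", (4.0, -1.0, -2.7)),
    ]),
]

# Modal pyruvate-like ligand placement (chain L, residue PYR 1).
_LIGAND_MODAL: list[tuple[str, str, tuple[float, float, float]]] = [
    ("C1", "C", (0.0, 0.0, 0.0)),
    ("O1", "O", (1.05, 0.6, 0.0)),
    ("O2", "O", (-1.05, 0.6, 0.0)),
    ("C2", "C", (0.0, -1.5, 0.0)),
    ("O3", "O", (1.1, -2.2, 0.0)),
    ("C3", "C", (-1.2, -2.3, 0.0)),
]

_NZ = np.array([0.0, 3.4, 0.0])


def build_binding_site() -> tuple[list[AtomRecord], list[GroupSpec]]:
    """The fixed binding-site scaffold and its GroupSpec selections."""
    atoms: list[AtomRecord] = []
    for chain, res, res_name, placed in _SITE_RESIDUES:
        for name, xyz in placed:
            atoms.append(AtomRecord(chain, res, res_name, name, name[0], xyz))
    specs = [GroupSpec(chain, frozenset({res}))
             for chain, res, _, _ in _SITE_RESIDUES]
    return atoms, specs


def generate_pose_set(n: int, modal_fraction: float,
                      ligand: LigandSpec | None = None,
                      seed: int = 0,
                      jitter_sigma: float = 0.05
                      ) -> tuple[list[StructureModel], pd.DataFrame, list[GroupSpec]]:
    """Seeded pose set with a controlled modal interaction fingerprint.

    ``round(n * modal_fraction)`` poses carry the designated modal
    geometry (plus margin-safe rigid jitter); the remainder are rigidly
    displaced until the ionic contact to the K49 analog is broken by a
    safe margin. Returns the poses, a ground-truth table (pose_id, modal)
    and the binding-site GroupSpecs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= modal_fraction <= 1.0):
        raise ValueError("modal_fraction must lie in [0, 1]")
    if ligand is None:
        ligand = builtin_ligand_spec("pyruvate")
    rng = np.random.default_rng(seed)
    site_atoms, specs = build_binding_site()
    n_modal = round(n * modal_fraction)
    lig_names = [name for name, _, _ in _LIGAND_MODAL]
    lig_elements = [el for _, el, _ in _LIGAND_MODAL]
    lig_base = np.array([xyz for _, _, xyz in _LIGAND_MODAL])
    carboxylate = lig_base[[1, 2]].mean(axis=0)

    poses: list[StructureModel] = []
    rows = []
    width = max(4, len(str(n)))
    for i in range(n):
        modal = i < n_modal
        if modal:
            shift = rng.normal(0.0, jitter_sigma, size=3)
        else:
            # push the ligand away from the K49-analog ammonium until the
            # ionic-centroid distance clears the cutoff with >= 0.5 A margin
            while True:
                direction = np.array([rng.uniform(-1, 1), -1.0, rng.uniform(-1, 1)])
                direction /= np.linalg.norm(direction)
                shift = direction * rng.uniform(4.0, 6.0)
                if np.linalg.norm(carboxylate + shift - _NZ) > 6.0:
                    break
        xyz = lig_base + shift
        atoms = list(site_atoms)
        for name, el, pos in zip(lig_names, lig_elements, xyz):
            atoms.append(AtomRecord("L", 1, ligand.res_name, name, el,
                                    (float(pos[0]), float(pos[1]), float(pos[2])),
                                    het=True))
        pid = f"pose_{i:0{width}d}"
        poses.append(StructureModel(pid, atoms, {"modal": modal, "seed": seed}))
        rows.append({"pose_id": pid, "modal": modal})
    labels = pd.DataFrame(rows, columns=["pose_id", "modal"])
    return poses, labels, specs
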