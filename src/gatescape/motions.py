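"""Rigid-body rotation analysis between two conformational states.

For a rocker-switch transporter the outward-open to inward-open
interconversion is dominated by rotation of a helical bundle (H2-H3 in
each MPC protomer) against a fixed frame. This module quantifies that
motion with a fixed-selection analysis: superpose state B onto state A on
a caller-chosen fixed selection, then fit the residual rigid transform of
the mobile selection and decompose it into a rotation angle, a rotation
axis, and a screw translation along that axis. The hinge report gives
per-residue Calpha displacements after the fixed alignment and flags the
sliding window with the steepest displacement gradient as the candidate
hinge/bending region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import (
    DegenerateGeometryError,
    GroupSpec,
    StructureModel,
    apply_transform,
    select_atoms,
    select_coords,
    superpose,
)

__all__ = ["RotationAnalysis", "bundle_rotation", "hinge_report"]


@dataclass
class RotationAnalysis:
    """Residual rigid-body motion of the mobile selection after fixed alignment."""

    fixed_selection: tuple[GroupSpec, ...]
    mobile_selection: tuple[GroupSpec, ...]
    angle_deg: float
    axis: np.ndarray
    screw_translation: float
    rmsd_fixed: float
    rmsd_mobile_after: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg <= 180.0):
            raise ValueError(f"angle {self.angle_deg} outside [0, 180]")
        if abs(float(np.linalg.norm(self.axis)) - 1.0) > 1e-9:
            raise ValueError("axis must have unit norm")


def _rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (deg, in [0, 180]) and unit axis of a proper rotation matrix."""
    tr = float(np.trace(R))
    angle = math.degrees(math.acos(max(-1.0, min(1.0, (tr - 1.0) / 2.0))))
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = float(np.linalg.norm(v))
    if norm > 1e-12:
        axis = v / norm
    else:
        # angle ~0 or ~180: take the eigenvector of R for eigenvalue +1
        w, V = np.linalg.eigh((R + R.T) / 2.0)
        axis = V[:, int(np.argmax(w))]
        axis = axis / np.linalg.norm(axis)
    return angle, axis


def bundle_rotation(state_a: StructureModel, state_b: StructureModel,
                    fixed: Sequence[GroupSpec], mobile: Sequence[GroupSpec]) -> RotationAnalysis:
    """Rotation of the mobile selection between two states.

    State B is first superposed onto state A using the fixed selection
    (its residual is ``rmsd_fixed``). The rigid transform that then best
    maps B's mobile atoms onto A's is decomposed into angle/axis/screw;
    ``rmsd_mobile_after`` is the residual of that second fit, i.e. how
    rigid the bundle motion really is.
    """
    fixed = tuple(fixed)
    mobile = tuple(mobile)
    fa = select_coords(state_a, fixed)
    fb = select_coords(state_b, fixed)
    ma = select_coords(state_a, mobile)
    mb = select_coords(state_b, mobile)
    if fa.shape != fb.shape:
        raise ValueError("fixed selections differ in atom count between states")
    if ma.shape != mb.shape:
        raise ValueError("mobile selections differ in atom count between states")
    align = superpose(fb, fa)
    mb_aligned = apply_transform(mb, align)
    residual = superpose(mb_aligned, ma)
    angle, axis = _rotation_angle_axis(residual.rotation)
    screw = float(np.dot(axis, residual.translation +
                         (residual.rotation - np.eye(3)) @ mb_aligned.mean(axis=0)))
    return RotationAnalysis(
        fixed_selection=fixed,
        mobile_selection=mobile,
        angle_deg=angle,
        axis=axis,
        screw_translation=screw,
        rmsd_fixed=align.rmsd,
        rmsd_mobile_after=residual.rmsd,
    )


def _ca_table(model: StructureModel, chain: str) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for a in model.atoms:
        if a.chain_id == chain and a.atom_name == "CA":
            out[a.res_seq] = np.asarray(a.coords)
    return out


def hinge_report(analysis: RotationAnalysis, state_a: StructureModel,
                 state_b: StructureModel, window: int = 5,
                 min_flag_displacement: float = 1e-6) -> pd.DataFrame:
    """Per-residue Calpha displacement after fixed-selection alignment.

    Recomputes the fixed alignment recorded in ``analysis``, then lists,
    for every chain appearing in the mobile selection, each residue's
    Calpha displacement between the aligned states. The contiguous
    ``window`` of residues with the largest mean absolute displacement
    gradient (first difference along the sequence) is flagged as the
    candidate hinge; ties break to the earliest window. Identical states
    (max displacement below ``min_flag_displacement``) flag nothing.
    """
    if window < 2:
        raise ValueError("window must span at least 2 residues")
    fa = select_coords(state_a, analysis.fixed_selection)
    fb = select_coords(state_b, analysis.fixed_selection)
    align = superpose(fb, fa)

    chains: list[str] = []
    for spec in analysis.mobile_selection:
        if spec.chain_id not in chains:
            chains.append(spec.chain_id)

    rows = []
    for chain in chains:
        ca_a = _ca_table(state_a, chain)
        ca_b = _ca_table(state_b, chain)
        shared = sorted(set(ca_a) & set(ca_b))
        if not shared:
            raise ValueError(f"no shared Calpha atoms on chain {chain!r}")
        for r in shared:
            moved = apply_transform(ca_b[r][None, :], align)[0]
            rows.append({
                "chain_id": chain,
                "res_seq": r,
                "displacement": float(np.linalg.norm(moved - ca_a[r])),
            })
    table = pd.DataFrame(rows)
    table["hinge"] = False

    if table["displacement"].max() >= min_flag_displacement:
        best: tuple[float, int] | None = None  # (-score, row offset) for ties
        for chain in chains:
            sub = table[table["chain_id"] == chain].reset_index()
            if len(sub) < window:
                continue
            grad = np.abs(np.diff(sub["displacement"].to_numpy()))
            # score windows of `window` residues = mean |gradient| inside
            for start in range(0, len(sub) - window + 1):
                score = float(grad[start:start + window - 1].mean())
                key = (-score, int(sub.loc[start, "index"]))
                if best is None or key < best[0]:
                    best = (key, start, chain)
        if best is not None and -best[0][0] > 0:
            _, start, chain = best
            sub_idx = table.index[table["chain_id"] == chain][start:start + window]
            table.loc[sub_idx, "hinge"] = True
    return table
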