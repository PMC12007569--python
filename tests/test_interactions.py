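"""Interaction typing, fingerprints, convergence and pose clustering."""

import itertools
import math

import numpy as np
import pytest

from gatescape.interactions import (
    InteractionCriteria,
    LigandSpec,
    builtin_ligand_spec,
    cluster_poses,
    detect_interactions,
    fingerprint,
    kelley_penalty,
    load_ligand_spec,
    pose_convergence,
)
from gatescape.structures import AtomRecord, GroupSpec, SelectionError, StructureModel
from gatescape.synthetic import generate_pose_set


def _res(chain, seq, name, placed):
    return [AtomRecord(chain, seq, name, an, an[0], xyz) for an, xyz in placed]


def _lig(placed, res_name="LIG"):
    return [AtomRecord("L", 1, res_name, an, el, xyz, het=True)
            for an, el, xyz in placed]


def _ring_at(center, z=0.0, radius=1.39, tilt_deg=0.0, prefix="C", start=1):
    """Planar hexagon; tilt rotates the ring plane about the x axis."""
    th = math.radians(tilt_deg)
    pts = []
    for i in range(6):
        ang = math.pi / 3 * i
        x, y, zz = radius * math.cos(ang), radius * math.sin(ang), 0.0
        y, zz = y * math.cos(th) - zz * math.sin(th), y * math.sin(th) + zz * math.cos(th)
        pts.append((f"{prefix}{start + i}",
                    (center[0] + x, center[1] + y, center[2] + zz + z)))
    return pts


LYS_STUB = [("N", (0, 10, 0)), ("CA", (0, 9, 0)), ("C", (1, 9, 0)), ("O", (1, 10, 0)),
            ("CB", (0, 7.5, 0)), ("CG", (0, 6.4, 0)), ("CD", (0, 5.2, 0)),
            ("CE", (0, 4.2, 0)), ("NZ", (0, 3.0, 0))]


def _model(prot_atoms, lig_atoms):
    return StructureModel("case", prot_atoms + lig_atoms)


ACCEPTOR_LIG = LigandSpec("LIG", acceptors=("O1",),
                          charged_groups=(("carboxylate", ("O1", "O2"), -1),))


class TestDetectInteractions:
    def test_carboxylate_near_lysine_gives_ionic_and_hbond(self):
        lig = _lig([("O1", "O", (0.0, 0.4, 0.0)), ("O2", "O", (1.2, -0.4, 0.0)),
                    ("C1", "C", (0.6, 0.0, 0.0))])
        model = _model(_res("B", 49, "LYS", LYS_STUB), lig)
        recs = detect_interactions(model, ACCEPTOR_LIG, [GroupSpec("B", frozenset({49}))])
        kinds = sorted(r.kind for r in recs)
        # NZ-O1 distance 2.6 A (hbond) and carboxylate centroid 3.0 A (ionic)
        assert kinds == ["hbond", "ionic"]

    def test_far_ligand_yields_no_records(self):
        lig = _lig([("O1", "O", (50.0, 50.0, 50.0)), ("O2", "O", (51.0, 50.0, 50.0))])
        model = _model(_res("B", 49, "LYS", LYS_STUB), lig)
        assert detect_interactions(model, ACCEPTOR_LIG,
                                   [GroupSpec("B", frozenset({49}))]) == []

    def test_parallel_stacked_rings(self):
        phe = _res("A", 68, "PHE",
                   [("N", (0, 0, 10)), ("CA", (0, 1, 10)), ("C", (1, 1, 10)),
                    ("O", (1, 0, 10)), ("CB", (0, 2, 8))]
                   + list(zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                              [xyz for _, xyz in _ring_at((0, 0, 0))])))
        ring_spec = LigandSpec("LIG", rings=(("R1", "R2", "R3", "R4", "R5", "R6"),))
        # offset 1.0 laterally, 3.9 vertically: centroid distance ~4.0, angle 5 deg
        lig = _lig([(f"R{i+1}", "C", xyz) for i, (_, xyz) in enumerate(
            _ring_at((1.0, 0, 0), z=3.9, tilt_deg=5.0))])
        model = _model(phe, lig)
        recs = detect_interactions(model, ring_spec, [GroupSpec("A", frozenset({68}))])
        assert [r.kind for r in recs] == ["pi_parallel"]

    def test_perpendicular_rings(self):
        phe = _res("A", 68, "PHE",
                   [("N", (0, 0, 12)), ("CA", (0, 1, 12)), ("C", (1, 1, 12)),
                    ("O", (1, 0, 12)), ("CB", (0, 2, 9))]
                   + list(zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                              [xyz for _, xyz in _ring_at((0, 0, 0))])))
        ring_spec = LigandSpec("LIG", rings=(("R1", "R2", "R3", "R4", "R5", "R6"),))
        lig = _lig([(f"R{i+1}", "C", xyz) for i, (_, xyz) in enumerate(
            _ring_at((0, 0, 0), z=5.0, tilt_deg=85.0))])
        recs = detect_interactions(_model(phe, lig), ring_spec,
                                   [GroupSpec("A", frozenset({68}))])
        assert [r.kind for r in recs] == ["pi_perpendicular"]

    def test_hydrophobic_collapsed_to_one_record_per_residue(self):
        leu = _res("B", 96, "LEU",
                   [("N", (0, 0, 8)), ("CA", (0, 1, 8)), ("C", (1, 1, 8)), ("O", (1, 0, 8)),
                    ("CB", (0, 0, 5)), ("CG", (0, 0, 4)),
                    ("CD1", (0, 0, 3.0)), ("CD2", (1.2, 0, 3.2))])
        apolar_lig = LigandSpec("LIG", apolar=("C3", "C4"))
        lig = _lig([("C3", "C", (0, 0, 0)), ("C4", "C", (1.0, 0, 0))])
        recs = detect_interactions(_model(leu, lig), apolar_lig,
                                   [GroupSpec("B", frozenset({96}))])
        assert len(recs) == 1
        assert recs[0].kind == "hydrophobic"
        assert recs[0].distance == pytest.approx(3.0, abs=1e-9)

    def test_unknown_site_residue_named_in_error(self):
        odd = _res("A", 7, "XXX", [("CA", (0, 0, 0))])
        lig = _lig([("O1", "O", (3, 0, 0)), ("O2", "O", (4, 0, 0))])
        with pytest.raises(SelectionError, match="XXX"):
            detect_interactions(_model(odd, lig), ACCEPTOR_LIG,
                                [GroupSpec("A", frozenset({7}))])

    def test_records_satisfy_their_own_cutoffs(self):
        poses, _, site = generate_pose_set(10, 0.5, seed=2)
        crit = InteractionCriteria()
        lig = builtin_ligand_spec("pyruvate")
        cutoff = {"hbond": crit.hbond_dist, "ionic": crit.ionic_dist,
                  "pi_parallel": crit.pi_parallel_dist,
                  "pi_perpendicular": crit.pi_perp_dist,
                  "hydrophobic": crit.hydrophobic_dist}
        for pose in poses:
            for rec in detect_interactions(pose, lig, site, crit):
                assert rec.distance <= cutoff[rec.kind]

    def test_invariant_under_rigid_transform_of_complex(self):
        poses, _, site = generate_pose_set(3, 1.0, seed=4)
        lig = builtin_ligand_spec("pyruvate")
        base = detect_interactions(poses[0], lig, site)
        th = math.radians(33)
        R = np.array([[math.cos(th), 0, math.sin(th)], [0, 1, 0],
                      [-math.sin(th), 0, math.cos(th)]])
        moved = poses[0].with_coords(poses[0].coords_array() @ R.T + [3, 1, -8])
        got = detect_interactions(moved, lig, site)
        assert fingerprint(got) == fingerprint(base)
        assert [r.distance for r in got] == pytest.approx(
            [r.distance for r in base], abs=1e-9)


class TestFingerprint:
    def test_empty_and_permutation_invariance(self):
        poses, _, site = generate_pose_set(2, 1.0, seed=1)
        lig = builtin_ligand_spec("pyruvate")
        recs = detect_interactions(poses[0], lig, site)
        assert fingerprint([]) == frozenset()
        assert fingerprint(recs) == fingerprint(list(reversed(recs)))

    def test_distance_jitter_within_cutoffs_preserves_fingerprint(self):
        poses, _, site = generate_pose_set(10, 1.0, seed=9)
        lig = builtin_ligand_spec("pyruvate")
        fps = {fingerprint(detect_interactions(p, lig, site)) for p in poses}
        assert len(fps) == 1


class TestPoseConvergence:
    def test_exact_fraction_on_constructed_pose_set(self):
        poses, labels, site = generate_pose_set(80, 0.70, seed=0)
        res = pose_convergence(poses, builtin_ligand_spec("pyruvate"), site)
        assert res.convergence_fraction == pytest.approx(0.70, abs=1e-12)
        # independent count: poses whose fingerprint contains the modal set
        count = sum(1 for fp in res.fingerprints.values()
                    if fp >= res.modal_fingerprint)
        assert res.convergence_fraction == count / 80

    def test_all_identical_poses_converge_fully(self):
        poses, _, site = generate_pose_set(12, 1.0, seed=3)
        res = pose_convergence(poses, builtin_ligand_spec("pyruvate"), site)
        assert res.convergence_fraction == 1.0


def _brute_force_average_linkage(D):
    """O(n^3) agglomeration; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(D))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestClusterPoses:
    def _grouped_poses(self, centers, per, seed, sigma=0.3):
        rng = np.random.default_rng(seed)
        base, _, site = generate_pose_set(1, 1.0, seed=0)
        lig_atoms = [a for a in base[0].atoms if a.het]
        site_atoms = [a for a in base[0].atoms if not a.het]
        poses, truth = [], []
        i = 0
        for c, center in enumerate(centers):
            for _ in range(per):
                shift = np.asarray(center, dtype=float) + rng.normal(0, sigma, 3)
                moved = [AtomRecord(a.chain_id, a.res_seq, a.res_name, a.atom_name,
                                    a.element, tuple(np.array(a.coords) + shift), True)
                         for a in lig_atoms]
                poses.append(StructureModel(f"p{i:03d}", site_atoms + moved))
                truth.append(c)
                i += 1
        return poses, truth, site

    @pytest.mark.parametrize("k_true", [2, 3, 4])
    def test_kelley_minimum_recovers_group_count(self, k_true):
        # tight groups (duplicated poses): spread vanishes at k >= k_true,
        # so the penalty minimum lands exactly on the group count
        from sklearn.metrics import adjusted_rand_score

        for seed in range(3):
            rng = np.random.default_rng(seed)
            centers = rng.uniform(-30, 30, size=(k_true, 3))
            centers = centers[np.argsort(centers[:, 0])]
            while np.min(np.diff(np.sort(centers[:, 0]))) < 15:
                centers[:, 0] = np.sort(rng.uniform(-30, 30, k_true)) * 2
            poses, truth, site = self._grouped_poses(centers, per=8, seed=seed,
                                                     sigma=0.0)
            res = cluster_poses(poses, site)
            assert res.chosen_k == k_true
            labels = [res.assignment[p.model_id] for p in poses]
            assert adjusted_rand_score(truth, labels) == 1.0

    def test_kelley_tolerates_jitter_for_multiple_groups(self):
        poses, truth, site = self._grouped_poses(
            [(0, 0, 0), (18, 0, 0), (0, 18, 0)], per=8, seed=11, sigma=0.2)
        res = cluster_poses(poses, site)
        assert res.chosen_k == 3

    def test_identical_poses_fall_back_to_k2_flagged_degenerate(self):
        poses, _, site = self._grouped_poses([(0, 0, 0)], per=6, seed=0, sigma=0.0)
        res = cluster_poses(poses, site)
        assert res.degenerate and res.chosen_k == 2

    def test_linkage_heights_match_brute_force(self):
        poses, _, site = self._grouped_poses(
            [(0, 0, 0), (10, 0, 0)], per=10, seed=5, sigma=2.0)  # n = 20
        res = cluster_poses(poses, site)
        from gatescape.interactions import _pose_coords
        coords = [_pose_coords(p, site) for p in poses]
        n = len(poses)
        D = np.zeros((n, n))
        from gatescape.structures import rmsd_unaligned
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = rmsd_unaligned(coords[i], coords[j])
        brute = _brute_force_average_linkage(D)
        assert np.allclose(sorted(res.linkage[:, 2]), brute, atol=1e-9)

    def test_chosen_k_stable_under_pose_permutation(self):
        poses, _, site = self._grouped_poses(
            [(0, 0, 0), (15, 0, 0), (0, 15, 0)], per=7, seed=7)
        base = cluster_poses(poses, site)
        rng = np.random.default_rng(0)
        shuffled = [poses[i] for i in rng.permutation(len(poses))]
        assert cluster_poses(shuffled, site).chosen_k == base.chosen_k

    def test_penalty_finite_over_full_k_range(self):
        poses, _, site = self._grouped_poses([(0, 0, 0), (12, 0, 0)], per=5, seed=1)
        res = cluster_poses(poses, site)
        assert sorted(res.kelley_penalty) == list(range(2, len(poses)))
        assert all(np.isfinite(v) for v in res.kelley_penalty.values())

    def test_composition_mismatch_rejected(self):
        poses, _, site = self._grouped_poses([(0, 0, 0)], per=3, seed=0)
        truncated = StructureModel("bad", poses[0].atoms[:-1])
        with pytest.raises(ValueError, match="composition"):
            cluster_poses(poses[:2] + [truncated], site)


class TestLigandSpecs:
    @pytest.mark.parametrize("name", ["pyruvate", "c7", "zaprinast", "mitoglitazone"])
    def test_builtin_specs_load(self, name):
        spec = builtin_ligand_spec(name)
        assert spec.res_name
        for ring in spec.rings:
            assert len(ring) >= 5

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "lig.yaml"
        path.write_text(
            "res_name: TST\ndonors: [N1]\nacceptors: [O1]\n"
            "charged_groups:\n  - {name: amine, atoms: [N1], sign: 1}\n"
            "rings:\n  - [C1, C2, C3, C4, C5]\napolar: [C9]\n")
        spec = load_ligand_spec(path)
        assert spec.res_name == "TST" and spec.charged_groups[0][2] == 1

    def test_small_ring_rejected(self):
        with pytest.raises(ValueError, match="fewer than 5"):
            LigandSpec("BAD", rings=(("C1", "C2", "C3"),))
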