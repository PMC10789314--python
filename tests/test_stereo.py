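"""Geometry, clustering and Boltzmann-weighting checks for stereochemistry calls."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fdmoscreen import stereo, synthetic as syn
from fdmoscreen.errors import ConfigError, DegenerateGeometryError, DomainError
from fdmoscreen.stereo import (
    Cluster,
    ClusterSet,
    RingSpec,
    ThermoParams,
    boltzmann_rfrac,
    classify_pose,
    cluster_poses,
    consensus_stereochemistry,
    label_from_rfrac,
    pose_angle,
    ring_plane_normal,
)
from fdmoscreen.structio import AtomRecord, Pose, PoseEnsemble

from conftest import shifted_pose


def _pose_from_points(points, names=None, energy=-1.0):
    names = names or [f"C{i + 1}" for i in range(len(points))]
    atoms = [AtomRecord(n, "C", 1, "LIG", "X", np.asarray(p, dtype=float))
             for n, p in zip(names, points)]
    return Pose(pose_id=1, ligand_atoms=atoms, energy=energy)


class TestRingPlaneNormal:
    def test_axis_aligned_cross_product(self):
        pose = _pose_from_points([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        n = ring_plane_normal(pose, RingSpec(("C1", "C2", "C3")))
        assert np.allclose(n, [0, 0, 1])

    def test_order_reversal_flips_normal(self):
        pose = _pose_from_points([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        n = ring_plane_normal(pose, RingSpec(("C1", "C3", "C2")))
        assert np.allclose(n, [0, 0, -1])

    def test_rotation_equivariance(self):
        # derived oracle: rotating the atoms rotates the base-case normal identically
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        base = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        pose = _pose_from_points([rot @ np.asarray(p, dtype=float) for p in base])
        n = ring_plane_normal(pose, RingSpec(("C1", "C2", "C3")))
        assert np.allclose(n, rot @ np.array([0, 0, 1.0]), atol=1e-12)

    def test_collinear_atoms_degenerate(self):
        pose = _pose_from_points([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        with pytest.raises(DegenerateGeometryError):
            ring_plane_normal(pose, RingSpec(("C1", "C2", "C3")))


class TestPoseAngle:
    def _fad(self, xyz):
        return AtomRecord("C4A", "C", 900, "FAD", "F", np.asarray(xyz, dtype=float))

    def test_parallel_antiparallel_orthogonal(self):
        pose = _pose_from_points([(1, 0, 0), (-0.5, 0.866, 0), (-0.5, -0.866, 0)])
        ring = RingSpec(("C1", "C2", "C3"))
        centroid = pose.centroid
        assert pose_angle(pose, ring, self._fad(centroid + [0, 0, 5])) == pytest.approx(0.0)
        assert pose_angle(pose, ring, self._fad(centroid + [0, 0, -5])) == pytest.approx(180.0)
        assert pose_angle(pose, ring, self._fad(centroid + [5, 0, 0])) == pytest.approx(90.0)

    def test_reference_at_centroid_degenerate(self):
        pose = _pose_from_points([(1, 0, 0), (-0.5, 0.866, 0), (-0.5, -0.866, 0)])
        with pytest.raises(DegenerateGeometryError):
            pose_angle(pose, RingSpec(("C1", "C2", "C3")), self._fad(pose.centroid))


@pytest.mark.parametrize(
    "angle,expected",
    [(0.0, "S"), (45.0, "S"), (89.9, "S"), (90.0, "degenerate"), (90.1, "R"),
     (135.0, "R"), (180.0, "R")],
)
def test_angle_rule(angle, expected):
    """Angles below 90 deg produce S poses, above 90 deg R poses."""
    assert classify_pose(angle) == expected


def test_classify_pose_rejects_out_of_range():
    with pytest.raises(DomainError):
        classify_pose(181.0)


class TestClustering:
    def test_identical_poses_single_cluster(self):
        base = _pose_from_points([(0, 0, 0), (1.5, 0, 0), (0, 1.5, 0)])
        poses = [shifted_pose(base, (0, 0, 0), pose_id=i, energy=-5.0 + i) for i in range(3)]
        cs = cluster_poses(PoseEnsemble("e", "l", poses))
        assert len(cs) == 1 and cs.top.size == 3
        assert cs.top.representative_pose_id == 0 and cs.top.energy == -5.0

    def test_distant_poses_split(self):
        base = _pose_from_points([(0, 0, 0), (1.5, 0, 0), (0, 1.5, 0)])
        poses = [shifted_pose(base, (0, 0, 0), pose_id=1, energy=-5.0),
                 shifted_pose(base, (10, 0, 0), pose_id=2, energy=-4.0)]
        cs = cluster_poses(PoseEnsemble("e", "l", poses))
        assert len(cs) == 2 and all(c.size == 1 for c in cs.clusters)

    def test_nonpositive_radius_rejected(self):
        base = _pose_from_points([(0, 0, 0), (1.5, 0, 0), (0, 1.5, 0)])
        with pytest.raises(DomainError):
            cluster_poses(PoseEnsemble("e", "l", [base]), radius=0.0)

    @staticmethod
    def _naive_leader(poses, radius):
        """Independent brute-force leader clustering over the same visit order."""
        leaders, parts = [], []
        for p in poses:
            for k, leader in enumerate(leaders):
                if np.sqrt(np.mean(np.sum((p.coords - leader.coords) ** 2, axis=1))) <= radius:
                    parts[k].add(p.pose_id)
                    break
            else:
                leaders.append(p)
                parts.append({p.pose_id})
        return parts

    def test_jittered_poses_match_naive_oracle(self):
        rng = np.random.default_rng(42)
        base = _pose_from_points([(0, 0, 0), (1.5, 0, 0), (0, 1.5, 0), (1, 1, 0.5)])
        centers = [(0, 0, 0), (4, 0, 0), (0, 4, 2)]
        poses = []
        for i in range(50):
            c = centers[rng.integers(3)]
            jit = rng.normal(scale=0.5, size=3)
            poses.append(shifted_pose(base, np.asarray(c) + jit, pose_id=i,
                                      energy=float(rng.normal())))
        ens = PoseEnsemble("e", "l", poses)
        cs = cluster_poses(ens, radius=1.0)
        expected = self._naive_leader(ens.poses, 1.0)
        assert sorted(map(sorted, (c.member_pose_ids for c in cs.clusters))) == sorted(
            map(sorted, expected)
        )

    def test_partition_and_representative_invariants(self):
        rng = np.random.default_rng(7)
        base = _pose_from_points([(0, 0, 0), (1.5, 0, 0), (0, 1.5, 0)])
        poses = [shifted_pose(base, rng.normal(scale=2, size=3), pose_id=i,
                              energy=float(rng.normal())) for i in range(40)]
        ens = PoseEnsemble("e", "l", poses)
        cs = cluster_poses(ens, radius=1.2)
        all_ids = sorted(i for c in cs.clusters for i in c.member_pose_ids)
        assert all_ids == sorted(p.pose_id for p in poses)
        by_id = {p.pose_id: p.energy for p in poses}
        for c in cs.clusters:
            assert c.energy == min(by_id[i] for i in c.member_pose_ids)
            assert by_id[c.representative_pose_id] == c.energy
        assert [c.energy for c in cs.clusters] == sorted(c.energy for c in cs.clusters)


def _clusters(specs, radius=1.0):
    cs = [Cluster(member_pose_ids=list(range(s_id * 100, s_id * 100 + g)),
                  representative_pose_id=s_id * 100, energy=e, angle=a, stereo_call=call)
          for s_id, (g, e, a, call) in enumerate(specs)]
    return ClusterSet(clusters=cs, radius=radius)


class TestBoltzmannRfrac:
    def test_single_r_cluster_normalizes_to_one(self):
        res = boltzmann_rfrac(_clusters([(3, -10.0, 120.0, "R")]))
        assert res.r_frac == 1.0 and res.label == "R"

    def test_equal_clusters_split_half(self):
        res = boltzmann_rfrac(_clusters([(2, -5.0, 120.0, "R"), (2, -5.0, 60.0, "S")]))
        assert res.r_frac == pytest.approx(0.5, abs=1e-15)
        assert res.label == "R/S"

    def test_closed_form_kt_ln2_energy_gap(self):
        # weights 1 and 1/2 -> R_frac = 2/3 exactly
        thermo = ThermoParams()
        gap = thermo.kt * math.log(2.0)
        res = boltzmann_rfrac(_clusters([(1, 0.0, 120.0, "R"), (1, gap, 60.0, "S")]), thermo)
        assert res.r_frac == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_brute_force_oracle_on_random_cluster_sets(self):
        rng = np.random.default_rng(3)
        thermo = ThermoParams()
        for _ in range(100):
            n = rng.integers(1, 13)
            sizes = rng.integers(1, 20, size=n)
            energies = rng.normal(scale=3.0, size=n)
            calls = rng.choice(["R", "S"], size=n)
            cs = _clusters([(int(g), float(e), 45.0, c)
                            for g, e, c in zip(sizes, energies, calls)])
            res = boltzmann_rfrac(cs, thermo)
            w = sizes * np.exp(-(energies - energies.min()) / thermo.kt)
            expected = w[calls == "R"].sum() / w.sum()
            assert res.r_frac == pytest.approx(expected, rel=1e-12)

    def test_shift_invariance(self):
        specs = [(2, -4.0, 120.0, "R"), (5, -2.0, 60.0, "S"), (1, -6.0, 130.0, "R")]
        r1 = boltzmann_rfrac(_clusters(specs)).r_frac
        shifted = [(g, e + 37.5, a, c) for g, e, a, c in specs]
        r2 = boltzmann_rfrac(_clusters(shifted)).r_frac
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_temperature_limits(self):
        specs = [(1, -10.0, 120.0, "R"), (9, -5.0, 60.0, "S")]
        cold = boltzmann_rfrac(_clusters(specs), ThermoParams(temperature=1e-3))
        hot = boltzmann_rfrac(_clusters(specs), ThermoParams(temperature=1e9))
        assert cold.r_frac == pytest.approx(1.0, abs=1e-12)  # unique minimum is R
        assert hot.r_frac == pytest.approx(0.1, abs=1e-5)  # -> g_R / sum g

    def test_degenerate_clusters_count_only_in_z(self):
        res = boltzmann_rfrac(
            _clusters([(1, -5.0, 120.0, "R"), (1, -5.0, 90.0, "degenerate")])
        )
        assert res.r_frac == pytest.approx(0.5, abs=1e-15)

    def test_all_degenerate_is_an_error(self):
        with pytest.raises(DegenerateGeometryError):
            boltzmann_rfrac(_clusters([(1, -5.0, 90.0, "degenerate")]))


def test_chirality_antisymmetry_reversing_ring_order():
    """Reversing the ring atom order maps angles to 180-theta and R_frac to 1-R_frac."""
    rng = np.random.default_rng(9)
    receptor, base = syn.generate_toy_complex(35.0, n_decoration_atoms=2)
    fad = receptor.fad_atom(syn.TOY_FAD_ATOM)
    poses = []
    for i in range(12):
        poses.append(shifted_pose(base, rng.normal(scale=4, size=3), pose_id=i,
                                  energy=float(rng.normal())))
    ens = PoseEnsemble("e", "l", poses)
    ring, ring_rev = syn.TOY_RING, syn.TOY_RING.reversed()
    for pose in ens.poses:
        a_fwd = pose_angle(pose, ring, fad)
        a_rev = pose_angle(pose, ring_rev, fad)
        assert a_fwd + a_rev == pytest.approx(180.0, abs=1e-9)
    _, res_fwd = stereo.call_stereochemistry(ens, ring, fad, radius=1.0)
    _, res_rev = stereo.call_stereochemistry(ens, ring_rev, fad, radius=1.0)
    assert res_fwd.r_frac == pytest.approx(1.0 - res_rev.r_frac, abs=1e-12)


@pytest.mark.parametrize(
    "r_frac,expected",
    [(0.9, "R"), (0.81, "R"), (0.8, "R/S"), (0.5, "R/S"), (0.2, "R/S"), (0.19, "S"), (0.1, "S")],
)
def test_label_cutoffs(r_frac, expected):
    """R above 0.8, S below 0.2, racemic in between (cutoffs inclusive to R/S)."""
    assert label_from_rfrac(r_frac) == expected


def test_label_rejects_out_of_unit_interval():
    with pytest.raises(DomainError):
        label_from_rfrac(1.2)


@pytest.mark.parametrize(
    "labels,expected",
    [(["R", "R", "S", "R/S"], "R"), (["R", "S"], "R/S"), (["S", "S", "S", "S"], "S"),
     (["R", "R", "S", "S", "R/S"], "R/S")],
)
def test_consensus_is_mode_with_racemic_ties(labels, expected):
    assert consensus_stereochemistry(labels) == expected


def test_consensus_empty_rejected():
    with pytest.raises(DomainError):
        consensus_stereochemistry([])
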