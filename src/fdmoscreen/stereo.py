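"""Geometric stereochemistry calling from docked pose ensembles.

The product enantiomer formed by an FAD-dependent monooxygenase is read off
the geometry of the docked substrate: three atoms on the ligand's resorcinol
ring define a plane normal, and the angle between that normal and the vector
from the ligand centroid to the reactive flavin ring atom (C4alpha, the atom
that bonds the hydroperoxyl group in the activated cofactor) classifies a
pose.  An angle in [0, 90) degrees is an S pose; (90, 180] is an R pose.

Poses are first clustered (greedy leader clustering at a fixed RMSD radius,
no superposition — the receptor frame is shared by construction) and each
cluster is treated as a mesostate with degeneracy g_i (cluster size) and
energy E_i (its lowest-energy representative).  The R fraction is then the
Boltzmann average over mesostates::

    R_frac = sum_{i in R} g_i exp(-E_i / kT) / Z,   Z = sum_i g_i exp(-E_i / kT)

R_frac > 0.8 calls R, R_frac < 0.2 calls S, anything between is racemic
(R/S).  Consensus over several ligands is the modal label, with R/S on ties.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, DomainError
from .structio import AtomRecord, Pose, PoseEnsemble

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/(mol K)
KB_KCAL = 0.0019872

S_LABEL, R_LABEL, RACEMIC_LABEL, DEGENERATE = "S", "R", "R/S", "degenerate"


@dataclass(frozen=True)
class RingSpec:
    """Ordered triple of ligand atom names spanning the aromatic ring plane.

    The atom order fixes the normal's sign via the right-hand rule; reversing
    the order flips every stereochemistry call (chirality antisymmetry).
    """

    atom_triple: tuple[str, str, str]

    def __post_init__(self):
        if len(set(self.atom_triple)) != 3:
            raise DomainError("RingSpec needs 3 distinct atom names")

    def reversed(self) -> "RingSpec":
        a, b, c = self.atom_triple
        return RingSpec((a, c, b))


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and Boltzmann constant for mesostate weighting."""

    temperature: float = 300.0  # K
    k_b: float = KB_KCAL  # kcal/(mol K)

    def __post_init__(self):
        if self.temperature <= 0:
            raise DomainError("temperature must be > 0 K")

    @property
    def kt(self) -> float:
        return self.k_b * self.temperature


@dataclass
class Cluster:
    """A pose mesostate: members, degeneracy, representative energy and call."""

    member_pose_ids: list[int]
    representative_pose_id: int
    energy: float  # kcal/mol, lowest-energy member
    angle: float | None = None  # degrees, representative pose
    stereo_call: str | None = None  # R, S or degenerate

    @property
    def size(self) -> int:
        return len(self.member_pose_ids)


@dataclass
class ClusterSet:
    """Clusters ranked by ascending representative energy."""

    clusters: list[Cluster]
    radius: float

    def __post_init__(self):
        self.clusters.sort(key=lambda c: (c.energy, c.representative_pose_id))

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def top(self) -> Cluster:
        return self.clusters[0]


@dataclass
class StereoResult:
    """Boltzmann-weighted R fraction and the resulting stereochemistry label."""

    r_frac: float
    partition_value: float
    label: str
    per_cluster_weights: np.ndarray = field(default_factory=lambda: np.empty(0))


def ring_plane_normal(pose: Pose, ring: RingSpec) -> np.ndarray:
    """Unit normal of the ring plane spanned by the three named atoms.

    Computed as the normalised cross product (a2-a1) x (a3-a1); orientation
    follows the right-hand rule on the given atom order.
    """
    p1, p2, p3 = (pose.atom(n).coords for n in ring.atom_triple)
    cross = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(cross)
    if norm < 1e-9:
        raise DegenerateGeometryError(f"ring atoms {ring.atom_triple} are collinear")
    return cross / norm


def pose_angle(pose: Pose, ring: RingSpec, fad_reference_atom: AtomRecord) -> float:
    """Angle (degrees) between the ring normal and the centroid-to-FAD vector.

    The reference point on the ligand is the mean heavy-atom coordinate; the
    FAD reference atom is the flavin ring atom bonding the hydroperoxyl group.
    """
    normal = ring_plane_normal(pose, ring)
    to_fad = fad_reference_atom.coords - pose.centroid
    d = np.linalg.norm(to_fad)
    if d < 1e-9:
        raise DegenerateGeometryError("FAD reference coincides with ligand centroid")
    cosang = float(np.clip(np.dot(normal, to_fad) / d, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def classify_pose(angle: float, tolerance: float = 1e-9) -> str:
    """Map a pose angle to S (< 90 deg), R (> 90 deg) or degenerate (~ 90 deg)."""
    if not 0.0 <= angle <= 180.0:
        raise DomainError(f"angle {angle} outside [0, 180]")
    if abs(angle - 90.0) <= tolerance:
        return DEGENERATE
    return S_LABEL if angle < 90.0 else R_LABEL


def _pairwise_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    # fixed-frame RMSD: no least-squares superposition
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def cluster_poses(ensemble: PoseEnsemble, radius: float = 1.0) -> ClusterSet:
    """Greedy leader clustering of poses at a heavy-atom RMSD radius.

    Poses are visited in ascending-energy order (the ensemble's native order).
    Each pose joins the first existing cluster whose *leader* lies within
    ``radius`` RMSD in the fixed receptor frame, else founds a new cluster.
    Because visiting order is ascending in energy, each leader is also the
    lowest-energy member, i.e. the cluster representative.
    """
    if radius <= 0:
        raise DomainError("cluster radius must be > 0")
    leaders: list[np.ndarray] = []
    clusters: list[Cluster] = []
    for pose in ensemble.poses:  # already sorted by energy
        coords = pose.coords
        for i, leader in enumerate(leaders):
            if _pairwise_rmsd(coords, leader) <= radius:
                clusters[i].member_pose_ids.append(pose.pose_id)
                break
        else:
            leaders.append(coords)
            clusters.append(
                Cluster(
                    member_pose_ids=[pose.pose_id],
                    representative_pose_id=pose.pose_id,
                    energy=pose.energy,
                )
            )
    return ClusterSet(clusters=clusters, radius=radius)


def annotate_clusters(
    clusters: ClusterSet,
    ensemble: PoseEnsemble,
    ring: RingSpec,
    fad_reference_atom: AtomRecord,
) -> ClusterSet:
    """Fill each cluster's angle and R/S call from its representative pose."""
    by_id = {p.pose_id: p for p in ensemble.poses}
    for c in clusters.clusters:
        rep = by_id[c.representative_pose_id]
        c.angle = pose_angle(rep, ring, fad_reference_atom)
        c.stereo_call = classify_pose(c.angle)
    return clusters


def boltzmann_rfrac(clusters: ClusterSet, thermo: ThermoParams = ThermoParams()) -> StereoResult:
    """Boltzmann-weighted fraction of ensemble weight in R-calling clusters.

    Each cluster i contributes weight g_i * exp(-(E_i - E_min)/kT); the shift
    by E_min is mathematically neutral (it cancels in the ratio) and keeps the
    exponentials in range.  Degenerate (90 deg) clusters contribute to the
    partition value Z but never to the R numerator — they are conservatively
    counted as non-R.
    """
    if not clusters.clusters:
        raise DomainError("empty cluster set")
    calls = [c.stereo_call for c in clusters.clusters]
    if any(call is None for call in calls):
        raise DomainError("all clusters must have stereo_call populated")
    if all(call == DEGENERATE for call in calls):
        raise DegenerateGeometryError("all clusters degenerate: stereochemistry undefined")
    if any(call == DEGENERATE for call in calls):
        logger.warning("degenerate clusters present; counted as non-R in R_frac")
    energies = np.array([c.energy for c in clusters.clusters])
    sizes = np.array([c.size for c in clusters.clusters], dtype=float)
    weights = sizes * np.exp(-(energies - energies.min()) / thermo.kt)
    z = float(weights.sum())
    is_r = np.array([call == R_LABEL for call in calls])
    r_frac = float(weights[is_r].sum() / z)
    return StereoResult(
        r_frac=r_frac,
        partition_value=z,
        label=label_from_rfrac(r_frac),
        per_cluster_weights=weights,
    )


def label_from_rfrac(r_frac: float) -> str:
    """R for R_frac > 0.8, S for R_frac < 0.2, racemic (R/S) otherwise.

    The cutoffs themselves (0.2 and 0.8 exactly) fall in the racemic band.
    """
    if not 0.0 <= r_frac <= 1.0:
        raise DomainError(f"r_frac {r_frac} outside [0, 1]")
    if r_frac > 0.8:
        return R_LABEL
    if r_frac < 0.2:
        return S_LABEL
    return RACEMIC_LABEL


def consensus_stereochemistry(labels: list[str]) -> str:
    """Modal label across ligands; R/S whenever the mode is not unique."""
    if not labels:
        raise DomainError("empty label list")
    counts = Counter(labels)
    top = counts.most_common()
    modes = [lab for lab, n in top if n == top[0][1]]
    return modes[0] if len(modes) == 1 else RACEMIC_LABEL


def call_stereochemistry(
    ensemble: PoseEnsemble,
    ring: RingSpec,
    fad_reference_atom: AtomRecord,
    radius: float = 1.0,
    thermo: ThermoParams = ThermoParams(),
) -> tuple[ClusterSet, StereoResult]:
    """Cluster, annotate and Boltzmann-average one enzyme-ligand ensemble."""
    clusters = cluster_poses(ensemble, radius=radius)
    annotate_clusters(clusters, ensemble, ring, fad_reference_atom)
    return clusters, boltzmann_rfrac(clusters, thermo)
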