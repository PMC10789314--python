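"""Synthetic fixtures with known ground truth for every pipeline stage.

Generators here emulate, at desk scale, the study conditions of the FDMO
functional screen: planar-ring ligand poses at controlled orientations to a
flavin reference atom, pose ensembles with planted cluster structure and
energies, descriptor tables drawn from a known logistic model, and sequence
libraries whose stereochemistry and reactivity labels are driven by planted
determinant columns (an F/Y stereo switch and an I/V reactivity switch,
mirroring the residue-239 and residue-54 mechanisms) plus label noise.

Every generator is a deterministic function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .reactivity import DESCRIPTOR_NAMES
from .seqfeatures import Alignment, ReferenceMap, ResidueSet, build_feature_matrix, FeatureMatrix
from .stereo import RingSpec
from .structio import AtomRecord, ComplexStructure, Pose, PoseEnsemble

#: ring atoms used by all toy ligands (counter-clockwise in the ring plane)
TOY_RING = RingSpec(("C1", "C3", "C5"))
TOY_FAD_ATOM = "C4A"
TOY_ANION_ATOM = "O1"
TOY_ARG_RESIDUE = 2

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _ring_atoms(ring_radius: float = 1.4) -> list[AtomRecord]:
    atoms = []
    for k in range(6):
        phi = math.radians(60.0 * k)
        atoms.append(
            AtomRecord(
                atom_name=f"C{k + 1}",
                element="C",
                residue_number=1,
                residue_name="LIG",
                chain_id="X",
                coords=np.array([ring_radius * math.cos(phi), ring_radius * math.sin(phi), 0.0]),
            )
        )
    return atoms


def generate_toy_complex(
    angle: float,
    n_decoration_atoms: int = 2,
    seed: int = 0,
    fad_distance: float = 5.0,
    anion_arg_distance: float = 3.0,
    energy: float = -20.0,
) -> tuple[ComplexStructure, Pose]:
    """A minimal receptor/pose pair with an exactly controlled pose angle.

    The ligand is a planar six-carbon ring (normal +z for the ``TOY_RING``
    atom order) decorated with in-plane atoms placed so the heavy-atom mean
    stays at the ring centre; the FAD reference atom ``C4A`` sits at
    ``fad_distance`` A from the centre along a direction making exactly
    ``angle`` degrees with the ring normal.  The receptor shell carries an
    arginine-like residue whose CZ lies ``anion_arg_distance`` A from the
    ligand anion oxygen ``O1``.
    """
    if not 0.0 <= angle <= 180.0:
        raise DomainError(f"angle {angle} outside [0, 180]")
    lig_atoms = _ring_atoms()
    deco_radius = 2.8
    if n_decoration_atoms == 1:
        positions = [np.zeros(3)]
    else:
        positions = [
            np.array(
                [
                    deco_radius * math.cos(2 * math.pi * k / n_decoration_atoms + 0.3),
                    deco_radius * math.sin(2 * math.pi * k / n_decoration_atoms + 0.3),
                    0.0,
                ]
            )
            for k in range(n_decoration_atoms)
        ]
    for k, p in enumerate(positions):
        name = TOY_ANION_ATOM if k == 0 else f"C{7 + k - 1}"
        elem = "O" if k == 0 else "C"
        lig_atoms.append(
            AtomRecord(name, elem, 1, "LIG", "X", p)
        )
    pose = Pose(pose_id=1, ligand_atoms=lig_atoms, energy=energy)

    a = math.radians(angle)
    fad_pos = fad_distance * np.array([math.sin(a), 0.0, math.cos(a)])
    anion = pose.atom(TOY_ANION_ATOM).coords
    out_dir = anion / np.linalg.norm(anion) if np.linalg.norm(anion) > 0 else np.array([1.0, 0, 0])
    cz_pos = anion + anion_arg_distance * out_dir
    protein = [
        AtomRecord("CA", "C", 1, "GLY", "A", np.array([8.0, 8.0, 0.0])),
        AtomRecord("CA", "C", TOY_ARG_RESIDUE, "ARG", "A", cz_pos + np.array([1.5, 0, 0])),
        AtomRecord("CZ", "C", TOY_ARG_RESIDUE, "ARG", "A", cz_pos),
        AtomRecord("CA", "C", 3, "ALA", "A", np.array([-9.0, 4.0, 2.0])),
    ]
    fad = [
        AtomRecord(TOY_FAD_ATOM, "C", 900, "FAD", "F", fad_pos),
        AtomRecord("N5", "N", 900, "FAD", "F", fad_pos + np.array([0.0, 1.3, 0.0])),
    ]
    receptor = ComplexStructure(protein_atoms=protein, fad_atoms=fad, enzyme_id=f"toy{seed}")
    return receptor, pose


@dataclass(frozen=True)
class PoseClusterSpec:
    """One planted cluster: a template pose, its size, jitter and energies."""

    center_pose: Pose
    n_members: int
    jitter: float  # A, max rigid-body translation of any member
    base_energy: float  # kcal/mol, the representative's energy
    energy_spread: float  # members get base + U(0, spread]


def generate_pose_ensemble(
    cluster_spec: list[PoseClusterSpec],
    seed: int = 0,
) -> tuple[PoseEnsemble, list[set[int]]]:
    """Pose ensemble with a known cluster partition.

    Members are rigid-body translations of their cluster's template (no
    rotation, so fixed-frame RMSDs equal translation distances and the
    recovery condition is analytic).  Returns the ensemble and the true
    partition as a list of pose-id sets, in cluster_spec order.
    """
    if not cluster_spec:
        raise DomainError("need at least one cluster spec")
    rng = np.random.default_rng(seed)
    centers = [cs.center_pose.coords for cs in cluster_spec]
    if len(centers) > 1:
        min_sep = min(
            float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
            for i, a in enumerate(centers)
            for b in centers[i + 1 :]
        )
        if max(cs.jitter for cs in cluster_spec) >= min_sep / 2:
            raise ConfigError(
                f"jitter >= half the minimum inter-center RMSD ({min_sep:.3f} A): "
                "clusters not separable"
            )
    poses, partition = [], []
    pose_id = 0
    for cs in cluster_spec:
        ids = set()
        for m in range(cs.n_members):
            pose_id += 1
            ids.add(pose_id)
            # uniform direction, uniform radius in the jitter ball
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = direction * cs.jitter * rng.uniform() ** (1 / 3)
            energy = cs.base_energy if m == 0 else cs.base_energy + rng.uniform(
                1e-6, cs.energy_spread
            )
            atoms = [
                AtomRecord(a.atom_name, a.element, a.residue_number, a.residue_name, a.chain_id,
                           a.coords + shift)
                for a in cs.center_pose.ligand_atoms
            ]
            poses.append(Pose(pose_id=pose_id, ligand_atoms=atoms, energy=energy))
        partition.append(ids)
    ensemble = PoseEnsemble(enzyme_id="synthetic", ligand_id="lig", poses=poses)
    return ensemble, partition


@dataclass(frozen=True)
class ScreenSimConfig:
    """Conditions for the planted-determinant sequence screen.

    Defaults reflect the desk-scale study conditions: 300 enzymes, 60
    alignment columns, an F/Y stereo switch and an I/V reactivity switch,
    10% label noise, uniform background composition with 2% gaps.
    """

    n_enzymes: int = 300
    n_columns: int = 60
    stereo_switch_column: int = 30
    stereo_alleles: tuple[str, str] = ("F", "Y")  # allele1 -> S (-1), allele2 -> R (+1)
    reactivity_switch_column: int = 10
    reactivity_alleles: tuple[str, str] = ("I", "V")  # allele1 -> reactive (1)
    label_noise: float = 0.1
    gap_probability: float = 0.02
    background_frequencies: tuple[float, ...] | None = None  # over the 20 amino acids
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.label_noise < 0.5):
            raise ConfigError("label_noise must be in [0, 0.5): signal must dominate")
        if not (0 <= self.gap_probability <= 1):
            raise ConfigError("gap_probability outside [0, 1]")
        if self.stereo_switch_column == self.reactivity_switch_column:
            raise ConfigError("switch columns must be distinct")
        for col in (self.stereo_switch_column, self.reactivity_switch_column):
            if not 1 <= col <= self.n_columns:
                raise ConfigError(f"switch column {col} outside 1..{self.n_columns}")
        if self.background_frequencies is not None:
            f = np.asarray(self.background_frequencies)
            if len(f) != 20 or not math.isclose(float(f.sum()), 1.0, rel_tol=1e-6):
                raise ConfigError("background_frequencies must be 20 values summing to 1")


def generate_screen_dataset(
    config: ScreenSimConfig,
) -> tuple[Alignment, pd.DataFrame, dict]:
    """Sequence library with planted stereo and reactivity determinants.

    The stereochemistry label is -1 (S) for allele1 at the stereo switch
    column and +1 (R) for allele2; with probability ``label_noise`` it is
    replaced by a uniform draw from the other two classes (including the
    racemic class 0).  The reactivity label is 1 for allele1 at the
    reactivity switch column and 0 for allele2, flipped with probability
    ``label_noise``.  All other columns are background draws independent of
    the labels; switch columns carry no gaps (they are determinant
    positions).
    """
    rng = np.random.default_rng(config.seed)
    freqs = (
        np.full(20, 0.05)
        if config.background_frequencies is None
        else np.asarray(config.background_frequencies, dtype=float)
    )
    aa = np.array(list(_AA20))
    n, m = config.n_enzymes, config.n_columns

    chars = aa[rng.choice(20, size=(n, m), p=freqs / freqs.sum())]
    gaps = rng.uniform(size=(n, m)) < config.gap_probability
    chars[gaps] = "-"

    stereo_col = config.stereo_switch_column - 1
    react_col = config.reactivity_switch_column - 1
    stereo_allele_is_2 = rng.uniform(size=n) < 0.5
    react_allele_is_1 = rng.uniform(size=n) < 0.5
    chars[:, stereo_col] = np.where(
        stereo_allele_is_2, config.stereo_alleles[1], config.stereo_alleles[0]
    )
    chars[:, react_col] = np.where(
        react_allele_is_1, config.reactivity_alleles[0], config.reactivity_alleles[1]
    )

    stereo_true = np.where(stereo_allele_is_2, 1, -1)
    react_true = np.where(react_allele_is_1, 1, 0)

    stereo_label = stereo_true.copy()
    noisy = rng.uniform(size=n) < config.label_noise
    for i in np.nonzero(noisy)[0]:
        others = [c for c in (-1, 0, 1) if c != stereo_true[i]]
        stereo_label[i] = others[rng.integers(2)]
    react_label = react_true.copy()
    flip = rng.uniform(size=n) < config.label_noise
    react_label[flip] = 1 - react_label[flip]

    ids = [f"enz{i + 1:04d}" for i in range(n)]
    alignment = Alignment(ids=ids, rows=["".join(row) for row in chars])
    labels = pd.DataFrame(
        {"stereochemistry": stereo_label, "reactivity": react_label}, index=ids
    )
    truth = dict(
        stereo_switch_column=config.stereo_switch_column,
        stereo_alleles=config.stereo_alleles,
        reactivity_switch_column=config.reactivity_switch_column,
        reactivity_alleles=config.reactivity_alleles,
        stereo_true=stereo_true,
        reactivity_true=react_true,
    )
    return alignment, labels, truth


def screen_feature_matrix(alignment: Alignment, labels: pd.DataFrame) -> FeatureMatrix:
    """Feature matrix for a generated screen (columns are their own numbering)."""
    n_cols = alignment.n_columns
    refmap = ReferenceMap(
        reference_id="synthetic",
        col_to_res={c: c for c in range(1, n_cols + 1)},
        res_to_col={c: c for c in range(1, n_cols + 1)},
    )
    roi = ResidueSet(frozenset(range(1, n_cols + 1)), "union")
    return build_feature_matrix(alignment, roi, refmap, labels)


def generate_descriptor_table(
    true_coefficients: dict[str, float],
    intercept: float,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Descriptor table drawn from a known logistic model.

    Descriptors are standard normal; the ``reactive`` column is Bernoulli
    with probability ``expit(intercept + x . beta)``.  Used to check that
    the reactivity fit recovers known coefficients.
    """
    if n < 50:
        raise DomainError("need n >= 50 for a meaningful fit")
    unknown = set(true_coefficients) - set(DESCRIPTOR_NAMES)
    if unknown:
        raise ConfigError(f"unknown descriptor names {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, len(DESCRIPTOR_NAMES)))
    beta = np.array([true_coefficients.get(name, 0.0) for name in DESCRIPTOR_NAMES])
    eta = intercept + x @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=n) < prob).astype(int)
    df = pd.DataFrame(x, columns=DESCRIPTOR_NAMES)
    df["reactive"] = y
    return df
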