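import numpy as np
import pytest

from fdmoscreen import synthetic as syn
from fdmoscreen.structio import AtomRecord, Pose


@pytest.fixture(scope="session")
def small_screen():
    """A small planted-determinant screen shared by the seqfunc tests."""
    cfg = syn.ScreenSimConfig(n_enzymes=120, n_columns=30, stereo_switch_column=17,
                              reactivity_switch_column=5, seed=11)
    alignment, labels, truth = syn.generate_screen_dataset(cfg)
    features = syn.screen_feature_matrix(alignment, labels)
    return features, truth


@pytest.fixture(scope="session")
def stereo_bundle(small_screen):
    """One trained ensemble (all three backends) on the small screen."""
    from fdmoscreen.seqfunc import FoldSpec, train_ensemble

    features, truth = small_screen
    bundle = train_ensemble(features, "stereochemistry", spec=FoldSpec(n_folds=5, seed=17))
    return bundle, truth


def shifted_pose(pose: Pose, shift, pose_id=None, energy=None) -> Pose:
    atoms = [
        AtomRecord(a.atom_name, a.element, a.residue_number, a.residue_name, a.chain_id,
                   a.coords + np.asarray(shift, dtype=float))
        for a in pose.ligand_atoms
    ]
    return Pose(
        pose_id=pose.pose_id if pose_id is None else pose_id,
        ligand_atoms=atoms,
        energy=pose.energy if energy is None else energy,
    )
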