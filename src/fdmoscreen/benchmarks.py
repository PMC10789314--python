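"""Desk-scale validation studies for the screening pipeline.

Each function runs one self-contained study on synthetic inputs with known
ground truth — the Boltzmann weighting against its closed form, clustering
against planted partitions, logistic coefficient recovery, planted-switch
recovery by consensus SHAP, and the metric implementations against
independent references — and returns summary numbers.  The test suite
asserts on these numbers; the reproduction script reports them.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import f1_score, matthews_corrcoef

from . import synthetic as syn
from .reactivity import DESCRIPTOR_NAMES, fit_reactivity_model
from .seqfunc import (
    FoldSpec,
    evaluate_predictions,
    macro_f1_from_confusion,
    mcc_from_confusion,
    shap_consensus_importance,
    train_ensemble,
)
from .stereo import (
    Cluster,
    ClusterSet,
    ThermoParams,
    boltzmann_rfrac,
    classify_pose,
    cluster_poses,
    pose_angle,
)
from .structio import PoseEnsemble


def _random_cluster_set(rng) -> tuple[ClusterSet, np.ndarray, np.ndarray, np.ndarray]:
    n = int(rng.integers(1, 13))
    sizes = rng.integers(1, 25, size=n)
    energies = rng.normal(scale=4.0, size=n)
    calls = rng.choice(["R", "S"], size=n)
    clusters = [
        Cluster(member_pose_ids=list(range(i * 50, i * 50 + int(g))),
                representative_pose_id=i * 50, energy=float(e), angle=45.0, stereo_call=c)
        for i, (g, e, c) in enumerate(zip(sizes, energies, calls))
    ]
    return ClusterSet(clusters=clusters, radius=1.0), sizes, energies, calls


def rfrac_oracle_study(n_sets: int = 500, seed: int = 0) -> dict:
    """Boltzmann R fraction vs the closed-form weighted sum, plus limits.

    Returns the maximum relative error against the brute-force formula over
    random cluster sets, the maximum error under a random energy shift, and
    the errors of the low- and high-temperature limits.
    """
    rng = np.random.default_rng(seed)
    thermo = ThermoParams()
    max_rel = 0.0
    max_shift = 0.0
    for _ in range(n_sets):
        cs, sizes, energies, calls = _random_cluster_set(rng)
        res = boltzmann_rfrac(cs, thermo)
        w = sizes * np.exp(-(energies - energies.min()) / thermo.kt)
        expected = float(w[calls == "R"].sum() / w.sum())
        denom = max(abs(expected), 1e-300)
        max_rel = max(max_rel, abs(res.r_frac - expected) / denom if expected else abs(res.r_frac))
        shift = float(rng.normal(scale=20.0))
        shifted = ClusterSet(
            clusters=[
                Cluster(c.member_pose_ids, c.representative_pose_id, c.energy + shift,
                        c.angle, c.stereo_call)
                for c in cs.clusters
            ],
            radius=1.0,
        )
        max_shift = max(max_shift, abs(boltzmann_rfrac(shifted, thermo).r_frac - res.r_frac))

    # temperature limits on a fixed two-cluster system (unique minimum is R)
    limit_set = ClusterSet(
        clusters=[
            Cluster([1], 1, -10.0, 120.0, "R"),
            Cluster(list(range(2, 11)), 2, -5.0, 60.0, "S"),
        ],
        radius=1.0,
    )
    cold_err = abs(boltzmann_rfrac(limit_set, ThermoParams(temperature=1e-3)).r_frac - 1.0)
    hot_err = abs(boltzmann_rfrac(limit_set, ThermoParams(temperature=1e9)).r_frac - 0.1)
    return dict(
        n_sets=n_sets,
        max_relative_error=max_rel,
        max_shift_error=max_shift,
        cold_limit_error=cold_err,
        hot_limit_error=hot_err,
    )


GEOMETRY_ANGLES = (0.0, 45.0, 89.9, 90.0, 90.1, 135.0, 180.0)


def geometry_study() -> dict:
    """The printed angle rule on constructed complexes, plus ring-order reversal."""
    expected = {a: ("S" if a < 90 else "R" if a > 90 else "degenerate")
                for a in GEOMETRY_ANGLES}
    n_correct = 0
    n_reversal_ok = 0
    for a in GEOMETRY_ANGLES:
        receptor, pose = syn.generate_toy_complex(a, n_decoration_atoms=2)
        fad = receptor.fad_atom(syn.TOY_FAD_ATOM)
        measured = pose_angle(pose, syn.TOY_RING, fad)
        call = classify_pose(measured)
        n_correct += call == expected[a]
        reversed_call = classify_pose(pose_angle(pose, syn.TOY_RING.reversed(), fad))
        swap = {"R": "S", "S": "R", "degenerate": "degenerate"}
        n_reversal_ok += reversed_call == swap[call]
    return dict(
        n_angles=len(GEOMETRY_ANGLES),
        n_rule_correct=n_correct,
        n_reversal_swapped=n_reversal_ok,
    )


def clustering_study(n_ensembles: int = 200, seed: int = 0) -> dict:
    """Partition/representative invariants and planted-partition recovery.

    Half the ensembles are free-form (random pose clouds, invariants only);
    half carry planted clusters satisfying the separability condition
    (jitter <= 0.4 x radius, centers >= 3 x radius apart) whose partitions
    must be recovered exactly.
    """
    rng = np.random.default_rng(seed)
    _, base = syn.generate_toy_complex(30.0, n_decoration_atoms=2)
    radius = 1.0
    n_invariant_ok = 0
    n_planted = 0
    n_recovered = 0
    for t in range(n_ensembles):
        if t % 2 == 0:
            # free-form cloud
            poses = [
                _shift(base, rng.normal(scale=2.0, size=3), i, float(rng.normal()))
                for i in range(int(rng.integers(5, 40)))
            ]
            ens = PoseEnsemble("e", "l", poses)
            cs = cluster_poses(ens, radius=radius)
            ids = sorted(i for c in cs.clusters for i in c.member_pose_ids)
            by_id = {p.pose_id: p.energy for p in ens.poses}
            ok = ids == sorted(by_id)
            ok &= all(c.energy == min(by_id[i] for i in c.member_pose_ids) for c in cs.clusters)
            ok &= [c.energy for c in cs.clusters] == sorted(c.energy for c in cs.clusters)
            n_invariant_ok += ok
        else:
            k = int(rng.integers(2, 5))
            centers = [np.array([3.5 * radius * j, 0.0, 0.0]) for j in range(k)]
            specs = [
                syn.PoseClusterSpec(
                    center_pose=_shift(base, c, j + 1, -20.0 + 2.0 * j),
                    n_members=int(rng.integers(2, 8)),
                    jitter=0.4 * radius,
                    base_energy=-20.0 + 2.0 * j,
                    energy_spread=1.5,
                )
                for j, c in enumerate(centers)
            ]
            ens, truth = syn.generate_pose_ensemble(specs, seed=int(rng.integers(2**31)))
            cs = cluster_poses(ens, radius=radius)
            got = sorted(map(sorted, (c.member_pose_ids for c in cs.clusters)))
            n_planted += 1
            n_recovered += got == sorted(map(sorted, truth))
    return dict(
        n_free=n_ensembles - n_planted,
        n_invariant_ok=n_invariant_ok,
        n_planted=n_planted,
        n_recovered=n_recovered,
    )


def _shift(pose, shift, pose_id, energy):
    from .structio import AtomRecord, Pose

    atoms = [
        AtomRecord(a.atom_name, a.element, a.residue_number, a.residue_name, a.chain_id,
                   a.coords + np.asarray(shift, dtype=float))
        for a in pose.ligand_atoms
    ]
    return Pose(pose_id=pose_id, ligand_atoms=atoms, energy=energy)


LOGISTIC_TRUTH = {
    "fad_angle": 0.8,
    "anion_distance": -1.2,
    "energy_efficiency": -0.5,
    "pkd_efficiency": 1.0,
}  # fad_distance deliberately null


def logistic_recovery_study(n_seeds: int = 20, n: int = 5000, seed: int = 0) -> dict:
    """Coefficient recovery of the reactivity fit on generated tables."""
    errors, within = [], []
    for s in range(n_seeds):
        df = syn.generate_descriptor_table(LOGISTIC_TRUTH, 0.3, n, seed=seed + s)
        m = fit_reactivity_model(df)
        est = dict(zip(m.descriptor_names, m.coefficients))
        ses = dict(zip(m.descriptor_names, m.standard_errors))
        errors.append([est[k] - v for k, v in LOGISTIC_TRUTH.items()])
        within.append(
            all(abs(est[k] - v) <= 3 * ses[k] for k, v in LOGISTIC_TRUTH.items())
        )
    bias = np.abs(np.mean(errors, axis=0))
    rel_bias = bias / np.abs(list(LOGISTIC_TRUTH.values()))
    return dict(
        n_seeds=n_seeds,
        n=n,
        max_relative_bias=float(rel_bias.max()),
        n_within_3se=int(np.sum(within)),
    )


def shap_recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    algorithms=("xgb", "lgbm", "rf"),
) -> dict:
    """Planted-switch recovery by consensus SHAP over seeded screen replicates.

    Each replicate generates a fresh 300-enzyme, 60-column screen (the
    generator defaults), trains the full ensemble for both targets, and
    records whether the stereo switch ranks first and the reactivity switch
    ranks in the top 2.  Held-out accuracies and MCCs of the last replicate's
    models are also returned.
    """
    stereo_top1 = 0
    react_top2 = 0
    metrics = {}
    for rep in range(n_replicates):
        cfg = syn.ScreenSimConfig(seed=seed + 1000 + rep)
        alignment, labels, truth = syn.generate_screen_dataset(cfg)
        features = syn.screen_feature_matrix(alignment, labels)
        spec = FoldSpec(n_folds=5, seed=17)

        bundle_s = train_ensemble(features, "stereochemistry", algorithms=algorithms, spec=spec)
        imp_s = shap_consensus_importance(bundle_s)
        ranked_s = imp_s.top(len(imp_s.residues))["residue"].tolist()
        stereo_top1 += ranked_s[0] == truth["stereo_switch_column"]

        bundle_r = train_ensemble(features, "reactivity", algorithms=algorithms, spec=spec)
        imp_r = shap_consensus_importance(bundle_r)
        ranked_r = imp_r.top(len(imp_r.residues))["residue"].tolist()
        react_top2 += truth["reactivity_switch_column"] in ranked_r[:2]

        if rep == n_replicates - 1:
            for target, bundle in (("stereochemistry", bundle_s), ("reactivity", bundle_r)):
                y = features.target(target)
                for alg in bundle.algorithms:
                    rep_m = evaluate_predictions(bundle.heldout_predictions(alg), y)
                    metrics[f"{target}_{alg}"] = dict(
                        accuracy=rep_m.accuracy, mcc=rep_m.mcc, macro_f1=rep_m.macro_f1
                    )
    return dict(
        n_replicates=n_replicates,
        stereo_switch_rank1=stereo_top1,
        reactivity_switch_top2=react_top2,
        last_replicate_metrics=metrics,
    )


def no_signal_study(
    n_replicates: int = 20,
    seed: int = 0,
    algorithms=("xgb", "lgbm", "rf"),
) -> dict:
    """Flatness control: shuffled labels must yield no dominant residue.

    A replicate passes when no residue's consensus importance exceeds twice
    the median importance.
    """
    flat = 0
    for rep in range(n_replicates):
        cfg = syn.ScreenSimConfig(seed=seed + 5000 + rep)
        alignment, labels, _ = syn.generate_screen_dataset(cfg)
        rng = np.random.default_rng(seed + 7000 + rep)
        labels = labels.copy()
        labels["reactivity"] = rng.permutation(labels["reactivity"].to_numpy())
        features = syn.screen_feature_matrix(alignment, labels)
        bundle = train_ensemble(features, "reactivity", algorithms=algorithms,
                                spec=FoldSpec(n_folds=5, seed=17))
        imp = shap_consensus_importance(bundle)
        med = float(np.median(imp.values))
        flat += bool(np.max(imp.values) <= 2.0 * med) if med > 0 else True
    return dict(n_replicates=n_replicates, n_flat=flat)


def metric_oracle_study(n_matrices: int = 200, seed: int = 0) -> dict:
    """Multiclass MCC / macro-F1 vs the scikit-learn reference implementations."""
    rng = np.random.default_rng(seed)
    max_mcc = 0.0
    max_f1 = 0.0
    done = 0
    while done < n_matrices:
        k = int(rng.integers(2, 6))
        n = int(rng.integers(20, 300))
        y_true = rng.integers(0, k, size=n)
        y_pred = rng.integers(0, k, size=n)
        if len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2:
            continue
        done += 1
        from .seqfunc import confusion_matrix_counts

        conf = confusion_matrix_counts(y_pred, y_true, range(k)).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            max_mcc = max(max_mcc, abs(mcc_from_confusion(conf) - matthews_corrcoef(y_true, y_pred)))
            max_f1 = max(
                max_f1,
                abs(
                    macro_f1_from_confusion(conf)
                    - f1_score(y_true, y_pred, average="macro", labels=range(k), zero_division=0)
                ),
            )
    return dict(n_matrices=n_matrices, max_mcc_error=max_mcc, max_macro_f1_error=max_f1)
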