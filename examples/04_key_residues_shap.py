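"""Recover planted functional residues by consensus SHAP ranking.

Generates a 300-enzyme screen whose stereochemistry is controlled by an
F/Y switch at column 30 and whose reactivity is controlled by an I/V
switch at column 10 (plus 10% label noise), trains XGBoost + LightGBM +
random-forest models under shared 5-fold CV, and ranks residues by the
fold-normalized mean absolute SHAP consensus.  The dependence profile of
the stereo switch shows the two alleles pushing opposite classes.
"""

from fdmoscreen.seqfunc import (
    FoldSpec,
    evaluate_predictions,
    shap_consensus_importance,
    shap_dependence,
    train_ensemble,
)
from fdmoscreen.synthetic import ScreenSimConfig, generate_screen_dataset, screen_feature_matrix


def main():
    cfg = ScreenSimConfig(seed=42)
    alignment, labels, truth = generate_screen_dataset(cfg)
    features = screen_feature_matrix(alignment, labels)

    bundle = train_ensemble(features, "stereochemistry", spec=FoldSpec(n_folds=5, seed=17))
    importance = shap_consensus_importance(bundle)
    print("top 5 residues for stereochemistry (planted switch at "
          f"{truth['stereo_switch_column']}):")
    print(importance.top(5).to_string(index=False))

    y = features.target("stereochemistry")
    for alg in bundle.algorithms:
        rep = evaluate_predictions(bundle.heldout_predictions(alg), y)
        print(f"{alg}: held-out accuracy {rep.accuracy:.3f}, MCC {rep.mcc:.3f}, "
              f"macro-F1 {rep.macro_f1:.3f}")

    profile = shap_dependence(bundle, truth["stereo_switch_column"], class_of_interest=1)
    means = profile.mean_by_aa()
    print("\nmean normalized SHAP toward the R class by amino acid at the switch:")
    for aa, v in means.items():
        print(f"  {aa}: {v:+.3f}")
    print("F pushes predictions away from R (toward S) and Y toward R —")
    print("the dependence profile reads the stereo switch directly off the model.")


if __name__ == "__main__":
    main()
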