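"""Fit and apply the logistic reactivity classifier.

Draws a descriptor table from a known logistic model (standard-normal
descriptors, known coefficients), fits the five-descriptor reactivity
model, and compares recovered coefficients with the truth.  The fitted
model then predicts the reactivity of a fresh enzyme's descriptors.
"""

from fdmoscreen.reactivity import fit_reactivity_model, predict_reactivity
from fdmoscreen.synthetic import generate_descriptor_table

TRUE = {"fad_angle": 0.8, "anion_distance": -1.2,
        "energy_efficiency": -0.5, "pkd_efficiency": 1.0}  # fad_distance: no effect


def main():
    table = generate_descriptor_table(TRUE, intercept=0.3, n=5000, seed=7)
    model = fit_reactivity_model(table)

    print(f"{'descriptor':<20} {'true':>6} {'fitted':>8} {'SE':>6} {'p':>9}")
    for name, coef, se, p in zip(model.descriptor_names, model.coefficients,
                                 model.standard_errors, model.p_values):
        print(f"{name:<20} {TRUE.get(name, 0.0):>6.2f} {coef:>8.3f} {se:>6.3f} {p:>9.2e}")

    probe = table.iloc[0][list(model.descriptor_names)].to_dict()
    prob, label = predict_reactivity(model, probe)
    print(f"\nfirst row: P(reactive) = {prob:.3f} -> {label}")
    print("Descriptors with |coef|/SE large are significant drivers of conversion;")
    print("the null descriptor (fad_distance) shows a large p-value, mirroring the")
    print("significance screen used to drop non-predictive descriptors.")


if __name__ == "__main__":
    main()
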