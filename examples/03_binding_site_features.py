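"""Select binding-site and second-shell residues and build a feature matrix.

Uses a toy receptor (one CA atom per residue) around a docked ring ligand:
residues with a heavy atom within 4.5 A of the ligand are binding-site
residues; residues within 4.5 A of those are second shell.  A small aligned
family is then restricted to that union of residues of interest, dropping
columns with more than 10% gaps.
"""

import numpy as np
import pandas as pd

from fdmoscreen.seqfeatures import (
    Alignment,
    build_feature_matrix,
    map_reference_numbering,
    select_binding_site_residues,
    select_second_shell,
)
from fdmoscreen.structio import AtomRecord, ComplexStructure, Pose


def main():
    rng = np.random.default_rng(0)
    # 12 residues on a line walking away from the ligand at the origin
    atoms = [AtomRecord("CA", "C", i + 1, "ALA", "A", np.array([2.0 + 2.5 * i, 0.0, 0.0]))
             for i in range(12)]
    fad = [AtomRecord("C4A", "C", 900, "FAD", "F", np.array([0.0, 0.0, 5.0]))]
    receptor = ComplexStructure(atoms, fad, enzyme_id="toy")
    ligand = Pose(1, [AtomRecord(f"C{i+1}", "C", 1, "LIG", "X", p) for i, p in
                      enumerate([(0, 0, 0), (1.4, 0, 0), (0.7, 1.2, 0)])], energy=-10.0)

    bs = select_binding_site_residues(receptor, [ligand], cutoff=4.5)
    shell = select_second_shell(receptor, bs, cutoff=4.5)
    print("binding-site residues:", sorted(bs.residues))
    print("second-shell residues:", sorted(shell.residues))

    # a 10-sequence family aligned over the 12 reference positions
    ref = "ACDEFGHIKLMN"
    rows = [ref] + ["".join(rng.choice(list("ACDEFGHIKLMN-")) for _ in ref) for _ in range(9)]
    aln = Alignment(ids=["ref"] + [f"seq{i}" for i in range(9)], rows=rows)
    refmap = map_reference_numbering(aln, "ref")
    labels = pd.DataFrame({"reactivity": rng.integers(0, 2, size=10)}, index=aln.ids)
    fm = build_feature_matrix(aln, bs | shell, refmap, labels, gap_threshold=0.10)
    print("retained feature columns (reference numbering):", fm.residues)
    print("dropped (too gappy):", fm.dropped_columns)
    print("Each retained column is one categorical feature per residue of interest,")
    print("so downstream SHAP values attribute model output residue by residue.")


if __name__ == "__main__":
    main()
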