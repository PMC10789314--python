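"""Sequence-side features: reference numbering, shell selection, MSA trimming.

The sequence-function models see each enzyme as the row of a multiple
sequence alignment restricted to residues of interest: binding-site residues
(any residue with a heavy atom within 4.5 A of any ligand heavy atom in the
top docked pose, union over ligands) plus second-shell residues (within
4.5 A of any binding-site residue).  Residue coordinates across the family
are expressed in the numbering of a reference sequence (TropB in the
original benchmark) through the alignment.

Columns that are outside the residues of interest, or that contain more than
10% gaps, are dropped before modelling.  Retained columns are categorical
amino-acid features (gap is its own category) with integer label encoding,
so each residue maps to exactly one model feature and one SHAP value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

from .errors import DomainError, FormatError, LookupError_
from .structio import ComplexStructure, Pose

logger = logging.getLogger(__name__)

GAP = "-"
#: fixed category order: gap first, then the 20 amino acids, then unknown
ALPHABET = GAP + "ACDEFGHIKLMNPQRSTVWY" + "X"
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}

STEREO_TO_INT = {"S": -1, "R/S": 0, "R": 1}
INT_TO_STEREO = {v: k for k, v in STEREO_TO_INT.items()}


@dataclass
class Alignment:
    """A multiple sequence alignment over {20 amino acids, '-'}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise DomainError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise DomainError("sequence ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise DomainError(f"rows have unequal lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError as exc:
            raise LookupError_(f"sequence id {seq_id!r} not in alignment") from exc

    def column(self, col: int) -> str:
        """1-based column as a string over rows."""
        return "".join(r[col - 1] for r in self.rows)

    def column_composition(self, col: int) -> pd.Series:
        """Relative frequency of each character in a 1-based column."""
        chars = pd.Series(list(self.column(col)))
        return chars.value_counts(normalize=True)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file (gap character '-')."""
    try:
        msa = AlignIO.read(str(path), "fasta")
    except Exception as exc:
        raise FormatError(f"cannot read aligned FASTA {path}: {exc}") from exc
    return Alignment(
        ids=[rec.id for rec in msa],
        rows=[str(rec.seq).upper() for rec in msa],
    )


def write_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


@dataclass
class ReferenceMap:
    """Bidirectional map between alignment columns and reference residue numbers.

    Columns and residue numbers are both 1-based; the k-th non-gap character
    of the reference row is residue k.
    """

    reference_id: str
    col_to_res: dict[int, int]
    res_to_col: dict[int, int]

    def column_for_residue(self, residue: int) -> int:
        try:
            return self.res_to_col[residue]
        except KeyError as exc:
            raise LookupError_(f"reference residue {residue} is unmapped") from exc

    def residue_for_column(self, col: int) -> int | None:
        return self.col_to_res.get(col)


def map_reference_numbering(alignment: Alignment, reference_id: str) -> ReferenceMap:
    """Build the column <-> reference-residue map from the reference row."""
    row = alignment.row(reference_id)
    col_to_res: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            res += 1
            col_to_res[col] = res
    if not col_to_res:
        warnings.warn(f"reference row {reference_id!r} is all gaps; empty map")
    return ReferenceMap(
        reference_id=reference_id,
        col_to_res=col_to_res,
        res_to_col={r: c for c, r in col_to_res.items()},
    )


@dataclass(frozen=True)
class ResidueSet:
    """A set of residue numbers with a provenance tag."""

    residues: frozenset[int]
    provenance: str = "binding_site"  # binding_site | second_shell | union

    def __or__(self, other: "ResidueSet") -> "ResidueSet":
        return ResidueSet(self.residues | other.residues, "union")

    def __contains__(self, r: int) -> bool:
        return r in self.residues

    def __len__(self) -> int:
        return len(self.residues)


def _residue_coord_table(receptor: ComplexStructure) -> dict[int, np.ndarray]:
    by_res: dict[int, list[np.ndarray]] = {}
    for (chain, resnum), atoms in receptor.residue_atoms(heavy_only=True).items():
        by_res.setdefault(resnum, []).extend(a.coords for a in atoms)
    return {r: np.array(coords) for r, coords in by_res.items()}


def select_binding_site_residues(
    receptor: ComplexStructure,
    top_poses: list[Pose],
    cutoff: float = 4.5,
) -> ResidueSet:
    """Residues with any heavy atom within ``cutoff`` A of any ligand heavy atom.

    The union is taken over the supplied top poses (one per ligand).  'Within'
    is inclusive (<=).  FAD atoms are not candidates — they are partitioned
    out of the protein at read time.
    """
    if not top_poses:
        raise DomainError("need at least one top pose")
    if cutoff <= 0:
        raise DomainError("cutoff must be positive")
    lig = np.vstack([p.coords for p in top_poses])
    selected = set()
    for resnum, coords in _residue_coord_table(receptor).items():
        d2 = np.sum((coords[:, None, :] - lig[None, :, :]) ** 2, axis=-1)
        if d2.min() <= cutoff**2:
            selected.add(resnum)
    return ResidueSet(frozenset(selected), "binding_site")


def select_second_shell(
    receptor: ComplexStructure,
    binding_site: ResidueSet,
    cutoff: float = 4.5,
) -> ResidueSet:
    """Residues within ``cutoff`` A of any binding-site residue heavy atom.

    Binding-site members themselves are excluded (the shells are disjoint).
    """
    if len(binding_site) == 0:
        raise DomainError("binding site is empty")
    table = _residue_coord_table(receptor)
    bs_coords = np.vstack([table[r] for r in binding_site.residues if r in table])
    selected = set()
    for resnum, coords in table.items():
        if resnum in binding_site:
            continue
        d2 = np.sum((coords[:, None, :] - bs_coords[None, :, :]) ** 2, axis=-1)
        if d2.min() <= cutoff**2:
            selected.add(resnum)
    return ResidueSet(frozenset(selected), "second_shell")


def translate_residue_numbers(
    alignment: Alignment,
    from_id: str,
    to_id: str,
    residues: ResidueSet,
) -> ResidueSet:
    """Re-express residue numbers of one sequence in another's numbering.

    Residues that land on a gap in the target row are dropped (they have no
    coordinate in the target numbering).
    """
    from_map = map_reference_numbering(alignment, from_id)
    to_map = map_reference_numbering(alignment, to_id)
    out = set()
    for r in residues.residues:
        col = from_map.res_to_col.get(r)
        if col is None:
            continue
        target = to_map.col_to_res.get(col)
        if target is not None:
            out.add(target)
    return ResidueSet(frozenset(out), residues.provenance)


def residues_of_interest_union(per_enzyme_sets: list[ResidueSet]) -> ResidueSet:
    """Union of per-enzyme shells, all already in reference numbering."""
    if not per_enzyme_sets:
        warnings.warn("union over zero enzymes: empty residues of interest")
        return ResidueSet(frozenset(), "union")
    out: frozenset[int] = frozenset()
    for s in per_enzyme_sets:
        out |= s.residues
    return ResidueSet(out, "union")


@dataclass
class FeatureMatrix:
    """Categorical per-residue features plus function labels, ready to encode.

    ``data`` has one row per enzyme and one single-letter column per retained
    reference residue; ``labels`` holds ``stereochemistry`` in {-1, 0, 1}
    (S, R/S, R) and/or ``reactivity`` in {0, 1}.
    """

    data: pd.DataFrame  # rows: enzymes, columns: residue numbers, values: letters
    labels: pd.DataFrame
    dropped_columns: dict[int, str] = field(default_factory=dict)

    @property
    def residues(self) -> list[int]:
        return list(self.data.columns)

    def encoded(self) -> np.ndarray:
        """Integer label encoding over the fixed alphabet (gap = category 0)."""
        return np.array(
            [[_CODE.get(ch, _CODE["X"]) for ch in self.data[c]] for c in self.data.columns]
        ).T

    def target(self, name: str) -> np.ndarray:
        if name not in self.labels.columns:
            raise LookupError_(f"label column {name!r} absent")
        return self.labels[name].to_numpy()


def build_feature_matrix(
    alignment: Alignment,
    roi: ResidueSet,
    refmap: ReferenceMap,
    labels: pd.DataFrame,
    gap_threshold: float = 0.10,
) -> FeatureMatrix:
    """Restrict the MSA to residues of interest and drop gappy columns.

    A column is retained iff its reference residue is in ``roi`` and its gap
    fraction is <= ``gap_threshold`` (strictly more than 10% gaps drops it).

    ``labels`` is indexed by sequence id with optional columns
    ``stereochemistry`` (values in {-1, 0, 1}) and ``reactivity`` ({0, 1}).
    """
    dropped: dict[int, str] = {}
    kept_cols: list[int] = []
    for residue in sorted(roi.residues):
        col = refmap.column_for_residue(residue)  # unmapped -> LookupError_
        gap_frac = alignment.column(col).count(GAP) / len(alignment.rows)
        if gap_frac > gap_threshold:
            dropped[residue] = f"gap fraction {gap_frac:.3f} > {gap_threshold}"
        else:
            kept_cols.append(residue)
    data = pd.DataFrame(
        {res: list(alignment.column(refmap.column_for_residue(res))) for res in kept_cols},
        index=alignment.ids,
    )
    lab = labels.reindex(data.index)
    if "stereochemistry" in lab.columns:
        bad = set(lab["stereochemistry"].dropna().unique()) - {-1, 0, 1}
        if bad:
            raise DomainError(f"stereochemistry labels outside {{-1,0,1}}: {sorted(bad)}")
    if "reactivity" in lab.columns:
        bad = set(lab["reactivity"].dropna().unique()) - {0, 1}
        if bad:
            raise DomainError(f"reactivity labels outside {{0,1}}: {sorted(bad)}")
    if dropped:
        logger.info("dropped %d gappy columns: %s", len(dropped), sorted(dropped))
    return FeatureMatrix(data=data, labels=lab, dropped_columns=dropped)


def stereo_labels_from_calls(
    per_ligand_labels: pd.DataFrame,
    method: str = "mode",
    racemic_band: float = 0.25,
) -> pd.Series:
    """Collapse per-ligand stereochemistry calls to one {-1, 0, 1} label per enzyme.

    ``method="mode"`` takes the modal call (ties -> 0, the racemic class);
    ``method="mean"`` averages the per-ligand integer labels and thresholds:
    |mean| < ``racemic_band`` -> 0, else the sign of the mean.

    ``per_ligand_labels``: rows = enzymes, columns = ligands, values in
    {"R", "S", "R/S"}.
    """
    if method not in ("mode", "mean"):
        raise DomainError(f"unknown consensus method {method!r}")
    ints = per_ligand_labels.apply(lambda col: col.map(STEREO_TO_INT))
    if method == "mean":
        m = ints.mean(axis=1)
        return m.apply(lambda v: 0 if abs(v) < racemic_band else int(np.sign(v)))

    def modal(row):
        counts = row.value_counts()
        modes = counts[counts == counts.iloc[0]]
        return int(modes.index[0]) if len(modes) == 1 else 0

    return ints.apply(modal, axis=1)
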