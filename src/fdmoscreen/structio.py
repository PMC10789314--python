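"""Structure and table I/O for the docking-based functional screen.

Reads receptor structures carrying an FAD cofactor, docked ligand pose
ensembles (multi-model PDB or flat pose tables) and screen annotation
tables.  Atom parsing of PDB files is delegated to biotite; this module
only adds the pose/energy bookkeeping the pipeline needs.

Coordinates are always kept in the receptor frame: poses are never
superposed onto each other, so inter-pose RMSDs are computed in a fixed
frame downstream.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .errors import (
    ConsistencyError,
    DomainError,
    EmptyStructureError,
    FormatError,
    MissingFieldError,
)

logger = logging.getLogger(__name__)

#: residue names recognised as the flavin cofactor by default
DEFAULT_FAD_NAMES = frozenset({"FAD", "FDA", "FMN"})

#: stereochemistry tokens accepted in screen annotation tables
STEREO_TOKENS = frozenset({"R", "S", "R/S", "NA"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element, residue context and Cartesian coordinates (A)."""

    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise DomainError(f"atom {self.atom_name!r}: coords must be a finite 3-vector")
        if not self.atom_name:
            raise DomainError("atom_name must be nonempty")
        object.__setattr__(self, "coords", c)

    @property
    def is_heavy(self) -> bool:
        """True unless the atom is hydrogen/deuterium.

        Decided from the element symbol; when the element column is blank the
        leading alphabetic character of the atom name is used instead (PDB
        files vary in element completeness).
        """
        elem = self.element.strip().upper()
        if not elem:
            stripped = self.atom_name.strip().lstrip("0123456789")
            elem = stripped[:1].upper()
        return elem not in ("H", "D")


@dataclass
class ComplexStructure:
    """Receptor protein plus (optional) FAD cofactor atoms."""

    protein_atoms: list[AtomRecord]
    fad_atoms: list[AtomRecord]
    enzyme_id: str = ""

    def __post_init__(self):
        if not self.protein_atoms:
            raise EmptyStructureError("structure contains zero protein atoms")
        seen = {}
        for a in self.protein_atoms:
            key = (a.chain_id, a.residue_number)
            if key in seen and seen[key] != a.residue_name:
                raise ConsistencyError(
                    f"residue {key} has conflicting names {seen[key]!r}/{a.residue_name!r}"
                )
            seen[key] = a.residue_name

    def fad_atom(self, atom_name: str) -> AtomRecord:
        """Return the named FAD atom (e.g. C4A, the hydroperoxyl-bearing ring atom)."""
        from .errors import LookupError_

        for a in self.fad_atoms:
            if a.atom_name == atom_name:
                return a
        raise LookupError_(f"FAD atom {atom_name!r} not found")

    def residue_atoms(self, heavy_only: bool = True) -> dict[tuple[str, int], list[AtomRecord]]:
        """Protein atoms grouped by (chain, residue number)."""
        out: dict[tuple[str, int], list[AtomRecord]] = {}
        for a in self.protein_atoms:
            if heavy_only and not a.is_heavy:
                continue
            out.setdefault((a.chain_id, a.residue_number), []).append(a)
        return out


@dataclass
class Pose:
    """One docked ligand pose: heavy atoms and a docking energy (kcal/mol)."""

    pose_id: int
    ligand_atoms: list[AtomRecord]
    energy: float

    def __post_init__(self):
        if len(self.ligand_atoms) < 3:
            raise DomainError(f"pose {self.pose_id}: needs >= 3 ligand atoms")
        if not np.isfinite(self.energy):
            raise DomainError(f"pose {self.pose_id}: energy must be finite")

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a.atom_name for a in self.ligand_atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in pose atom order."""
        return np.array([a.coords for a in self.ligand_atoms])

    @property
    def centroid(self) -> np.ndarray:
        """Mean heavy-atom coordinate (the ligand reference point)."""
        return self.coords.mean(axis=0)

    def atom(self, name: str) -> AtomRecord:
        from .errors import LookupError_

        for a in self.ligand_atoms:
            if a.atom_name == name:
                return a
        raise LookupError_(f"ligand atom {name!r} not found in pose {self.pose_id}")


@dataclass
class PoseEnsemble:
    """All docked poses for one enzyme-ligand pair, sorted by ascending energy."""

    enzyme_id: str
    ligand_id: str
    poses: list[Pose] = field(default_factory=list)

    def __post_init__(self):
        if not self.poses:
            raise DomainError("pose ensemble must be nonempty")
        names = self.poses[0].atom_names
        for p in self.poses[1:]:
            if p.atom_names != names:
                raise ConsistencyError(
                    f"pose {p.pose_id} atom names differ from pose {self.poses[0].pose_id}"
                )
        self.poses.sort(key=lambda p: (p.energy, p.pose_id))

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def energies(self) -> np.ndarray:
        return np.array([p.energy for p in self.poses])


def _atoms_from_array(arr) -> list[AtomRecord]:
    elements = arr.element if "element" in arr.get_annotation_categories() else [""] * arr.array_length()
    return [
        AtomRecord(
            atom_name=str(arr.atom_name[i]),
            element=str(elements[i]),
            residue_number=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]),
            coords=arr.coord[i],
        )
        for i in range(arr.array_length())
    ]


def read_receptor_structure(
    path,
    fad_residue_names=DEFAULT_FAD_NAMES,
    enzyme_id: str = "",
) -> ComplexStructure:
    """Read a receptor PDB and partition atoms into protein vs FAD cofactor.

    Water is dropped; protein hydrogens are kept (downstream operations select
    heavy atoms themselves).

    Raises
    ------
    FormatError
        If the file cannot be parsed as PDB.
    EmptyStructureError
        If no protein atoms remain after partitioning.
    """
    fad_names = {n.upper() for n in fad_residue_names}
    try:
        pdb = pdbio.PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises assorted parse errors
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path}: no atoms")
    res_names = np.char.upper(arr.res_name.astype(str))
    is_fad = np.isin(res_names, sorted(fad_names))
    is_water = np.isin(res_names, ["HOH", "WAT", "TIP3"])
    fad_atoms = _atoms_from_array(arr[is_fad])
    protein_atoms = _atoms_from_array(arr[~is_fad & ~is_water])
    if not fad_atoms:
        logger.warning("%s: no FAD residue matched %s", path, sorted(fad_names))
    if not protein_atoms:
        raise EmptyStructureError(f"{path}: zero protein atoms")
    return ComplexStructure(protein_atoms=protein_atoms, fad_atoms=fad_atoms, enzyme_id=enzyme_id)


def _parse_model_remark_energies(text: str) -> list[float | None]:
    """Scan MODEL...ENDMDL blocks for 'REMARK ENERGY <float>' lines."""
    energies: list[float | None] = []
    current: float | None = None
    in_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, current = True, None
        elif rec == "ENDMDL":
            energies.append(current)
            in_model, current = False, None
        elif rec == "REMARK" and in_model:
            tokens = line.split()
            for j, tok in enumerate(tokens):
                if tok.upper() == "ENERGY" and j + 1 < len(tokens):
                    try:
                        current = float(tokens[j + 1])
                    except ValueError:
                        pass
    return energies


def read_pose_ensemble(
    path,
    energy_source: str = "remark",
    enzyme_id: str = "",
    ligand_id: str = "",
) -> PoseEnsemble:
    """Read a docked pose ensemble from a multi-model PDB or a CSV pose table.

    Parameters
    ----------
    path
        Multi-model PDB (one MODEL per pose) or a CSV with columns
        ``pose_id, atom_name, element, x, y, z, energy``.
    energy_source
        ``"remark"`` reads a per-model ``REMARK ENERGY <float>`` line
        (CHARMM-exported poses carry no standard energy field);
        ``"bfactor"`` falls back to the B-factor of each model's first atom.

    Poses are returned heavy-atoms-only, ordered by ascending energy.
    """
    path = str(path)
    if path.lower().endswith(".csv"):
        return _read_pose_table(path, enzyme_id=enzyme_id, ligand_id=ligand_id)
    if energy_source not in ("remark", "bfactor"):
        raise DomainError(f"unknown energy_source {energy_source!r}")
    with open(path) as fh:
        text = fh.read()
    try:
        pdb = pdbio.PDBFile.read(io.StringIO(text))
        n_models = pdb.get_model_count()
    except Exception as exc:
        raise FormatError(f"cannot parse pose PDB {path}: {exc}") from exc
    remark_energies = _parse_model_remark_energies(text)
    poses = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, extra_fields=["b_factor"])
        atoms = [a for a in _atoms_from_array(arr) if a.is_heavy]
        if energy_source == "remark":
            energy = remark_energies[m - 1] if m - 1 < len(remark_energies) else None
            if energy is None:
                raise MissingFieldError(f"{path}: model {m} has no REMARK ENERGY line")
        else:
            energy = float(arr.b_factor[0])
        poses.append(Pose(pose_id=m, ligand_atoms=atoms, energy=energy))
    return PoseEnsemble(enzyme_id=enzyme_id, ligand_id=ligand_id, poses=poses)


def _read_pose_table(path, enzyme_id="", ligand_id="") -> PoseEnsemble:
    df = pd.read_csv(path)
    required = {"pose_id", "atom_name", "x", "y", "z", "energy"}
    missing = required - set(df.columns)
    if missing:
        raise MissingFieldError(f"{path}: pose table missing columns {sorted(missing)}")
    if df["energy"].isna().any():
        raise MissingFieldError(f"{path}: pose table has missing energies")
    poses = []
    for pid, grp in df.groupby("pose_id", sort=True):
        energies = grp["energy"].unique()
        if len(energies) != 1:
            raise ConsistencyError(f"{path}: pose {pid} has multiple energies")
        atoms = [
            AtomRecord(
                atom_name=str(r.atom_name),
                element=str(getattr(r, "element", "") or ""),
                residue_number=int(getattr(r, "residue_number", 1) or 1),
                residue_name=str(getattr(r, "residue_name", "LIG") or "LIG"),
                chain_id=str(getattr(r, "chain_id", "X") or "X"),
                coords=np.array([r.x, r.y, r.z], dtype=float),
            )
            for r in grp.itertuples(index=False)
        ]
        atoms = [a for a in atoms if a.is_heavy]
        poses.append(Pose(pose_id=int(pid), ligand_atoms=atoms, energy=float(energies[0])))
    return PoseEnsemble(enzyme_id=enzyme_id, ligand_id=ligand_id, poses=poses)


def write_pose_ensemble(ensemble: PoseEnsemble, path) -> None:
    """Write an ensemble as multi-model PDB with per-model REMARK ENERGY lines."""
    blocks = []
    for m, pose in enumerate(ensemble.poses, start=1):
        arr = struc.AtomArray(len(pose.ligand_atoms))
        for i, a in enumerate(pose.ligand_atoms):
            arr.coord[i] = a.coords
            arr.atom_name[i] = a.atom_name
            arr.element[i] = a.element or a.atom_name[:1]
            arr.res_id[i] = a.residue_number
            arr.res_name[i] = a.residue_name
            arr.chain_id[i] = a.chain_id
            arr.hetero[i] = True
        pdb = pdbio.PDBFile()
        pdb.set_structure(arr)
        atom_lines = [l for l in pdb.lines if l.startswith(("ATOM", "HETATM"))]
        blocks.append(
            f"MODEL     {m:4d}\nREMARK ENERGY {pose.energy!r}\n" + "\n".join(atom_lines) + "\nENDMDL"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(blocks) + "\nEND\n")


def write_pose_table(ensemble: PoseEnsemble, path) -> None:
    """Write an ensemble as a flat CSV pose table (energies round-trip exactly)."""
    rows = []
    for pose in ensemble.poses:
        for a in pose.ligand_atoms:
            rows.append(
                dict(
                    pose_id=pose.pose_id,
                    atom_name=a.atom_name,
                    element=a.element,
                    residue_number=a.residue_number,
                    residue_name=a.residue_name,
                    chain_id=a.chain_id,
                    x=a.coords[0],
                    y=a.coords[1],
                    z=a.coords[2],
                    energy=pose.energy,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_screen_table(path) -> pd.DataFrame:
    """Read and validate a screen annotation table.

    Expected CSV columns: ``enzyme_id, ligand_id, stereochemistry, conversion``
    with stereochemistry in {R, S, R/S, NA}.  NA means not assayed or no
    conversion observed.
    """
    try:
        df = pd.read_csv(path, dtype={"enzyme_id": str, "ligand_id": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty screen table")
        return pd.DataFrame(columns=["enzyme_id", "ligand_id", "stereochemistry", "conversion"])
    required = {"enzyme_id", "ligand_id", "stereochemistry", "conversion"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: screen table missing columns {sorted(missing)}")
    stereo = df["stereochemistry"].fillna("NA").astype(str).str.strip().str.upper()
    bad = sorted(set(stereo) - STEREO_TOKENS)
    if bad:
        raise FormatError(f"{path}: unknown stereochemistry tokens {bad}")
    df = df.copy()
    df["stereochemistry"] = stereo
    df["conversion"] = pd.to_numeric(df["conversion"], errors="raise")
    return df
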