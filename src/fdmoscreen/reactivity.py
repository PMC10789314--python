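"""Docking-derived reactivity descriptors and the logistic reactivity model.

Five descriptors summarise the top-ranked docked pose of a substrate in an
FDMO active site:

* ``fad_distance`` — distance (A) from the ligand mean heavy-atom coordinate
  to the flavin ring atom that bonds the hydroperoxyl group (C4alpha).
* ``fad_angle`` — the top cluster's ring-normal angle (degrees) from the
  stereochemistry caller.
* ``anion_distance`` — distance (A) from the ligand's anionic oxygen to the
  CZ atom of the active-site arginine (R206 in TropB numbering), which
  anchors the substrate phenolate.
* ``energy_efficiency`` — docking energy divided by the number of ligand
  heavy atoms (kcal/mol per heavy atom).
* ``pkd_efficiency`` — externally predicted pKd divided by the number of
  ligand heavy atoms.  The pKd comes from a pluggable affinity scorer (e.g. a
  table of CNN-predicted affinities); it is consumed, never computed here.

An enzyme is labelled reactive if it shows any non-zero conversion with any
ligand; a maximum-likelihood logistic regression maps descriptors to that
binary label, with a small-ridge fallback when the classes are separable.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import (
    CollinearityError,
    DegenerateFitError,
    DomainError,
    LookupError_,
    MissingFieldError,
)
from .structio import ComplexStructure, Pose

logger = logging.getLogger(__name__)

DESCRIPTOR_NAMES = (
    "fad_distance",
    "fad_angle",
    "anion_distance",
    "energy_efficiency",
    "pkd_efficiency",
)


@dataclass
class DescriptorVector:
    """The five reactivity descriptors for one enzyme-ligand complex.

    A ``None`` entry marks a missing descriptor (e.g. no affinity score for
    the complex); rows with missing entries are excluded from fitting.
    """

    fad_distance: float | None = None
    fad_angle: float | None = None
    anion_distance: float | None = None
    energy_efficiency: float | None = None
    pkd_efficiency: float | None = None

    def __post_init__(self):
        for name in ("fad_distance", "anion_distance"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise DomainError(f"{name} must be finite and >= 0, got {v}")
        if self.fad_angle is not None and not 0 <= self.fad_angle <= 180:
            raise DomainError(f"fad_angle {self.fad_angle} outside [0, 180]")
        for name in ("energy_efficiency", "pkd_efficiency"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v}")

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.as_dict().values())


@dataclass(frozen=True)
class AnionSpec:
    """Which atoms define the anion distance.

    The arginine residue number is given in each enzyme's own numbering (map
    TropB R206 through the alignment first); the ligand anion atom defaults
    to the phenolate oxygen name used in the ligand topology.
    """

    arg_residue_number: int
    ligand_atom_name: str
    arg_atom_name: str = "CZ"


class AffinityScorer:
    """Contract for external per-complex affinity predictions (pKd).

    Implementations return a finite pKd or ``None`` as the declared missing
    marker.
    """

    def predict_pkd(
        self, receptor: ComplexStructure, pose: Pose, ligand_id: str = ""
    ) -> float | None:
        raise NotImplementedError


class TableAffinityScorer(AffinityScorer):
    """Affinity lookup from a (enzyme_id, ligand_id) -> pKd table."""

    def __init__(self, table: pd.DataFrame):
        required = {"enzyme_id", "ligand_id", "pkd"}
        if not required <= set(table.columns):
            raise MissingFieldError(f"affinity table needs columns {sorted(required)}")
        self._lut = {
            (str(r.enzyme_id), str(r.ligand_id)): float(r.pkd)
            for r in table.itertuples(index=False)
        }

    def predict_pkd(self, receptor, pose, ligand_id=""):
        return self._lut.get((receptor.enzyme_id, str(ligand_id)))


class ConstantAffinityScorer(AffinityScorer):
    """Fixed-pKd scorer, mainly for tests and synthetic pipelines."""

    def __init__(self, pkd: float):
        self._pkd = float(pkd)

    def predict_pkd(self, receptor, pose, ligand_id=""):
        return self._pkd


def compute_descriptors(
    receptor: ComplexStructure,
    top_pose: Pose,
    top_cluster_angle: float,
    fad_reference_atom_name: str,
    anion_spec: AnionSpec,
    scorer: AffinityScorer | None = None,
    ligand_id: str = "",
) -> DescriptorVector:
    """Compute the five descriptors from the top-ranked cluster representative."""
    n_heavy = len(top_pose.ligand_atoms)
    fad_atom = receptor.fad_atom(fad_reference_atom_name)
    fad_distance = float(np.linalg.norm(top_pose.centroid - fad_atom.coords))

    anion_distance = None
    arg_atoms = [
        a
        for a in receptor.protein_atoms
        if a.residue_number == anion_spec.arg_residue_number
        and a.atom_name == anion_spec.arg_atom_name
    ]
    if not arg_atoms:
        logger.warning(
            "no %s atom at residue %d (arginine absent at the mapped position?); "
            "anion_distance marked missing",
            anion_spec.arg_atom_name,
            anion_spec.arg_residue_number,
        )
    else:
        try:
            lig_atom = top_pose.atom(anion_spec.ligand_atom_name)
        except LookupError_:
            raise
        anion_distance = float(np.linalg.norm(lig_atom.coords - arg_atoms[0].coords))

    pkd_eff = None
    if scorer is not None:
        pkd = scorer.predict_pkd(receptor, top_pose, ligand_id=ligand_id)
        if pkd is None:
            logger.warning(
                "affinity scorer missing for (%s, %s); pkd_efficiency marked missing",
                receptor.enzyme_id,
                ligand_id,
            )
        else:
            pkd_eff = float(pkd) / n_heavy

    return DescriptorVector(
        fad_distance=fad_distance,
        fad_angle=float(top_cluster_angle),
        anion_distance=anion_distance,
        energy_efficiency=top_pose.energy / n_heavy,
        pkd_efficiency=pkd_eff,
    )


def consensus_descriptors(per_ligand: list[DescriptorVector]) -> DescriptorVector:
    """Arithmetic mean of descriptors over ligands, ignoring missing values."""
    if not per_ligand:
        raise DomainError("need at least one ligand descriptor vector")
    out: dict[str, float | None] = {}
    for name in DESCRIPTOR_NAMES:
        vals = [getattr(d, name) for d in per_ligand if getattr(d, name) is not None]
        if not vals:
            warnings.warn(f"descriptor {name} missing for every ligand")
            out[name] = None
        else:
            if len(vals) < len(per_ligand):
                warnings.warn(f"descriptor {name} missing for some ligands; mean over the rest")
            out[name] = float(np.mean(vals))
    return DescriptorVector(**out)


@dataclass
class ReactivityModel:
    """Fitted logistic reactivity classifier.

    ``ridge_alpha`` is 0 for a plain maximum-likelihood fit; a positive value
    (with ``separation_flagged``) marks the penalized fallback used when the
    classes were (quasi-)separable.
    """

    descriptor_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    standard_errors: np.ndarray
    p_values: np.ndarray
    ridge_alpha: float = 0.0
    separation_flagged: bool = False

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(x, dtype=float) @ self.coefficients

    def to_json(self) -> str:
        return json.dumps(
            dict(
                descriptor_names=list(self.descriptor_names),
                coefficients=self.coefficients.tolist(),
                intercept=self.intercept,
                standard_errors=self.standard_errors.tolist(),
                p_values=self.p_values.tolist(),
                ridge_alpha=self.ridge_alpha,
                separation_flagged=self.separation_flagged,
            ),
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReactivityModel":
        d = json.loads(text)
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            standard_errors=np.asarray(d["standard_errors"], dtype=float),
            p_values=np.asarray(d["p_values"], dtype=float),
            ridge_alpha=float(d["ridge_alpha"]),
            separation_flagged=bool(d["separation_flagged"]),
        )


def _design(table: pd.DataFrame, names) -> tuple[np.ndarray, np.ndarray]:
    x = table[list(names)].to_numpy(dtype=float)
    y = table["reactive"].to_numpy(dtype=float)
    return x, y


def _check_rank(x: np.ndarray, names) -> None:
    design = np.column_stack([np.ones(len(x)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full rank
        offenders = []
        for j in range(x.shape[1]):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                offenders.append(names[j])
        raise CollinearityError(offenders or list(names))


def _ridge_logistic(x: np.ndarray, y: np.ndarray, alpha: float):
    """Penalized logistic fit: neg log-likelihood + alpha/2 * ||beta||^2.

    The intercept is unpenalized.  Standard errors come from the inverse of
    the penalized Hessian at the optimum (a Wald-type approximation).
    """
    design = np.column_stack([np.ones(len(x)), x])
    pen = np.full(design.shape[1], alpha)
    pen[0] = 0.0

    def negll(beta):
        eta = design @ beta
        # log(1 + e^eta) - y*eta, computed stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(pen * beta**2))

    def grad(beta):
        p = scipy.special.expit(design @ beta)
        return design.T @ (p - y) + pen * beta

    res = scipy.optimize.minimize(negll, np.zeros(design.shape[1]), jac=grad, method="L-BFGS-B")
    beta = res.x
    p = 1.0 / (1.0 + np.exp(-(design @ beta)))
    w = p * (1 - p)
    hess = design.T @ (design * w[:, None]) + np.diag(pen)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    return beta, se


def fit_reactivity_model(
    table: pd.DataFrame,
    descriptor_names=DESCRIPTOR_NAMES,
    ridge_alpha: float = 1e-4,
) -> ReactivityModel:
    """Maximum-likelihood logistic fit of reactive (0/1) on the descriptors.

    Rows with any missing descriptor are dropped with a warning.  When the
    fit shows (quasi-)separation — statsmodels raises, fails to converge, or
    produces runaway coefficients — the model is refit with a small ridge
    penalty and flagged.

    Parameters
    ----------
    table
        One row per enzyme (or enzyme-ligand pair): descriptor columns plus a
        binary ``reactive`` column.
    """
    names = tuple(descriptor_names)
    work = table.dropna(subset=list(names) + ["reactive"])
    if len(work) < len(table):
        warnings.warn(f"dropped {len(table) - len(work)} rows with missing descriptors")
    y_unique = set(work["reactive"].unique().tolist()) if len(work) else set()
    if len(y_unique) < 2:
        raise DegenerateFitError("reactivity labels contain a single class")
    if len(work) < len(names) + 2:
        raise DegenerateFitError(f"need >= {len(names) + 2} rows, got {len(work)}")
    x, y = _design(work, names)
    _check_rank(x, names)

    design = sm.add_constant(x, has_constant="add")
    separable = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params, bse = fit.params, fit.bse
        if not fit.mle_retvals.get("converged", True) or np.max(np.abs(params)) > 1e3 or not np.all(
            np.isfinite(bse)
        ):
            separable = True
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        separable = True

    if separable:
        logger.warning("quasi-separation detected; refitting with ridge alpha=%g", ridge_alpha)
        params, bse = _ridge_logistic(x, y, ridge_alpha)

    z = params / bse
    pvals = 2 * scipy.stats.norm.sf(np.abs(z))
    return ReactivityModel(
        descriptor_names=names,
        coefficients=np.asarray(params[1:], dtype=float),
        intercept=float(params[0]),
        standard_errors=np.asarray(bse[1:], dtype=float),
        p_values=np.asarray(pvals[1:], dtype=float),
        ridge_alpha=ridge_alpha if separable else 0.0,
        separation_flagged=separable,
    )


def predict_reactivity(
    model: ReactivityModel,
    descriptors: DescriptorVector | dict,
    threshold: float = 0.5,
) -> tuple[float, str]:
    """Predicted reactivity probability and label for one descriptor vector."""
    d = descriptors.as_dict() if isinstance(descriptors, DescriptorVector) else dict(descriptors)
    try:
        x = np.array([d[name] for name in model.descriptor_names], dtype=float)
    except (KeyError, TypeError) as exc:
        raise MissingFieldError(f"descriptor missing for prediction: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise MissingFieldError("descriptor vector has missing values")
    eta = float(model.linear_predictor(x))
    prob = 1.0 / (1.0 + math.exp(-eta))
    return prob, ("reactive" if prob >= threshold else "unreactive")


def screen_descriptors(
    models: list[ReactivityModel],
    p_threshold: float = 0.10,
    min_models: int = 3,
) -> list[str]:
    """Descriptors non-predictive across ligand-specific fits.

    A descriptor is flagged when its Wald p-value exceeds ``p_threshold`` in
    at least ``min_models`` of the supplied models — the screen used to drop
    uninformative descriptors (FAD distance in the original benchmark).
    """
    if not models:
        raise DomainError("need at least one fitted model")
    names = models[0].descriptor_names
    flagged = []
    for j, name in enumerate(names):
        n_bad = sum(1 for m in models if m.p_values[j] > p_threshold)
        if n_bad >= min_models:
            flagged.append(name)
    return flagged
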