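"""Model quality evaluation: G-domain superposition, ligand RMSD (L-RMSD),
CAPRI quality classes, and cohort hit-rate / success-rate curves.

L-RMSD is computed the docking way: the receptor G-domains (M-chain residues
1-180) of model and reference are superposed by least squares and the RMSD
is then taken over the peptide atoms *without* refitting on the peptide, so
it measures where the peptide sits in the groove, not just its internal
shape. Four atom-set dialects are supported: backbone {N, CA, C, O},
c_alpha, backbone_cb and full_atom.

A "hit" is a model below the hit threshold (default 2.0 Å). For one case,
hit_rate(K) = n_hits(K) / M where M is the case's total number of
near-native models — a recall of the achievable hits (an alternative reading
normalizes by K; we implement the recall form). success_rate(K) over a
cohort is the fraction of cases with at least one hit among their top K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import PmhcStructure

DIALECTS = {
    "backbone": ("N", "CA", "C", "O"),
    "c_alpha": ("CA",),
    "backbone_cb": ("N", "CA", "C", "O", "CB"),
    "full_atom": None,  # every atom present in both structures
}

#: CAPRI-style quality bins on backbone L-RMSD (upper edges, Å). The last
#: class is open-ended: anything >= the Acceptable edge is Incorrect.
CAPRI_EDGES = ((1.0, "High"), (2.0, "Medium"), (5.0, "Acceptable"))

DEFAULT_HIT_THRESHOLD = 2.0


class EvaluationError(Exception):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ (x - centroid_src) + centroid_dst."""

    rotation: np.ndarray
    centroid_src: np.ndarray
    centroid_dst: np.ndarray
    fit_rmsd: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, float)
        if (
            np.array_equal(self.rotation, np.eye(3))
            and np.array_equal(self.centroid_src, self.centroid_dst)
        ):
            # exact identity: avoid introducing rounding through -c ... +c
            return xyz.copy()
        return (xyz - self.centroid_src) @ self.rotation.T + self.centroid_dst


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of src onto dst (proper rotation,
    det = +1), via SVD of the covariance matrix."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise EvaluationError("point sets must be matching (n, 3) arrays")
    if len(src) < 3:
        raise EvaluationError("need at least 3 corresponding atoms")
    if np.array_equal(src, dst):
        # exact self-comparison: return the identity transform so identical
        # structures score an L-RMSD of exactly zero
        c = src.mean(axis=0)
        return RigidTransform(rotation=np.eye(3), centroid_src=c, centroid_dst=c, fit_rmsd=0.0)
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    h = (src - c_src).T @ (dst - c_dst)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (src - c_src) @ rot.T + c_dst
    fit = float(np.sqrt(np.mean(np.sum((moved - dst) ** 2, axis=1))))
    return RigidTransform(rotation=rot, centroid_src=c_src, centroid_dst=c_dst, fit_rmsd=fit)


def _chain_atoms(chain, atom_names, gdomain_end=None):
    out = {}
    for r in chain:
        if gdomain_end is not None and r.seq_pos > gdomain_end:
            continue
        for a in r.atoms:
            if atom_names is None or a.name in atom_names:
                out[(r.seq_pos, a.name)] = np.asarray(a.xyz, float)
    return out


def superpose_gdomain(
    model: PmhcStructure, reference: PmhcStructure, gdomain_end: int = 180
) -> RigidTransform:
    """Fit the model's G-domain onto the reference's: backbone atoms of
    M-chain residues 1..180, restricted to the subset resolved in both."""
    m = _chain_atoms(model.m_chain, DIALECTS["backbone"], gdomain_end)
    r = _chain_atoms(reference.m_chain, DIALECTS["backbone"], gdomain_end)
    keys = sorted(m.keys() & r.keys())
    if len(keys) < 3:
        raise EvaluationError("fewer than 3 common G-domain backbone atoms")
    src = np.array([m[k] for k in keys])
    dst = np.array([r[k] for k in keys])
    return kabsch(src, dst)


def lrmsd(
    model: PmhcStructure,
    reference: PmhcStructure,
    dialect: str = "backbone",
    transform: RigidTransform | None = None,
) -> float:
    """Ligand RMSD in Å over corresponding P-chain atoms of the chosen
    dialect, after G-domain superposition (no refitting on the peptide)."""
    if dialect not in DIALECTS:
        raise EvaluationError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    if transform is None:
        transform = superpose_gdomain(model, reference)
    atoms = DIALECTS[dialect]
    m = _chain_atoms(model.p_chain, atoms)
    r = _chain_atoms(reference.p_chain, atoms)
    keys = sorted(m.keys() & r.keys())
    if not keys:
        raise EvaluationError("no corresponding peptide atoms")
    src = transform.apply(np.array([m[k] for k in keys]))
    dst = np.array([r[k] for k in keys])
    return float(np.sqrt(np.mean(np.sum((src - dst) ** 2, axis=1))))


def capri_class(lrmsd_value: float) -> str:
    """Quality label from backbone L-RMSD: High < 1 Å, Medium < 2 Å,
    Acceptable < 5 Å, else Incorrect."""
    if lrmsd_value < 0:
        raise EvaluationError("L-RMSD cannot be negative")
    for edge, label in CAPRI_EDGES:
        if lrmsd_value < edge:
            return label
    return "Incorrect"


def hit_rate(
    case_lrmsds, k: int, threshold: float = DEFAULT_HIT_THRESHOLD
) -> float:
    """Per-case hit recall at rank K: hits among the top K divided by the
    case's total number of hits M. ``case_lrmsds`` is ordered by rank.
    Requires M >= 1 (cases without any hit carry no signal here and are
    excluded from cohort averages by the caller)."""
    if k < 1:
        raise EvaluationError("K must be >= 1")
    vals = list(case_lrmsds)
    m = sum(1 for v in vals if v < threshold)
    if m == 0:
        raise EvaluationError("case has no hits (M = 0)")
    n_hits = sum(1 for v in vals[:k] if v < threshold)
    return n_hits / m


def cohort_hit_rate(cohort, k: int, threshold: float = DEFAULT_HIT_THRESHOLD) -> float:
    """Mean per-case hit rate at K; cases with no hit at all are excluded."""
    rates = []
    for case in cohort:
        if any(v < threshold for v in case):
            rates.append(hit_rate(case, k, threshold))
    if not rates:
        raise EvaluationError("no case in the cohort has any hit")
    return float(np.mean(rates))


def success_rate(cohort, k: int, threshold: float = DEFAULT_HIT_THRESHOLD) -> float:
    """Fraction of cases with at least one hit among their top K models."""
    if k < 1:
        raise EvaluationError("K must be >= 1")
    cohort = list(cohort)
    if not cohort:
        raise EvaluationError("empty cohort")
    ok = sum(1 for case in cohort if any(v < threshold for v in list(case)[:k]))
    return ok / len(cohort)


@dataclass
class CaseEvaluation:
    case_id: str
    lrmsd_by_dialect: dict[str, float]
    capri: str
    per_model_lrmsd: list[float]


@dataclass
class EvaluationReport:
    """Per-case L-RMSDs plus cohort hit/success curves over K = 1..n."""

    cases: list[CaseEvaluation]
    hit_threshold: float
    n_models: int
    hit_rate_curve: list[float] = field(default_factory=list)
    success_rate_curve: list[float] = field(default_factory=list)


def evaluate_case(
    models,
    reference: PmhcStructure,
    case_id: str = "",
    dialects=("backbone", "c_alpha", "backbone_cb", "full_atom"),
) -> CaseEvaluation:
    """Evaluate ranked models of one case against its reference structure.

    The headline L-RMSD (and CAPRI class) is the backbone L-RMSD of the
    rank-1 model; ``per_model_lrmsd`` holds backbone values by rank.
    """
    if not models:
        raise EvaluationError("no models to evaluate")
    ordered = sorted(models, key=lambda m: m.rank)
    per_model = []
    for m in ordered:
        per_model.append(lrmsd(m.structure, reference, "backbone"))
    top = ordered[0].structure
    transform = superpose_gdomain(top, reference)
    by_dialect = {d: lrmsd(top, reference, d, transform) for d in dialects}
    return CaseEvaluation(
        case_id=case_id,
        lrmsd_by_dialect=by_dialect,
        capri=capri_class(by_dialect["backbone"]),
        per_model_lrmsd=per_model,
    )


def evaluate_cohort(
    case_evals: list[CaseEvaluation],
    n_models: int,
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
) -> EvaluationReport:
    cohort = [c.per_model_lrmsd for c in case_evals]
    hit_curve = []
    success_curve = []
    any_hits = any(any(v < hit_threshold for v in case) for case in cohort)
    for k in range(1, n_models + 1):
        success_curve.append(success_rate(cohort, k, hit_threshold))
        hit_curve.append(cohort_hit_rate(cohort, k, hit_threshold) if any_hits else float("nan"))
    return EvaluationReport(
        cases=case_evals,
        hit_threshold=hit_threshold,
        n_models=n_models,
        hit_rate_curve=hit_curve,
        success_rate_curve=success_curve,
    )
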