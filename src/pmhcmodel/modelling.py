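"""Anchor-restrained peptide loop modelling.

The pipeline grafts the target onto the selected template (MHC backbone
copied, mismatched side chains truncated to Cβ; peptide backbone copied
column-by-column from the anchor-driven alignment), then produces an
ensemble: each model starts from the initial graft with every loop-residue
atom displaced by an independent uniform offset of up to ±5 Å per
coordinate, followed by a short two-phase minimization — phase one restores
bonded geometry, phase two adds steric clash and optional secondary-structure
restraints. Anchor residues and the whole MHC chain never move.

Models are ranked by the final minimization objective (lower is better), the
package's surrogate for an engine-internal ranking score such as molpdf: the
ranking semantics (ascending scores, identical-case shortcut scored one unit
below the best generated model) are preserved exactly. The module can also
emit MODELLER-ready input files (PIR alignment, template PDB, restraint list)
for users who want to run the licensed engine instead.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.spatial.distance import cdist

from . import geometry as geom
from .structure_io import (
    AA1_TO_3,
    AA3_TO_1,
    Atom,
    PmhcStructure,
    Residue,
    write_structure,
)
from .template_db import (
    AlleleName,
    SequenceNotFoundError,
    TemplateDatabase,
    TemplateEntry,
    resolve_mhc_sequence,
)
from .selection import AMINO_ACIDS, PeptideAlignment, select_template

logger = logging.getLogger(__name__)

DEFAULT_AMPLITUDE = 5.0
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: iteration budget (phase 1, phase 2) per refinement preset
PRESETS = {
    "fast": (100, 150),
    "default": (200, 300),
    "thorough": (800, 1200),
}

_ELEMENT = {"N": "N", "O": "O"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], "C")


class ModellingError(Exception):
    """Pipeline failure; ``stage`` names the step that failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SSRestraint:
    """Secondary-structure restraint request on peptide positions
    [start, end] (1-based, inclusive). ``kind`` is ``helix`` (O(i)-N(i+4)
    targets of 3.0 Å) or ``strand_pair`` (hairpin Cα(start+k)-Cα(end-k)
    targets of 4.8 Å)."""

    kind: str
    start: int
    end: int


@dataclass
class ModellingTarget:
    """A modelling query: peptide sequence and MHC allele, plus run options.

    Anchors default to the canonical {2, Ω} set. ``seed`` drives every source
    of randomness; model ``i`` uses stream ``seed + i`` so earlier models are
    unchanged when ``n_models`` grows.
    """

    peptide_seq: str
    allele: AlleleName | str
    anchors: tuple[int, ...] | None = None
    mhc_seq: str | None = None
    ss_restraints: tuple[SSRestraint, ...] = ()
    n_models: int = 20
    seed: int = 0
    preset: str = "default"

    def __post_init__(self):
        n = len(self.peptide_seq)
        if not 7 <= n <= 15:
            raise ValueError(f"peptide length {n} outside 7-15")
        if any(c not in AMINO_ACIDS for c in self.peptide_seq):
            raise ValueError(f"invalid peptide sequence {self.peptide_seq!r}")
        if isinstance(self.allele, str):
            self.allele = AlleleName.parse(self.allele)
        if self.anchors is None:
            self.anchors = (2, n)
        self.anchors = tuple(sorted(set(self.anchors)))
        if len(self.anchors) < 2 or any(not 1 <= a <= n for a in self.anchors):
            raise ValueError(f"invalid anchors {self.anchors} for {n}-mer")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")


@dataclass(frozen=True)
class RestraintWeights:
    """Objective weights (Å² energy units) and the clash floor distance."""

    w_bond: float = 10.0
    w_clash: float = 5.0
    w_anchor: float = 100.0
    w_ss: float = 10.0
    d_min: float = 2.8

    def __post_init__(self):
        if min(self.w_bond, self.w_clash, self.w_anchor, self.w_ss) <= 0:
            raise ValueError("all weights must be positive")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")


@dataclass
class ModelResult:
    structure: PmhcStructure
    score: float
    rank: int
    diagnostics: dict
    seed_used: int | None


# ---------------------------------------------------------------------------
# MHC pairwise alignment

def align_mhc(target_seq: str, template_seq: str) -> tuple[str, str]:
    """Global pairwise alignment of the target and template MHC sequences
    (BLOSUM62, affine gaps -11/-1, deterministic first optimum)."""
    for seq in (target_seq, template_seq):
        if not seq:
            raise ValueError("empty MHC sequence")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-amino-acid characters in MHC sequence: {sorted(bad)}")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(target_seq, template_seq)[0]
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# Initial model construction

def _residue_from_template(tres: Residue, target_aa: str, pos: int) -> Residue:
    """Copy a template residue for the target sequence: identical residues
    keep every atom, mismatches are truncated to the backbone plus Cβ (ideal
    position if the template has none; glycine gets no Cβ)."""
    name3 = AA1_TO_3[target_aa]
    if tres.name == name3:
        atoms = tuple(replace(a) for a in tres.atoms)
        return Residue(name=name3, seq_pos=pos, atoms=atoms)
    atoms = [a for a in tres.atoms if a.name in BACKBONE_ATOMS]
    if target_aa != "G":
        cb = tres.atom("CB")
        if cb is not None:
            atoms.append(Atom("CB", "C", cb.xyz))
        else:
            n, ca, c = (tres.coord(x) for x in ("N", "CA", "C"))
            if n is not None and ca is not None and c is not None:
                xyz = geom.ideal_cb(n, ca, c)
                atoms.append(Atom("CB", "C", tuple(float(v) for v in xyz)))
    return Residue(name=name3, seq_pos=pos, atoms=tuple(atoms))


def _approx_residue(aa: str, pos: int, ca: np.ndarray, u: np.ndarray) -> Residue:
    """Rough backbone around an interpolated Cα; phase-one minimization
    restores proper geometry for these loop insertions."""
    u = u / np.linalg.norm(u)
    v = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, np.array([0.0, 1.0, 0.0]))
    v /= np.linalg.norm(v)
    n = ca - geom.BOND_N_CA * (0.866 * u + 0.5 * v)
    c = ca + geom.BOND_CA_C * (0.866 * u - 0.5 * v)
    o = c + geom.BOND_C_O * v
    atoms = [
        Atom("N", "N", tuple(map(float, n))),
        Atom("CA", "C", tuple(map(float, ca))),
        Atom("C", "C", tuple(map(float, c))),
        Atom("O", "O", tuple(map(float, o))),
    ]
    if aa != "G":
        atoms.append(Atom("CB", "C", tuple(map(float, geom.ideal_cb(n, ca, c)))))
    return Residue(name=AA1_TO_3[aa], seq_pos=pos, atoms=tuple(atoms))


def _build_chain_from_alignment(
    target_row: str, template_row: str, template_residues, stage: str
) -> list[Residue]:
    """Column-wise chain graft: matched columns copy the template residue,
    target-row gaps skip it, template-row gaps (target insertions) are built
    by linear interpolation of the flanking Cα positions."""
    plan: list[tuple[str, object]] = []  # ("copy", template residue) | ("insert", aa)
    si = 0
    for ta, sa in zip(target_row, template_row):
        if ta == "-" and sa == "-":
            continue
        if ta == "-":
            si += 1
            continue
        if sa == "-":
            plan.append(("insert", ta))
        else:
            if si >= len(template_residues):
                raise ModellingError(stage, "alignment inconsistent with template length")
            plan.append(("copy", (template_residues[si], ta)))
            si += 1
    if si != len(template_residues):
        raise ModellingError(stage, "alignment inconsistent with template length")

    out: list[Residue] = []
    pos = 0
    i = 0
    while i < len(plan):
        kind, payload = plan[i]
        if kind == "copy":
            tres, aa = payload
            pos += 1
            out.append(_residue_from_template(tres, aa, pos))
            i += 1
            continue
        # run of insertions
        j = i
        while j < len(plan) and plan[j][0] == "insert":
            j += 1
        aas = [plan[k][1] for k in range(i, j)]
        prev_ca = None
        if out:
            prev_ca = out[-1].coord("CA")
        next_ca = None
        if j < len(plan):
            next_ca = plan[j][1][0].coord("CA")
        k = len(aas)
        if prev_ca is None and next_ca is None:
            raise ModellingError(stage, "alignment consists only of insertions")
        if prev_ca is None:  # leading insertions: extrapolate backwards
            nxt2 = plan[j + 1][1][0].coord("CA") if j + 1 < len(plan) and plan[j + 1][0] == "copy" else next_ca + np.array([3.8, 0, 0])
            d = next_ca - nxt2
            d = d / np.linalg.norm(d) if np.linalg.norm(d) > 1e-6 else np.array([1.0, 0, 0])
            for m, aa in enumerate(aas):
                pos += 1
                ca = next_ca + d * 3.8 * (k - m)
                out.append(_approx_residue(aa, pos, ca, -d))
        elif next_ca is None:  # trailing insertions: extrapolate forwards
            prev2 = out[-2].coord("CA") if len(out) >= 2 else prev_ca - np.array([3.8, 0, 0])
            d = prev_ca - prev2
            d = d / np.linalg.norm(d) if np.linalg.norm(d) > 1e-6 else np.array([1.0, 0, 0])
            for m, aa in enumerate(aas, start=1):
                pos += 1
                out.append(_approx_residue(aa, pos, prev_ca + d * 3.8 * m, d))
        else:
            u = next_ca - prev_ca
            for m, aa in enumerate(aas, start=1):
                pos += 1
                ca = prev_ca + u * (m / (k + 1))
                out.append(_approx_residue(aa, pos, ca, u))
        i = j
    return out


def build_initial_model(
    template: TemplateEntry,
    peptide_alignment: PeptideAlignment,
    mhc_alignment: tuple[str, str],
    target: ModellingTarget,
) -> PmhcStructure:
    """Graft the target sequences onto the template coordinates."""
    if peptide_alignment.target_seq != target.peptide_seq:
        raise ModellingError("initial-model", "peptide alignment does not match target sequence")
    if peptide_alignment.template_seq != template.peptide_seq:
        raise ModellingError("initial-model", "peptide alignment does not match template sequence")
    m_chain = _build_chain_from_alignment(
        mhc_alignment[0], mhc_alignment[1], template.structure.m_chain, "initial-model"
    )
    p_chain = _build_chain_from_alignment(
        peptide_alignment.target_row,
        peptide_alignment.template_row,
        template.structure.p_chain,
        "initial-model",
    )
    return PmhcStructure(
        m_chain=tuple(m_chain),
        p_chain=tuple(p_chain),
        source_id=f"model_on_{template.source_id}",
    )


# ---------------------------------------------------------------------------
# Secondary-structure restraints

def build_ss_restraints(
    specs, peptide_length: int
) -> list[tuple[tuple[int, str], tuple[int, str], float]]:
    """Expand restraint requests into ((pos, atom), (pos, atom), target Å)
    distance terms."""
    terms = []
    for spec in specs or ():
        kind = spec.kind.replace("-", "_")
        if not (1 <= spec.start < spec.end <= peptide_length):
            raise ValueError(f"restraint span {spec.start}-{spec.end} invalid for {peptide_length}-mer")
        if kind == "helix":
            if spec.end - spec.start + 1 < 5:
                raise ValueError("helix restraint needs a span of at least 5 residues")
            for i in range(spec.start, spec.end - 3):
                terms.append(((i, "O"), (i + 4, "N"), 3.0))
        elif kind == "strand_pair":
            k = 0
            while spec.start + k < spec.end - k:
                terms.append(((spec.start + k, "CA"), (spec.end - k, "CA"), 4.8))
                k += 1
        else:
            raise ValueError(f"unknown secondary-structure kind {spec.kind!r}")
    return terms


# ---------------------------------------------------------------------------
# Restrained minimization

class MinimizationError(ModellingError):
    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__("minimize", message)
        self.diagnostics = diagnostics or {}


class _LoopSystem:
    """Array view of one peptide chain against a fixed MHC background.

    Atom order is the flattened residue order of the P chain; only atoms of
    non-anchor ("loop") residues are free variables.
    """

    def __init__(
        self,
        model: PmhcStructure,
        anchors: tuple[int, ...],
        weights: RestraintWeights,
        ss_terms=(),
        m_cutoff: float = 14.0,
    ):
        self.weights = weights
        self.anchors = tuple(anchors)
        self.model = model
        index: dict[tuple[int, str], int] = {}
        coords = []
        res_of_atom = []
        for r in model.p_chain:
            for a in r.atoms:
                index[(r.seq_pos, a.name)] = len(coords)
                coords.append(a.xyz)
                res_of_atom.append(r.seq_pos)
        self.index = index
        self.coords0 = np.asarray(coords, float)
        self.res_of_atom = np.asarray(res_of_atom)
        self.moving = np.asarray([p not in anchors for p in res_of_atom])
        self.n_atoms = len(coords)

        # bonded + angle-encoding 1-3 distance terms
        bonds: list[tuple[int, int, float, bool]] = []

        def add(p1, a1, p2, a2, d0, true_bond):
            i = index.get((p1, a1))
            j = index.get((p2, a2))
            if i is not None and j is not None:
                bonds.append((i, j, d0, true_bond))

        positions = [r.seq_pos for r in model.p_chain]
        for p in positions:
            add(p, "N", p, "CA", geom.BOND_N_CA, True)
            add(p, "CA", p, "C", geom.BOND_CA_C, True)
            add(p, "C", p, "O", geom.BOND_C_O, True)
            add(p, "CA", p, "CB", geom.D_CA_CB, True)
            add(p, "N", p, "C", geom.D13_N_C, False)
            add(p, "CA", p, "O", geom.D13_CA_O, False)
            add(p, "N", p, "CB", geom.D13_N_CB_EFF, False)
            add(p, "C", p, "CB", geom.D13_C_CB_EFF, False)
        for p, q in zip(positions, positions[1:]):
            add(p, "C", q, "N", geom.BOND_C_N, True)
            add(p, "CA", q, "N", geom.D13_CA_N_NEXT, False)
            add(p, "C", q, "CA", geom.D13_C_CA_NEXT, False)
        self.bond_i = np.asarray([b[0] for b in bonds])
        self.bond_j = np.asarray([b[1] for b in bonds])
        self.bond_d0 = np.asarray([b[2] for b in bonds])
        self.true_bond = np.asarray([b[3] for b in bonds])

        # anchor backbone position restraints (anchor atoms are also fixed;
        # the term exists so a non-default loop definition stays restrained)
        anc = [
            index[(p, a)]
            for p in anchors
            for a in BACKBONE_ATOMS
            if (p, a) in index
        ]
        self.anchor_idx = np.asarray(anc, dtype=int)
        self.anchor_targets = self.coords0[self.anchor_idx].copy()

        # secondary-structure distance terms
        ss = []
        for (p1, a1), (p2, a2), d0 in ss_terms:
            if (p1, a1) in index and (p2, a2) in index:
                ss.append((index[(p1, a1)], index[(p2, a2)], d0))
        self.ss_i = np.asarray([s[0] for s in ss], dtype=int)
        self.ss_j = np.asarray([s[1] for s in ss], dtype=int)
        self.ss_d0 = np.asarray([s[2] for s in ss], dtype=float)

        # clash partners: MHC atoms near the peptide (the loop can wander by
        # the randomization amplitude, hence the generous cutoff)
        m_xyz = np.asarray(
            [a.xyz for r in model.m_chain for a in r.atoms], float
        )
        if len(m_xyz):
            lo = self.coords0.min(axis=0) - m_cutoff
            hi = self.coords0.max(axis=0) + m_cutoff
            keep = np.all((m_xyz >= lo) & (m_xyz <= hi), axis=1)
            self.m_near = m_xyz[keep]
        else:
            self.m_near = np.zeros((0, 3))

        # peptide-peptide clash exclusion: same or adjacent residues
        dres = np.abs(self.res_of_atom[:, None] - self.res_of_atom[None, :])
        self.pp_mask = np.triu(dres > 1)

    # -- objective -----------------------------------------------------

    def energy(self, coords: np.ndarray, phase: int):
        w = self.weights
        grad = np.zeros_like(coords)
        terms = {}

        delta = coords[self.bond_i] - coords[self.bond_j]
        d = np.linalg.norm(delta, axis=1)
        dev = d - self.bond_d0
        e_bond = w.w_bond * float(np.sum(dev * dev))
        g = (2.0 * w.w_bond * dev / np.maximum(d, 1e-12))[:, None] * delta
        np.add.at(grad, self.bond_i, g)
        np.add.at(grad, self.bond_j, -g)
        terms["bond"] = e_bond

        dd = coords[self.anchor_idx] - self.anchor_targets
        e_anchor = w.w_anchor * float(np.sum(dd * dd))
        grad[self.anchor_idx] += 2.0 * w.w_anchor * dd
        terms["anchor"] = e_anchor

        e_ss = 0.0
        e_clash = 0.0
        if phase >= 2:
            if len(self.ss_i):
                delta = coords[self.ss_i] - coords[self.ss_j]
                d = np.linalg.norm(delta, axis=1)
                dev = d - self.ss_d0
                e_ss = w.w_ss * float(np.sum(dev * dev))
                g = (2.0 * w.w_ss * dev / np.maximum(d, 1e-12))[:, None] * delta
                np.add.at(grad, self.ss_i, g)
                np.add.at(grad, self.ss_j, -g)

            dpp = cdist(coords, coords)
            viol = self.pp_mask & (dpp < w.d_min)
            ii, jj = np.nonzero(viol)
            if len(ii):
                delta = coords[ii] - coords[jj]
                d = np.maximum(dpp[ii, jj], 1e-12)
                gap = w.d_min - d
                e_clash += w.w_clash * float(np.sum(gap * gap))
                g = (-2.0 * w.w_clash * gap / d)[:, None] * delta
                np.add.at(grad, ii, g)
                np.add.at(grad, jj, -g)
            if len(self.m_near):
                dpm = cdist(coords, self.m_near)
                viol = dpm < w.d_min
                ii, jj = np.nonzero(viol)
                if len(ii):
                    delta = coords[ii] - self.m_near[jj]
                    d = np.maximum(dpm[ii, jj], 1e-12)
                    gap = w.d_min - d
                    e_clash += w.w_clash * float(np.sum(gap * gap))
                    g = (-2.0 * w.w_clash * gap / d)[:, None] * delta
                    np.add.at(grad, ii, g)
        terms["ss"] = e_ss
        terms["clash"] = e_clash
        e = e_bond + e_anchor + e_ss + e_clash
        return e, grad, terms

    # -- optimizer -----------------------------------------------------

    def minimize(self, coords: np.ndarray, preset: str = "default"):
        """Two-phase gradient descent with step halving on objective
        increase. The accepted-step objective sequence is non-increasing
        within each phase; only loop-residue atoms move."""
        n1, n2 = PRESETS[preset]
        coords = coords.copy()
        mov = self.moving
        iterations = 0
        traces = {}
        terms = {}
        e = math.inf
        for phase, n_iter in ((1, n1), (2, n2)):
            e, grad, terms = self.energy(coords, phase)
            if not math.isfinite(e):
                raise MinimizationError("non-finite objective", {"terms": terms})
            trace = [e]
            step = 0.01
            x_prev = None
            g_prev = None
            for _ in range(n_iter):
                g = grad[mov]
                if float(np.abs(g).max(initial=0.0)) < 1e-9:
                    break
                # Barzilai-Borwein spectral step, safeguarded by halving on
                # any objective increase so accepted E never goes up
                if x_prev is not None:
                    dx = coords[mov] - x_prev
                    dg = g - g_prev
                    denom = float(np.sum(dx * dg))
                    if denom > 1e-12:
                        step = float(np.sum(dx * dx)) / denom
                step = float(min(max(step, 1e-7), 1.0))
                x_prev = coords[mov].copy()
                g_prev = g.copy()
                accepted = False
                for _ in range(40):
                    trial = coords.copy()
                    trial[mov] = coords[mov] - step * g
                    e_t, grad_t, terms_t = self.energy(trial, phase)
                    if not math.isfinite(e_t):
                        raise MinimizationError("non-finite objective", {"terms": terms_t})
                    if e_t <= e:
                        accepted = True
                        break
                    step *= 0.5
                if not accepted:
                    break
                coords, e, grad, terms = trial, e_t, grad_t, terms_t
                trace.append(e)
                iterations += 1
            traces[phase] = trace
        anchor_disp = 0.0
        if len(self.anchor_idx):
            anchor_disp = float(
                np.linalg.norm(coords[self.anchor_idx] - self.anchor_targets, axis=1).max()
            )
        diagnostics = {
            "objective_terms": terms,
            "anchor_max_displacement": anchor_disp,
            "iterations": iterations,
            "bond_rms": self.bond_rms(coords),
            "objective_traces": traces,
        }
        return coords, e, diagnostics

    def bond_rms(self, coords: np.ndarray) -> float:
        """RMS deviation of true bond lengths from their ideal values."""
        i = self.bond_i[self.true_bond]
        j = self.bond_j[self.true_bond]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        dev = d - self.bond_d0[self.true_bond]
        return float(np.sqrt(np.mean(dev * dev)))

    def with_coords(self, coords: np.ndarray, round_decimals: int | None = 3) -> PmhcStructure:
        p_chain = []
        k = 0
        for r in self.model.p_chain:
            atoms = []
            for a in r.atoms:
                xyz = coords[k]
                if round_decimals is not None:
                    xyz = np.round(xyz, round_decimals)
                atoms.append(Atom(a.name, a.element, tuple(float(v) for v in xyz)))
                k += 1
            p_chain.append(replace(r, atoms=tuple(atoms)))
        return replace(self.model, p_chain=tuple(p_chain))


def _randomize(coords: np.ndarray, moving: np.ndarray, amplitude: float, rng) -> np.ndarray:
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = coords.copy()
    offsets = rng.uniform(-amplitude, amplitude, size=(int(moving.sum()), 3))
    out[moving] += offsets
    return out


def randomize_loop(
    model: PmhcStructure,
    loop_positions,
    amplitude: float,
    rng,
) -> PmhcStructure:
    """Displace every atom of the loop residues by an independent uniform
    offset in [-amplitude, +amplitude] per coordinate. Anchor residues and
    the MHC chain are untouched. Deterministic given the generator state."""
    if amplitude <= 0:
        if amplitude == 0:
            return model
        raise ValueError("amplitude must be positive")
    loop = set(loop_positions)
    anchors = tuple(r.seq_pos for r in model.p_chain if r.seq_pos not in loop)
    system = _LoopSystem(model, anchors, RestraintWeights())
    coords = _randomize(system.coords0, system.moving, amplitude, rng)
    return system.with_coords(coords, round_decimals=None)


def minimize(
    model: PmhcStructure,
    anchors,
    weights: RestraintWeights = RestraintWeights(),
    ss_terms=(),
    preset: str = "default",
) -> tuple[PmhcStructure, float, dict]:
    """Two-phase restrained minimization of the peptide loop (phase one:
    bonded + anchor terms; phase two: all terms)."""
    system = _LoopSystem(model, tuple(anchors), weights, ss_terms=ss_terms)
    coords, e, diag = system.minimize(system.coords0.copy(), preset=preset)
    return system.with_coords(coords), e, diag


# ---------------------------------------------------------------------------
# Full per-case pipeline

def _is_identical_case(target: ModellingTarget, entry: TemplateEntry) -> bool:
    if target.peptide_seq != entry.peptide_seq:
        return False
    for raw in entry.alleles:
        if raw == target.allele.raw:
            return True
        parsed = AlleleName.parse(raw)
        if target.allele.protein and parsed.protein == target.allele.protein:
            return True
    return False


def model_case(
    target: ModellingTarget,
    db: TemplateDatabase,
    weights: RestraintWeights = RestraintWeights(),
    amplitude: float = DEFAULT_AMPLITUDE,
) -> list[ModelResult]:
    """Run the full pipeline for one target; returns models sorted by
    ascending score with ranks 1..n.

    If the target peptide sequence and allele exactly match the selected
    template, the unrandomized initial model is additionally returned at
    rank 1 with a score one unit below the best generated model.
    """
    entry, pep_aln = select_template(db, target)
    try:
        target_mhc = resolve_mhc_sequence(db, target.allele, target.mhc_seq)
    except SequenceNotFoundError:
        target_mhc = "".join(AA3_TO_1.get(r.name, "X") for r in entry.structure.m_chain)
        logger.warning(
            "no reference MHC sequence for %s; falling back to template %s sequence",
            target.allele.raw,
            entry.source_id,
        )
    template_mhc = "".join(AA3_TO_1.get(r.name, "X") for r in entry.structure.m_chain)
    mhc_rows = align_mhc(target_mhc, template_mhc)
    initial = build_initial_model(entry, pep_aln, mhc_rows, target)
    ss_terms = build_ss_restraints(target.ss_restraints, len(target.peptide_seq))
    system = _LoopSystem(initial, target.anchors, weights, ss_terms=ss_terms)
    base = system.coords0.copy()
    generated = []
    for i in range(target.n_models):
        seed_i = target.seed + i
        rng = np.random.default_rng(seed_i)
        coords = _randomize(base, system.moving, amplitude, rng)
        coords, e, diag = system.minimize(coords, preset=target.preset)
        generated.append((e, seed_i, coords, diag))
    generated.sort(key=lambda t: (t[0], t[1]))
    results = []
    for rank, (e, seed_i, coords, diag) in enumerate(generated, start=1):
        results.append(
            ModelResult(
                structure=system.with_coords(coords),
                score=float(e),
                rank=rank,
                diagnostics=diag,
                seed_used=seed_i,
            )
        )
    if _is_identical_case(target, entry):
        logger.info(
            "target %s/%s is identical to template %s; returning the template "
            "conformation as rank 1",
            target.peptide_seq,
            target.allele.raw,
            entry.source_id,
        )
        shortcut_score = results[0].score - 1.0 if results else 0.0
        shortcut = ModelResult(
            structure=system.with_coords(base),
            score=shortcut_score,
            rank=1,
            diagnostics={"identical_case": True},
            seed_used=None,
        )
        for r in results:
            r.rank += 1
        results.insert(0, shortcut)
    return results


# ---------------------------------------------------------------------------
# MODELLER-ready input emission (alternative backend)

def _wrap(seq: str, width: int = 75) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def emit_modeller_inputs(
    target: ModellingTarget,
    template: TemplateEntry,
    peptide_alignment: PeptideAlignment,
    mhc_alignment: tuple[str, str],
    outdir,
) -> dict[str, str]:
    """Write MODELLER-compatible input files: a PIR alignment (structureX
    entry for the template, sequence entry for the target, chains M/P
    separated by '/'), the template PDB, and a restraint description file.
    Returns the written paths."""
    os.makedirs(outdir, exist_ok=True)
    template_name = template.source_id or "template"
    target_name = "target"
    pdb_path = os.path.join(outdir, f"{template_name}.pdb")
    with open(pdb_path, "w") as fh:
        fh.write(write_structure(template.structure))
    n_pep = len(template.peptide_seq)
    res = f"{template.resolution:.2f}" if template.resolution is not None else ""
    pir_lines = [
        f">P1;{template_name}",
        f"structureX:{template_name}:1:M:{n_pep}:P:::{res}:",
        _wrap(mhc_alignment[1] + "/" + peptide_alignment.template_row + "*"),
        f">P1;{target_name}",
        f"sequence:{target_name}::::::::",
        _wrap(mhc_alignment[0] + "/" + peptide_alignment.target_row + "*"),
    ]
    pir_path = os.path.join(outdir, "alignment.pir")
    with open(pir_path, "w") as fh:
        fh.write("\n".join(pir_lines) + "\n")
    restraint_path = os.path.join(outdir, "restraints.txt")
    with open(restraint_path, "w") as fh:
        fh.write("# anchor positions (1-based peptide residues, kept restrained)\n")
        fh.write("anchors\t" + ",".join(str(a) for a in target.anchors) + "\n")
        for spec in target.ss_restraints:
            fh.write(f"ss\t{spec.kind}\t{spec.start}\t{spec.end}\n")
    return {"pir": pir_path, "template_pdb": pdb_path, "restraints": restraint_path}


def parse_pir(text: str) -> list[dict]:
    """Minimal PIR reader: returns [{id, header, sequence}] where sequence
    keeps gap characters and '/' chain separators, without the closing '*'."""
    entries = []
    current = None
    for line in text.splitlines():
        if line.startswith(">"):
            if current is not None:
                entries.append(current)
            if not line.startswith(">P1;"):
                raise ValueError(f"unsupported PIR header: {line!r}")
            current = {"id": line[4:].strip(), "header": None, "sequence": ""}
        elif current is not None:
            if current["header"] is None:
                current["header"] = line.strip()
            else:
                current["sequence"] += line.strip()
    if current is not None:
        entries.append(current)
    for e in entries:
        if not e["sequence"].endswith("*"):
            raise ValueError(f"PIR entry {e['id']} not terminated by '*'")
        e["sequence"] = e["sequence"][:-1]
    return entries
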