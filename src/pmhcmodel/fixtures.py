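"""Deterministic synthetic pMHC fixtures.

Every pipeline stage (parsing, curation filters, template selection,
modelling, evaluation) is testable offline against structures generated
here. The pseudo-MHC scaffold is *synthetic*: it is not a real MHC fold,
just 180 residues of ideal-geometry secondary structure arranged as two
groove walls, a floor and two anchor pockets, so that chain extraction,
renumbering, G-domain superposition, the groove-ligand test and the
contact-anchor heuristic are all exercised with known ground truth.

Determinism contract: identical spec + seed produce byte-identical PDB text.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry as geom
from .structure_io import AA1_TO_3, Atom, Chain, PmhcStructure, Residue, format_pdb
from .template_db import StructureInput, TemplateDatabase, TemplateEntry
from .modelling import ModellingTarget, SSRestraint, minimize as _relax

DEFECT_FLAGS = {
    "noncanonical_residue",
    "groove_ligand",
    "corrupt_record",
    "missing_allele",
    "short_peptide",
}

#: expected curation outcome per defect flag, in filter precedence order
_DEFECT_REASON = [
    ("missing_allele", "NO_ALLELE"),
    ("corrupt_record", "UNPARSEABLE"),
    ("short_peptide", "BAD_LENGTH"),
    ("groove_ligand", "GROOVE_LIGAND"),
    ("noncanonical_residue", "NONCANONICAL"),
]

_PEPTIDE_ALPHABET = "ADEFHIKLMNPQRSTVWY"  # no Gly (keeps Cβ) and no Cys
_ALLELE_POOL = (
    "HLA-A*02:01",
    "HLA-A*11:01",
    "HLA-B*07:02",
    "HLA-A*02:05",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic pMHC structure."""

    peptide_seq: str | None = None
    allele: str = "HLA-A*02:01"
    anchors: tuple[int, ...] | None = None
    helix_span: tuple[int, int] | None = None
    defects: frozenset = frozenset()
    seed: int = 0
    resolution: float = 1.8
    source_id: str = "FIX0001"


@dataclass
class ToyPmhc:
    """A generated fixture plus its ground truth."""

    pdb_text: str
    structure_input: StructureInput
    reference: PmhcStructure
    peptide_seq: str
    anchors: tuple[int, ...]
    expected_rejection: str | None


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def _backbone_dicts(n: int, conformation, helix_span=None):
    if isinstance(conformation, str):
        pp = []
        for i in range(1, n + 1):
            if helix_span and helix_span[0] <= i <= helix_span[1]:
                pp.append(geom.PHI_PSI["helix"])
            else:
                pp.append(geom.PHI_PSI[conformation])
    else:
        pp = list(conformation)
    return geom.build_backbone(pp)


def _orient_along(bb, axis: np.ndarray, center: np.ndarray):
    """Rigidly place a backbone so its Cα1→Cαn direction follows ``axis``
    and its Cα centroid sits at ``center``."""
    cas = np.array([r["CA"] for r in bb])
    rot = _rotation_between(cas[-1] - cas[0], np.asarray(axis, float))
    centroid = cas.mean(axis=0)
    out = []
    for r in bb:
        out.append({k: rot @ (v - centroid) + center for k, v in r.items()})
    return out


def _to_residues(bb, seq: str, start_pos: int = 1, with_cb: bool = True):
    residues = []
    for i, (r, aa) in enumerate(zip(bb, seq)):
        atoms = [
            Atom("N", "N", _r3(r["N"])),
            Atom("CA", "C", _r3(r["CA"])),
            Atom("C", "C", _r3(r["C"])),
            Atom("O", "O", _r3(r["O"])),
        ]
        if with_cb and aa != "G":
            atoms.append(Atom("CB", "C", _r3(geom.ideal_cb(r["N"], r["CA"], r["C"]))))
        residues.append(Residue(name=AA1_TO_3[aa], seq_pos=start_pos + i, atoms=tuple(atoms)))
    return residues


def _r3(xyz) -> tuple[float, float, float]:
    return tuple(float(round(v, 3)) for v in np.asarray(xyz, float))


def make_ideal_peptide(seq: str, conformation="extended", helix_span=None) -> list[Residue]:
    """Peptide chain with ideal bond geometry in an extended or helical
    conformation (optionally helical only within ``helix_span``), oriented
    along +x and centred at the origin. Glycine gets no Cβ."""
    if not 1 <= len(seq) <= 20:
        raise ValueError("peptide fixtures support 1-20 residues")
    bad = set(seq) - set(AA1_TO_3)
    if bad:
        raise ValueError(f"invalid residue letters {sorted(bad)}")
    bb = _backbone_dicts(len(seq), conformation, helix_span)
    if len(seq) > 1:
        bb = _orient_along(bb, np.array([1.0, 0.0, 0.0]), np.zeros(3))
    return _to_residues(bb, seq)


def mhc_sequence_for_allele(allele: str, length: int = 180) -> str:
    """Deterministic pseudo-MHC sequence per allele name: structures and
    reference tables that cite the same allele always agree."""
    rng = np.random.default_rng(zlib.crc32(allele.encode()))
    return "".join(rng.choice(list(_PEPTIDE_ALPHABET), size=length))


def reference_fasta(alleles) -> str:
    """Reference MHC sequence table (FASTA keyed by allele) matching the
    fixture scaffolds."""
    records = []
    for a in dict.fromkeys(alleles):
        records.append(f">{a}\n{mhc_sequence_for_allele(a)}")
    return "\n".join(records) + "\n"


def _mhc_scaffold(allele: str, peptide: list[Residue], anchors: tuple[int, ...]):
    """180-residue pseudo-MHC: two wall helices flanking the peptide, a
    floor helix below, and one 5-residue pocket segment parked beneath each
    anchor's side chain so only anchor residues make side-chain contacts."""
    seq = mhc_sequence_for_allele(allele)
    segments = []
    x_axis = np.array([1.0, 0.0, 0.0])
    y_axis = np.array([0.0, 1.0, 0.0])
    wall_a = _orient_along(_backbone_dicts(60, "helix"), x_axis, np.array([0.0, -9.0, 2.0]))
    wall_b = _orient_along(_backbone_dicts(60, "helix"), x_axis, np.array([0.0, 9.0, 2.0]))
    floor = _orient_along(_backbone_dicts(50, "helix"), x_axis, np.array([0.0, 0.0, -9.5]))
    segments += [(wall_a, seq[0:60]), (wall_b, seq[60:120]), (floor, seq[120:170])]
    pocket_anchors = (min(anchors), max(anchors))
    for k, a in enumerate(pocket_anchors):
        res = peptide[a - 1]
        ca = res.coord("CA")
        cb = res.coord("CB")
        if cb is None:
            cb = ca + np.array([0.0, 0.0, -1.5])
        # pocket runs outward along the side-chain direction (projected off
        # the peptide axis) so only this anchor makes a side-chain contact
        w = cb - ca
        w[0] = 0.0
        if np.linalg.norm(w) < 1e-6:
            w = np.array([0.0, 0.0, -1.0])
        w /= np.linalg.norm(w)
        center = cb + w * (3.2 + 7.6)
        pocket = _orient_along(_backbone_dicts(5, "extended"), w, center)
        segments.append((pocket, seq[170 + 5 * k : 175 + 5 * k]))
    residues = []
    pos = 1
    for bb, sub_seq in segments:
        residues.extend(_to_residues(bb, sub_seq, start_pos=pos))
        pos += len(bb)
    return residues


def _corrupt_coordinate(pdb_text: str) -> str:
    lines = pdb_text.splitlines()
    atom_lines = [i for i, l in enumerate(lines) if l.startswith("ATOM")]
    i = atom_lines[2]
    lines[i] = lines[i][:30] + " 12.3x4 " + lines[i][38:]
    return "\n".join(lines) + "\n"


def make_toy_pmhc(spec: FixtureSpec) -> ToyPmhc:
    """Generate one synthetic pMHC PDB fixture with ground-truth metadata.

    The emitted text uses author chain ids "A" (receptor) and "C" (peptide,
    numbered from 1001) so that extraction, relabelling and renumbering are
    genuinely exercised. Defect flags inject exactly the failure each
    curation filter looks for.
    """
    unknown = set(spec.defects) - DEFECT_FLAGS
    if unknown:
        raise ValueError(f"unknown defect flags {sorted(unknown)}")
    seq = spec.peptide_seq
    if "short_peptide" in spec.defects:
        if seq is not None and len(seq) >= 7:
            raise ValueError("short_peptide defect contradicts a peptide of length >= 7")
        seq = seq or "ALYGFV"
    if seq is None:
        rng = np.random.default_rng(spec.seed)
        seq = "".join(rng.choice(list(_PEPTIDE_ALPHABET), size=9))
    n = len(seq)
    anchors = tuple(sorted(spec.anchors)) if spec.anchors else (2, n)
    if spec.helix_span and not (1 <= spec.helix_span[0] < spec.helix_span[1] <= n):
        raise ValueError(f"helix span {spec.helix_span} invalid for {n}-mer")

    peptide = make_ideal_peptide(seq, "extended", helix_span=spec.helix_span)
    mhc = _mhc_scaffold(spec.allele, peptide, anchors)

    # author-numbered chains as found "in the wild"
    author_chains: list[tuple[str, list[Residue]]] = [
        ("A", mhc),
        ("C", [replace(r, seq_pos=1000 + r.seq_pos) for r in peptide]),
    ]
    p_author = author_chains[1][1]
    if "noncanonical_residue" in spec.defects:
        i = min(4, n - 1)
        p_author[i] = replace(p_author[i], name="ABA", het=True)
        author_chains[1] = ("C", p_author)
    if "groove_ligand" in spec.defects:
        xc = float(np.mean([r.coord("CA")[0] for r in peptide]))
        lig = Residue(
            name="LIG",
            seq_pos=1,
            atoms=tuple(
                Atom(f"C{j + 1}", "C", _r3((xc + dx, 2.0, 0.8)))
                for j, dx in enumerate((-2.0, 0.0, 2.0))
            ),
            het=True,
        )
        author_chains.append(("L", [lig]))

    pdb_text = format_pdb(author_chains)
    if "corrupt_record" in spec.defects:
        pdb_text = _corrupt_coordinate(pdb_text)

    alleles = () if "missing_allele" in spec.defects else (spec.allele,)
    expected = None
    for flag, reason in _DEFECT_REASON:
        if flag in spec.defects:
            expected = reason
            break

    reference = PmhcStructure(
        m_chain=tuple(mhc), p_chain=tuple(peptide), source_id=spec.source_id
    )
    return ToyPmhc(
        pdb_text=pdb_text,
        structure_input=StructureInput(
            pdb_text=pdb_text,
            source_id=spec.source_id,
            alleles=alleles,
            resolution=spec.resolution,
            anchors=anchors if spec.anchors else None,
        ),
        reference=reference,
        peptide_seq=seq,
        anchors=anchors,
        expected_rejection=expected,
    )


def make_defect_set(seed: int = 0) -> list[ToyPmhc]:
    """The canonical 12-structure curation fixture set: 8 clean structures
    plus one structure per injected defect (non-canonical residue, groove
    ligand, corrupt record, missing allele)."""
    out = []
    for i in range(8):
        out.append(
            make_toy_pmhc(
                FixtureSpec(
                    allele=_ALLELE_POOL[i % len(_ALLELE_POOL)],
                    seed=seed * 100 + i,
                    source_id=f"FIX{i + 1:04d}",
                )
            )
        )
    for j, defect in enumerate(
        ("noncanonical_residue", "groove_ligand", "corrupt_record", "missing_allele")
    ):
        out.append(
            make_toy_pmhc(
                FixtureSpec(
                    allele=_ALLELE_POOL[j % len(_ALLELE_POOL)],
                    seed=seed * 100 + 8 + j,
                    defects=frozenset({defect}),
                    source_id=f"FIX{9 + j:04d}",
                )
            )
        )
    return out


@dataclass
class CohortCase:
    """One cross-docking-style benchmark case: a reference structure, a
    perturbed template derived from it, and the modelling target."""

    case_id: str
    target: ModellingTarget
    reference: PmhcStructure
    entry: TemplateEntry

    def database(self) -> TemplateDatabase:
        allele = self.target.allele.raw
        return TemplateDatabase(
            entries=[self.entry],
            ref_sequences={allele: mhc_sequence_for_allele(allele)},
            build_metadata={"source": "fixtures.make_benchmark_cohort"},
        )


def _mutate_peptide(structure: PmhcStructure, n_mutations: int, anchors, rng) -> PmhcStructure:
    loop = [r.seq_pos for r in structure.p_chain if r.seq_pos not in anchors]
    k = min(n_mutations, len(loop))
    chosen = set(rng.choice(loop, size=k, replace=False).tolist()) if k else set()
    p_chain = []
    for r in structure.p_chain:
        if r.seq_pos in chosen:
            options = [AA1_TO_3[a] for a in _PEPTIDE_ALPHABET if AA1_TO_3[a] != r.name]
            p_chain.append(replace(r, name=options[int(rng.integers(len(options)))]))
        else:
            p_chain.append(r)
    return replace(structure, p_chain=tuple(p_chain))


def _jitter(structure: PmhcStructure, sigma: float, rng) -> PmhcStructure:
    def chain(residues):
        out = []
        for r in residues:
            atoms = tuple(
                Atom(a.name, a.element, _r3(np.asarray(a.xyz) + rng.normal(0.0, sigma, 3)))
                for a in r.atoms
            )
            out.append(replace(r, atoms=atoms))
        return tuple(out)

    if sigma == 0:
        return structure
    jittered = replace(
        structure, m_chain=chain(structure.m_chain), p_chain=chain(structure.p_chain)
    )
    # Atom-wise jitter models a conformational difference between crystals,
    # which keeps near-ideal covalent geometry in reality; relax the peptide
    # bonded terms (all residues free) so the template stays plausible.
    relaxed, _, _ = _relax(jittered, anchors=())
    return relaxed


def make_benchmark_cohort(
    n_cases: int,
    seed: int,
    peptide_length: int = 9,
    anchor_mode: str = "canonical",
    n_mutations: int = 2,
    noise: float = 0.25,
    n_models: int = 20,
    preset: str = "default",
    helix_span: tuple[int, int] | None = None,
    ss_restraints: bool = False,
) -> list[CohortCase]:
    """Seeded cross-docking benchmark: each case pairs a reference fixture
    with a template that is a perturbation of it (``n_mutations`` peptide
    point mutations outside the anchors plus ``noise``-Å Gaussian coordinate
    jitter). ``noise=0, n_mutations=0`` gives self-docking cases.

    ``anchor_mode``: "canonical" uses {2, Ω}; "noncanonical" uses {1, Ω}.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cases = []
    for i in range(n_cases):
        rng = np.random.default_rng([seed, i])
        allele = _ALLELE_POOL[i % len(_ALLELE_POOL)]
        seq = "".join(rng.choice(list(_PEPTIDE_ALPHABET), size=peptide_length))
        if anchor_mode == "canonical":
            anchors = (2, peptide_length)
        elif anchor_mode == "noncanonical":
            anchors = (1, peptide_length)
        else:
            raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
        fixture = make_toy_pmhc(
            FixtureSpec(
                peptide_seq=seq,
                allele=allele,
                anchors=anchors,
                helix_span=helix_span,
                seed=int(rng.integers(2**31)),
                source_id=f"REF{i:04d}",
            )
        )
        template_structure = _mutate_peptide(fixture.reference, n_mutations, anchors, rng)
        template_structure = _jitter(template_structure, noise, rng)
        template_structure = replace(template_structure, source_id=f"TMPL{i:04d}")
        entry = TemplateEntry(
            structure=template_structure,
            peptide_seq=template_structure.peptide_seq,
            alleles=(allele,),
            anchors=anchors,
            resolution=round(float(rng.uniform(1.5, 2.5)), 2),
            source_id=f"TMPL{i:04d}",
        )
        target = ModellingTarget(
            peptide_seq=seq,
            allele=allele,
            anchors=anchors,
            n_models=n_models,
            seed=seed * 1000 + i,
            preset=preset,
            ss_restraints=(
                (SSRestraint("helix", helix_span[0], helix_span[1]),)
                if (ss_restraints and helix_span)
                else ()
            ),
        )
        cases.append(
            CohortCase(
                case_id=f"case{i:04d}",
                target=target,
                reference=fixture.reference,
                entry=entry,
            )
        )
    return cases
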