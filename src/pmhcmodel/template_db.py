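"""Template database: curation filters, allele names, persistence and
reference-sequence resolution.

A template is one cleaned pMHC-I structure. Candidate structures are rejected
when they contain a non-tolerated non-canonical residue, a non-amino-acid
molecule inside the binding groove, cannot be parsed, carry no allele
annotation, or have a peptide outside the configured length bounds. Every
input ends up counted exactly once: accepted, or under a single rejection
reason code.

Allele names follow the G-domain naming convention, e.g. ``HLA-A*02:01``:
``HLA-A`` is the gene, ``HLA-A*02`` the allele group and ``HLA-A*02:01`` the
protein. Names without ``*`` or ``:`` degrade gracefully to the levels they
can express.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass, field
from enum import Enum

import numpy as np
from Bio import SeqIO

from . import structure_io as sio
from .structure_io import (
    AA3_TO_1,
    Atom,
    PmhcStructure,
    Residue,
    StructureError,
    NoPeptideError,
    NoReceptorError,
    NoncanonicalResidueError,
)

logger = logging.getLogger(__name__)

DB_FORMAT = "pmhcmodel-template-db"
DB_VERSION = 1


class RejectionReason(str, Enum):
    NONCANONICAL = "NONCANONICAL"
    GROOVE_LIGAND = "GROOVE_LIGAND"
    UNPARSEABLE = "UNPARSEABLE"
    NO_ALLELE = "NO_ALLELE"
    BAD_LENGTH = "BAD_LENGTH"


class TemplateRejection(Exception):
    """A candidate structure failed curation; carries one reason code."""

    def __init__(self, reason: RejectionReason, message: str):
        super().__init__(f"{reason.value}: {message}")
        self.reason = reason


class DatabaseFormatError(Exception):
    """Database archive is unreadable or has an incompatible version."""


class SequenceNotFoundError(KeyError):
    """No MHC sequence could be resolved for an allele."""


@dataclass(frozen=True)
class AlleleName:
    """Hierarchical G-domain allele name: gene > group > protein."""

    raw: str
    gene: str
    group: str | None = None
    protein: str | None = None

    @classmethod
    def parse(cls, raw: str) -> "AlleleName":
        if not raw:
            raise ValueError("empty allele name")
        if "*" not in raw:
            return cls(raw=raw, gene=raw)
        gene, _, rest = raw.partition("*")
        fields = rest.split(":")
        group = f"{gene}*{fields[0]}"
        protein = f"{gene}*{fields[0]}:{fields[1]}" if len(fields) >= 2 else None
        return cls(raw=raw, gene=gene, group=group, protein=protein)


def parse_allele(raw: str) -> AlleleName:
    return AlleleName.parse(raw)


@dataclass(frozen=True)
class FilterSettings:
    """Curation thresholds. The groove-ligand test flags a non-amino-acid
    group when at least one of its atoms lies within ``groove_contact_cutoff``
    of atoms from at least ``groove_min_residues`` distinct peptide
    residues."""

    peptide_min: int = 7
    peptide_max: int = 15
    alpha_min: int = 150
    groove_contact_cutoff: float = 4.0
    groove_min_residues: int = 3
    anchor_contact_cutoff: float = 4.5


@dataclass(frozen=True)
class StructureInput:
    """One candidate structure: raw PDB text plus its annotations."""

    pdb_text: str
    source_id: str
    alleles: tuple[str, ...] = ()
    resolution: float | None = None
    anchors: tuple[int, ...] | None = None


@dataclass(frozen=True)
class TemplateEntry:
    structure: PmhcStructure
    peptide_seq: str
    alleles: tuple[str, ...]
    anchors: tuple[int, ...]
    resolution: float | None = None
    source_id: str = ""

    def __post_init__(self):
        n = len(self.peptide_seq)
        if len(self.peptide_seq) != len(self.structure.p_chain):
            raise ValueError("peptide sequence length does not match P chain")
        if not self.alleles:
            raise ValueError("template entry needs at least one allele")
        if len(self.anchors) < 2 or not all(1 <= a <= n for a in self.anchors):
            raise ValueError(f"invalid anchors {self.anchors} for {n}-mer")


@dataclass
class TemplateDatabase:
    entries: list[TemplateEntry] = field(default_factory=list)
    ref_sequences: dict[str, str] = field(default_factory=dict)
    build_metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def _ligand_groups(raw: sio.RawStructure, alpha_id: str, peptide_id: str, table) -> list[Residue]:
    """Residues that are candidate small-molecule ligands: not canonical
    amino acids, not tolerated substitutions, and not polymer residues of the
    extracted chains."""
    out = []
    for chain in raw.chains:
        for r in chain.residues:
            if r.name in AA3_TO_1 or r.name in table:
                continue
            if chain.chain_id in (alpha_id, peptide_id) and r.atom("CA") is not None:
                continue  # polymer residue; handled by the non-canonical filter
            out.append(r)
    return out


def _in_groove(ligand: Residue, peptide: sio.Chain, settings: FilterSettings) -> bool:
    pep_atoms = []
    pep_res_idx = []
    for i, r in enumerate(peptide.protein_residues()):
        for a in r.atoms:
            pep_atoms.append(a.xyz)
            pep_res_idx.append(i)
    pep_atoms = np.asarray(pep_atoms, float)
    pep_res_idx = np.asarray(pep_res_idx)
    lig = np.asarray([a.xyz for a in ligand.atoms], float)
    d = np.linalg.norm(lig[:, None, :] - pep_atoms[None, :, :], axis=-1)
    close = (d <= settings.groove_contact_cutoff).any(axis=0)
    n_res = len(set(pep_res_idx[close].tolist()))
    return n_res >= settings.groove_min_residues


def apply_filters(
    candidate: StructureInput,
    settings: FilterSettings = FilterSettings(),
    substitution_table: dict | None = None,
) -> TemplateEntry:
    """Run the curation filters on one candidate structure.

    Returns the accepted :class:`TemplateEntry` or raises
    :class:`TemplateRejection` with exactly one reason code. Rejection
    precedence when several defects coexist: NO_ALLELE, UNPARSEABLE,
    BAD_LENGTH, GROOVE_LIGAND, NONCANONICAL.
    """
    table = substitution_table if substitution_table is not None else sio.load_substitution_table()
    if not candidate.alleles:
        raise TemplateRejection(
            RejectionReason.NO_ALLELE, f"{candidate.source_id}: no allele annotation"
        )
    try:
        raw = sio.parse_structure(candidate.pdb_text, source_id=candidate.source_id)
    except (sio.ParseError, sio.UnparseableError) as exc:
        raise TemplateRejection(RejectionReason.UNPARSEABLE, str(exc)) from exc
    try:
        alpha, peptide = sio.extract_alpha_and_peptide(
            raw,
            alpha_min=settings.alpha_min,
            peptide_bounds=(settings.peptide_min, settings.peptide_max),
        )
    except NoPeptideError as exc:
        raise TemplateRejection(RejectionReason.BAD_LENGTH, str(exc)) from exc
    except NoReceptorError as exc:
        raise TemplateRejection(RejectionReason.UNPARSEABLE, str(exc)) from exc

    for ligand in _ligand_groups(raw, alpha.chain_id, peptide.chain_id, table):
        if _in_groove(ligand, peptide, settings):
            raise TemplateRejection(
                RejectionReason.GROOVE_LIGAND,
                f"{candidate.source_id}: {ligand.name} inside the binding groove",
            )

    def normalize(chain: sio.Chain) -> sio.Chain:
        subbed = []
        for r in chain.protein_residues():
            try:
                subbed.append(sio.substitute_noncanonical(r, table))
            except NoncanonicalResidueError as exc:
                raise TemplateRejection(RejectionReason.NONCANONICAL, str(exc)) from exc
        return sio.Chain(chain.chain_id, tuple(subbed))

    alpha = normalize(alpha)
    peptide = normalize(peptide)
    structure, _ = sio.renumber(alpha, peptide, source_id=candidate.source_id)
    n = len(structure.p_chain)
    anchors = candidate.anchors if candidate.anchors else (2, n)
    return TemplateEntry(
        structure=structure,
        peptide_seq=structure.peptide_seq,
        alleles=tuple(candidate.alleles),
        anchors=tuple(sorted(anchors)),
        resolution=candidate.resolution,
        source_id=candidate.source_id,
    )


def contact_anchors(structure: PmhcStructure, cutoff: float = 4.5) -> tuple[int, int]:
    """Contact-based anchor heuristic (synthetic stand-in for anchors derived
    from an experimental structure): the two peptide positions with the most
    side-chain heavy atoms within ``cutoff`` of any MHC atom, the first
    searched among positions {1,2,3}, the second among the last three.
    """
    m_xyz = np.asarray(
        [a.xyz for r in structure.m_chain for a in r.atoms], float
    )
    n = len(structure.p_chain)
    counts = []
    min_dist = []
    for r in structure.p_chain:
        side = [a.xyz for a in r.atoms if a.name not in ("N", "CA", "C", "O") and a.element != "H"]
        if not side:
            counts.append(0)
            min_dist.append(float("inf"))
            continue
        d = np.linalg.norm(np.asarray(side, float)[:, None, :] - m_xyz[None, :, :], axis=-1)
        counts.append(int((d.min(axis=1) <= cutoff).sum()))
        min_dist.append(float(d.min()))
    # ties on the contact count are broken by the closest side-chain contact
    first = max(range(1, min(3, n) + 1), key=lambda p: (counts[p - 1], -min_dist[p - 1], -p))
    last = max(range(max(n - 2, 1), n + 1), key=lambda p: (counts[p - 1], -min_dist[p - 1], p))
    return first, last


def build_database(
    inputs: list[StructureInput],
    ref_fasta: str | None = None,
    settings: FilterSettings = FilterSettings(),
) -> TemplateDatabase:
    """Build the cleaned template database from candidate structures.

    ``ref_fasta`` is FASTA text whose record ids are allele names. The build
    metadata records the filter settings and a histogram partitioning the
    inputs into accepted + one count per rejection reason.
    """
    if not inputs:
        raise ValueError("no input structures")
    seen_ids = set()
    entries: list[TemplateEntry] = []
    counts: dict[str, int] = {"ACCEPTED": 0}
    table = sio.load_substitution_table()
    for inp in inputs:
        if inp.source_id in seen_ids:
            raise ValueError(f"duplicate source_id {inp.source_id!r}")
        seen_ids.add(inp.source_id)
        try:
            entry = apply_filters(inp, settings, substitution_table=table)
        except TemplateRejection as rej:
            logger.info("rejected %s: %s", inp.source_id, rej)
            counts[rej.reason.value] = counts.get(rej.reason.value, 0) + 1
            continue
        counts["ACCEPTED"] += 1
        entries.append(entry)
    if not entries:
        raise ValueError("empty database: no input structure passed the filters")
    ref_sequences: dict[str, str] = {}
    if ref_fasta:
        for rec in SeqIO.parse(io.StringIO(ref_fasta), "fasta"):
            ref_sequences[rec.id] = str(rec.seq)
    return TemplateDatabase(
        entries=entries,
        ref_sequences=ref_sequences,
        build_metadata={
            "format": DB_FORMAT,
            "version": DB_VERSION,
            "settings": asdict(settings),
            "counts": counts,
        },
    )


# ---------------------------------------------------------------------------
# Persistence: a single-file JSON archive with a version header.

def _residue_to_json(r: Residue) -> dict:
    return {
        "name": r.name,
        "seq_pos": r.seq_pos,
        "atoms": [[a.name, a.element, list(a.xyz)] for a in r.atoms],
    }


def _residue_from_json(d: dict) -> Residue:
    return Residue(
        name=d["name"],
        seq_pos=d["seq_pos"],
        atoms=tuple(Atom(n, e, (x, y, z)) for n, e, (x, y, z) in d["atoms"]),
    )


def _entry_to_json(e: TemplateEntry) -> dict:
    return {
        "source_id": e.source_id,
        "peptide_seq": e.peptide_seq,
        "alleles": list(e.alleles),
        "anchors": list(e.anchors),
        "resolution": e.resolution,
        "m_chain": [_residue_to_json(r) for r in e.structure.m_chain],
        "p_chain": [_residue_to_json(r) for r in e.structure.p_chain],
    }


def _entry_from_json(d: dict) -> TemplateEntry:
    structure = PmhcStructure(
        m_chain=tuple(_residue_from_json(r) for r in d["m_chain"]),
        p_chain=tuple(_residue_from_json(r) for r in d["p_chain"]),
        source_id=d["source_id"],
    )
    return TemplateEntry(
        structure=structure,
        peptide_seq=d["peptide_seq"],
        alleles=tuple(d["alleles"]),
        anchors=tuple(d["anchors"]),
        resolution=d["resolution"],
        source_id=d["source_id"],
    )


def save_database(db: TemplateDatabase, path) -> None:
    doc = {
        "format": DB_FORMAT,
        "version": DB_VERSION,
        "metadata": db.build_metadata,
        "ref_sequences": db.ref_sequences,
        "entries": [_entry_to_json(e) for e in db.entries],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_database(path) -> TemplateDatabase:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise DatabaseFormatError(f"not a readable database archive: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != DB_FORMAT:
        raise DatabaseFormatError("missing or wrong format header")
    if doc.get("version") != DB_VERSION:
        raise DatabaseFormatError(
            f"incompatible database version {doc.get('version')!r}, expected {DB_VERSION}"
        )
    return TemplateDatabase(
        entries=[_entry_from_json(e) for e in doc["entries"]],
        ref_sequences=dict(doc["ref_sequences"]),
        build_metadata=dict(doc["metadata"]),
    )


def resolve_mhc_sequence(
    db: TemplateDatabase,
    allele: AlleleName | str,
    user_seq: str | None = None,
) -> str:
    """Resolve the target MHC protein sequence.

    Priority: a user-provided sequence verbatim; the reference sequence for
    the exact allele; failing that, a reference sequence from the same allele
    group (logged as a warning). Raises :class:`SequenceNotFoundError` naming
    the nearest available alleles otherwise.
    """
    if user_seq:
        return user_seq
    if isinstance(allele, str):
        allele = AlleleName.parse(allele)
    if allele.raw in db.ref_sequences:
        return db.ref_sequences[allele.raw]
    if allele.protein and allele.protein in db.ref_sequences:
        return db.ref_sequences[allele.protein]
    if allele.group:
        group_members = sorted(
            name
            for name in db.ref_sequences
            if AlleleName.parse(name).group == allele.group
        )
        if group_members:
            logger.warning(
                "no reference sequence for %s; using group representative %s",
                allele.raw,
                group_members[0],
            )
            return db.ref_sequences[group_members[0]]
    nearest = sorted(
        name
        for name in db.ref_sequences
        if AlleleName.parse(name).gene == allele.gene
    )
    raise SequenceNotFoundError(
        f"no MHC sequence resolvable for {allele.raw}; nearest available: {nearest or 'none'}"
    )
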