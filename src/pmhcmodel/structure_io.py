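"""Reading, normalizing and writing pMHC structures in PDB format.

The template-curation pipeline works on plain PDB text: parse it with the
strict Biopython parser, pull out one MHC α chain and its bound peptide,
substitute tolerated non-canonical residues, renumber both chains from 1 and
relabel them "M" (MHC) and "P" (peptide). β2-microglobulin and any other
chains are discarded.

Coordinates are kept at the 3-decimal precision of the PDB coordinate field,
so ``parse(write(s))`` reproduces ``s`` exactly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "RawStructure",
    "PmhcStructure",
    "StructureError",
    "ParseError",
    "UnparseableError",
    "NoPeptideError",
    "NoReceptorError",
    "NoncanonicalResidueError",
    "WriteError",
    "parse_structure",
    "extract_alpha_and_peptide",
    "substitute_noncanonical",
    "load_substitution_table",
    "renumber",
    "write_structure",
    "AA3_TO_1",
    "AA1_TO_3",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

_WATER = {"HOH", "WAT", "DOD"}


class StructureError(Exception):
    """Base class for structure handling failures; carries a reason code."""

    reason = "ERROR"


class ParseError(StructureError):
    """PDB text could not be parsed; message names the offending line."""

    reason = "UNPARSEABLE"


class UnparseableError(StructureError):
    reason = "UNPARSEABLE"


class NoPeptideError(StructureError):
    reason = "BAD_LENGTH"


class NoReceptorError(StructureError):
    reason = "UNPARSEABLE"


class NoncanonicalResidueError(StructureError):
    reason = "NONCANONICAL"


class WriteError(StructureError):
    reason = "WRITE_ERROR"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    name: str
    seq_pos: int
    atoms: tuple[Atom, ...]
    icode: str = ""
    het: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else np.asarray(a.xyz, float)

    @property
    def is_amino_acid(self) -> bool:
        return self.name in AA3_TO_1


@dataclass(frozen=True)
class Chain:
    chain_id: str
    residues: tuple[Residue, ...]

    def protein_residues(self) -> tuple[Residue, ...]:
        return tuple(r for r in self.residues if r.atom("CA") is not None)


@dataclass(frozen=True)
class RawStructure:
    chains: tuple[Chain, ...]
    source_id: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


@dataclass(frozen=True)
class PmhcStructure:
    """A cleaned pMHC-I complex: MHC G-domain chain "M" and peptide chain
    "P", each renumbered 1..n."""

    m_chain: tuple[Residue, ...]
    p_chain: tuple[Residue, ...]
    source_id: str = ""

    @property
    def peptide_seq(self) -> str:
        return "".join(AA3_TO_1.get(r.name, "X") for r in self.p_chain)

    def chain(self, chain_id: str) -> tuple[Residue, ...]:
        if chain_id == "M":
            return self.m_chain
        if chain_id == "P":
            return self.p_chain
        raise KeyError(chain_id)


def _pick_altloc(bio_atom):
    """Highest-occupancy altloc; ties broken toward altloc 'A'."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = bio_atom.disordered_get_list()
    return min(children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))


def parse_structure(pdb_text: str, source_id: str = "") -> RawStructure:
    """Parse PDB-format text into an ordered multi-chain structure.

    Only the first MODEL is read; ANISOU records are ignored. Insertion-coded
    residues keep their author order. For disordered atoms the
    highest-occupancy altloc is kept (tie -> 'A'). Waters are dropped.

    Raises :class:`ParseError` on malformed records (message carries the line
    number) and :class:`UnparseableError` if no protein chain is present.
    """
    if not pdb_text or not pdb_text.strip():
        raise ParseError("empty PDB text")
    parser = PDBParser(PERMISSIVE=0, QUIET=1)
    try:
        bio = parser.get_structure(source_id or "structure", io.StringIO(pdb_text))
    except PDBConstructionException as exc:
        raise ParseError(f"PDB parse failure: {exc}") from exc
    except (ValueError, IndexError, KeyError) as exc:
        # truncated or malformed records can escape the strict parser as
        # bare builtin exceptions
        raise ParseError(f"PDB parse failure: {exc!r}") from exc
    try:
        model = next(iter(bio))
    except StopIteration:  # pragma: no cover - empty but parseable text
        raise UnparseableError("no coordinate model in PDB text")
    chains = []
    for bio_chain in model:
        residues = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            name = bio_res.get_resname().strip()
            if name in _WATER:
                continue
            atoms = []
            seen = set()
            for bio_atom in bio_res:
                a = _pick_altloc(bio_atom)
                aname = a.get_name()
                if aname in seen:
                    continue
                seen.add(aname)
                x, y, z = (round(float(v), 3) for v in a.coord)
                atoms.append(Atom(aname, (a.element or "").strip(), (x, y, z)))
            residues.append(
                Residue(
                    name=name,
                    seq_pos=int(resseq),
                    atoms=tuple(atoms),
                    icode=icode.strip(),
                    het=(hetflag.strip() != ""),
                )
            )
        if residues:
            chains.append(Chain(str(bio_chain.id), tuple(residues)))
    raw = RawStructure(tuple(chains), source_id=source_id)
    if not any(c.protein_residues() for c in raw.chains):
        raise UnparseableError("no protein chains found")
    return raw


def extract_alpha_and_peptide(
    raw: RawStructure,
    alpha_min: int = 150,
    peptide_bounds: tuple[int, int] = (7, 15),
    gdomain_len: int = 180,
) -> tuple[Chain, Chain]:
    """Pick exactly one MHC α chain and its bound peptide.

    The α chain is the protein chain with the most resolved residues among
    those of length >= ``alpha_min`` (tie -> lowest chain id). The peptide is
    the chain of peptide length with the smallest mean Cα distance to the α
    chain's first ``gdomain_len`` residues.
    """
    lo, hi = peptide_bounds
    alphas = [c for c in raw.chains if len(c.protein_residues()) >= alpha_min]
    if not alphas:
        raise NoReceptorError(
            f"no chain with >= {alpha_min} residues (candidate receptor) in {raw.source_id!r}"
        )
    peptides = [c for c in raw.chains if lo <= len(c.protein_residues()) <= hi]
    if not peptides:
        raise NoPeptideError(
            f"no chain of peptide length {lo}-{hi} in {raw.source_id!r}"
        )
    alpha = min(alphas, key=lambda c: (-len(c.protein_residues()), c.chain_id))
    g_cas = np.array(
        [
            r.coord("CA")
            for r in alpha.protein_residues()[:gdomain_len]
            if r.coord("CA") is not None
        ]
    )

    def mean_ca_dist(pep: Chain) -> float:
        cas = np.array([r.coord("CA") for r in pep.protein_residues()])
        d = np.linalg.norm(cas[:, None, :] - g_cas[None, :, :], axis=-1)
        return float(d.min(axis=1).mean())

    peptide = min(peptides, key=lambda c: (mean_ca_dist(c), c.chain_id))
    return alpha, peptide


def load_substitution_table() -> dict[str, tuple[str, frozenset[str]]]:
    """Tolerated non-canonical residue substitutions shipped with the
    package: 3-letter code -> (canonical code, atom names to delete)."""
    table: dict[str, tuple[str, frozenset[str]]] = {}
    text = resources.files("pmhcmodel.data").joinpath("noncanonical.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, canonical, atoms = (line.split("\t") + [""])[:3]
        delete = frozenset(a for a in atoms.split(",") if a)
        table[code] = (canonical, delete)
    return table


def substitute_noncanonical(
    residue: Residue,
    table: dict[str, tuple[str, frozenset[str]]] | None = None,
) -> Residue:
    """Map a tolerated non-canonical residue onto its canonical parent by
    deleting the extra atoms (e.g. phosphoserine -> serine, dropping the
    phosphate). Canonical residues pass through unchanged; anything not in
    the tolerance table raises :class:`NoncanonicalResidueError`.
    """
    if residue.name in AA3_TO_1:
        return residue
    if table is None:
        table = load_substitution_table()
    if residue.name not in table:
        raise NoncanonicalResidueError(
            f"non-canonical residue {residue.name} at position {residue.seq_pos} is not tolerated"
        )
    canonical, delete = table[residue.name]
    kept = tuple(a for a in residue.atoms if a.name not in delete)
    return replace(residue, name=canonical, atoms=kept, het=False)


def renumber(
    alpha: Chain, peptide: Chain, source_id: str = ""
) -> tuple[PmhcStructure, dict[str, dict[str, int]]]:
    """Renumber both chains 1..n in author order, relabel them M and P.

    Insertion codes are flattened into the linear order. Returns the cleaned
    structure and the old->new numbering map per chain (old labels keep their
    insertion code, e.g. "100A").
    """
    mapping: dict[str, dict[str, int]] = {"M": {}, "P": {}}

    def do(chain: Chain, new_id: str) -> tuple[Residue, ...]:
        out = []
        for i, r in enumerate(chain.protein_residues(), start=1):
            mapping[new_id][f"{r.seq_pos}{r.icode}"] = i
            out.append(replace(r, seq_pos=i, icode="", het=False))
        return tuple(out)

    structure = PmhcStructure(
        m_chain=do(alpha, "M"), p_chain=do(peptide, "P"), source_id=source_id
    )
    return structure, mapping


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def format_pdb(chains: list[tuple[str, list[Residue] | tuple[Residue, ...]]]) -> str:
    """Render chains as PDB text (ATOM/HETATM, TER, END)."""
    lines = []
    serial = 1
    for chain_id, residues in chains:
        if not residues:
            raise WriteError(f"chain {chain_id!r} is empty")
        for r in residues:
            record = "HETATM" if r.het and r.name not in AA3_TO_1 else "ATOM  "
            for a in r.atoms:
                x, y, z = a.xyz
                if not all(math.isfinite(v) for v in (x, y, z)):
                    raise WriteError(
                        f"non-finite coordinate on atom {a.name} of residue "
                        f"{r.name} {r.seq_pos}"
                    )
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(a.name, a.element)} "
                    f"{r.name:>3s} {chain_id}{r.seq_pos:4d}{r.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                    f"{a.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].name:>3s} {chain_id}{residues[-1].seq_pos:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(structure: PmhcStructure) -> str:
    """Write a cleaned pMHC structure as PDB text, chain M before chain P.

    ``parse_structure(write_structure(s))`` reproduces ``s`` exactly.
    """
    return format_pdb([("M", structure.m_chain), ("P", structure.p_chain)])
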