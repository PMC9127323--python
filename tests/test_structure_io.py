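"""PDB parsing, chain extraction, residue normalization and writing."""

import math
from dataclasses import replace

import pytest

from pmhcmodel import structure_io as sio

MINIMAL = (
    "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
    "ATOM      2  CA  ALA A   1      11.639   7.420  -6.135  1.00  0.00           C\n"
    "END\n"
)


class TestParse:
    def test_minimal_block_preserves_literals(self):
        raw = sio.parse_structure(MINIMAL, "mini")
        assert len(raw.chains) == 1
        (res,) = raw.chains[0].residues
        assert res.name == "ALA" and res.seq_pos == 1
        assert res.atom("N").xyz == (11.104, 6.134, -6.504)
        assert res.atom("CA").xyz == (11.639, 7.420, -6.135)

    def test_fixture_chain_lengths(self, defect_set):
        raw = sio.parse_structure(defect_set[0].pdb_text, "fix")
        lengths = sorted(len(c.residues) for c in raw.chains)
        assert lengths == [9, 180]

    def test_corrupted_coordinate_names_line(self):
        bad = MINIMAL.replace("7.420", "7.4x0")
        with pytest.raises(sio.ParseError, match="line 2"):
            sio.parse_structure(bad)

    def test_empty_text_rejected(self):
        with pytest.raises(sio.ParseError):
            sio.parse_structure("   \n")

    def test_no_protein_chain_rejected(self):
        hetatm_only = (
            "HETATM    1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(sio.UnparseableError):
            sio.parse_structure(hetatm_only)


class TestExtract:
    def test_single_pair(self, defect_set):
        raw = sio.parse_structure(defect_set[0].pdb_text, "fix")
        alpha, pep = sio.extract_alpha_and_peptide(raw)
        assert len(alpha.protein_residues()) == 180
        assert len(pep.protein_residues()) == 9

    def test_short_peptide_only_is_no_peptide(self, defect_set):
        raw = sio.parse_structure(defect_set[0].pdb_text, "fix")
        pep6 = sio.Chain("C", raw.chain("C").residues[:6])
        trimmed = sio.RawStructure((raw.chain("A"), pep6), "fix")
        with pytest.raises(sio.NoPeptideError):
            sio.extract_alpha_and_peptide(trimmed)

    def test_no_receptor_chain(self, defect_set):
        raw = sio.parse_structure(defect_set[0].pdb_text, "fix")
        with pytest.raises(sio.NoReceptorError):
            sio.extract_alpha_and_peptide(sio.RawStructure((raw.chain("C"),), "fix"))

    def test_multiple_copies_picks_fullest_alpha_and_bound_peptide(self, defect_set):
        raw = sio.parse_structure(defect_set[0].pdb_text, "fix")
        alpha = raw.chain("A")
        pep = raw.chain("C")
        truncated = sio.Chain("B", alpha.residues[:-3])
        far_pep = sio.Chain(
            "D",
            tuple(
                replace(
                    r,
                    atoms=tuple(
                        sio.Atom(a.name, a.element, (a.xyz[0], a.xyz[1] + 50.0, a.xyz[2]))
                        for a in r.atoms
                    ),
                )
                for r in pep.residues
            ),
        )
        asym = sio.RawStructure((truncated, alpha, far_pep, pep), "fix")
        got_alpha, got_pep = sio.extract_alpha_and_peptide(asym)
        assert got_alpha.chain_id == "A"  # most resolved copy wins
        assert got_pep.chain_id == "C"  # peptide nearest the chosen groove


class TestSubstitution:
    def test_phosphoserine_to_serine(self):
        sep = sio.Residue(
            name="SEP",
            seq_pos=3,
            het=True,
            atoms=(
                sio.Atom("N", "N", (0.0, 0.0, 0.0)),
                sio.Atom("CA", "C", (1.4, 0.0, 0.0)),
                sio.Atom("C", "C", (2.0, 1.3, 0.0)),
                sio.Atom("O", "O", (3.2, 1.4, 0.0)),
                sio.Atom("CB", "C", (2.0, -1.2, 0.8)),
                sio.Atom("OG", "O", (1.5, -2.4, 1.5)),
                sio.Atom("P", "P", (2.3, -3.7, 1.8)),
                sio.Atom("O1P", "O", (3.6, -3.5, 2.4)),
                sio.Atom("O2P", "O", (1.5, -4.6, 2.7)),
                sio.Atom("O3P", "O", (2.5, -4.3, 0.4)),
            ),
        )
        ser = sio.substitute_noncanonical(sep)
        assert ser.name == "SER" and not ser.het
        assert {a.name for a in ser.atoms} == {"N", "CA", "C", "O", "CB", "OG"}
        # retained atoms keep their exact coordinates
        for a in ser.atoms:
            assert a.xyz == sep.atom(a.name).xyz

    def test_canonical_passthrough(self):
        ala = sio.Residue("ALA", 1, (sio.Atom("CA", "C", (0.0, 0.0, 0.0)),))
        assert sio.substitute_noncanonical(ala) is ala

    def test_unlisted_code_rejected(self):
        bad = sio.Residue("XYZ", 1, (sio.Atom("CA", "C", (0.0, 0.0, 0.0)),))
        with pytest.raises(sio.NoncanonicalResidueError):
            sio.substitute_noncanonical(bad)


def _toy_chain(chain_id, positions, icodes=None):
    icodes = icodes or [""] * len(positions)
    residues = tuple(
        sio.Residue(
            "ALA",
            p,
            (sio.Atom("CA", "C", (float(i), 0.0, 0.0)),),
            icode=ic,
        )
        for i, (p, ic) in enumerate(zip(positions, icodes))
    )
    return sio.Chain(chain_id, residues)


class TestRenumber:
    def test_author_numbering_shift(self, defect_set):
        raw = sio.parse_structure(defect_set[0].pdb_text, "fix")
        alpha, pep = sio.extract_alpha_and_peptide(raw)
        assert [r.seq_pos for r in pep.residues] == list(range(1001, 1010))
        structure, mapping = sio.renumber(alpha, pep, "fix")
        assert [r.seq_pos for r in structure.p_chain] == list(range(1, 10))
        assert mapping["P"]["1001"] == 1 and mapping["P"]["1009"] == 9

    def test_insertion_codes_flattened_in_author_order(self):
        chain = _toy_chain("A", [99, 100, 100, 101], icodes=["", "", "A", ""])
        big = _toy_chain("M", list(range(1, 181)))
        structure, mapping = sio.renumber(big, chain, "x")
        assert [r.seq_pos for r in structure.p_chain] == [1, 2, 3, 4]
        assert mapping["P"] == {"99": 1, "100": 2, "100A": 3, "101": 4}

    def test_idempotent_on_one_based_chain(self):
        alpha = _toy_chain("M", list(range(1, 181)))
        pep = _toy_chain("P", list(range(1, 10)))
        s1, _ = sio.renumber(alpha, pep, "x")
        s2, _ = sio.renumber(
            sio.Chain("M", s1.m_chain), sio.Chain("P", s1.p_chain), "x"
        )
        assert s1 == s2


class TestWrite:
    def test_round_trip_identity(self, clean_db):
        s = clean_db.entries[0].structure
        text = sio.write_structure(s)
        raw = sio.parse_structure(text, s.source_id)
        alpha, pep = sio.extract_alpha_and_peptide(raw)
        back, _ = sio.renumber(alpha, pep, s.source_id)
        assert back == s
        assert text.index("ATOM") < text.index(" P ")  # chain M first

    def test_rewrite_is_byte_identical(self, clean_db):
        s = clean_db.entries[0].structure
        text = sio.write_structure(s)
        raw = sio.parse_structure(text, s.source_id)
        alpha, pep = sio.extract_alpha_and_peptide(raw)
        back, _ = sio.renumber(alpha, pep, s.source_id)
        assert sio.write_structure(back) == text

    def test_empty_chain_is_write_error(self, clean_db):
        s = replace(clean_db.entries[0].structure, p_chain=())
        with pytest.raises(sio.WriteError):
            sio.write_structure(s)

    def test_nonfinite_coordinate_is_write_error(self, clean_db):
        s = clean_db.entries[0].structure
        bad_res = replace(
            s.p_chain[0],
            atoms=(sio.Atom("CA", "C", (math.nan, 0.0, 0.0)),),
        )
        with pytest.raises(sio.WriteError):
            sio.write_structure(replace(s, p_chain=(bad_res,) + s.p_chain[1:]))
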