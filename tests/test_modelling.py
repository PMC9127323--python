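"""Initial-model grafting, loop randomization, restrained minimization and
the ranked model pipeline."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from pmhcmodel import fixtures, modelling
from pmhcmodel.modelling import (
    ModellingTarget,
    RestraintWeights,
    SSRestraint,
    _LoopSystem,
    align_mhc,
    build_initial_model,
    build_ss_restraints,
    minimize,
    model_case,
    parse_pir,
    randomize_loop,
)
from pmhcmodel.selection import anchor_align
from pmhcmodel.structure_io import AA3_TO_1


def _gotoh_score(a, b, open_=-11, extend=-1):
    """Independent affine-gap global alignment DP (Gotoh) used as oracle."""
    m = substitution_matrices.load("BLOSUM62")
    neg = float("-inf")
    la, lb = len(a), len(b)
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in b (vertical)
    Y = np.full((la + 1, lb + 1), neg)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = open_ + (i - 1) * extend
    for j in range(1, lb + 1):
        Y[0, j] = open_ + (j - 1) * extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = m[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend)
    return max(M[la, lb], X[la, lb], Y[la, lb])


def _score_rows(ra, rb, open_=-11, extend=-1):
    m = substitution_matrices.load("BLOSUM62")
    score = 0.0
    for row in (ra, rb):
        in_gap = False
        for ch in row:
            if ch == "-":
                score += extend if in_gap else open_
                in_gap = True
            else:
                in_gap = False
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            score += m[x, y]
    return score


class TestAlignMhc:
    def test_identical_sequences_self_align(self):
        seq = fixtures.mhc_sequence_for_allele("HLA-A*02:01")
        rows = align_mhc(seq, seq)
        assert rows == (seq, seq)

    def test_single_deletion_single_gap(self):
        a, b = align_mhc("ACDEFGHIKL", "ACDEGHIKL")
        assert a == "ACDEFGHIKL"
        assert b.count("-") == 1 and b.replace("-", "") == "ACDEGHIKL"

    @pytest.mark.parametrize("seed", range(5))
    def test_score_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(letters, size=int(rng.integers(6, 13))))
        b = "".join(rng.choice(letters, size=int(rng.integers(6, 13))))
        ra, rb = align_mhc(a, b)
        assert _score_rows(ra, rb) == pytest.approx(_gotoh_score(a, b))

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            align_mhc("ACDB", "ACD")


def _case(seed=11, **kw):
    return fixtures.make_benchmark_cohort(1, seed=seed, **kw)[0]


def _initial(case):
    db = case.database()
    from pmhcmodel.selection import select_template
    from pmhcmodel.template_db import resolve_mhc_sequence

    entry, aln = select_template(db, case.target)
    tm = "".join(AA3_TO_1[r.name] for r in entry.structure.m_chain)
    rows = align_mhc(resolve_mhc_sequence(db, case.target.allele), tm)
    return entry, aln, rows, build_initial_model(entry, aln, rows, case.target)


class TestInitialModel:
    def test_identical_case_copies_peptide_backbone_exactly(self):
        case = _case(seed=21, n_mutations=0, noise=0.0)
        entry, _, _, model = _initial(case)
        for mres, tres in zip(model.p_chain, entry.structure.p_chain):
            for name in ("N", "CA", "C", "O"):
                assert tuple(mres.atom(name).xyz) == tuple(tres.atom(name).xyz)

    def test_mutation_truncated_to_cbeta(self):
        case = _case(seed=22, n_mutations=2, noise=0.0)
        entry, _, _, model = _initial(case)
        mutated = [
            (mres, tres)
            for mres, tres in zip(model.p_chain, entry.structure.p_chain)
            if mres.name != tres.name
        ]
        assert mutated
        for mres, tres in mutated:
            assert {a.name for a in mres.atoms} <= {"N", "CA", "C", "O", "CB"}
            for name in ("N", "CA", "C", "O"):
                assert tuple(mres.atom(name).xyz) == tuple(tres.atom(name).xyz)

    def test_shorter_target_on_longer_template_keeps_anchor_coordinates(self):
        case = _case(seed=23, noise=0.0, n_mutations=0)
        entry, _, _, _ = _initial(case)
        target = ModellingTarget(
            peptide_seq=case.target.peptide_seq[:4] + case.target.peptide_seq[5:],
            allele=case.target.allele.raw,
            anchors=(2, 8),
            n_models=1,
            seed=0,
        )
        aln = anchor_align(target.peptide_seq, (2, 8), entry.peptide_seq, (2, 9))
        tm = "".join(AA3_TO_1[r.name] for r in entry.structure.m_chain)
        rows = align_mhc(tm, tm)
        model = build_initial_model(entry, aln, rows, target)
        assert len(model.p_chain) == 8
        # anchors carry the template anchor residues' backbone coordinates
        for tgt_pos, tpl_pos in ((2, 2), (8, 9)):
            mres = model.p_chain[tgt_pos - 1]
            tres = entry.structure.p_chain[tpl_pos - 1]
            for name in ("N", "CA", "C", "O"):
                assert tuple(mres.atom(name).xyz) == tuple(tres.atom(name).xyz)

    def test_inconsistent_alignment_rejected(self):
        case = _case(seed=24)
        entry, aln, rows, _ = _initial(case)
        bad_target = ModellingTarget(
            peptide_seq="AAAAAAAAA", allele=case.target.allele.raw, n_models=1
        )
        with pytest.raises(modelling.ModellingError):
            build_initial_model(entry, aln, rows, bad_target)


class TestRandomize:
    def test_zero_amplitude_is_identity(self, small_cohort):
        case = small_cohort[0]
        _, _, _, model = _initial(case)
        loop = [p for p in range(1, 10) if p not in case.target.anchors]
        assert randomize_loop(model, loop, 0.0, np.random.default_rng(1)) == model

    def test_seeded_determinism_and_bounds(self, small_cohort):
        case = small_cohort[0]
        _, _, _, model = _initial(case)
        loop = [p for p in range(1, 10) if p not in case.target.anchors]
        a = randomize_loop(model, loop, 5.0, np.random.default_rng(7))
        b = randomize_loop(model, loop, 5.0, np.random.default_rng(7))
        assert a == b
        for r0, r1 in zip(model.p_chain, a.p_chain):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                d = np.abs(np.subtract(a1.xyz, a0.xyz))
                if r0.seq_pos in case.target.anchors:
                    assert d.max() == 0.0
                else:
                    assert d.max() <= 5.0

    def test_negative_amplitude_rejected(self, small_cohort):
        case = small_cohort[0]
        _, _, _, model = _initial(case)
        with pytest.raises(ValueError):
            randomize_loop(model, [3], -1.0, np.random.default_rng(0))


class TestMinimize:
    def test_ideal_start_stays_put(self):
        case = _case(seed=25, n_mutations=0, noise=0.0)
        _, _, _, model = _initial(case)
        system = _LoopSystem(model, case.target.anchors, RestraintWeights())
        e0, _, _ = system.energy(system.coords0, 2)
        _, e, diag = system.minimize(system.coords0.copy())
        assert e <= e0 + 1e-6
        assert diag["anchor_max_displacement"] == 0.0

    def test_descent_from_perturbed_start(self):
        case = _case(seed=26)
        _, _, _, model = _initial(case)
        system = _LoopSystem(model, case.target.anchors, RestraintWeights())
        rng = np.random.default_rng(1)
        coords = modelling._randomize(system.coords0, system.moving, 5.0, rng)
        e_start, _, _ = system.energy(coords, 2)
        _, e_end, diag = system.minimize(coords)
        assert e_end < e_start
        for trace in diag["objective_traces"].values():
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_gradient_matches_central_differences(self):
        case = _case(seed=27)
        _, _, _, model = _initial(case)
        ss = build_ss_restraints((SSRestraint("helix", 3, 8),), 9)
        system = _LoopSystem(model, case.target.anchors, RestraintWeights(), ss_terms=ss)
        rng = np.random.default_rng(3)
        coords = modelling._randomize(system.coords0, system.moving, 2.0, rng)
        _, grad, _ = system.energy(coords, 2)
        h = 1e-6
        moving_idx = np.nonzero(system.moving)[0]
        for k in rng.choice(moving_idx, size=6, replace=False):
            for axis in range(3):
                for sign, store in ((1, "up"), (-1, "dn")):
                    trial = coords.copy()
                    trial[k, axis] += sign * h
                    e, _, _ = system.energy(trial, 2)
                    if sign == 1:
                        e_up = e
                    else:
                        e_dn = e
                num = (e_up - e_dn) / (2 * h)
                scale = max(abs(num), 1.0)
                assert abs(num - grad[k, axis]) / scale < 1e-4


class TestSSRestraints:
    def test_helix_pair_count(self):
        terms = build_ss_restraints((SSRestraint("helix", 4, 10),), 12)
        assert [(a[0], b[0]) for a, b, _ in terms] == [(4, 8), (5, 9), (6, 10)]
        assert all(d == 3.0 for _, _, d in terms)

    def test_helix_span_too_short(self):
        with pytest.raises(ValueError):
            build_ss_restraints((SSRestraint("helix", 4, 7),), 12)

    def test_strand_pair_hairpin(self):
        terms = build_ss_restraints((SSRestraint("strand_pair", 2, 7),), 9)
        assert [(a[0], b[0]) for a, b, _ in terms] == [(2, 7), (3, 6), (4, 5)]
        assert all(d == 4.8 for _, _, d in terms)

    def test_empty_spec_is_empty(self):
        assert build_ss_restraints((), 9) == []


class TestModelCase:
    def test_ranks_and_scores_sorted(self, small_cohort_results):
        for _case_obj, results in small_cohort_results:
            assert [r.rank for r in results] == list(range(1, len(results) + 1))
            scores = [r.score for r in results]
            assert scores == sorted(scores)

    def test_n_models_one(self):
        case = _case(seed=28, n_models=1)
        results = model_case(case.target, case.database())
        assert len(results) == 1

    def test_identical_case_shortcut(self):
        case = _case(seed=29, n_models=3, n_mutations=0, noise=0.0)
        results = model_case(case.target, case.database())
        assert len(results) == 4
        generated = [r for r in results if r.seed_used is not None]
        assert results[0].seed_used is None and results[0].rank == 1
        assert results[0].score == pytest.approx(min(r.score for r in generated) - 1.0)

    def test_seeded_rerun_bit_identical(self, small_cohort, small_cohort_results):
        case, first = small_cohort[0], small_cohort_results[0][1]
        again = model_case(case.target, case.database())
        for a, b in zip(first, again):
            assert a.score == b.score and a.structure == b.structure


class TestModellerEmission:
    def test_pir_round_trip(self, tmp_path):
        case = _case(seed=30)
        entry, aln, rows, _ = _initial(case)
        paths = modelling.emit_modeller_inputs(case.target, entry, aln, rows, tmp_path)
        text = open(paths["pir"]).read()
        entries = parse_pir(text)
        assert [e["id"] for e in entries] == [entry.source_id, "target"]
        assert entries[0]["sequence"] == rows[1] + "/" + aln.template_row
        assert entries[1]["sequence"] == rows[0] + "/" + aln.target_row
        assert len(entries[0]["sequence"]) == len(entries[1]["sequence"])
        assert entries[0]["header"].startswith("structureX:")
        # template PDB round-trips through the parser
        from pmhcmodel.structure_io import parse_structure

        raw = parse_structure(open(paths["template_pdb"]).read(), "t")
        assert {c.chain_id for c in raw.chains} == {"M", "P"}

    def test_gap_preserved_in_pir(self, tmp_path):
        case = _case(seed=31)
        entry, _, rows, _ = _initial(case)
        aln = anchor_align(case.target.peptide_seq, (2, 9), entry.peptide_seq + "A", (2, 10))
        gapped_entry = entry
        paths = modelling.emit_modeller_inputs(case.target, gapped_entry, aln, rows, tmp_path)
        entries = parse_pir(open(paths["pir"]).read())
        assert "-" in entries[1]["sequence"]
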