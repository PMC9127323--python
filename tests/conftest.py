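import pytest

from pmhcmodel import fixtures, modelling, template_db


@pytest.fixture(scope="session")
def defect_set():
    """The 12-structure curation set: 8 clean + 4 single-defect fixtures."""
    return fixtures.make_defect_set(seed=0)


@pytest.fixture(scope="session")
def clean_db(defect_set):
    """Template database built from the defect set (8 accepted entries)."""
    alleles = [a for f in defect_set for a in f.structure_input.alleles]
    return template_db.build_database(
        [f.structure_input for f in defect_set],
        ref_fasta=fixtures.reference_fasta(alleles),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return fixtures.make_benchmark_cohort(3, seed=11, n_models=4)


@pytest.fixture(scope="session")
def small_cohort_results(small_cohort):
    return [
        (case, modelling.model_case(case.target, case.database()))
        for case in small_cohort
    ]
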