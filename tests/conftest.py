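import pytest

from famhx import (
    Cohort,
    ConditionRecord,
    GeneratorConfig,
    Pedigree,
    ProbandCovariates,
    Relative,
    RelationCode,
    generate,
)

R = RelationCode


def rel(pid, relation, gender="female", vital="alive", age=None, aod=None,
        cod=None, conditions=(), data=True):
    """Terse Relative constructor for hand-built test pedigrees."""
    return Relative(
        person_id=pid,
        relation=relation,
        gender=gender,
        vital_status=vital,
        current_age=age,
        age_at_death=aod,
        cause_of_death=cod,
        conditions=list(conditions),
        data_reported=data,
    )


def small_pedigree(pid="P1", **cov):
    """proband + mother + maternal grandmother + brother (3 generations)."""
    return Pedigree(
        pid,
        rel(f"{pid}-0", R.PROBAND, "female", age=58),
        [
            rel(f"{pid}-1", R.MOTHER, "female", age=84),
            rel(f"{pid}-2", R.MATERNAL_GRANDMOTHER, "female", "deceased", aod=90, cod="heart_attack"),
            rel(f"{pid}-3", R.BROTHER, "male", age=55),
        ],
        ProbandCovariates(age=58, gender="female", **cov),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort, shared across tests."""
    cohort, truth = generate(GeneratorConfig(n_pedigrees=1184, seed=20240901))
    return cohort, truth
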