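import pytest

from epicohort.cohort_table import (
    CohortVariantRecord,
    FamilyHistory,
    InheritanceMode,
    Segregation,
    Sex,
    VariantType,
    Zygosity,
)


def make_record(**overrides) -> CohortVariantRecord:
    """A valid default record; override any field."""
    defaults = dict(
        patient_ids=["P1"],
        sex=Sex.F,
        gene="SCN1A",
        inheritance_mode=frozenset({InheritanceMode.AD}),
        zygosity=Zygosity.HT,
        segregation=Segregation.DE_NOVO,
        family_history=FamilyHistory.NEGATIVE,
        variant_type=VariantType.MISSENSE,
        condel_score=0.7,
        gerp_score=5.0,
        refseq="NM_000000.1",
        hgvs="c.1A>G; p.M1V",
    )
    defaults.update(overrides)
    return CohortVariantRecord(**defaults)


@pytest.fixture(scope="session")
def table1a():
    from epicohort import load_fixture

    return load_fixture("table1A")


@pytest.fixture(scope="session")
def table1b():
    from epicohort import load_fixture

    return load_fixture("table1B")
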