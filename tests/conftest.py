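import dataclasses

import pytest

from cpdiet.dataio import (
    AnalyteClass,
    ConcentrationRecord,
    CongenerGroup,
    Sex,
    SurveyIndividual,
)
from cpdiet.synthetic import default_study_specs, gen_concentrations, gen_survey


@pytest.fixture
def conc_csv(tmp_path):
    """Small hand-written concentration table."""
    path = tmp_path / "conc.csv"
    path.write_text(
        "sample_id,region,carbon,chlorine,conc_ng_g\n"
        "s1,Jilin,10,6,30.5\n"
        "s1,Jilin,14,6,70.0\n"
        "s2,Hebei,14,5,<MDL\n"
        "s2,Hebei,10,5,<MDL\n"
        "s2,Hebei,11,7,12.0\n"
    )
    return path


@pytest.fixture
def survey_csv(tmp_path):
    path = tmp_path / "survey.csv"
    path.write_text(
        "person_id,sex,age,body_weight,day1,day2,day3\n"
        "p1,male,35,70,0,50,10\n"
        "p2,female,8,,30,30,30\n"
        "p3,female,62,55,20,30,40\n"
        "p4,male,5,18,25,,\n"
    )
    return path


def make_record(sample_id="s1", region="R", **conc):
    """Record from C{carbon}Cl{chlorine}=value keyword pairs, e.g. c10cl6=30."""
    concentrations = {}
    for key, value in conc.items():
        carbon, chlorine = key.lower().lstrip("c").split("cl")
        concentrations[CongenerGroup(int(carbon), int(chlorine))] = float(value)
    return ConcentrationRecord(sample_id, region, concentrations)


def make_individual(person_id="p", sex=Sex.MALE, age=30.0, bw=60.0,
                    days=(20.0, 30.0, 40.0)):
    return SurveyIndividual(person_id, sex, age, bw, list(days))


@pytest.fixture(scope="session")
def small_synthetic():
    """Synthetic study at reduced survey scale, shared across tests."""
    region_specs, survey_specs = default_study_specs(survey_scale=0.02)
    records = [r for spec in region_specs for r in gen_concentrations(spec, 7)]
    individuals = gen_survey(survey_specs, 7)
    return records, individuals
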