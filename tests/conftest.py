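from pathlib import Path

import pytest
from hypothesis import settings

from wikischema import parse_schema

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"
DATA = Path(__file__).resolve().parent / "data"

PATIENTS_VISITS_TSV = """\
!site\tClinic
!category\tPatients
Age\tnumber\t0:120\tyears\tage at enrollment
!category\tVisits\tconnection=Has Patient->Patients
Temperature\tnumber\t30:45\t°C\tbody temperature
"""


@pytest.fixture(scope="session")
def covid_schema():
    return parse_schema((EXAMPLES / "covid.tsv").read_text(encoding="utf-8"))


@pytest.fixture(scope="session")
def audiology_schema():
    return parse_schema((EXAMPLES / "audiology.tsv").read_text(encoding="utf-8"))


@pytest.fixture(scope="session")
def patients_visits_schema():
    return parse_schema(PATIENTS_VISITS_TSV)


@pytest.fixture(scope="session")
def export_xsd():
    from lxml import etree

    return etree.XMLSchema(etree.parse(str(DATA / "export-0.10-synthetic.xsd")))
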