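import pytest

from oceandeg.hydrophobicity import RepeatUnit

REPEAT_UNITS = {
    "PE": RepeatUnit(name="polyethylene", structure="*CC*", polymer_class="polyolefin"),
    "PCL": RepeatUnit(name="polycaprolactone", structure="*OCCCCCC(=O)*", polymer_class="polyester"),
    "Nylon6": RepeatUnit(name="Nylon 6", structure="*NCCCCCC(=O)*", polymer_class="polyamide"),
    "PEG": RepeatUnit(name="poly(ethylene glycol)", structure="*OCC*", polymer_class="polyether"),
    "PVA": RepeatUnit(name="poly(vinyl alcohol)", structure="*CC(O)*", polymer_class="polyol"),
    "PLA": RepeatUnit(name="poly(lactic acid)", structure="*OC(C)C(=O)*", polymer_class="polyester"),
}


@pytest.fixture
def pe_unit():
    return REPEAT_UNITS["PE"]


@pytest.fixture
def pcl_unit():
    return REPEAT_UNITS["PCL"]


@pytest.fixture
def nylon6_unit():
    return REPEAT_UNITS["Nylon6"]
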