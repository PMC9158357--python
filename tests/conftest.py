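import pytest

from miascore import Aneurysm, Cohort, Patient, table3_fixture

# Published scores of the 38 aneurysms of the misidentified-patient table,
# keyed by (patient_id, aneurysm_id) in table order. These are the printed
# 5-decimal values; the package never stores them — tests recompute each one
# from (diameter, location, shape) and compare.
TABLE3_PRINTED_SCORES = {
    ("1", "1a"): 0.86563, ("1", "1b"): 0.85282,
    ("2", "2a"): 0.21591, ("2", "2b"): 0.14759,
    ("3", "3a"): 0.73085, ("3", "3b"): -0.22189, ("3", "3c"): 0.59009,
    ("4", "4a"): 0.63078, ("4", "4b"): 0.19456,
    ("5", "5a"): 0.72899, ("5", "5b"): 0.1604,
    ("6", "6a"): 0.42783, ("6", "6b"): -0.23043,
    ("7", "7a"): 0.32025, ("7", "7b"): 0.26047,
    ("8", "8a"): 0.39367, ("8", "8b"): -0.23862,
    ("9", "9a"): 0.44491, ("9", "9b"): 0.14759,
    ("10", "10a"): 0.17321, ("10", "10b"): -0.37099,
    ("11", "11a"): 0.85468, ("11", "11b"): 0.5392,
    ("12", "12a"): 0.21777, ("12", "12b"): -0.25178,
    ("13", "13a"): 0.22018, ("13", "13b"): 0.08982,
    ("14", "14a"): -0.45639, ("14", "14b"): -0.4692,
    ("15", "15a"): 0.42356, ("15", "15b"): 0.75888, ("15", "15c"): 0.27569,
    ("16", "16a"): 0.8272, ("16", "16b"): 0.77169,
    ("17", "17a"): -0.28594, ("17", "17b"): 0.83147,
    ("17", "17c"): -0.4692, ("17", "17d"): 0.81012,
}


@pytest.fixture(scope="session")
def table3():
    return table3_fixture()


@pytest.fixture
def two_patient_cohort():
    """Tiny toy cohort where the score rule identifies every rupture."""
    return Cohort(
        patients=(
            Patient("A", (
                Aneurysm("A1", 9.0, "PcomA", "irregular", True),
                Aneurysm("A2", 3.0, "ICA", "regular", False),
            )),
            Patient("B", (
                Aneurysm("B1", 2.0, "MCA", "regular", False),
                Aneurysm("B2", 6.0, "AcomA", "irregular", True),
                Aneurysm("B3", 2.5, "MCA", "regular", False),
            )),
        ),
        mode="validation",
    )
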