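import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def events_frame(rows):
    """Build an event table from (patient_id, month, kind, code) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "month", "kind", "code"])


def enrollment_frame(rows):
    """Build an enrollment table from (patient_id, enroll_month) tuples."""
    df = pd.DataFrame(rows, columns=["patient_id", "enroll_month"])
    df["disenroll_month"] = pd.NA
    return df


@pytest.fixture
def toy_claims_dir(tmp_path):
    """Three prescriptions, three diagnoses, two enrollment rows on disk."""
    (tmp_path / "prescriptions.tsv").write_text(
        "patient_id\tmonth\tdrug_code\n"
        "p1\t0\tD1\n"
        "p2\t5\tD1\n"
        "p3\t11\tD2\n")
    (tmp_path / "diagnoses.tsv").write_text(
        "patient_id\tmonth\tcondition_code\n"
        "p1\t8\tC1\n"
        "p2\t2\tC1\n"
        "p3\t11\tC1\n")
    (tmp_path / "enrollment.tsv").write_text(
        "patient_id\tenroll_month\tdisenroll_month\n"
        "p1\t0\t12\n"
        "p2\t0\t12\n"
        "p3\t0\t12\n")
    return tmp_path


@pytest.fixture
def toy_reports_dir(tmp_path):
    """Four-report corpus with one duplicate case and one orphan row."""
    (tmp_path / "demo.tsv").write_text(
        "report_id\tcase_id\n"
        "1\tA\n"
        "2\tA\n"   # duplicate of case A, later version
        "3\tB\n"
        "4\tC\n")
    (tmp_path / "drug.tsv").write_text(
        "report_id\tdrugname\n"
        "1\taspirin tabs\n"
        "2\taspirin tabs\n"
        "3\tASPIRIN  TABS\n"    # case/whitespace variant
        "3\tibuprofen\n"
        "4\tibuprofen\n"
        "99\tghost drug\n")     # orphan
    (tmp_path / "reac.tsv").write_text(
        "report_id\tpt\n"
        "1\tnausea\n"
        "2\tnausea\n"
        "2\trash\n"
        "3\tnausea\n"
        "4\trash\n")
    (tmp_path / "drug_dict.tsv").write_text(
        "raw_term\tcode\naspirin tabs\tASA\nibuprofen\tIBU\n")
    (tmp_path / "event_dict.tsv").write_text(
        "raw_term\tcode\nnausea\tNAU\nrash\tRSH\n")
    return tmp_path
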