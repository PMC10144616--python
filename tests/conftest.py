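import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pvaff import load_default_smq, read_tables

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


TOY_CSVS = {
    "drug": """case_id,drug_name,role,start_date
A,alendronic acid,suspect,2020-01-01
A,ascorbic acid,concomitant,
A,alendronic acid,suspect,2020-01-01
B,prednisolone,suspect,2020-01
C,loxoprofen,concomitant,
""",
    "reac": """case_id,event_term,event_date
A,atypical femoral fracture,2020-01-10
A,atypical femoral fracture,2020-01-10
B,nausea,
C,rash,2020-03-01
""",
    "demo": """case_id,report_version,sex,age_code,height_code,weight_code
A,1,female,60s,150s,50s
A,2,female,60s,150s,50s
B,1,male,under 10,,72
C,1,,30s,160s,60s
""",
    "hist": """case_id,disease_term
A,osteoporosis
B,breast cancer
""",
}


@pytest.fixture
def toy_csv_dir(tmp_path):
    """Four tiny CSV tables: 3 cases, one duplicated submission."""
    paths = {}
    for name, text in TOY_CSVS.items():
        p = tmp_path / f"{name}.csv"
        p.write_text(text)
        paths[name] = p
    return paths


@pytest.fixture
def toy_tables(toy_csv_dir):
    return read_tables(toy_csv_dir)


@pytest.fixture(scope="session")
def smq_map():
    return load_default_smq()


@pytest.fixture
def tiny_records():
    """Hand-built analysis records: 10 cases, 2 exposed-with-event."""
    rows = []
    for i in range(10):
        drugs = frozenset({"drug X"}) if i < 4 else frozenset({"drug Y"})
        events = (
            frozenset({"atypical femoral fracture"})
            if i in (0, 1, 5)
            else frozenset({"nausea"})
        )
        rows.append({
            "case_id": f"K{i}", "sex": "female", "age_years": 65.0,
            "height_cm": 155.0, "weight_kg": 55.0, "bmi": 22.9,
            "suspect_drugs": drugs, "events": events,
        })
    return pd.DataFrame(rows)
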