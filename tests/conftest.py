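import pytest

from pdl1time.io_model import (
    Cohort,
    MarkerDensityRecord,
    PatientAnnotation,
    PDL1AssayReadout,
)
from pdl1time.synthetic import SimulationConfig, generate_cohort_with_truth


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Two patients, two cores each, full assay panel — hand-checkable."""
    densities = []
    for pid, base in (("P1", 100.0), ("P2", 300.0)):
        for core, region in (("c1", "invasion_front"), ("c2", "tumor_center")):
            for marker in ("CD3", "CD8", "FOXP3", "CD56", "CD68",
                           "CTLA4", "LAG3", "PD1", "GZMB"):
                densities.append(MarkerDensityRecord(
                    patient_id=pid, core_id=f"{pid}-{core}", region=region,
                    marker=marker, density=base, qc_pass=True,
                ))
    assays = []
    for pid, ic, tc, cps in (("P1", 2.0, 1.0, 3.1), ("P2", 30.0, 40.0, 55.5)):
        for assay in ("SP142", "SP263", "22C3", "28-8"):
            assays.append(PDL1AssayReadout(
                patient_id=pid, assay=assay,
                ic_percent=ic, tc_percent=tc, cps=cps,
            ))
    annotations = [
        PatientAnnotation(
            patient_id="P1", stils_percent=5.0,
            dss_time=24.5, dss_event=True, dfs_time=12.25, dfs_event=True,
            covariates={"pT_stage": "pT2", "pN_stage": "pN0",
                        "lymphovascular_invasion": "L0", "age": 63.5,
                        "gender": "male", "margin_status": "R0",
                        "adjuvant_chemo": "no", "grade": "G3"},
        ),
        PatientAnnotation(
            patient_id="P2", stils_percent=40.0,
            dss_time=80.0, dss_event=False, dfs_time=80.0, dfs_event=False,
            covariates={"pT_stage": "pT3", "pN_stage": "pN1",
                        "lymphovascular_invasion": "L1", "age": 71.0,
                        "gender": "female", "margin_status": "R1",
                        "adjuvant_chemo": "yes", "grade": "G2"},
        ),
    ]
    return Cohort(densities, assays, annotations)


@pytest.fixture(scope="session")
def default_cohort_with_truth():
    """One default 193-patient synthetic cohort shared across tests."""
    return generate_cohort_with_truth(SimulationConfig(seed=11))
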