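import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pedigrs import genoqc, simdata  # noqa: E402


@pytest.fixture(scope="session")
def qc_config():
    """The engineered QC study: 56-SNP panel, 8 call-rate + 4 HWE failures,
    600 children."""
    return simdata.SimConfig(seed=20240601)


@pytest.fixture(scope="session")
def qc_fixture(qc_config):
    panel, _ = simdata.simulate_panel(qc_config)
    genotypes, truth = simdata.simulate_genotypes(panel, qc_config)
    return panel, genotypes, truth


@pytest.fixture(scope="session")
def clean_config():
    """A failure-free panel used wherever QC is not the subject."""
    return simdata.SimConfig(
        n_snps=44, n_qc_fail_callrate=0, n_qc_fail_hwe=0,
        n_individuals=2000, missing_rate=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def scored_cohort(clean_config):
    """Panel, complete dosage, scores and phenotyped cohort shared by the
    association/prediction/interaction tests."""
    from pedigrs import score as score_mod

    cfg = clean_config
    panel, _ = simdata.simulate_panel(cfg)
    genotypes, _ = simdata.simulate_genotypes(panel, cfg)
    dosage = genoqc.impute_missing(genoqc.to_dosage(genotypes, panel))
    cohort, truth = simdata.simulate_phenotypes(dosage, panel, cfg)
    scores = score_mod.compute_pgrs(dosage, panel)
    cohort = cohort.set_index("id")
    scores.index = cohort.index
    return {
        "config": cfg,
        "panel": panel,
        "dosage": dosage,
        "cohort": cohort,
        "scores": scores,
        "truth": truth,
    }


def make_null_cohort(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort with no score effect anywhere, for calibration checks."""
    return pd.DataFrame(
        {
            "id": [f"n{i}" for i in range(n)],
            "bmi_z": rng.normal(0, 1, n),
            "pgrs": rng.normal(1.18, 0.13, n),
            "origin": rng.choice(["Zaragoza", "Santiago", "Cordoba"], n),
            "tanner": rng.choice(["I", "II", "III", "IV", "V"], n),
        }
    )
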