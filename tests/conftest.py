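import numpy as np
import pytest

import tgtree as tt


@pytest.fixture(scope="session")
def default_cfg():
    return tt.default_config()


@pytest.fixture(scope="session")
def planted_cohort(default_cfg):
    """One default synthetic cohort (n = 1314) shared across tests."""
    return tt.generate(default_cfg, seed=1)


@pytest.fixture()
def tiny_records():
    """Three valid hand-written records covering all endpoint labels."""
    return [
        tt.PatientRecord(age=52, sex="F", histology="PTC", t_stage=1, n_stage=0,
                         ata_risk="low", tsh=64.5, tg=2.5, raiu=4.4,
                         ptwbs="negative", center="A"),
        tt.PatientRecord(age=47, sex="M", histology="FTC", t_stage=3, n_stage=1,
                         ata_risk="high", tsh=88.0, tg=40.0, raiu=2.2,
                         ptwbs="positive", center="A"),
        tt.PatientRecord(age=61, sex="F", histology="PTC-FV", t_stage=2, n_stage=0,
                         ata_risk="intermediate", tsh=31.0, tg=0.7, raiu=7.8,
                         ptwbs="remnant", center="B"),
    ]


@pytest.fixture()
def tiny_cohort(tiny_records):
    return tt.Cohort.from_records(tiny_records, provenance="handmade")


def make_signal_cohort(rng: np.random.Generator, n: int = 500,
                       cut: float = 35.0, lo: float = 0.058,
                       hi: float = 0.563) -> tt.Cohort:
    """Cohort where only Tg carries signal: risk jumps lo -> hi at ``cut``.

    Tg is uniform so the jump is well inside the observed range; all
    other predictors are outcome-independent noise.
    """
    tg = rng.uniform(0.0, 2 * cut, n)
    risk = np.where(tg > cut, hi, lo)
    y = rng.random(n) < risk
    import pandas as pd

    df = pd.DataFrame({
        "age": rng.integers(18, 90, n),
        "sex": rng.choice(["M", "F"], n),
        "histology": rng.choice(["PTC", "PTC-FV", "FTC", "HCTC"], n),
        "t_stage": rng.integers(1, 5, n),
        "n_stage": rng.integers(0, 2, n),
        "ata_risk": rng.choice(["low", "intermediate", "high"], n),
        "tsh": rng.uniform(30.0, 100.0, n),
        "tg": tg,
        "raiu": rng.uniform(1.0, 10.0, n),
        "ptwbs": np.where(y, "positive", "negative"),
        "center": None,
    })
    return tt.Cohort(df, provenance="tg-signal-only")
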