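import numpy as np
import pandas as pd
import pytest

from remitehr import DiagnosticThresholds, GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def th() -> DiagnosticThresholds:
    return DiagnosticThresholds()


@pytest.fixture(scope="session")
def small_ds():
    """A small but fully featured synthetic dataset shared across tests."""
    return generate_dataset(GeneratorConfig(n_patients=600, seed=11))


@pytest.fixture(scope="session")
def medium_ds():
    """Mid-size dataset for distributional checks."""
    return generate_dataset(GeneratorConfig(n_patients=10_000, seed=29))


def lab_frame(records) -> pd.DataFrame:
    """records: (patient_id, day_offset_from_2020_06_01, kind, value)."""
    base = pd.Timestamp("2020-06-01")
    return pd.DataFrame(
        [
            {"patient_id": p, "date": base + pd.Timedelta(days=d), "kind": k,
             "value": float(v)}
            for p, d, k, v in records
        ],
        columns=["patient_id", "date", "kind", "value"],
    )


def empty_frame(*cols) -> pd.DataFrame:
    return pd.DataFrame(columns=list(cols))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
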