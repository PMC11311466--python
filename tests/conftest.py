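import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from peepbarcode import SimConfig, simulate_cohort
from peepbarcode.stratify import DonorRecord, ReleaseStats


def stats_with(mean: float, sd: float) -> list[float]:
    """Two values whose sample mean/SD (n-1) equal the given mean and SD."""
    h = sd / np.sqrt(2.0)
    return [mean - h, mean + h]


@pytest.fixture(scope="session")
def cohort_stats_262() -> ReleaseStats:
    """The full normal-cohort release stats: mean 24.1, SD 15.1 -> (9.0, 39.2)."""
    return ReleaseStats(mean_pct=24.1, sd_pct=15.1, n=262)


@pytest.fixture(scope="session")
def printed_donors() -> pd.DataFrame:
    """The six worked-example donors: release %, group, panel statuses, code."""
    rows = [
        ("D#148", 57.3, "High", ("Up", "Up", "Up", "Up"), "4U0N0D", "4-Up"),
        ("D#014", 20.4, "Ave", ("Norm", "Down", "Down", "Norm"), "0U2N2D", "Others"),
        ("D#118", 5.9, "Low", ("Norm", "Norm", "Norm", "Norm"), "0U4N0D", "Others"),
        ("SH#1", 11.5, "Ave", ("Norm", "Norm", "Norm", "Norm"), "0U4N0D", "Others"),
        ("SH#5", 36.3, "Ave", ("Norm", "Down", "Down", "Norm"), "0U2N2D", "Others"),
        ("SH#7", 44.2, "High", ("Up", "Norm", "Up", "Up"), "3U1N0D", "3-Up"),
    ]
    return pd.DataFrame(
        rows, columns=["donor_id", "release_pct", "group", "statuses", "code", "category"]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-donor simulated cohort shared across tests."""
    return simulate_cohort(SimConfig(n_donors=60, seed=11))


@pytest.fixture()
def donor_records():
    def make(values, prefix="D"):
        return [DonorRecord(f"{prefix}{i}", float(v)) for i, v in enumerate(values)]

    return make
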