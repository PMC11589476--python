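import warnings

import numpy as np
import pandas as pd
import pytest

from bayesrct.cohort import TrialDataset

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def two_arm_dataset(deaths: tuple[int, int], totals: tuple[int, int],
                    site: str = "site_001") -> TrialDataset:
    """Single-site dataset with the given (usual, high) death counts."""
    rows = []
    for arm, (k, n) in enumerate(zip(deaths, totals)):
        y = np.zeros(n)
        y[:k] = 1.0
        for v in y:
            rows.append({"site_id": site, "arm": arm, "death60": v})
    df = pd.DataFrame(rows)
    df["patient_id"] = [f"p{i}" for i in range(len(df))]
    return TrialDataset(df)


def survival_dataset(times, events, arms, sites=None) -> TrialDataset:
    """Minimal dataset for the discharge model: times are discharge times
    for events and censoring times otherwise."""
    n = len(times)
    sites = sites if sites is not None else ["site_001"] * n
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "site_id": sites,
            "arm": list(arms),
            "death60": 0.0,
            "t_discharge": list(times),
            "discharge_event": list(events),
            "died_in_hospital": 0,
        }
    )
    return TrialDataset(df)


@pytest.fixture(scope="session")
def reconstructed_cohort():
    from bayesrct.cohort import ArmSummary, reconstruct_from_summaries

    return reconstruct_from_summaries(
        ArmSummary(645, 656, 0.345, 0.322), n_sites=85, largest_site_size=120, seed=0
    )
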