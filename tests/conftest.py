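import numpy as np
import pandas as pd
import pytest

from ctcmd import synthio


def make_events(rows):
    """Build a minimal flow event table from (event_id, sample, session,
    cycle, response, epcam, psma, is_control) tuples."""
    recs = []
    for event_id, sample, session, cycle, response, epcam, psma, is_control in rows:
        recs.append(
            {
                "event_id": event_id,
                "patient_id": sample.split("_")[0],
                "sample_id": sample,
                "session_id": session,
                "cycle": cycle,
                "response": response,
                "epcam_mfi": epcam,
                "psma_mfi": psma,
                "is_control": is_control,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_cohort_events():
    """A small but complete simulated cohort (one seed, reused read-only)."""
    config = synthio.CohortConfig(n_patients_per_group=8, seed=11)
    skeleton = synthio.simulate_cohort(config)
    return synthio.simulate_flow_events(skeleton)


@pytest.fixture(scope="session")
def small_counts():
    """A small simulated count fixture (reused read-only)."""
    return synthio.simulate_counts(synthio.CountSimConfig(n_genes=400, n_deg=20, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
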