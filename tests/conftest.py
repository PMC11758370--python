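import numpy as np
import pandas as pd
import pytest

from fatality_window import JoinPointParams
from fatality_window.simulate import generate_cohort, model_exact_cohort, single_stratum_config


@pytest.fixture(scope="session")
def overall_params():
    """The headline cohort hazard: 0.917 / 0.185 per 1000 per day, join at 23.8."""
    return JoinPointParams.from_per_1000(0.917, 0.185, 23.8)


@pytest.fixture(scope="session")
def medium_sim(overall_params):
    """One moderately sized simulated cohort shared across tests:
    registry table, ground truth, config and the model-exact cohort."""
    cfg = single_stratum_config(overall_params, n=20000, seed=424242)
    table, truth = generate_cohort(cfg)
    return {
        "config": cfg,
        "table": table,
        "truth": truth,
        "exact": model_exact_cohort(truth, cfg),
    }


@pytest.fixture()
def toy_table():
    """Ten hand-written registry rows: 2 emergency, 1 unknown status."""
    rows = []
    for i in range(10):
        rows.append(
            dict(
                id=i + 1, age=60 + i, sex="male" if i % 2 else "female",
                asa="II", year=2010 + i % 3, site="colon" if i < 6 else "rectal",
                stage="II", urgency="elective", survival_time=180,
                vital_status="alive", status_known=1,
            )
        )
    rows[0]["urgency"] = "emergency"
    rows[1]["urgency"] = "emergency"
    rows[2]["status_known"] = 0
    rows[5].update(survival_time=10, vital_status="dead")
    rows[6].update(survival_time=1, vital_status="dead")
    return pd.DataFrame(rows)


def random_cohort(rng, n=200, horizon=60):
    """Small arbitrary right-censored cohort for oracle-equivalence tests."""
    from fatality_window import Cohort

    time = np.round(rng.uniform(3, horizon, size=n), 0) + 0.0
    event = rng.uniform(size=n) < 0.4
    return Cohort(time, event)
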