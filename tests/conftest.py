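import numpy as np
import pandas as pd
import pytest

from pubgrowth.sitar import fit_sitar
from pubgrowth.synthetic import CohortSpec, SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """Two-cohort simulation, no dropout: (config, truth, growth, pubertal)."""
    cfg = SimConfig(
        n_children_per_cohort=60,
        cohorts=(
            CohortSpec("A"),
            CohortSpec("B", a_offset=1.72, b_offset=-0.07, c_offset=0.017,
                       pubertal_spacing_months=12.0),
        ),
        dropout_hazard=0.0,
        seed=7,
    )
    truth, growth, pub = simulate(cfg)
    return cfg, truth, growth, pub


@pytest.fixture(scope="session")
def truth_frame(sim_small):
    _, truth, _, _ = sim_small
    return pd.DataFrame(
        [(r.child_id, r.sex, r.cohort, r.a, r.b, r.c, r.aphv, r.phv,
          r.takeoff_age, r.overweight, r.onset_age) for r in truth],
        columns=["child_id", "sex", "cohort", "a", "b", "c", "aphv", "phv",
                 "takeoff_age", "overweight", "onset_age"],
    ).set_index("child_id")


@pytest.fixture(scope="session")
def sitar_fit_girls(sim_small):
    _, _, growth, _ = sim_small
    return fit_sitar(growth[growth["sex"] == "F"], df=6, sex="F")


def interval_schedule(onset, visits):
    """Reference censoring of an onset age against sorted visit ages."""
    visits = np.asarray(visits, float)
    after = visits[visits >= onset]
    before = visits[visits < onset]
    if len(after) == 0:
        return float(visits[-1]), np.inf, "right"
    if len(before) == 0:
        return 0.0, float(after[0]), "left"
    return float(before[-1]), float(after[0]), "interval"
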