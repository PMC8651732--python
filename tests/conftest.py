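import numpy as np
import pandas as pd
import pytest

import plastevol as pe


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def full_design():
    sel = pe.enumerate_selection_design()
    cg = pe.enumerate_common_garden_design(sel)
    return sel, cg


@pytest.fixture(scope="session")
def small_experiment(full_design):
    """One simulated experiment at the study design, modest per-sample counts."""
    sel, cg = full_design
    params = pe.default_params(seed=7)
    params.mean_count = 10.0
    records = pe.simulate_experiment(params, sel, cg, seed=7)
    return params, records


@pytest.fixture(scope="session")
def analysis_table(small_experiment):
    _, records = small_experiment
    return pe.prepare_analysis_table(records)


def make_grouped_data(
    rng,
    n_groups=12,
    per_group=10,
    slope=2.0,
    group_effect=0.0,
    sigma_group=1.0,
    sigma_resid=1.0,
    intercept=1.0,
):
    """Simple one-factor random-intercept regression dataset."""
    g = np.repeat(np.arange(n_groups), per_group)
    x = rng.normal(size=n_groups * per_group)
    c = (np.arange(n_groups) % 2)[g].astype(float)
    u = rng.normal(0.0, sigma_group, n_groups)[g] if sigma_group > 0 else 0.0
    eps = rng.normal(0.0, sigma_resid, n_groups * per_group) if sigma_resid > 0 else 0.0
    y = intercept + slope * x + group_effect * c + u + eps
    return pd.DataFrame(dict(y=y, x=x, c=c, g=[f"g{i}" for i in g]))
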