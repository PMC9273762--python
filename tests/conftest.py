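import numpy as np
import pandas as pd
import pytest

import wardflag as wf
from wardflag import cohort as cohort_mod


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-encounter synthetic ward with episodes, features and labels."""
    params = wf.GeneratorParams(n_encounters=150, random_seed=3, hazard_scale=8.0)
    enc, obs, truth = wf.generate(params)
    kept, report = wf.filter_cohort(enc, obs)
    enc_k = enc[enc["encounter_id"].isin(kept)]
    obs_k = obs[obs["encounter_id"].isin(kept)]
    flags = wf.detect_red_flags(obs_k)
    cfg = wf.RunConfig(random_seed=3)
    table = wf.assemble_design_matrix(enc_k, obs_k, flags, cfg, cohort_ids=kept)
    return {
        "params": params,
        "encounters": enc,
        "observations": obs,
        "truth": truth,
        "kept": kept,
        "report": report,
        "flags": flags,
        "config": cfg,
        "table": table,
    }


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """A 40-tree encounter forest fitted on the small cohort (8-h labels)."""
    model = wf.fit_ef(
        small_cohort["table"],
        small_cohort["config"],
        wf.TreeSpec(max_depth=5, min_samples_leaf=10),
        label_col="label_8h",
        n_bootstrap=40,
    )
    return model


def make_feature_table(X: np.ndarray, y: np.ndarray, one_encounter_per_row=True):
    """Wrap a plain (X, y) problem in the versioned feature schema.

    Informative values go into the first columns of the schema; the rest are
    zero.  Each row is its own encounter so stage-1 sub-sampling keeps all.
    """
    n, d = X.shape
    cols = {c: np.zeros(n) for c in wf.FEATURE_COLUMNS}
    for j in range(d):
        cols[wf.FEATURE_COLUMNS[j]] = X[:, j].astype(float)
    table = pd.DataFrame(cols)
    table.insert(0, "encounter_id", [f"E{i:05d}" for i in range(n)])
    table.insert(1, "time", pd.Timestamp("2021-01-01"))
    table["label_8h"] = y.astype(int)
    return table


@pytest.fixture
def xor_tables():
    """Interaction-driven labels: separable at depth >= 2 only."""
    rng = np.random.default_rng(42)
    n = 600
    X = np.zeros((n, 2))
    X[:, 0] = rng.integers(0, 2, n)
    X[:, 1] = rng.integers(0, 2, n)
    y = (X[:, 0].astype(int) ^ X[:, 1].astype(int)).astype(int)
    train = make_feature_table(X[:400], y[:400])
    valid = make_feature_table(X[400:], y[400:])
    return train, valid
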