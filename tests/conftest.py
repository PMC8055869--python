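import numpy as np
import pandas as pd
import pytest

from pmstack import evaluation, model as model_mod, observations as obs_mod, prediction
from pmstack.features import assemble_features
from pmstack.synthetic import WorldConfig, generate_world, raw_source_tables, sample_observations

#: Small world used by unit tests: winter + spring 2013, modest network.
SMALL_CONFIG = WorldConfig(
    seed=7,
    n_days=120,
    n_monitors=40,
    n_mobile_fire_monitors=5,
    every_third_day_fraction=0.5,
    duplicate_fraction=0.10,
    extreme_injection_count=3,
)

#: Low-capacity learner settings so unit-test fits stay quick.
FAST_PARAMS = {
    "bagged": {"n_estimators": 10, "num_leaves": 31},
    "boosted": {"n_estimators": 30, "num_leaves": 15},
}


@pytest.fixture(scope="session")
def small_world():
    return generate_world(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_obs(small_world):
    return sample_observations(small_world)


@pytest.fixture(scope="session")
def qc_obs(small_obs):
    clean, _ = obs_mod.qc_pipeline(raw_source_tables(small_obs))
    return clean.sort_values(["monitor_id", "date"], kind="stable").reset_index(drop=True)


@pytest.fixture(scope="session")
def small_features(qc_obs, small_world):
    keys = qc_obs.rename(columns={"monitor_id": "location_id"})[
        ["location_id", "lon", "lat", "state", "date"]
    ]
    feats = assemble_features(keys, small_world, include_ctm=True)
    return feats


@pytest.fixture(scope="session")
def small_complete(small_features):
    completed, flags = prediction.impute_missing(small_features, seed=7)
    return completed, flags


@pytest.fixture(scope="session")
def small_model(small_complete, qc_obs):
    feats, _ = small_complete
    labels = qc_obs["pm25"].to_numpy()
    plan = evaluation.make_spatial_folds(feats, k=5, seed=7)
    model = model_mod.fit_ensemble(feats, labels, plan, params=FAST_PARAMS, seed=7)
    return model, plan, labels


TINY_CLI_CONFIG = """\
world:
  seed: 11
  n_days: 45
  n_monitors: 25
  n_mobile_fire_monitors: 3
  every_third_day_fraction: 0.4
model:
  bagged: {n_estimators: 8}
  boosted: {n_estimators: 25}
  importance_rows: 300
  importance_repeats: 1
evaluation:
  k: 5
prediction:
  level: county
"""


@pytest.fixture(scope="session")
def cli_runs(tmp_path_factory):
    """Two identical end-to-end CLI runs of a small configuration."""
    from click.testing import CliRunner
    from pmstack.cli import main

    base = tmp_path_factory.mktemp("cli")
    cfg_path = base / "config.yaml"
    cfg_path.write_text(TINY_CLI_CONFIG)
    runner = CliRunner()
    dirs = []
    for name in ("run1", "run2"):
        out = base / name
        res = runner.invoke(
            main, ["--config", str(cfg_path), "--out", str(out), "all"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0, res.output
        dirs.append(out)
    return dirs
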