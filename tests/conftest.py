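import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")

from adscore.adnet import NetworkSpec, TrainConfig, build_network, mc_predict, train
from adscore.deconfound import apply_deconfounder, fit_deconfounder
from adscore.morphometry_io import stratified_split
from adscore.synthetic_cohort import CohortSpec, generate_cohort

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def small_cohort():
    """60-row planted cohort used for I/O round-trips and smoke checks."""
    return generate_cohort(CohortSpec(n_subjects=60, seed=5))


@pytest.fixture(scope="session")
def trained_setup():
    """A full desk-scale training run shared across evaluation tests.

    Cohort of 736 with the default planted atrophy, 90/10 stratified split,
    leakage-free deconfounding, 100-epoch training and 50-pass MC scoring of
    the validation set.
    """
    cohort = generate_cohort(CohortSpec(seed=11))
    table = cohort.features
    sp = stratified_split(table, 0.9, seed=13)
    train_tbl = table[table["subject_id"].isin(sp.train_ids)].reset_index(drop=True)
    val_tbl = table[table["subject_id"].isin(sp.validation_ids)].reset_index(drop=True)
    dc = fit_deconfounder(train_tbl)
    train_z = apply_deconfounder(dc, train_tbl)
    val_z = apply_deconfounder(dc, val_tbl)
    net = build_network(NetworkSpec(), seed=2)
    model = train(net, train_z, val_z, TrainConfig(seed=4))
    scores_val = mc_predict(model, val_z, n_passes=50, seed=9)
    return {
        "cohort": cohort,
        "train_raw": train_tbl,
        "val_raw": val_tbl,
        "deconfounder": dc,
        "train_z": train_z,
        "val_z": val_z,
        "model": model,
        "scores_val": scores_val,
        "y_val": (val_tbl["diagnosis"] == "AD").to_numpy(int),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
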