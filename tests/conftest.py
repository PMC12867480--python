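import numpy as np
import pandas as pd
import pytest

from smresidence.locio import LocalizationTable
from smresidence.simulate import SimConfig, simulate_condition


def make_table(frames, xs, ys, precision=10.0, **extra):
    """Hand-built localization table for small deterministic cases."""
    n = len(frames)
    data = {
        "frame": np.asarray(frames, dtype=int),
        "x_nm": np.asarray(xs, dtype=float),
        "y_nm": np.asarray(ys, dtype=float),
        "precision_nm": np.full(n, precision, dtype=float)
        if np.isscalar(precision)
        else np.asarray(precision, dtype=float),
    }
    data.update({k: np.asarray(v) for k, v in extra.items()})
    df = pd.DataFrame(data).sort_values(["frame", "x_nm"], kind="mergesort").reset_index(drop=True)
    return LocalizationTable(df=df)


@pytest.fixture(scope="session")
def sim_20ms():
    """Short-exposure regime: bound and free molecules both detectable."""
    cfg = SimConfig(
        n_molecules=300, seed=11, k_off=0.5, k_on=0.5, k_bleach=0.5,
        frame_interval=0.02, n_frames=3000, sigma_loc=25.0,
    )
    table, truth = simulate_condition(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def sim_500ms():
    """Long-exposure regime: only chromatin-bound molecules localizable."""
    cfg = SimConfig(
        n_molecules=800, seed=21, k_off=0.05, k_bleach=0.02,
        frame_interval=0.5, n_frames=3000, sigma_loc=25.0,
    )
    table, truth = simulate_condition(cfg)
    return cfg, table, truth
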