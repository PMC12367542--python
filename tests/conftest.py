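import numpy as np
import pandas as pd
import pytest

from bwasplan.scaling import AccuracyGrid, TheoreticalParams, evaluate_theoretical


def make_model_grid(
    params: TheoreticalParams,
    n_vals=(100, 200, 300, 400, 500, 600, 700),
    t_vals=(2, 6, 10, 14, 22, 30, 42, 58),
    noise_sd: float = 0.0,
    seed: int = 0,
    dataset="sim",
    phenotype="pheno",
) -> AccuracyGrid:
    """Grid generated exactly (or noisily) from the theoretical law."""
    nn, tt = np.meshgrid(np.asarray(n_vals, float), np.asarray(t_vals, float))
    nn, tt = nn.ravel(), tt.ravel()
    acc = evaluate_theoretical(params, nn, tt)
    if noise_sd:
        acc = acc + np.random.default_rng(seed).normal(0, noise_sd, acc.shape)
    acc = np.clip(acc, -1, 1)
    return AccuracyGrid(
        dataset_id=dataset,
        phenotype_id=phenotype,
        metric="pearson",
        cells=pd.DataFrame({"n_train": nn, "t_min": tt, "accuracy": acc, "n_reps": 1}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_params(rng, k0_range=(0.2, 0.9), k1_range=(0.5, 3.3), k2_range=(2.5, 4.5)):
    """Random plausible theoretical parameters (k1, k2 log-uniform)."""
    return TheoreticalParams(
        k0=float(rng.uniform(*k0_range)),
        k1=float(10 ** rng.uniform(*k1_range)),
        k2=float(10 ** rng.uniform(*k2_range)),
    )
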