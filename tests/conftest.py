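import warnings

import numpy as np
import pytest

import condorcet as cc


def make_draws(
    z=None, theta=None, delta=None, b=None, g=None, coef=None, coef_names=None
):
    """Hand-build a PosteriorDraws from (chain, draw, ...) arrays for summary tests."""
    n_chains, n_draws = 2, 10
    for arr in (z, theta, delta, b, g):
        if arr is not None:
            n_chains, n_draws = arr.shape[:2]
            break
    m = z.shape[2] if z is not None else (delta.shape[2] if delta is not None else 2)
    n = theta.shape[2] if theta is not None else (b.shape[2] if b is not None else 2)
    arrays = {
        "z": z if z is not None else np.ones((n_chains, n_draws, m), dtype=np.int8),
        "theta": theta if theta is not None else np.zeros((n_chains, n_draws, n)),
        "delta": delta if delta is not None else np.zeros((n_chains, n_draws, m)),
        "b": b if b is not None else np.full((n_chains, n_draws, n), 0.8),
        "g": g if g is not None else np.full((n_chains, n_draws, n), 0.5),
        "sigma_delta": np.ones((n_chains, n_draws)),
    }
    names = coef_names or {}
    if coef is not None:
        for target, arr in coef.items():
            arrays[f"beta:{target}"] = arr
            arrays[f"sigma:{target}"] = np.ones((n_chains, n_draws))
    config = cc.McmcConfig(n_chains=max(n_chains, 2), n_burnin=0, n_samples=n_draws)
    return cc.PosteriorDraws(
        arrays=arrays,
        respondent_ids=[f"r{i+1}" for i in range(n)],
        item_ids=[f"item{k+1}" for k in range(m)],
        coef_names=names,
        config=config,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 40x20 synthetic survey at study-scale population parameters."""
    return cc.generate_dataset(cc.GeneratorConfig(n_respondents=40, n_items=20, seed=11))


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short but converging-enough fit with the full latent regression."""
    ds = small_dataset
    reg = cc.RegressionSpec(
        {t: [n for n in names if n != "intercept"] for t, names in ds.coef_names.items()}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cc.fit_ecm(
            ds.responses,
            ds.covariates,
            reg,
            cc.McmcConfig(n_chains=2, n_burnin=300, n_samples=300, seed=5),
        )
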