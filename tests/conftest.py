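"""Shared fixtures: small synthetic datasets and a reusable fitted model."""

from __future__ import annotations

import numpy as np
import pytest

from bluecarbon.compilation import AdjustedEstimate, SourceEstimate, VariabilityMeasure
from bluecarbon.model import ModelSpec, fit_mcmc, model_data
from bluecarbon.synthetic import GeneratorConfig, generate_compilation

HABITATS = ("saltmarsh", "mangrove", "seagrass")
CLIMATES = ("tropical", "temperate")
METHODS = ("standard", "bayesian", "other")


def make_adjusted(
    n: int = 40,
    n_studies: int = 20,
    seed: int = 0,
    sigma_between: float = 0.5,
    sigma_resid: float = 0.3,
    beta_intercept: float = -0.3,
    beta_saltmarsh: float = -0.4,
    sigma_hat: float = 0.2,
) -> tuple[list[AdjustedEstimate], dict]:
    """Adjusted estimates drawn directly from the meta-regression's own
    generative model (no percent-scale round trip), for well-specified
    calibration checks."""
    rng = np.random.default_rng(seed)
    study = np.concatenate([np.arange(n_studies), rng.integers(0, n_studies, n - n_studies)])
    habitat = rng.choice(HABITATS, size=n)
    climate = rng.choice(CLIMATES, size=n)
    method = rng.choice(METHODS, size=n)
    depth = rng.lognormal(-2.0, 1.0, n)
    zeta = rng.standard_normal(n_studies)
    mu = (
        beta_intercept
        + np.where(habitat == "saltmarsh", beta_saltmarsh, 0.0)
        + sigma_between * zeta[study]
    )
    s_hat = np.full(n, sigma_hat)
    y = rng.normal(mu, np.sqrt(s_hat**2 + sigma_resid**2))
    estimates = [
        AdjustedEstimate(
            estimate_id=f"e{i:03d}",
            study_id=f"s{study[i]:03d}",
            habitat=str(habitat[i]),
            climate=str(climate[i]),
            method=str(method[i]),
            depth_mid_m=float(depth[i]),
            n_endmembers=int(rng.integers(2, 8)),
            n_replicates=int(rng.integers(2, 20)),
            logratio_mean=float(y[i]),
            logratio_sd=float(s_hat[i]),
        )
        for i in range(n)
    ]
    truth = {
        "sigma_between": sigma_between,
        "sigma_resid": sigma_resid,
        "beta[intercept]": beta_intercept,
        "beta[habitat[saltmarsh]]": beta_saltmarsh,
    }
    return estimates, truth


def make_record(
    estimate_id: str = "e1",
    study_id: str = "s1",
    habitat: str = "mangrove",
    climate: str = "tropical",
    method: str = "bayesian",
    auto_mean_pct: float = 40.0,
    var: VariabilityMeasure | None = None,
    n_replicates: int = 6,
    **kwargs,
) -> SourceEstimate:
    return SourceEstimate(
        estimate_id=estimate_id,
        study_id=study_id,
        habitat=habitat,
        climate=climate,
        method=method,
        depth_mid_m=kwargs.get("depth_mid_m", 0.2),
        n_endmembers=kwargs.get("n_endmembers", 3),
        n_replicates=n_replicates,
        auto_mean_pct=auto_mean_pct,
        variability=var or VariabilityMeasure("sd", 10.0),
    )


@pytest.fixture(scope="session")
def small_fit():
    """One modest well-specified fit shared across evaluation tests."""
    estimates, truth = make_adjusted(n=40, n_studies=20, seed=11)
    spec = ModelSpec(
        fixed_effects=("habitat",), chains=2, iterations=1500, warmup=500, seed=5
    )
    data = model_data(estimates, spec)
    draws = fit_mcmc(data, spec)
    return draws, data, truth, spec


@pytest.fixture(scope="session")
def synthetic_compilation():
    config = GeneratorConfig()
    records, truth = generate_compilation(config, seed=101)
    return records, truth, config
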