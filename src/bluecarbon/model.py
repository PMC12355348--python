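"""Bayesian hierarchical meta-regression with known within-estimate variance.

Each adjusted estimate supplies a log-ratio mean theta_hat and its known
sampling SD sigma_hat.  The model is

    theta_hat_i ~ Normal(mu_i, sqrt(sigma_hat_i^2 + sigma^2))
    mu_i        = x_i' beta + Delta_k(i)
    Delta_k     = zeta_k * sigma_between          (non-centred study effect)
    beta_t, zeta_k ~ Normal(0, 1)
    sigma_between, sigma ~ Normal(0.5, 0.1) truncated to (0, inf)

where k(i) maps estimates to publications (the random-intercept grouping),
beta holds the intercept plus fixed effects of habitat, climate, mixing-model
method, soil-depth midpoint, end-member count and replication, sigma_between
is the between-study heterogeneity and sigma a residual SD.

Conditional on the two scale parameters the model is linear-Gaussian, so
:func:`fit_mcmc` uses a blocked Gibbs sampler: exact multivariate-normal
updates for beta, independent normal updates for zeta, a truncated-normal
conjugate update for sigma_between (it enters the mean linearly), and
univariate slice sampling for sigma (it enters the variance).  The sampler
is validated against brute-force grid integration and convergence
diagnostics rather than trusted on faith.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from bluecarbon.compilation import (
    CLIMATES,
    HABITATS,
    METHODS,
    AdjustedEstimate,
)

CONTINUOUS_EFFECTS = ("depth_mid_m", "n_endmembers", "n_replicates")
CATEGORICAL_LEVELS = {"habitat": HABITATS, "climate": CLIMATES, "method": METHODS}
DEFAULT_FIXED_EFFECTS = (
    "habitat",
    "climate",
    "method",
    "depth_mid_m",
    "n_endmembers",
    "n_replicates",
)
DEFAULT_REFERENCE_LEVELS = {
    "habitat": "mangrove",
    "climate": "tropical",
    "method": "bayesian",
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure, priors and MCMC settings.

    ``fixed_effects`` may be any subset of the six design covariates; the
    empty tuple gives the null (intercept-only) meta-regression, which keeps
    the study random intercept and the known measurement-error term.
    ``group_by`` selects the random-intercept grouping: ``"study_id"``
    (publications; default) or ``"estimate_id"``.
    """

    fixed_effects: tuple[str, ...] = DEFAULT_FIXED_EFFECTS
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS)
    )
    prior_coef: tuple[float, float] = (0.0, 1.0)
    prior_scale: tuple[float, float] = (0.5, 0.1)
    chains: int = 4
    iterations: int = 10_000
    warmup: int = 5_000
    seed: int = 0
    group_by: str = "study_id"

    def __post_init__(self):
        for name in self.fixed_effects:
            if name not in DEFAULT_FIXED_EFFECTS:
                raise ValueError(f"unknown fixed effect {name!r}")
        for var, level in self.reference_levels.items():
            if level not in CATEGORICAL_LEVELS[var]:
                raise ValueError(f"reference level {level!r} not in {var} vocabulary")
        if not self.warmup < self.iterations:
            raise ValueError("warmup must be < iterations")
        if self.group_by not in ("study_id", "estimate_id"):
            raise ValueError("group_by must be 'study_id' or 'estimate_id'")


@dataclass(frozen=True)
class DesignMatrix:
    """Fixed-effects matrix with coding metadata and group index.

    ``X`` is n_obs x T with a leading intercept column; dummy columns are
    0/1 against the spec's reference levels; continuous columns are centred
    and scaled by the stored in-sample mean/SD (ddof=1), kept for
    prediction on new data.  ``group_index`` maps each observation to its
    random-intercept group.
    """

    X: np.ndarray
    column_names: tuple[str, ...]
    centers: dict[str, float]
    scales: dict[str, float]
    group_index: np.ndarray
    group_labels: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass(frozen=True)
class ModelData:
    """Observed log-ratio means, their known SDs, and the design."""

    y: np.ndarray
    sigma_hat: np.ndarray
    design: DesignMatrix

    def __post_init__(self):
        if not (len(self.y) == len(self.sigma_hat) == self.design.n_obs):
            raise ValueError("y, sigma_hat and design have mismatched lengths")


@dataclass(frozen=True)
class ParameterState:
    """One point in parameter space (non-centred parameterisation)."""

    beta: np.ndarray
    zeta: np.ndarray
    sigma_between: float
    sigma_resid: float

    @property
    def study_offset(self) -> np.ndarray:
        return self.zeta * self.sigma_between

    def linear_predictor(self, design: DesignMatrix) -> np.ndarray:
        return design.X @ self.beta + self.study_offset[design.group_index]


def build_design(estimates: list[AdjustedEstimate], spec: ModelSpec) -> DesignMatrix:
    """Code covariates into a fixed-effects matrix with reference-level dummies.

    Dummy columns that are constant in-sample (an absent level, or a level
    shared by every observation) are dropped with a warning; a zero-variance
    continuous covariate is an error naming the column.
    """
    if not estimates:
        raise ValueError("no estimates")
    study_ids = [getattr(e, spec.group_by) for e in estimates]
    group_labels = tuple(dict.fromkeys(study_ids))
    if len(group_labels) < 2:
        raise ValueError("need >= 2 distinct groups for the random intercept")
    label_pos = {g: i for i, g in enumerate(group_labels)}
    group_index = np.array([label_pos[s] for s in study_ids], dtype=np.intp)

    n = len(estimates)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    centers: dict[str, float] = {}
    scales: dict[str, float] = {}

    for eff in spec.fixed_effects:
        if eff in CATEGORICAL_LEVELS:
            ref = spec.reference_levels[eff]
            values = [getattr(e, eff) for e in estimates]
            for level in CATEGORICAL_LEVELS[eff]:
                if level == ref:
                    continue
                col = np.array([1.0 if v == level else 0.0 for v in values])
                if col.min() == col.max():
                    warnings.warn(
                        f"dropping constant dummy column {eff}[{level}]", stacklevel=2
                    )
                    continue
                columns.append(col)
                names.append(f"{eff}[{level}]")
        else:
            raw = np.array([float(getattr(e, eff)) for e in estimates])
            sd = float(np.std(raw, ddof=1))
            if sd == 0.0:
                raise ValueError(f"zero-variance continuous column: {eff}")
            center = float(np.mean(raw))
            columns.append((raw - center) / sd)
            names.append(eff)
            centers[eff] = center
            scales[eff] = sd

    return DesignMatrix(
        X=np.column_stack(columns),
        column_names=tuple(names),
        centers=centers,
        scales=scales,
        group_index=group_index,
        group_labels=group_labels,
    )


def model_data(estimates: list[AdjustedEstimate], spec: ModelSpec) -> ModelData:
    """Bundle adjusted estimates and their design for fitting."""
    design = build_design(estimates, spec)
    y = np.array([e.logratio_mean for e in estimates])
    s = np.array([e.logratio_sd for e in estimates])
    return ModelData(y=y, sigma_hat=s, design=design)


# --------------------------------------------------------------------------
# densities


def _halfnormal_lognorm(mu: float, sd: float) -> float:
    # log of the (0, inf) truncation normaliser of Normal(mu, sd)
    return math.log(ndtr(mu / sd))


def log_likelihood(state: ParameterState, data: ModelData) -> float:
    """Sum over estimates of log N(theta_hat | mu, sqrt(sigma_hat^2 + sigma^2))."""
    if state.sigma_resid <= 0:
        raise ValueError("sigma_resid must be positive")
    mu = state.linear_predictor(data.design)
    var = data.sigma_hat**2 + state.sigma_resid**2
    resid = data.y - mu
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * var) + resid**2 / var))


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log prior: standard-normal coefficients and study effects,
    positive-truncated Normal(0.5, 0.1) scales (normaliser included)."""
    if state.sigma_between <= 0 or state.sigma_resid <= 0:
        return -np.inf
    m0, s0 = spec.prior_coef
    lp = float(np.sum(stats.norm.logpdf(state.beta, m0, s0)))
    lp += float(np.sum(stats.norm.logpdf(state.zeta, 0.0, 1.0)))
    ms, ss = spec.prior_scale
    lognorm = _halfnormal_lognorm(ms, ss)
    for sigma in (state.sigma_between, state.sigma_resid):
        lp += stats.norm.logpdf(sigma, ms, ss) - lognorm
    return lp


def log_posterior(state: ParameterState, data: ModelData, spec: ModelSpec) -> float:
    """Unnormalised log posterior (likelihood + prior)."""
    lp = log_prior(state, spec)
    if not np.isfinite(lp):
        return lp
    return lp + log_likelihood(state, data)


# --------------------------------------------------------------------------
# sampler


def _sample_truncnorm_pos(rng: np.random.Generator, mean: float, sd: float) -> float:
    # inverse-CDF draw from Normal(mean, sd) truncated to (0, inf)
    lo = ndtr(-mean / sd)
    u = rng.uniform(lo, 1.0)
    u = min(u, 1.0 - 1e-16)
    return mean + sd * ndtri(u)


def _slice_sample_sigma(
    rng: np.random.Generator,
    sigma: float,
    resid: np.ndarray,
    sigma_hat: np.ndarray,
    prior: tuple[float, float],
    width: float = 0.25,
) -> float:
    """One slice-sampling update of the residual SD (stepping out + shrink)."""
    ms, ss = prior

    def logp(s: float) -> float:
        if s <= 0:
            return -np.inf
        var = sigma_hat**2 + s * s
        ll = -0.5 * np.sum(np.log(var) + resid**2 / var)
        return float(ll) - 0.5 * ((s - ms) / ss) ** 2

    y0 = logp(sigma) + math.log(rng.uniform())
    lo = sigma - width * rng.uniform()
    hi = lo + width
    for _ in range(50):
        if lo <= 0 or logp(lo) < y0:
            break
        lo -= width
    lo = max(lo, 1e-12)
    for _ in range(50):
        if logp(hi) < y0:
            break
        hi += width
    for _ in range(100):
        prop = rng.uniform(lo, hi)
        if logp(prop) >= y0:
            return prop
        if prop < sigma:
            lo = prop
        else:
            hi = prop
    return sigma  # pragma: no cover - shrinkage virtually always succeeds


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws with chain structure and diagnostics.

    Arrays are indexed (chain, iteration); ``beta`` and ``zeta`` carry an
    extra trailing parameter axis.  ``diagnostics()`` reports split R-hat
    and a Geyer-windowed effective sample size per scalar parameter.
    """

    beta: np.ndarray  # (chains, draws, T)
    zeta: np.ndarray  # (chains, draws, K)
    sigma_between: np.ndarray  # (chains, draws)
    sigma_resid: np.ndarray  # (chains, draws)
    column_names: tuple[str, ...]
    group_labels: tuple[str, ...]
    spec: ModelSpec

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def parameter_arrays(self, include_zeta: bool = True) -> dict[str, np.ndarray]:
        out = {
            f"beta[{name}]": self.beta[:, :, j]
            for j, name in enumerate(self.column_names)
        }
        if include_zeta:
            for k, label in enumerate(self.group_labels):
                out[f"zeta[{label}]"] = self.zeta[:, :, k]
        out["sigma_between"] = self.sigma_between
        out["sigma_resid"] = self.sigma_resid
        return out

    def flat(self, name: str) -> np.ndarray:
        return self.parameter_arrays()[name].reshape(-1)

    def state(self, chain: int, draw: int) -> ParameterState:
        return ParameterState(
            beta=self.beta[chain, draw],
            zeta=self.zeta[chain, draw],
            sigma_between=float(self.sigma_between[chain, draw]),
            sigma_resid=float(self.sigma_resid[chain, draw]),
        )

    def linear_predictors(self, design: DesignMatrix) -> np.ndarray:
        """mu for every draw: array (chains*draws, n_obs)."""
        c, s, t = self.beta.shape
        beta = self.beta.reshape(c * s, t)
        offs = (self.zeta * self.sigma_between[:, :, None]).reshape(c * s, -1)
        return beta @ design.X.T + offs[:, design.group_index]

    def diagnostics(self, include_zeta: bool = False) -> pd.DataFrame:
        rows = []
        for name, arr in self.parameter_arrays(include_zeta=include_zeta).items():
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(arr)),
                    "q2.5": float(np.quantile(arr, 0.025)),
                    "q97.5": float(np.quantile(arr, 0.975)),
                    "rhat": gelman_rubin(arr, split=True),
                    "ess": effective_sample_size(arr),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (chain, iteration, parameter, value)."""
        frames = []
        for name, arr in self.parameter_arrays().items():
            c, s = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), s),
                        "iteration": np.tile(np.arange(s), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


class FitDiagnosticError(RuntimeError):
    """Raised when a fit produces non-finite draws; carries trace summaries."""


def _run_chain(
    data: ModelData,
    spec: ModelSpec,
    seed: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    X = data.design.X
    y = data.y
    g = data.design.group_index
    n, T = X.shape
    K = data.design.n_groups
    m0, s0 = spec.prior_coef
    ms, ss = spec.prior_scale
    prior_prec_beta = 1.0 / s0**2
    prior_prec_scale = 1.0 / ss**2

    beta = np.zeros(T)
    zeta = np.zeros(K)
    sigma_b = ms
    sigma = ms

    n_keep = spec.iterations - spec.warmup
    out_beta = np.empty((n_keep, T))
    out_zeta = np.empty((n_keep, K))
    out_sb = np.empty(n_keep)
    out_s = np.empty(n_keep)

    # per-group observation lists for vectorised zeta updates
    group_mat = np.zeros((K, n))
    group_mat[g, np.arange(n)] = 1.0

    for it in range(spec.iterations):
        var = data.sigma_hat**2 + sigma**2
        w = 1.0 / var

        # beta | rest : multivariate normal
        offset = sigma_b * zeta[g]
        Xw = X * w[:, None]
        prec = Xw.T @ X + prior_prec_beta * np.eye(T)
        mean_rhs = Xw.T @ (y - offset) + prior_prec_beta * m0
        chol = np.linalg.cholesky(prec)
        mu_beta = np.linalg.solve(prec, mean_rhs)
        z = rng.standard_normal(T)
        beta = mu_beta + np.linalg.solve(chol.T, z)

        # zeta | rest : independent normals per group
        resid0 = y - X @ beta
        prec_z = 1.0 + sigma_b**2 * (group_mat @ w)
        mean_z = sigma_b * (group_mat @ (resid0 * w)) / prec_z
        zeta = mean_z + rng.standard_normal(K) / np.sqrt(prec_z)

        # sigma_between | rest : truncated-normal (linear in the mean)
        zobs = zeta[g]
        prec_sb = prior_prec_scale + np.sum(zobs**2 * w)
        mean_sb = (prior_prec_scale * ms + np.sum(zobs * resid0 * w)) / prec_sb
        sigma_b = _sample_truncnorm_pos(rng, mean_sb, 1.0 / math.sqrt(prec_sb))

        # sigma | rest : slice sampling (enters the variance)
        resid = resid0 - sigma_b * zobs
        sigma = _slice_sample_sigma(rng, sigma, resid, data.sigma_hat, (ms, ss))

        if it >= spec.warmup:
            j = it - spec.warmup
            out_beta[j] = beta
            out_zeta[j] = zeta
            out_sb[j] = sigma_b
            out_s[j] = sigma

    return out_beta, out_zeta, out_sb, out_s


def fit_mcmc(data: ModelData, spec: ModelSpec) -> PosteriorDraws:
    """Fit the meta-regression by blocked Gibbs sampling.

    Runs ``spec.chains`` independent chains of ``spec.iterations`` sweeps,
    discarding ``spec.warmup``; a fixed ``spec.seed`` reproduces draws
    exactly.  Raises :class:`FitDiagnosticError` on non-finite draws.
    """
    if data.design.n_groups < 2:
        raise ValueError("need >= 2 groups")
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    betas, zetas, sbs, ss_ = [], [], [], []
    for c in range(spec.chains):
        b, z, sb, s = _run_chain(data, spec, seeds[c])
        betas.append(b)
        zetas.append(z)
        sbs.append(sb)
        ss_.append(s)
    draws = PosteriorDraws(
        beta=np.stack(betas),
        zeta=np.stack(zetas),
        sigma_between=np.stack(sbs),
        sigma_resid=np.stack(ss_),
        column_names=data.design.column_names,
        group_labels=data.design.group_labels,
        spec=spec,
    )
    for name, arr in draws.parameter_arrays().items():
        if not np.all(np.isfinite(arr)):
            raise FitDiagnosticError(
                f"non-finite draws in {name}; trace summary: "
                f"{np.nanmin(arr)}..{np.nanmax(arr)}"
            )
    return draws


# --------------------------------------------------------------------------
# diagnostics and derived quantities


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor R-hat.

    ``chains`` is (m, n).  The classic (non-split) estimator is
    sqrt(((n-1)/n * W + B/n) / W); ``split=True`` halves each chain first,
    which also detects within-chain trends.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    if split:
        half = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, n = arr.shape
    if n < 4:
        raise ValueError("need >= 4 draws per chain")
    chain_means = arr.mean(axis=1)
    W = float(np.mean(arr.var(axis=1, ddof=1)))
    B = n * float(np.var(chain_means, ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    v_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(v_hat / W))


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-based effective sample size (Geyer initial-monotone).

    Accepts a single chain (n,) or stacked chains (m, n).  A constant chain
    is degenerate and reported as ESS 0.
    """
    arr = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = arr.shape
    if n < 4:
        raise ValueError("need >= 4 draws")
    if np.all(arr == arr.flat[0]):
        return 0.0

    # mean autocovariance across chains (biased, FFT)
    centered = arr - arr.mean(axis=1, keepdims=True)
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)

    W = float(np.mean(arr.var(axis=1, ddof=1)))
    if m > 1:
        B_over_n = float(np.var(arr.mean(axis=1), ddof=1))
        var_plus = W * (n - 1) / n + B_over_n
    else:
        var_plus = W * (n - 1) / n
    rho = 1.0 - (W - mean_acov) / var_plus
    rho[0] = 1.0

    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 0.0
    prev_pair = np.inf
    t = 0
    max_t = n - 2
    while t + 1 <= max_t:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        pair = min(pair, prev_pair)
        tau += pair
        prev_pair = pair
        t += 2
    tau = max(2.0 * tau - 1.0, 1e-12)
    return float(m * n / tau)


def fold_variation(sigma_between_draws: np.ndarray) -> np.ndarray:
    """Implied fold-variation exp(2 sigma) of the auto:allo ratio per draw."""
    return np.exp(2.0 * np.asarray(sigma_between_draws, dtype=float))


def summarize_fold_variation(sigma_between_draws: np.ndarray) -> dict[str, float]:
    fv = fold_variation(np.asarray(sigma_between_draws).reshape(-1))
    return {
        "median": float(np.median(fv)),
        "q2.5": float(np.quantile(fv, 0.025)),
        "q97.5": float(np.quantile(fv, 0.975)),
    }


def bayes_r2(draws: PosteriorDraws, data: ModelData) -> dict[str, object]:
    """Per-draw Bayesian R^2 = V_fit / (V_fit + V_res).

    V_fit is the variance (ddof=1) across observations of the draw's linear
    predictor; V_res the mean modelled residual variance
    sigma_hat_i^2 + sigma^2.  Returns the per-draw vector and a
    median / 95%-interval summary.
    """
    if data.design.n_obs < 2:
        raise ValueError("R^2 undefined for a single observation")
    mu = draws.linear_predictors(data.design)  # (S, n)
    v_fit = mu.var(axis=1, ddof=1)
    sig = np.concatenate(
        [draws.sigma_resid[c] for c in range(draws.n_chains)]
    )
    v_res = np.mean(data.sigma_hat**2) + sig**2
    r2 = v_fit / (v_fit + v_res)
    return {
        "draws": r2,
        "median": float(np.median(r2)),
        "q2.5": float(np.quantile(r2, 0.025)),
        "q97.5": float(np.quantile(r2, 0.975)),
    }
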