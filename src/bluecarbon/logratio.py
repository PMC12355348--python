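"""Monte-Carlo construction of log-ratio effect sizes.

Each estimate's reported autochthonous mean and adjusted SD (percentage
points) define a normal distribution truncated to the open interval
(0, 100).  Draws a from that distribution give the allochthonous complement
100 - a, and the effect size is the natural log-ratio ln(a / (100 - a)).
The per-estimate mean and SD of those log-ratios feed the meta-regression
as a known-measurement-error observation.

A deterministic quadrature oracle (:func:`logratio_oracle`) computes the
same two moments by numerical integration; it exists to validate the
sampler, not to replace it.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import ndtr, ndtri

from bluecarbon.compilation import AdjustedEstimate, SourceEstimate, harmonize

_CLAMP_PCT = 0.1  # boundary means 0/100 are moved this far into the open interval


@dataclass(frozen=True)
class LogRatioSummary:
    """Mean and SD of ln(auto/allo) for one estimate, with sampling metadata."""

    mean: float
    sd: float
    n_draws: int
    seed: int
    degenerate: bool = False


def _truncnorm_draws(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Inverse-CDF draws from Normal(mean, sd) truncated to (0, 100).

    Draws that round to exactly 0 or 100 in floating point are resampled so
    the log-ratio stays finite.
    """
    lo = ndtr((0.0 - mean) / sd)
    hi = ndtr((100.0 - mean) / sd)
    out = np.empty(size)
    n_filled = 0
    while n_filled < size:
        u = rng.uniform(lo, hi, size - n_filled)
        x = mean + sd * ndtri(u)
        x = x[(x > 0.0) & (x < 100.0)]
        out[n_filled : n_filled + x.size] = x
        n_filled += x.size
    return out


def sample_logratio(
    auto_mean_pct: float,
    adjusted_sd_pct: float,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> LogRatioSummary:
    """Monte-Carlo mean and SD of ln(a / (100 - a)), a ~ TN(mean, sd; 0, 100).

    A boundary mean of exactly 0 or 100 is clamped to 0.1 / 99.9 with a
    warning; a non-positive SD short-circuits to the point-mass log-ratio
    with sd 0 and the ``degenerate`` flag set.
    """
    m = float(auto_mean_pct)
    if m in (0.0, 100.0):
        clamped = _CLAMP_PCT if m == 0.0 else 100.0 - _CLAMP_PCT
        warnings.warn(
            f"autochthonous mean {m}% clamped to {clamped}% for log-ratio sampling",
            stacklevel=2,
        )
        m = clamped
    if not 0.0 < m < 100.0:
        raise ValueError(f"auto_mean_pct outside (0, 100): {auto_mean_pct}")
    if adjusted_sd_pct <= 0.0:
        return LogRatioSummary(
            mean=math.log(m / (100.0 - m)), sd=0.0, n_draws=0, seed=seed, degenerate=True
        )
    rng = np.random.default_rng(seed)
    a = _truncnorm_draws(rng, m, adjusted_sd_pct, n_draws)
    logratio = np.log(a) - np.log(100.0 - a)
    return LogRatioSummary(
        mean=float(np.mean(logratio)),
        sd=float(np.std(logratio, ddof=1)),
        n_draws=n_draws,
        seed=seed,
    )


def logratio_oracle(auto_mean_pct: float, adjusted_sd_pct: float) -> tuple[float, float]:
    """Exact (quadrature) mean and SD of the truncated-normal log-ratio.

    Integrates ln(x/(100-x)) and its square against the TN(mean, sd; 0, 100)
    density with adaptive quadrature to relative tolerance 1e-8.  Exploits
    antisymmetry: at mean 50 the first moment is exactly 0.
    """
    m, s = float(auto_mean_pct), float(adjusted_sd_pct)
    if not 0.0 < m < 100.0:
        raise ValueError(f"auto_mean_pct outside (0, 100): {m}")
    if s <= 0.0:
        return math.log(m / (100.0 - m)), 0.0

    # integrate in probability space: with u uniform on (F(0), F(100)) under
    # the untruncated normal CDF F, x(u) = m + s * ndtri(u) maps exactly onto
    # the truncated normal, and the integrand stays resolvable even for
    # near-degenerate s
    lo = ndtr((0.0 - m) / s)
    hi = ndtr((100.0 - m) / s)
    width = hi - lo

    def moment(power: int) -> float:
        def f(t):
            x = m + s * ndtri(lo + width * t)
            x = min(max(x, 1e-300), 100.0 - 1e-13)
            return (math.log(x) - math.log(100.0 - x)) ** power

        val, _ = integrate.quad(
            f, 0.0, 1.0, epsabs=1e-13, epsrel=1e-8, limit=400, points=[0.5]
        )
        return val

    mean = 0.0 if m == 50.0 else moment(1)
    second = moment(2)
    var = second - mean * mean
    if var < 0 and var > -1e-12:
        var = 0.0
    return mean, math.sqrt(var)


def _substream_seed(master_seed: int, estimate_id: str) -> int:
    """Stable per-record seed keyed by (master seed, estimate id), not position."""
    digest = hashlib.sha256(f"{master_seed}:{estimate_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def batch_logratios(
    records: list[SourceEstimate],
    n_draws: int = 1_000_000,
    master_seed: int = 0,
) -> list[AdjustedEstimate]:
    """Harmonise and Monte-Carlo convert a list of records to log-ratio scale.

    Each record gets an independent RNG substream keyed by its estimate id,
    so output is invariant to input order and to batching.
    """
    out: list[AdjustedEstimate] = []
    for rec in records:
        try:
            mean_pct, sd_pct = harmonize(rec)
            seed = _substream_seed(master_seed, rec.estimate_id)
            summary = sample_logratio(mean_pct, sd_pct, n_draws=n_draws, seed=seed)
            if summary.degenerate:
                raise ValueError("adjusted SD is zero; log-ratio SD undefined")
            out.append(
                AdjustedEstimate(
                    estimate_id=rec.estimate_id,
                    study_id=rec.study_id,
                    habitat=rec.habitat,
                    climate=rec.climate,
                    method=rec.method,
                    depth_mid_m=rec.depth_mid_m,
                    n_endmembers=rec.n_endmembers,
                    n_replicates=rec.n_replicates,
                    logratio_mean=summary.mean,
                    logratio_sd=summary.sd,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"estimate {rec.estimate_id!r}: {exc}") from exc
    return out
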