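"""Reading, validation and harmonisation of the soil-carbon compilation.

A compilation is a flat table with one row per independent habitat-specific
estimate of the autochthonous (locally fixed) percentage of soil organic
carbon, together with the study it came from, design covariates, and a
reported variability measure.  Published studies report dispersion in
heterogeneous ways (SD, SE, 95% CI, variance); everything downstream works
on a single "adjusted SD" scale, obtained here by normal-theory conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

HABITATS = ("saltmarsh", "mangrove", "seagrass")
CLIMATES = ("tropical", "temperate")
METHODS = ("standard", "bayesian", "other")

VARIABILITY_KINDS = ("sd", "se", "ci95", "variance")

COMPILATION_COLUMNS = [
    "estimate_id",
    "study_id",
    "habitat",
    "climate",
    "method",
    "depth_mid_m",
    "n_endmembers",
    "n_replicates",
    "auto_mean_pct",
    "var_kind",
    "var_a",
    "var_b",
]

CONTRIBUTION_COLUMNS = ["estimate_id", "source_name", "mean_pct", "sd_pct", "n_estimates"]


class SchemaError(ValueError):
    """The input table does not match the documented column schema."""


class RowError(ValueError):
    """A data row failed validation; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class VariabilityMeasure:
    """A reported dispersion value for the autochthonous percentage.

    ``kind`` is one of ``sd``, ``se``, ``ci95`` or ``variance``; ``value_a``
    holds the SD/SE/variance or the CI lower bound (percentage points), and
    ``value_b`` the CI upper bound for ``ci95``.
    """

    kind: str
    value_a: float
    value_b: float | None = None

    def __post_init__(self):
        if self.kind not in VARIABILITY_KINDS:
            raise ValueError(f"unknown variability kind {self.kind!r}")
        if self.kind == "ci95":
            if self.value_b is None or not self.value_b > self.value_a:
                raise ValueError("ci95 requires value_b > value_a")
        elif self.value_a < 0:
            raise ValueError(f"{self.kind} must be non-negative, got {self.value_a}")


@dataclass(frozen=True)
class SourceContribution:
    """One dataset's estimated contribution of a named carbon source (%)."""

    source_name: str
    mean_pct: float
    sd_pct: float
    n_estimates: int = 1

    def __post_init__(self):
        if not 0.0 <= self.mean_pct <= 100.0:
            raise ValueError(f"mean_pct out of [0, 100]: {self.mean_pct}")
        if self.sd_pct < 0:
            raise ValueError(f"sd_pct negative: {self.sd_pct}")
        if self.n_estimates < 1:
            raise ValueError("n_estimates must be positive")


@dataclass(frozen=True)
class SourceEstimate:
    """One curated row of the compilation.

    ``auto_mean_pct`` is the reported autochthonous percentage of soil
    organic carbon; ``variability`` its typed dispersion measure;
    ``contributions`` the per-source breakdown where the study reported one.
    """

    estimate_id: str
    study_id: str
    habitat: str
    climate: str
    method: str
    depth_mid_m: float
    n_endmembers: int
    n_replicates: int
    auto_mean_pct: float
    variability: VariabilityMeasure
    contributions: tuple[SourceContribution, ...] = ()

    def __post_init__(self):
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.climate not in CLIMATES:
            raise ValueError(f"unknown climate {self.climate!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.depth_mid_m < 0:
            raise ValueError("depth_mid_m must be >= 0")
        if self.n_endmembers < 2:
            raise ValueError("n_endmembers must be >= 2")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not math.isfinite(self.auto_mean_pct) or not 0 <= self.auto_mean_pct <= 100:
            raise ValueError(f"auto_mean_pct out of [0, 100]: {self.auto_mean_pct}")

    @property
    def boundary_mean(self) -> bool:
        """True when the reported mean sits exactly on 0% or 100%.

        Such rows are accepted at ingest but flagged; the log-ratio stage
        decides how to clamp them.
        """
        return self.auto_mean_pct in (0.0, 100.0)


@dataclass(frozen=True)
class AdjustedEstimate:
    """Unit of analysis for the meta-regression.

    ``logratio_mean`` and ``logratio_sd`` are the Monte-Carlo mean and SD of
    ln(autochthonous% / allochthonous%) for this estimate; covariates ride
    along for the design matrix.
    """

    estimate_id: str
    study_id: str
    habitat: str
    climate: str
    method: str
    depth_mid_m: float
    n_endmembers: int
    n_replicates: int
    logratio_mean: float
    logratio_sd: float

    def __post_init__(self):
        if not math.isfinite(self.logratio_mean):
            raise ValueError("logratio_mean must be finite")
        if not self.logratio_sd > 0:
            raise ValueError("logratio_sd must be > 0")


def se_to_sd(se: float, n: int) -> float:
    """Convert a standard error of a mean over ``n`` replicates to an SD."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if se < 0:
        raise ValueError("se must be non-negative")
    return se * math.sqrt(n)

def ci_to_sd(lower: float, upper: float, n: int, level: float = 0.95) -> float:
    """Convert a normal confidence interval for a mean to a sample SD.

    Assumes the interval was ``mean +- z * SD/sqrt(n)`` with z the standard
    normal quantile at (1 + level)/2, so SD = sqrt(n) (upper - lower)/(2 z).
    """
    if not upper > lower:
        raise ValueError("upper must exceed lower")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return math.sqrt(n) * (upper - lower) / (2.0 * z)


def harmonize(record: SourceEstimate) -> tuple[float, float]:
    """Return ``(auto_mean_pct, adjusted_sd_pct)`` on the common SD scale.

    Dispatches on the reported variability kind: SD passes through, SE and
    95% CI are scaled up by the replication, variance is square-rooted.
    Unrecognised kinds are rejected rather than guessed.
    """
    v = record.variability
    if v.kind == "sd":
        sd = v.value_a
    elif v.kind == "se":
        sd = se_to_sd(v.value_a, record.n_replicates)
    elif v.kind == "ci95":
        sd = ci_to_sd(v.value_a, v.value_b, record.n_replicates, level=0.95)
    elif v.kind == "variance":
        sd = math.sqrt(v.value_a)
    else:  # pragma: no cover - blocked by VariabilityMeasure validation
        raise ValueError(f"unknown variability kind {v.kind!r}")
    return record.auto_mean_pct, sd


def _norm_enum(value: str, vocabulary: tuple[str, ...], column: str, row: int) -> str:
    token = str(value).strip().lower()
    if token not in vocabulary:
        raise RowError(row, f"{column} value {value!r} not in {vocabulary}")
    return token


def read_compilation(
    path: str | Path,
    contributions_path: str | Path | None = None,
) -> list[SourceEstimate]:
    """Read a compilation CSV (and optional per-source contribution CSV).

    Enum columns are normalised case-insensitively.  Raises
    :class:`SchemaError` for a missing column and :class:`RowError` (with the
    0-based data-row index) for an unparseable row.
    """
    df = pd.read_csv(path, dtype={"estimate_id": str, "study_id": str})
    missing = [c for c in COMPILATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    by_estimate: dict[str, list[SourceContribution]] = {}
    if contributions_path is not None:
        cdf = pd.read_csv(contributions_path, dtype={"estimate_id": str})
        cmissing = [c for c in CONTRIBUTION_COLUMNS if c not in cdf.columns]
        if cmissing:
            raise SchemaError(f"missing column(s): {', '.join(cmissing)}")
        for _, r in cdf.iterrows():
            by_estimate.setdefault(r["estimate_id"], []).append(
                SourceContribution(
                    source_name=str(r["source_name"]).strip().lower(),
                    mean_pct=float(r["mean_pct"]),
                    sd_pct=float(r["sd_pct"]),
                    n_estimates=int(r["n_estimates"]),
                )
            )

    records: list[SourceEstimate] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            var_b = getattr(row, "var_b")
            variability = VariabilityMeasure(
                kind=_norm_enum(row.var_kind, VARIABILITY_KINDS, "var_kind", i),
                value_a=float(row.var_a),
                value_b=None if pd.isna(var_b) else float(var_b),
            )
            records.append(
                SourceEstimate(
                    estimate_id=str(row.estimate_id),
                    study_id=str(row.study_id),
                    habitat=_norm_enum(row.habitat, HABITATS, "habitat", i),
                    climate=_norm_enum(row.climate, CLIMATES, "climate", i),
                    method=_norm_enum(row.method, METHODS, "method", i),
                    depth_mid_m=float(row.depth_mid_m),
                    n_endmembers=int(row.n_endmembers),
                    n_replicates=int(row.n_replicates),
                    auto_mean_pct=float(row.auto_mean_pct),
                    variability=variability,
                    contributions=tuple(by_estimate.get(str(row.estimate_id), ())),
                )
            )
        except RowError:
            raise
        except (TypeError, ValueError) as exc:
            raise RowError(i, str(exc)) from exc
    return records


def compilation_frame(records: Iterable[SourceEstimate]) -> pd.DataFrame:
    """Flatten records to the documented compilation CSV schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "estimate_id": r.estimate_id,
                "study_id": r.study_id,
                "habitat": r.habitat,
                "climate": r.climate,
                "method": r.method,
                "depth_mid_m": r.depth_mid_m,
                "n_endmembers": r.n_endmembers,
                "n_replicates": r.n_replicates,
                "auto_mean_pct": r.auto_mean_pct,
                "var_kind": r.variability.kind,
                "var_a": r.variability.value_a,
                "var_b": r.variability.value_b,
            }
        )
    return pd.DataFrame(rows, columns=COMPILATION_COLUMNS)


def contributions_frame(records: Iterable[SourceEstimate]) -> pd.DataFrame:
    rows = []
    for r in records:
        for c in r.contributions:
            rows.append(
                {
                    "estimate_id": r.estimate_id,
                    "source_name": c.source_name,
                    "mean_pct": c.mean_pct,
                    "sd_pct": c.sd_pct,
                    "n_estimates": c.n_estimates,
                }
            )
    return pd.DataFrame(rows, columns=CONTRIBUTION_COLUMNS)


def write_compilation(
    records: Iterable[SourceEstimate],
    path: str | Path,
    contributions_path: str | Path | None = None,
) -> None:
    """Write records back to the documented CSV schema (UTF-8, header row)."""
    records = list(records)
    compilation_frame(records).to_csv(path, index=False)
    if contributions_path is not None:
        contributions_frame(records).to_csv(contributions_path, index=False)


def read_contributions(path: str | Path) -> pd.DataFrame:
    """Read a per-source contributions CSV, validating the schema."""
    df = pd.read_csv(path, dtype={"estimate_id": str})
    missing = [c for c in CONTRIBUTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df["source_name"] = df["source_name"].str.strip().str.lower()
    return df


def adjusted_frame(estimates: Iterable[AdjustedEstimate]) -> pd.DataFrame:
    """Flatten adjusted estimates to the adjusted.csv schema."""
    return pd.DataFrame(
        [
            {
                "estimate_id": e.estimate_id,
                "study_id": e.study_id,
                "habitat": e.habitat,
                "climate": e.climate,
                "method": e.method,
                "depth_mid_m": e.depth_mid_m,
                "n_endmembers": e.n_endmembers,
                "n_replicates": e.n_replicates,
                "logratio_mean": e.logratio_mean,
                "logratio_sd": e.logratio_sd,
            }
            for e in estimates
        ]
    )
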