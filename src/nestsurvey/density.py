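"""Nest and builder density estimation from line and strip transects.

Two estimators are provided:

* standing-crop nest count (SCNC) from line transects,
      D_nest = n * f(0) / (2 L),
  with n the number of detected nests after truncation, f(0) the fitted
  probability density of detection distances at zero (per metre) and L the
  total transect length;

* marked nest count (MNC) from strip transects,
      D_builder = n_new / (2 s L t p),
  with n_new the number of newly built nests detected within a strip of
  half-width s from the second visit onwards, t the days elapsed between
  first and last visit and p the daily nest production rate per builder.

Uncertainty is quantified by a nonparametric bootstrap that resamples
transects (the replicate unit of the survey design) with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NumericalError, SchemaError
from .units import M_PER_KM

__all__ = [
    "TransectLayout",
    "DensityEstimate",
    "SurveySchedule",
    "encounter_rate",
    "scnc_nest_density",
    "mnc_builder_density",
    "habitat_weighted_mean",
    "bootstrap_ci",
    "bootstrap_distribution",
]


@dataclass
class TransectLayout:
    """Transect lengths and their per-habitat composition (km)."""

    table: pd.DataFrame  # columns: transect_id, length_km, one column per habitat

    def __post_init__(self):
        t = self.table
        required = {"transect_id", "length_km"}
        if not required.issubset(t.columns):
            missing = required - set(t.columns)
            raise SchemaError(f"transect table lacks column(s) {sorted(missing)}")
        if (t["length_km"] <= 0).any():
            raise SchemaError("transect lengths must be positive")
        comp = t[self.habitats]
        if len(self.habitats):
            if (comp < -1e-12).to_numpy().any():
                raise SchemaError("negative habitat component length")
            resid = (comp.sum(axis=1) - t["length_km"]).abs()
            if (resid > 1e-6).any():
                bad = t.loc[resid > 1e-6, "transect_id"].tolist()
                raise SchemaError(
                    f"habitat components do not sum to length_km for transect(s) {bad}"
                )

    @property
    def habitats(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("transect_id", "length_km")]

    @property
    def total_length_km(self) -> float:
        return float(self.table["length_km"].sum())

    def effort_km(self, habitat: str | None = None) -> float:
        """Total length (km), optionally of one habitat stratum."""
        if habitat is None:
            return self.total_length_km
        if habitat not in self.habitats:
            raise SchemaError(f"unknown habitat {habitat!r} in transect layout")
        return float(self.table[habitat].sum())

    @classmethod
    def from_csv(cls, path) -> "TransectLayout":
        return cls(pd.read_csv(path))


@dataclass
class SurveySchedule:
    """Visit day offsets per transect; t is days from first to last visit."""

    visit_days: Sequence[float]

    def __post_init__(self):
        d = np.asarray(self.visit_days, dtype=float)
        if d.size < 2:
            raise SchemaError("a schedule needs at least two visits")
        if not np.all(np.diff(d) > 0):
            raise SchemaError("visit days must be strictly increasing")
        self.visit_days = d

    @property
    def t_days(self) -> float:
        return float(self.visit_days[-1] - self.visit_days[0])

    @property
    def n_visits(self) -> int:
        return int(len(self.visit_days))


@dataclass
class DensityEstimate:
    """Point estimate with optional bootstrap uncertainty.

    Units: objects (nests or builders) per km².
    """

    value: float
    stratum: str = "global"
    cv: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n: int | None = None
    effort_km: float | None = None
    estimator: str = ""

    def __post_init__(self):
        if self.value < 0:
            raise SchemaError("density cannot be negative")
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low - 1e-9 <= self.value <= self.ci_high + 1e-9):
                raise SchemaError("point estimate outside its confidence interval")

    def scaled(self, factor: float, estimator: str | None = None) -> "DensityEstimate":
        """Multiply the estimate (and CI endpoints) by a positive constant."""
        if factor < 0:
            raise SchemaError("scale factor must be nonnegative")
        return DensityEstimate(
            value=self.value * factor, stratum=self.stratum, cv=self.cv,
            ci_low=self.ci_low * factor, ci_high=self.ci_high * factor,
            n=self.n, effort_km=self.effort_km,
            estimator=self.estimator if estimator is None else estimator,
        )


# ---------------------------------------------------------------------------
# point estimators


def encounter_rate(n: int, effort_km: float) -> float:
    """Nests encountered per km of transect."""
    if effort_km <= 0:
        raise SchemaError("effort must be positive")
    if n < 0:
        raise SchemaError("count cannot be negative")
    return n / effort_km


def scnc_nest_density(
    n: int, f0_per_m: float, effort_km: float, stratum: str = "global"
) -> DensityEstimate:
    """Standing-crop line-transect nest density, nests/km².

    f(0) enters per metre and effort per kilometre; the conversion to nests
    per km² is ``n * f0 / (2 L)`` with both lengths in metres, times 1e6.
    """
    if n < 0:
        raise SchemaError("count cannot be negative")
    if effort_km <= 0:
        raise SchemaError("effort must be positive")
    if n > 0 and not f0_per_m > 0:
        raise SchemaError(f"f(0) must be positive, got {f0_per_m}")
    value = n * f0_per_m * M_PER_KM / (2.0 * effort_km)
    return DensityEstimate(value=value, stratum=stratum, n=n,
                           effort_km=effort_km, estimator="scnc")


def mnc_builder_density(
    n_new: int,
    effort_km: float,
    s_m: float,
    t_days: float,
    production: float,
    stratum: str = "global",
) -> DensityEstimate:
    """Marked-nest-count strip-transect builder density, builders/km².

    ``n_new`` counts new nests within the strip from the second visit on;
    ``s_m`` is the strip half-width (m), ``t_days`` the span first→last
    visit, ``production`` the nests built per builder per day.
    """
    if n_new < 0:
        raise SchemaError("count cannot be negative")
    if effort_km <= 0:
        raise SchemaError("effort must be positive")
    for name, v in (("strip half-width s", s_m), ("elapsed time t", t_days),
                    ("production rate p", production)):
        if not v > 0:
            raise SchemaError(f"{name} must be positive, got {v}")
    value = n_new / (2.0 * (s_m / M_PER_KM) * effort_km * t_days * production)
    return DensityEstimate(value=value, stratum=stratum, n=n_new,
                           effort_km=effort_km, estimator="mnc")


def habitat_weighted_mean(
    estimates: Mapping[str, DensityEstimate],
    areas_km2: Mapping[str, float],
) -> DensityEstimate:
    """Area-weighted global density from habitat-specific estimates.

    The CV of the weighted mean treats strata as independent:
    cv = sqrt(sum (A_h D_h cv_h)^2) / sum(A_h D_h); CI endpoints are
    likewise area-weighted when every stratum carries one.
    """
    if not estimates:
        raise SchemaError("no habitat estimates supplied")
    missing = [h for h in estimates if h not in areas_km2]
    if missing:
        raise SchemaError(f"no area supplied for habitat(s) {missing}")
    habs = list(estimates)
    areas = np.array([areas_km2[h] for h in habs], dtype=float)
    if np.any(areas <= 0):
        raise SchemaError("habitat areas must be positive")
    dens = np.array([estimates[h].value for h in habs])
    total = areas.sum()
    value = float(areas @ dens / total)

    cvs = np.array([estimates[h].cv for h in habs])
    num = areas * dens
    if np.all(np.isfinite(cvs)) and num.sum() > 0:
        cv = float(np.sqrt(np.sum((num * cvs) ** 2)) / num.sum())
    else:
        cv = np.nan
    lows = np.array([estimates[h].ci_low for h in habs])
    highs = np.array([estimates[h].ci_high for h in habs])
    if np.all(np.isfinite(lows)) and np.all(np.isfinite(highs)):
        ci_low = float(areas @ lows / total)
        ci_high = float(areas @ highs / total)
    else:
        ci_low = ci_high = np.nan
    n_total = sum(e.n for e in estimates.values() if e.n is not None)
    return DensityEstimate(
        value=value, stratum="global", cv=cv, ci_low=ci_low, ci_high=ci_high,
        n=n_total or None, estimator=next(iter(estimates.values())).estimator,
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_distribution(
    groups: Sequence,
    estimator: Callable[[Sequence], float],
    B: int = 999,
    seed: int = 0,
    max_failure_fraction: float = 0.2,
) -> np.ndarray:
    """Bootstrap distribution of ``estimator`` under transect resampling.

    ``groups`` holds one element per transect (any payload the estimator
    understands); each resample draws ``len(groups)`` transects with
    replacement and re-runs the estimator.  Resamples where the estimator
    raises :class:`NumericalError` are dropped; more than
    ``max_failure_fraction`` failures aborts.
    """
    if len(groups) < 2:
        raise SchemaError("bootstrap needs at least 2 transects")
    if B < 1:
        raise SchemaError("B must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(groups)
    values = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, k, size=k)
        try:
            values.append(float(estimator([groups[i] for i in idx])))
        except NumericalError:
            failures += 1
    if failures > max_failure_fraction * B:
        raise NumericalError(
            f"bootstrap estimator failed in {failures}/{B} resamples"
        )
    return np.asarray(values, dtype=float)


def bootstrap_ci(
    groups: Sequence,
    estimator: Callable[[Sequence], float],
    B: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Percentile bootstrap: returns (cv, ci_low, ci_high).

    cv = sd/mean of the bootstrap distribution; the interval is the
    (alpha/2, 1-alpha/2) percentile pair.  Deterministic given ``seed``.
    """
    boot = bootstrap_distribution(groups, estimator, B=B, seed=seed)
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    mean = boot.mean()
    sd = boot.std(ddof=1) if boot.size > 1 else 0.0
    cv = float(sd / mean) if mean != 0 else 0.0
    return cv, float(lo), float(hi)
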