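"""End-to-end estimation pipelines tying detection fits to densities.

These functions are the library-level counterparts of the command-line
subcommands: they take an observation table and a transect layout, run
truncation, detection-function selection, density estimation and the
transect bootstrap, and return tidy results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import (
    DensityEstimate,
    TransectLayout,
    bootstrap_ci,
    encounter_rate,
    habitat_weighted_mean,
    mnc_builder_density,
    scnc_nest_density,
)
from .detection import (
    DetectionModelSpec,
    DistanceSample,
    ModelSelection,
    fit_detection,
    select_detection_model,
    select_stepwise,
    strip_half_width,
    truncate,
)
from .errors import NumericalError, SchemaError
from .rates import DecayRate, ProductionRate, builders_from_nests, solve_decay_rate

log = logging.getLogger("nestsurvey")

__all__ = ["ScncResult", "MncResult", "run_scnc", "run_mnc", "recover_decay_rate"]


@dataclass
class ScncResult:
    per_habitat: dict[str, DensityEstimate]
    global_estimate: DensityEstimate
    selection: dict[str, ModelSelection]
    encounter_rates: dict[str, float]
    sample: DistanceSample


@dataclass
class MncResult:
    per_habitat: dict[str, DensityEstimate]
    global_estimate: DensityEstimate
    selection: dict[str, ModelSelection]
    strip_half_widths_m: dict[str, float]
    t_days: float


def _select(sample: DistanceSample, candidates, stepwise: bool, seed: int) -> ModelSelection:
    if candidates is not None:
        return select_detection_model(sample, candidates, seed=seed)
    if stepwise:
        return select_stepwise(sample, seed=seed)
    fit = fit_detection(sample, DetectionModelSpec("half-normal", 0), seed=seed)
    return ModelSelection(best=fit, delta_aic=None, table=pd.DataFrame())


def _first_visit(obs: pd.DataFrame, year: int | None) -> pd.DataFrame:
    sub = obs[obs["visit"] == 1]
    if year is not None:
        sub = sub[sub["year"] == year]
    if len(sub) == 0:
        raise SchemaError("no first-visit observations" + (f" for year {year}" if year else ""))
    return sub


def _transect_counts(obs: pd.DataFrame, layout: TransectLayout, habitat: str | None):
    """(count, effort) pairs per transect, restricted to one habitat stratum."""
    groups = []
    for _, row in layout.table.iterrows():
        tid = row["transect_id"]
        sub = obs[obs["transect_id"] == tid]
        if habitat is not None:
            sub = sub[sub["habitat"] == habitat]
            effort = float(row[habitat]) if habitat in layout.habitats else 0.0
        else:
            effort = float(row["length_km"])
        groups.append((len(sub), effort))
    return groups


def _bootstrap_density(groups, unit_factor: float, B: int, seed: int):
    """Bootstrap a count/effort density with a fixed detection scaling.

    ``unit_factor`` converts the pooled encounter rate n/L into the density
    scale (e.g. f0·1000/2 for SCNC); detection is held fixed across
    resamples, so the interval reflects encounter-rate variance between
    transects.
    """

    def estimator(resampled):
        n = sum(g[0] for g in resampled)
        L = sum(g[1] for g in resampled)
        if L <= 0:
            raise NumericalError("zero effort in resample")
        return unit_factor * n / L

    return bootstrap_ci(groups, estimator, B=B, seed=seed)


def run_scnc(
    obs: pd.DataFrame,
    layout: TransectLayout,
    w: float,
    year: int | None = None,
    per_habitat: bool = True,
    areas_km2: dict[str, float] | None = None,
    candidates=None,
    stepwise: bool = True,
    decay: DecayRate | None = None,
    production: ProductionRate | None = None,
    B: int = 999,
    seed: int = 0,
) -> ScncResult:
    """Standing-crop line-transect pipeline.

    Uses first-visit observations (optionally of one year), truncates at
    ``w`` (m), fits/selects a detection function (pooled, or one per habitat
    when ``per_habitat``), forms per-stratum nest densities, bootstraps
    transects for CIs, and area-weights strata into a global estimate when
    ``areas_km2`` is given.  If ``decay`` and ``production`` are supplied the
    nest densities are additionally converted to builder densities.
    """
    first = _first_visit(obs, year)
    sample = truncate(first, w=w)
    log.info("scnc: %d observations read, %d retained at w=%.1f m",
             len(first), sample.n, sample.w)

    strata = (
        sample.by_habitat() if per_habitat else {"pooled": sample}
    )
    selections: dict[str, ModelSelection] = {}
    estimates: dict[str, DensityEstimate] = {}
    rates: dict[str, float] = {}
    habitats = list(strata)
    pooled_sel: ModelSelection | None = None
    for h, sub in strata.items():
        try:
            selections[h] = _select(sub, candidates, stepwise, seed)
        except NumericalError as exc:
            # sparse stratum: fall back to the pooled detection function
            if pooled_sel is None:
                pooled_sel = _select(sample, candidates, stepwise, seed)
            log.warning("scnc: stratum %s detection fit failed (%s); "
                        "using pooled fit", h, exc)
            selections[h] = pooled_sel

    truncated_table = first[first["distance_m"] <= sample.w]
    for h in habitats:
        sel = selections[h]
        f0 = sel.best.f0
        hab = None if h == "pooled" else h
        n = int(
            len(truncated_table)
            if hab is None
            else (truncated_table["habitat"] == hab).sum()
        )
        effort = layout.effort_km(hab)
        if effort <= 0:
            raise SchemaError(f"no effort recorded for habitat {h!r}")
        est = scnc_nest_density(n, f0, effort, stratum=h)
        groups = _transect_counts(truncated_table, layout, hab)
        unit_factor = f0 * 1000.0 / 2.0
        cv, lo, hi = _bootstrap_density(groups, unit_factor, B=B, seed=seed)
        estimates[h] = DensityEstimate(
            value=est.value, stratum=h, cv=cv,
            ci_low=min(lo, est.value), ci_high=max(hi, est.value),
            n=n, effort_km=effort, estimator="scnc",
        )
        rates[h] = encounter_rate(n, effort)

    if per_habitat and areas_km2 is not None:
        global_est = habitat_weighted_mean(estimates, areas_km2)
    elif per_habitat:
        # fall back to effort weights when no areas are supplied
        areas = {h: layout.effort_km(h) for h in estimates}
        global_est = habitat_weighted_mean(estimates, areas)
    else:
        global_est = estimates["pooled"]

    if decay is not None and production is not None:
        estimates = {
            h: builders_from_nests(e, decay, production) for h, e in estimates.items()
        }
        global_est = builders_from_nests(global_est, decay, production)

    return ScncResult(
        per_habitat=estimates, global_estimate=global_est,
        selection=selections, encounter_rates=rates, sample=sample,
    )


def run_mnc(
    obs: pd.DataFrame,
    layout: TransectLayout,
    w: float,
    t_days: float,
    production: ProductionRate,
    year: int | None = None,
    per_habitat: bool = True,
    areas_km2: dict[str, float] | None = None,
    candidates=None,
    stepwise: bool = True,
    tau: float = 0.9,
    B: int = 999,
    seed: int = 0,
) -> MncResult:
    """Marked-nest-count strip-transect pipeline.

    Uses new-nest observations (``is_new == 1``, second visit onward),
    truncates at ``w``, selects a detection function, takes the strip
    half-width s from the detection shoulder (retention ``tau``), counts new
    nests within s and applies the strip estimator with elapsed time
    ``t_days`` and production rate ``production``.
    """
    if "is_new" not in obs.columns:
        raise SchemaError("MNC needs the is_new flag in the observation table")
    new = obs[obs["is_new"] == 1]
    if year is not None:
        new = new[new["year"] == year]
    if len(new) == 0:
        raise SchemaError("no marked-nest (is_new=1) observations")
    sample = truncate(new, w=w)
    log.info("mnc: %d new-nest observations, %d retained at w=%.1f m",
             len(new), sample.n, sample.w)

    strata = sample.by_habitat() if per_habitat else {"pooled": sample}
    selections = {}
    widths = {}
    estimates = {}
    truncated_table = new[new["distance_m"] <= sample.w]
    pooled_sel: ModelSelection | None = None
    for h, sub in strata.items():
        try:
            selections[h] = _select(sub, candidates, stepwise, seed)
        except NumericalError as exc:
            if pooled_sel is None:
                pooled_sel = _select(sample, candidates, stepwise, seed)
            log.warning("mnc: stratum %s detection fit failed (%s); "
                        "using pooled fit", h, exc)
            selections[h] = pooled_sel
        s_m = strip_half_width(selections[h].best, tau=tau)
        widths[h] = s_m
        hab = None if h == "pooled" else h
        in_strip = truncated_table[truncated_table["distance_m"] <= s_m]
        if hab is not None:
            in_strip = in_strip[in_strip["habitat"] == hab]
        n_new = len(in_strip)
        effort = layout.effort_km(hab)
        est = mnc_builder_density(n_new, effort, s_m, t_days, production.p, stratum=h)
        groups = _transect_counts(in_strip, layout, hab)
        unit_factor = 1.0 / (2.0 * (s_m / 1000.0) * t_days * production.p)
        cv, lo, hi = _bootstrap_density(groups, unit_factor, B=B, seed=seed)
        estimates[h] = DensityEstimate(
            value=est.value, stratum=h, cv=cv,
            ci_low=min(lo, est.value), ci_high=max(hi, est.value),
            n=n_new, effort_km=effort, estimator="mnc",
        )

    if per_habitat:
        areas = areas_km2 or {h: layout.effort_km(h) for h in estimates}
        global_est = habitat_weighted_mean(estimates, areas)
    else:
        global_est = estimates["pooled"]
    return MncResult(
        per_habitat=estimates, global_estimate=global_est,
        selection=selections, strip_half_widths_m=widths, t_days=t_days,
    )


def recover_decay_rate(
    scnc: ScncResult, mnc: MncResult, production: ProductionRate
) -> DecayRate:
    """Back-calculate mean nest lifetime from an SCNC nest density and an
    MNC builder density estimated on the same survey."""
    return solve_decay_rate(
        scnc.global_estimate, mnc.global_estimate, production,
        cvs=[c for c in (scnc.global_estimate.cv, mnc.global_estimate.cv,
                         production.cv) if np.isfinite(c)],
    )
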