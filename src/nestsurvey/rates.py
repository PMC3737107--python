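"""Conversions between nest density and nest-builder density.

At stationarity, standing nest density, builder density, daily nest
production p (nests per builder per day) and mean nest decay time r (days)
are linked by

    D_nest = D_builder * p * r.

Rearranged, r can be back-calculated from an independent pair of nest and
builder density estimates, and an SCNC nest density can be converted to a
builder density given (r, p).  CVs of products/quotients of independent
estimates combine by the delta method: squared CVs add.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .density import DensityEstimate
from .errors import SchemaError

__all__ = [
    "ProductionRate",
    "DecayRate",
    "solve_decay_rate",
    "delta_cv",
    "builders_from_nests",
    "population_size",
    "PopulationSize",
]

@dataclass(frozen=True)
class ProductionRate:
    """Nests built per nest-building animal per day."""

    p: float
    cv: float = 0.0

    def __post_init__(self):
        if not self.p > 0:
            raise SchemaError("production rate must be positive")
        if self.cv < 0:
            raise SchemaError("CV cannot be negative")


@dataclass(frozen=True)
class DecayRate:
    """Mean nest lifetime (days until a nest becomes undetectable)."""

    r: float
    cv: float = np.nan

    def __post_init__(self):
        if not self.r > 0:
            raise SchemaError("decay rate must be positive")


#: published daily nest production rate (nests/builder/day) from Taï NP,
#: with its CV; the conventional import when no local estimate exists
TAI_PRODUCTION = ProductionRate(p=1.143, cv=0.0351)


def _as_value(x) -> float:
    return x.value if isinstance(x, DensityEstimate) else float(x)


def solve_decay_rate(
    d_nests,
    d_builders,
    production: ProductionRate | float,
    cvs: Iterable[float] | None = None,
) -> DecayRate:
    """Back-calculate mean nest decay time r = D_nest / (D_builder * p).

    ``d_nests`` and ``d_builders`` may be plain densities (per km²) or
    :class:`DensityEstimate` objects.  If ``cvs`` is given (the CVs of the
    inputs), the CV of r is propagated by the delta method.
    """
    p = production if isinstance(production, ProductionRate) else ProductionRate(float(production))
    dn = _as_value(d_nests)
    db = _as_value(d_builders)
    if not dn > 0:
        raise SchemaError("nest density must be positive to solve for decay")
    if not db > 0:
        raise SchemaError("decay rate undefined: builder density must be positive")
    r = dn / (db * p.p)
    cv = delta_cv(cvs) if cvs is not None else np.nan
    return DecayRate(r=float(r), cv=cv)


def delta_cv(cvs: Iterable[float]) -> float:
    """Delta-method CV of a product/quotient of independent estimates:
    sqrt(sum cv_i^2)."""
    arr = np.asarray(list(cvs), dtype=float)
    if np.any(arr < 0):
        raise SchemaError("CVs cannot be negative")
    return float(np.sqrt(np.sum(arr**2)))


def builders_from_nests(
    d_nests,
    decay: DecayRate | float,
    production: ProductionRate | float,
    propagate_rate_cvs: bool = False,
) -> DensityEstimate:
    """Convert a standing-crop nest density into builder density,
    D_builder = D_nest / (r * p).

    By default the CV and the relative CI of the nest density are carried
    over unchanged (r and p treated as constants); with
    ``propagate_rate_cvs`` their CVs are folded in by the delta method and
    the CI is rebuilt lognormally from the combined CV.
    """
    r = decay if isinstance(decay, DecayRate) else DecayRate(float(decay))
    p = production if isinstance(production, ProductionRate) else ProductionRate(float(production))
    if isinstance(d_nests, DensityEstimate):
        est = d_nests
    else:
        est = DensityEstimate(value=float(d_nests))
    factor = 1.0 / (r.r * p.p)
    out = est.scaled(factor, estimator="scnc-converted")
    if propagate_rate_cvs:
        parts = [est.cv if np.isfinite(est.cv) else 0.0]
        if np.isfinite(r.cv):
            parts.append(r.cv)
        parts.append(p.cv)
        cv = delta_cv(parts)
        lo, hi = _lognormal_ci(out.value, cv)
        out = DensityEstimate(
            value=out.value, stratum=out.stratum, cv=cv, ci_low=lo, ci_high=hi,
            n=out.n, effort_km=out.effort_km, estimator=out.estimator,
        )
    return out


def _lognormal_ci(value: float, cv: float, z: float = 1.959964) -> tuple[float, float]:
    """Lognormal 95% interval for a positive estimate with given CV."""
    if value <= 0 or cv <= 0:
        return value, value
    c = np.exp(z * np.sqrt(np.log(1.0 + cv**2)))
    return value / c, value * c


@dataclass(frozen=True)
class PopulationSize:
    """Abundance over a reference area, with the unrounded value retained."""

    n: int
    n_exact: float
    ci_low: float
    ci_high: float
    area_km2: float


def population_size(density: DensityEstimate, area_km2: float) -> PopulationSize:
    """Scale a density (per km²) to a population size over ``area_km2``.

    CI endpoints scale identically; the headline count is rounded to the
    nearest integer while the exact product is retained.
    """
    if not area_km2 > 0:
        raise SchemaError("area must be positive")
    n_exact = density.value * area_km2
    lo = density.ci_low * area_km2 if np.isfinite(density.ci_low) else np.nan
    hi = density.ci_high * area_km2 if np.isfinite(density.ci_high) else np.nan
    return PopulationSize(
        n=int(round(n_exact)), n_exact=float(n_exact),
        ci_low=float(lo), ci_high=float(hi), area_km2=float(area_km2),
    )
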