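"""Line-transect detection functions for nest surveys.

Implements conventional distance sampling (CDS) detection-function fitting
for perpendicular nest distances: a key function (uniform or half-normal)
times a cosine adjustment series,

    g(y) = key(y) * [1 + sum_{j=1..m} a_j cos(j*pi*y/w)],   0 <= y <= w,

fitted by maximum likelihood on truncated distances, selected by AIC, and
checked with chi-square / Kolmogorov-Smirnov / Cramér-von Mises
goodness-of-fit tests.  The quantity carried forward to density estimation
is f(0), the fitted probability density of detection distances at zero;
1/f(0) is the effective strip half-width.

Shape constraints follow standard CDS practice: the fitted g must be
nonnegative and (numerically) non-increasing on a 512-point grid, so that a
detection "shoulder" is meaningful and the strip half-width rule applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import NumericalError, SchemaError

KEYS = ("uniform", "half-normal")

_CONSTRAINT_GRID_N = 512
_MONOTONE_TOL = 1e-6
_QUAD_N = 128  # Gauss-Legendre nodes for the normalizing integral
_CDF_GRID_N = 4097

__all__ = [
    "DistanceSample",
    "DetectionModelSpec",
    "DetectionFit",
    "GofReport",
    "ModelSelection",
    "truncate",
    "fit_detection",
    "select_detection_model",
    "select_stepwise",
    "goodness_of_fit",
    "strip_half_width",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DistanceSample:
    """Truncated perpendicular detection distances with survey labels.

    Distances are in metres; ``w`` is the truncation distance.  Records
    removed by truncation are tallied in ``n_discarded`` (they are not
    carried, only counted).  Label arrays are optional and, when present,
    are aligned with ``distances``.
    """

    distances: np.ndarray
    w: float
    habitat: np.ndarray | None = None
    transect_id: np.ndarray | None = None
    visit: np.ndarray | None = None
    year: np.ndarray | None = None
    n_discarded: int = 0

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 1:
            raise SchemaError("distances must be one-dimensional")
        if self.distances.size == 0:
            raise SchemaError("no observations")
        if not np.all(np.isfinite(self.distances)):
            raise SchemaError("non-finite distance encountered")
        if np.any(self.distances < 0):
            raise SchemaError("negative perpendicular distance")
        if not self.w > 0:
            raise SchemaError(f"truncation distance w must be > 0, got {self.w}")
        if np.any(self.distances > self.w):
            raise SchemaError("distance beyond truncation distance w")
        for name in ("habitat", "transect_id", "visit", "year"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.distances.shape:
                    raise SchemaError(f"label array {name!r} misaligned with distances")
                setattr(self, name, arr)

    @property
    def n(self) -> int:
        return int(self.distances.size)

    def subset(self, mask: np.ndarray) -> "DistanceSample":
        mask = np.asarray(mask, dtype=bool)
        labels = {
            name: (getattr(self, name)[mask] if getattr(self, name) is not None else None)
            for name in ("habitat", "transect_id", "visit", "year")
        }
        return DistanceSample(self.distances[mask], self.w, n_discarded=0, **labels)

    def by_habitat(self) -> dict[str, "DistanceSample"]:
        """Split into per-habitat samples sharing this sample's w."""
        if self.habitat is None:
            raise SchemaError("sample has no habitat labels")
        return {
            str(h): self.subset(self.habitat == h) for h in np.unique(self.habitat)
        }


@dataclass(frozen=True)
class DetectionModelSpec:
    """Key function plus cosine adjustment order."""

    key: str
    n_adjustments: int = 0

    def __post_init__(self):
        if self.key not in KEYS:
            raise SchemaError(f"unknown key function {self.key!r}; expected one of {KEYS}")
        if self.n_adjustments < 0:
            raise SchemaError("n_adjustments must be >= 0")

    @property
    def n_free_params(self) -> int:
        return (1 if self.key == "half-normal" else 0) + self.n_adjustments

    def __str__(self) -> str:
        return f"{self.key}+cos({self.n_adjustments})" if self.n_adjustments else self.key


@dataclass
class DetectionFit:
    """A fitted detection function on [0, w]."""

    spec: DetectionModelSpec
    sigma: float | None  # half-normal scale (m); None for uniform key
    adjustments: np.ndarray  # cosine coefficients a_1..a_m
    w: float
    f0: float  # fitted pdf of detection distances at 0 (1/m)
    loglik: float
    aic: float
    n: int
    _mu: float = field(repr=False, default=np.nan)  # integral of g over [0, w]
    _cdf_grid: tuple[np.ndarray, np.ndarray] | None = field(
        repr=False, default=None, compare=False
    )

    @property
    def n_free_params(self) -> int:
        return self.spec.n_free_params

    @property
    def effective_half_width_m(self) -> float:
        return 1.0 / self.f0

    def g(self, y) -> np.ndarray:
        """Unnormalized detection function (g(0) = 1 + sum a_j)."""
        return _g(np.asarray(y, dtype=float), self.spec.key, self.sigma,
                  self.adjustments, self.w)

    def pdf(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        out = self.g(y) / self._mu
        return np.where((y >= 0) & (y <= self.w), out, 0.0)

    def cdf(self, y) -> np.ndarray:
        if self._cdf_grid is None:
            xs = np.linspace(0.0, self.w, _CDF_GRID_N)
            dens = self.pdf(xs)
            cum = np.concatenate(
                [[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(xs))]
            )
            cum /= cum[-1]
            self._cdf_grid = (xs, cum)
        xs, cum = self._cdf_grid
        return np.interp(np.asarray(y, dtype=float), xs, cum, left=0.0, right=1.0)


@dataclass
class GofReport:
    chisq_stat: float
    chisq_df: int
    chisq_p: float
    ks_stat: float
    ks_p: float
    cvm_stat: float
    cvm_p: float

    def passed(self, alpha: float = 0.05) -> bool:
        return min(self.chisq_p, self.ks_p, self.cvm_p) > alpha


@dataclass
class ModelSelection:
    """Outcome of AIC model selection over a candidate set."""

    best: DetectionFit
    delta_aic: float | None  # AIC(runner-up) - AIC(best); None if single candidate
    table: pd.DataFrame  # one row per candidate: model, k, loglik, aic, status


# ---------------------------------------------------------------------------
# truncation


def truncate(
    obs,
    w: float | None = None,
    discard_fraction: float | None = None,
) -> DistanceSample:
    """Truncate raw perpendicular distances at a fixed ``w`` or by discarding
    the largest fraction of observations.

    ``obs`` may be an observation DataFrame (column ``distance_m`` plus
    optional label columns) or a plain sequence of distances.  With the
    fraction rule, ``w`` becomes the largest retained distance.
    """
    if (w is None) == (discard_fraction is None):
        raise SchemaError("specify exactly one of w or discard_fraction")

    labels: dict[str, np.ndarray | None] = {
        "habitat": None, "transect_id": None, "visit": None, "year": None,
    }
    if isinstance(obs, pd.DataFrame):
        if "distance_m" not in obs.columns:
            raise SchemaError("observation table lacks column 'distance_m'")
        dist = obs["distance_m"].to_numpy(dtype=float)
        for name in labels:
            if name in obs.columns:
                labels[name] = obs[name].to_numpy()
    else:
        dist = np.asarray(obs, dtype=float)

    if dist.size == 0:
        raise SchemaError("no observations")
    if np.any(~np.isfinite(dist)) or np.any(dist < 0):
        raise SchemaError("distances must be finite and nonnegative")

    if w is not None:
        if not w > 0:
            raise SchemaError(f"truncation distance w must be > 0, got {w}")
        keep = dist <= w
        w_out = float(w)
        if np.isinf(w):
            w_out = float(np.inf)
    else:
        if not (0.0 <= discard_fraction < 0.5):
            raise SchemaError("discard_fraction must lie in [0, 0.5)")
        n_drop = int(np.ceil(discard_fraction * dist.size - 1e-12))
        if n_drop == 0:
            keep = np.ones_like(dist, dtype=bool)
        else:
            cutoff_idx = np.argsort(dist, kind="stable")[: dist.size - n_drop]
            keep = np.zeros_like(dist, dtype=bool)
            keep[cutoff_idx] = True
        if not keep.any():
            raise SchemaError("truncation removed every observation")
        w_out = float(dist[keep].max())

    if not keep.any():
        raise SchemaError("truncation removed every observation")
    kept_labels = {
        name: (arr[keep] if arr is not None else None) for name, arr in labels.items()
    }
    return DistanceSample(
        dist[keep],
        w_out,
        n_discarded=int(dist.size - keep.sum()),
        **kept_labels,
    )


# ---------------------------------------------------------------------------
# model evaluation


def _key_fn(key: str, y: np.ndarray, sigma: float | None) -> np.ndarray:
    if key == "uniform":
        return np.ones_like(y)
    return np.exp(-0.5 * (y / sigma) ** 2)


def _series(y: np.ndarray, a: np.ndarray, w: float) -> np.ndarray:
    if a.size == 0:
        return np.ones_like(y)
    j = np.arange(1, a.size + 1)
    return 1.0 + np.cos(np.multiply.outer(y, j) * (np.pi / w)) @ a


def _g(y: np.ndarray, key: str, sigma: float | None, a: np.ndarray, w: float) -> np.ndarray:
    return _key_fn(key, y, sigma) * _series(y, a, w)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_QUAD_N)


def _integral_g(key: str, sigma: float | None, a: np.ndarray, w: float) -> float:
    """∫₀ʷ g via Gauss-Legendre; exact to machine precision for these smooth g."""
    x = 0.5 * w * (_GL_NODES + 1.0)
    return float(0.5 * w * _GL_WEIGHTS @ _g(x, key, sigma, a, w))


def _constraint_violation(key, sigma, a, w, grid) -> float:
    gv = _g(grid, key, sigma, a, w)
    neg = float(np.maximum(0.0, -gv).max(initial=0.0))
    rising = float(np.maximum(0.0, np.diff(gv) - _MONOTONE_TOL).max(initial=0.0))
    return max(neg, rising)


# ---------------------------------------------------------------------------
# fitting


def _unpack(theta: np.ndarray, key: str) -> tuple[float | None, np.ndarray]:
    if key == "half-normal":
        return float(theta[0]), np.asarray(theta[1:], dtype=float)
    return None, np.asarray(theta, dtype=float)


def _neg_loglik(theta, y, key, w, grid) -> float:
    sigma, a = _unpack(np.asarray(theta, dtype=float), key)
    gy = _g(y, key, sigma, a, w)
    if np.any(gy <= 0.0):
        return 1e12
    mu = _integral_g(key, sigma, a, w)
    if not mu > 0:
        return 1e12
    nll = -(np.sum(np.log(gy)) - y.size * np.log(mu))
    # hinge on the shape constraints (no slack, linear + quadratic) drives the
    # optimizer strictly inside the monotone nonnegative region; hard
    # feasibility at the 1e-6 tolerance is re-checked afterwards
    gv = _g(grid, key, sigma, a, w)
    neg = np.maximum(0.0, -gv)
    rise = np.maximum(0.0, np.diff(gv))
    viol_lin = neg.sum() + rise.sum()
    viol_sq = np.square(neg).sum() + np.square(rise).sum()
    return nll + 1e4 * viol_lin + 1e6 * viol_sq


def fit_detection(
    sample: DistanceSample,
    spec: DetectionModelSpec,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> DetectionFit:
    """Maximum-likelihood fit of a detection model to truncated distances.

    Uses bounded quasi-Newton (L-BFGS-B) from ``n_restarts`` jittered starting
    points (deterministic given ``seed``).  Raises :class:`NumericalError` if
    the sample is too small for the parameter count (n < 5·(1+m)) or if no
    restart converges to a shape-admissible optimum.
    """
    y = sample.distances
    w = float(sample.w)
    n = y.size
    if not np.isfinite(w):
        raise SchemaError("truncation distance must be finite for fitting")
    m = spec.n_adjustments
    # rough sample-size floor for the adjustment series; a bare key function
    # is allowed down to very small n so strata stay fittable
    if m >= 1 and n < 5 * (1 + m):
        raise NumericalError(
            f"overparameterized: n={n} observations cannot support m={m} "
            f"adjustment terms (need n >= {5 * (1 + m)})"
        )

    k = spec.n_free_params
    if k == 0:
        # uniform key, no adjustments: f is flat 1/w, no free parameters
        loglik = -n * np.log(w)
        return DetectionFit(
            spec=spec, sigma=None, adjustments=np.empty(0), w=w,
            f0=1.0 / w, loglik=float(loglik), aic=float(-2.0 * loglik),
            n=n, _mu=w,
        )

    grid = np.linspace(0.0, w, _CONSTRAINT_GRID_N)
    rng = np.random.default_rng(seed)

    sigma0 = float(np.std(y))
    if not sigma0 > 0:
        sigma0 = w / 4.0
    if spec.key == "half-normal":
        theta0 = np.concatenate([[sigma0], np.zeros(m)])
        bounds = [(w * 1e-3, w * 20.0)] + [(-5.0, 5.0)] * m
    else:
        theta0 = np.zeros(m)
        bounds = [(-5.0, 5.0)] * m

    best = None
    best_nll = np.inf
    attempts = []
    for r in range(n_restarts):
        start = theta0.copy()
        if r > 0:
            if spec.key == "half-normal":
                start[0] *= float(np.exp(rng.normal(0.0, 0.5)))
                start[1:] += rng.normal(0.0, 0.3, size=m)
            else:
                start += rng.normal(0.0, 0.3, size=m)
            start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _neg_loglik, start, args=(y, spec.key, w, grid),
            method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        attempts.append(res)
        sigma, a = _unpack(res.x, spec.key)
        feasible = _constraint_violation(spec.key, sigma, a, w, grid) <= _MONOTONE_TOL
        if res.fun < best_nll and feasible and res.fun < 1e11:
            best_nll = float(res.fun)
            best = res

    if best is None:
        raise NumericalError(
            f"detection fit failed for {spec}: no restart reached a "
            "shape-admissible optimum",
            diagnostics={
                "best_objective": float(min(a.fun for a in attempts)),
                "messages": [str(a.message) for a in attempts],
            },
        )

    sigma, a = _unpack(best.x, spec.key)
    mu = _integral_g(spec.key, sigma, a, w)
    g0 = float(_g(np.array([0.0]), spec.key, sigma, a, w)[0])
    f0 = g0 / mu
    loglik = float(np.sum(np.log(_g(y, spec.key, sigma, a, w))) - n * np.log(mu))
    return DetectionFit(
        spec=spec, sigma=sigma, adjustments=a, w=w,
        f0=float(f0), loglik=loglik, aic=float(2.0 * k - 2.0 * loglik),
        n=n, _mu=float(mu),
    )


# ---------------------------------------------------------------------------
# model selection


def select_detection_model(
    sample: DistanceSample,
    candidates: Sequence[DetectionModelSpec],
    **fit_kwargs,
) -> ModelSelection:
    """Fit each candidate and return the minimum-AIC fit.

    Ties (AIC equal to within 1e-9) are broken in favour of fewer free
    parameters.  The result carries ΔAIC to the runner-up and a table of all
    candidates including those that failed to fit.
    """
    if len(candidates) == 0:
        raise SchemaError("no candidate models supplied")
    fits: list[DetectionFit] = []
    rows = []
    failures = []
    for spec in candidates:
        try:
            fit = fit_detection(sample, spec, **fit_kwargs)
        except (NumericalError, SchemaError) as exc:
            failures.append((spec, exc))
            rows.append({"model": str(spec), "k": spec.n_free_params,
                         "loglik": np.nan, "aic": np.nan, "status": f"failed: {exc}"})
            continue
        fits.append(fit)
        rows.append({"model": str(spec), "k": spec.n_free_params,
                     "loglik": fit.loglik, "aic": fit.aic, "status": "ok"})
    if not fits:
        raise NumericalError(
            "all candidate detection models failed to fit: "
            + "; ".join(f"{s}: {e}" for s, e in failures)
        )
    order = sorted(fits, key=lambda f: (round(f.aic, 9), f.n_free_params))
    best = order[0]
    delta = float(order[1].aic - best.aic) if len(order) > 1 else None
    table = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    return ModelSelection(best=best, delta_aic=delta, table=table)


def select_stepwise(
    sample: DistanceSample,
    keys: Iterable[str] = KEYS,
    max_adjustments: int = 3,
    **fit_kwargs,
) -> ModelSelection:
    """Forward-stepwise cosine-order search for each key, then AIC selection.

    For each key function, adjustment terms are added one at a time while the
    AIC keeps decreasing (up to ``max_adjustments``); the per-key best models
    are then compared by AIC across keys.
    """
    candidates: list[DetectionModelSpec] = []
    for key in keys:
        prev_aic = np.inf
        for m in range(0, max_adjustments + 1):
            spec = DetectionModelSpec(key, m)
            try:
                fit = fit_detection(sample, spec, **fit_kwargs)
            except (NumericalError, SchemaError):
                break
            candidates.append(spec)
            if fit.aic >= prev_aic:
                break
            prev_aic = fit.aic
    if not candidates:
        raise NumericalError("stepwise search produced no fittable model")
    return select_detection_model(sample, candidates, **fit_kwargs)


# ---------------------------------------------------------------------------
# goodness of fit


def goodness_of_fit(
    fit: DetectionFit,
    sample: DistanceSample,
    n_bins: int | None = None,
) -> GofReport:
    """Chi-square (equal-width bins), KS and Cramér-von Mises tests of the
    fitted distance density against the observed distances.

    P-values are naive (parameters treated as known), as conventional
    distance-sampling software reports them; with estimated parameters they
    are mildly conservative.
    """
    y = sample.distances
    n = y.size
    if abs(fit.w - sample.w) > 1e-9:
        raise SchemaError("fit and sample disagree on truncation distance w")
    if n_bins is None:
        n_bins = min(10, n // 5)
    if n_bins < 2:
        raise SchemaError("need at least 2 bins for the chi-square test")
    k = fit.n_free_params
    df = n_bins - 1 - k
    if df < 1:
        raise SchemaError(
            f"chi-square df = {n_bins} - 1 - {k} < 1; increase n_bins"
        )
    edges = np.linspace(0.0, fit.w, n_bins + 1)
    cdf_edges = fit.cdf(edges)
    expected = n * np.diff(cdf_edges)
    if np.any(expected < 1.0):
        raise NumericalError(
            "expected count < 1 in a chi-square bin; use fewer bins"
        )
    observed, _ = np.histogram(y, bins=edges)
    chisq = float(np.sum((observed - expected) ** 2 / expected))
    chisq_p = float(stats.chi2.sf(chisq, df))

    ks = stats.kstest(y, fit.cdf)
    cvm = stats.cramervonmises(y, fit.cdf)
    return GofReport(
        chisq_stat=chisq, chisq_df=int(df), chisq_p=chisq_p,
        ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
        cvm_stat=float(cvm.statistic), cvm_p=float(cvm.pvalue),
    )


# ---------------------------------------------------------------------------
# strip half-width from the detection shoulder


def strip_half_width(fit: DetectionFit, tau: float = 0.9) -> float:
    """Width of the detection shoulder: the largest x in [0, w] with
    g(x)/g(0) >= tau.

    This operationalizes choosing a strip-transect half-width as the distance
    over which detection remains near certain.  For a flat (uniform, no
    adjustment) detection function the shoulder spans the whole truncated
    strip, s = w.
    """
    if not (0.0 < tau <= 1.0):
        raise SchemaError("tau must lie in (0, 1]")
    xs = np.linspace(0.0, fit.w, _CDF_GRID_N)
    ratio = fit.g(xs) / fit.g(0.0)
    ok = ratio >= tau
    if ok.all():
        return float(fit.w)
    if not ok[0]:
        return 0.0
    i = int(np.max(np.nonzero(ok)[0]))
    lo, hi = xs[i], xs[i + 1]
    g0 = float(fit.g(0.0))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if fit.g(mid) / g0 >= tau:
            lo = mid
        else:
            hi = mid
    return float(lo)
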