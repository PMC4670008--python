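"""Developmental-rate response models in oxygen and temperature.

Six candidate families describe total developmental time against a single
predictor: linear, exponential (a*e^(b*x)), logarithmic (a + b*ln x),
quadratic, cubic, and inverse-proportional (a + b/x, the Monod-style law).
Family selection maximizes the Pearson correlation between fitted and
observed responses on the original scale, with exact ties broken by
parsimony; families that would saturate the design (parameter count >= number
of distinct predictor values) are excluded as unselectable by goodness of
fit.

Temperature enters the Arrhenius-style fits as 1/T with T in degrees Celsius.
This is nonstandard (an Arrhenius law is usually written in kelvin) but it is
the scale on which a ~2x slowdown over 17.5->27.5 C comes out with
coefficients of the printed magnitude, and the fit is purely empirical.

The combined oxygen-by-temperature response is chosen from a declared
catalogue of surfaces combining an exponential temperature component with
inverse-proportional oxygen components, fitted by nonlinear least squares and
selected by adjusted R^2.  Every candidate surface is multiplicatively
separable in temperature, so the selected surface is a compromise across
temperatures and can depart from the individual per-temperature fits.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .data_model import ANCHOR_END, ANCHOR_START, Dataset, total_dev_time
from .errors import (
    DegenerateDesignError,
    DomainError,
    FitError,
    SampleSizeError,
    SelectionError,
)

logger = logging.getLogger(__name__)

#: Fixed family order (selection tie-break of last resort).
FAMILIES: tuple[str, ...] = (
    "linear",
    "exponential",
    "logarithmic",
    "quadratic",
    "cubic",
    "inverse_proportional",
)

PARAM_COUNTS: dict[str, int] = {
    "linear": 2,
    "exponential": 2,
    "logarithmic": 2,
    "quadratic": 3,
    "cubic": 4,
    "inverse_proportional": 2,
}

_NLS_MAX_ITER = 200
_NLS_TOL = 1e-10


@dataclass
class ModelFit:
    """A fitted single-predictor response model.

    ``parameters`` are ordered (a, b) for the two-parameter families —
    a + b*x, a*e^(b*x), a + b*ln x, a + b/x — and low-to-high degree
    coefficients for polynomials.  ``pearson_r`` correlates fitted with
    observed responses on the original scale so families are comparable.
    """

    family: str
    parameters: tuple[float, ...]
    pearson_r: float
    adjusted_r2: float
    n: int
    sse: float
    zero_variance: bool = False
    predictor: str = "x"

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        p = self.parameters
        if self.family == "linear":
            return p[0] + p[1] * x
        if self.family == "exponential":
            return p[0] * np.exp(p[1] * x)
        if self.family == "logarithmic":
            return p[0] + p[1] * np.log(x)
        if self.family in ("quadratic", "cubic"):
            return np.polyval(p[::-1], x)
        if self.family == "inverse_proportional":
            return p[0] + p[1] / x
        raise ValueError(f"unknown family {self.family!r}")


def _fit_metrics(y: np.ndarray, yhat: np.ndarray, n_params: int) -> tuple[float, float, float, bool]:
    resid = y - yhat
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0, 0.0, sse, True
    if np.std(yhat) == 0.0:
        r = 0.0
    else:
        r = float(np.corrcoef(yhat, y)[0, 1])
    r2 = 1.0 - sse / sst
    n = y.size
    if n - n_params - 1 > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    else:
        # saturated or near-saturated fit: adjusted R^2 is undefined unless exact
        adj = 1.0 if sse <= 1e-12 * max(sst, 1.0) else float("nan")
    return r, adj, sse, False


def _ols_design(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def fit_family(x, y, family: str, predictor: str = "x") -> ModelFit:
    """Least-squares fit of one model family.

    Requires n >= parameter count + 1 and more distinct predictor values than
    parameters; logarithmic/inverse families require x > 0, and exponential
    fitting requires y > 0 (log-linear initialization).
    """
    if family not in PARAM_COUNTS:
        raise ValueError(f"unknown family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    k = PARAM_COUNTS[family]
    if x.size < k + 1:
        raise SampleSizeError(f"{family}: need at least {k + 1} points, got {x.size}")
    if np.unique(x).size < k:
        raise DegenerateDesignError(
            f"{family}: {np.unique(x).size} distinct predictor values cannot "
            f"identify {k} parameters"
        )
    if family in ("logarithmic", "inverse_proportional") and (x <= 0).any():
        raise DomainError(f"{family}: predictor must be strictly positive")
    if family == "exponential" and (y <= 0).any():
        raise DomainError("exponential: response must be strictly positive to initialize")

    ones = np.ones_like(x)
    if family == "linear":
        params = tuple(_ols_design(np.column_stack([ones, x]), y))
    elif family == "logarithmic":
        params = tuple(_ols_design(np.column_stack([ones, np.log(x)]), y))
    elif family == "inverse_proportional":
        params = tuple(_ols_design(np.column_stack([ones, 1.0 / x]), y))
    elif family in ("quadratic", "cubic"):
        deg = 2 if family == "quadratic" else 3
        cols = np.column_stack([x**d for d in range(deg + 1)])
        params = tuple(_ols_design(cols, y))
    else:  # exponential, on the original scale with log-linear initialization
        lin = _ols_design(np.column_stack([ones, x]), np.log(y))
        p0 = (math.exp(lin[0]), lin[1])
        try:
            with warnings.catch_warnings():
                # the parameter covariance is unused; flat data make it singular
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    lambda t, a, b: a * np.exp(b * t),
                    x,
                    y,
                    p0=p0,
                    maxfev=_NLS_MAX_ITER * (x.size + 1),
                    xtol=_NLS_TOL,
                    ftol=_NLS_TOL,
                )
            params = tuple(float(v) for v in popt)
        except RuntimeError:
            logger.warning("exponential refinement did not converge; keeping log-linear start")
            params = p0

    fit = ModelFit(
        family=family,
        parameters=tuple(float(v) for v in params),
        pearson_r=0.0,
        adjusted_r2=0.0,
        n=int(x.size),
        sse=0.0,
        predictor=predictor,
    )
    r, adj, sse, zero_var = _fit_metrics(y, fit.predict(x), k)
    fit.pearson_r, fit.adjusted_r2, fit.sse, fit.zero_variance = r, adj, sse, zero_var
    return fit


def select_best_family(
    x,
    y,
    families: Sequence[str] = FAMILIES,
    tie_tol: float = 1e-9,
    predictor: str = "x",
) -> ModelFit:
    """Fit every admissible family and return the one with the highest
    Pearson correlation between fitted and observed responses.

    Correlations within ``tie_tol`` of the best are treated as tied and
    resolved by fewer parameters, then by fixed family order.  Families that
    cannot be fitted (domain, sample size, saturation) are skipped.
    """
    fits: list[ModelFit] = []
    reasons: dict[str, str] = {}
    n_distinct = np.unique(np.asarray(x, dtype=float)).size
    for fam in families:
        if n_distinct <= PARAM_COUNTS[fam]:
            # a saturated family reproduces the level means exactly, so
            # goodness of fit cannot rank it against the others
            reasons[fam] = f"saturated: {PARAM_COUNTS[fam]} parameters for {n_distinct} levels"
            continue
        try:
            fits.append(fit_family(x, y, fam, predictor=predictor))
        except (SampleSizeError, DegenerateDesignError, DomainError) as exc:
            reasons[fam] = str(exc)
    if not fits:
        raise SelectionError(f"no fittable family; reasons: {reasons}")
    best_r = max(f.pearson_r for f in fits)
    tied = [f for f in fits if f.pearson_r >= best_r - tie_tol]
    tied.sort(key=lambda f: (PARAM_COUNTS[f.family], FAMILIES.index(f.family)))
    return tied[0]


# ---------------------------------------------------------------------------
# dataset-level fits


def total_times(
    dataset: Dataset, anchor: str = "cellularization"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-embryo (oxygen, temperature, total developmental time).

    ``anchor='cellularization'`` measures from the end of cellularization;
    ``anchor='polebud'`` measures from pole-bud appearance when recorded,
    falling back to the cellularization anchor otherwise.  Embryos that never
    filled their trachea carry no total time and are skipped.
    """
    if anchor not in ("cellularization", "polebud"):
        raise ValueError(f"unknown anchor {anchor!r}")
    o2, temp, hours = [], [], []
    for obs in dataset:
        if ANCHOR_END not in obs.event_times:
            continue
        if anchor == "polebud" and "pole_bud_appearance" in obs.event_times:
            start = "pole_bud_appearance"
        else:
            start = ANCHOR_START
        if start not in obs.event_times:
            continue
        o2.append(obs.condition.oxygen_percent)
        temp.append(obs.condition.temperature_celsius)
        hours.append(total_dev_time(obs, start, ANCHOR_END))
    return np.asarray(o2), np.asarray(temp), np.asarray(hours)


def fit_monod_per_temperature(
    dataset: Dataset, anchor: str = "cellularization"
) -> dict[float, ModelFit]:
    """Inverse-proportional (Monod-style) fit of per-embryo total time against
    oxygen, separately at each temperature.

    Temperatures with fewer than two oxygen levels are omitted with a logged
    warning.
    """
    o2, temp, hours = total_times(dataset, anchor)
    out: dict[float, ModelFit] = {}
    for t in sorted(set(temp.tolist())):
        mask = temp == t
        if np.unique(o2[mask]).size < 2:
            logger.warning("T=%s C: single oxygen level, Monod fit omitted", t)
            continue
        out[t] = fit_family(o2[mask], hours[mask], "inverse_proportional", predictor="oxygen_percent")
    return out


def fit_arrhenius_per_oxygen(
    dataset: Dataset, anchor: str = "cellularization"
) -> dict[float, ModelFit]:
    """Exponential fit t = a * e^(b/T) of total time against temperature,
    separately at each oxygen level (T in degrees C, entering as 1/T).

    Oxygen levels with fewer than two temperatures are omitted with a warning.
    """
    o2, temp, hours = total_times(dataset, anchor)
    out: dict[float, ModelFit] = {}
    for o in sorted(set(o2.tolist())):
        mask = o2 == o
        if np.unique(temp[mask]).size < 2:
            logger.warning("O2=%s%%: single temperature, Arrhenius fit omitted", o)
            continue
        out[o] = fit_family(
            1.0 / temp[mask], hours[mask], "exponential", predictor="inverse_temperature"
        )
    return out


# ---------------------------------------------------------------------------
# combined oxygen x temperature surface


@dataclass(frozen=True)
class SurfaceForm:
    """One candidate combined-response surface t(O2, T)."""

    tag: str
    fun: Callable[..., np.ndarray]
    n_params: int
    description: str


def _sf_exp_invO_invT_monod(X, al, be, ga):
    o, t = X
    return np.exp(al / o + be / t) * (ga / o + 1.0)


def _sf_exp_invO_invT_over_linO(X, al, be, ga):
    o, t = X
    return np.exp(al / o + be / t) / (ga * o + 1.0)


def _sf_exp_linO_invT_monod(X, al, be, ga):
    o, t = X
    return np.exp(al * o + be / t) * (ga / o + 1.0)


def _sf_arrhenius_times_monod(X, al, be, ga):
    o, t = X
    return np.exp(be / t) * (al + ga / o)


DEFAULT_SURFACE_CATALOGUE: tuple[SurfaceForm, ...] = (
    SurfaceForm(
        "exp(a/O2 + b/T) * (c/O2 + 1)",
        _sf_exp_invO_invT_monod,
        3,
        "inverse-proportional oxygen inside the exponent and in the prefactor",
    ),
    SurfaceForm(
        "exp(a/O2 + b/T) / (c*O2 + 1)",
        _sf_exp_invO_invT_over_linO,
        3,
        "exponential with a linear-oxygen divisor",
    ),
    SurfaceForm(
        "exp(a*O2 + b/T) * (c/O2 + 1)",
        _sf_exp_linO_invT_monod,
        3,
        "linear oxygen inside the exponent, inverse-proportional prefactor",
    ),
    SurfaceForm(
        "exp(b/T) * (a + c/O2)",
        _sf_arrhenius_times_monod,
        3,
        "no-interaction product of the Arrhenius and Monod components",
    ),
)


@dataclass
class SurfaceFit:
    """The selected combined surface plus the full candidate audit table."""

    form_tag: str
    parameters: tuple[float, ...]
    adjusted_r2: float
    n: int
    sse: float
    candidates: list[dict] = field(default_factory=list)

    def predict(self, oxygen, temperature):
        form = next(
            f for f in DEFAULT_SURFACE_CATALOGUE if f.tag == self.form_tag
        )
        o = np.asarray(oxygen, dtype=float)
        t = np.asarray(temperature, dtype=float)
        return form.fun((o, t), *self.parameters)


def _surface_p0(form: SurfaceForm, o2: np.ndarray, temp: np.ndarray, hours: np.ndarray):
    # Arrhenius slope from condition means of log time vs 1/T
    u = 1.0 / temp
    A = np.column_stack([np.ones_like(u), u])
    c0, be0 = np.linalg.lstsq(A, np.log(hours), rcond=None)[0]
    if form.fun is _sf_arrhenius_times_monod:
        # profile out the linear (al, ga) given be0
        z = hours / np.exp(be0 / temp)
        B = np.column_stack([np.ones_like(o2), 1.0 / o2])
        al0, ga0 = np.linalg.lstsq(B, z, rcond=None)[0]
        return (al0, be0, ga0)
    if form.fun is _sf_exp_invO_invT_over_linO:
        return (5.0, be0, 0.01)
    if form.fun is _sf_exp_linO_invT_monod:
        return (0.01, be0, 50.0)
    return (0.5, be0, 50.0)


def fit_combined_surface(
    dataset: Dataset,
    anchor: str = "cellularization",
    catalogue: Sequence[SurfaceForm] = DEFAULT_SURFACE_CATALOGUE,
) -> SurfaceFit:
    """Fit every catalogue surface by nonlinear least squares and select the
    highest adjusted R^2 (ties go to fewer parameters, then catalogue order).

    Candidates whose optimizer fails are recorded as failed and skipped; if
    every candidate fails a :class:`FitError` is raised.
    """
    o2, temp, hours = total_times(dataset, anchor)
    if np.unique(o2).size < 2 or np.unique(temp).size < 2:
        raise DegenerateDesignError(
            "combined surface needs at least two oxygen levels and two temperatures"
        )
    sst = float(((hours - hours.mean()) ** 2).sum())
    n = hours.size
    rows: list[dict] = []
    fitted: list[tuple[SurfaceFit, int, int]] = []
    for order, form in enumerate(catalogue):
        p0 = _surface_p0(form, o2, temp, hours)
        try:
            popt, _ = curve_fit(
                form.fun,
                (o2, temp),
                hours,
                p0=p0,
                maxfev=10000,
                xtol=_NLS_TOL,
                ftol=_NLS_TOL,
            )
        except RuntimeError as exc:
            rows.append({"form": form.tag, "converged": False, "error": str(exc)})
            continue
        resid = hours - form.fun((o2, temp), *popt)
        sse = float(resid @ resid)
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        adj = (
            1.0 - (1.0 - r2) * (n - 1) / (n - form.n_params - 1)
            if n > form.n_params + 1
            else (1.0 if sse <= 1e-12 * max(sst, 1.0) else float("nan"))
        )
        rows.append(
            {
                "form": form.tag,
                "converged": True,
                "parameters": [float(v) for v in popt],
                "sse": sse,
                "adjusted_r2": adj,
            }
        )
        fit = SurfaceFit(
            form_tag=form.tag,
            parameters=tuple(float(v) for v in popt),
            adjusted_r2=adj,
            n=n,
            sse=sse,
        )
        fitted.append((fit, form.n_params, order))
    if not fitted:
        raise FitError(f"all surface candidates failed: {rows}")
    fitted.sort(key=lambda item: (-item[0].adjusted_r2, item[1], item[2]))
    best = fitted[0][0]
    for row in rows:
        row["selected"] = row.get("form") == best.form_tag
    best.candidates = rows
    return best
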