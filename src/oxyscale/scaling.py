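"""Heterochrony analysis: timeline normalization, per-event oxygen-response
regression, pooled-variance slope comparison with Bonferroni correction, and
event-order inversion estimation.

Each embryo's landmark times are rescaled to a dimensionless timeline with the
end of cellularization at 0 and tracheal filling at 1.  If development scaled
uniformly with oxygen, every landmark's normalized position would be flat in
[O2]; a nonzero slope is heterochrony.  Two landmarks whose fitted lines cross
inside the observed oxygen range swap their order of completion — the
inversion point.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data_model import (
    ANCHOR_END,
    ANCHOR_START,
    EVENT_INDEX,
    EVENTS,
    Condition,
    Dataset,
    EmbryoObservation,
)
from .errors import (
    CensoringError,
    DegenerateDataError,
    DegenerateDesignError,
    SampleSizeError,
)

#: Events with a free normalized position (the anchors are 0 and 1 by
#: construction and carry no oxygen signal).
REGRESSABLE_EVENTS: tuple[str, ...] = tuple(
    e for e in EVENTS if e not in (ANCHOR_START, ANCHOR_END)
)


@dataclass
class NormalizedTimeline:
    """One embryo's landmarks on the dimensionless 0-1 developmental axis."""

    embryo_id: str
    condition: Condition
    normalized_times: dict[str, float]


def normalize_timeline(obs: EmbryoObservation) -> NormalizedTimeline:
    """Rescale an embryo's times so cellularization end = 0, trachea fill = 1.

    Requires both anchor events; earlier landmarks (the pole bud) map to
    negative values.
    """
    for anchor in (ANCHOR_START, ANCHOR_END):
        if anchor not in obs.event_times:
            raise CensoringError(
                f"embryo {obs.embryo_id!r}: anchor {anchor!r} not observed"
            )
    t0 = obs.event_times[ANCHOR_START]
    t1 = obs.event_times[ANCHOR_END]
    if t1 - t0 <= 0:
        raise DegenerateDataError(
            f"embryo {obs.embryo_id!r}: anchor interval is {t1 - t0} h"
        )
    return NormalizedTimeline(
        embryo_id=obs.embryo_id,
        condition=obs.condition,
        normalized_times={e: (t - t0) / (t1 - t0) for e, t in obs.event_times.items()},
    )


@dataclass
class LinearFit:
    """Ordinary least-squares line with the sufficient statistics needed for
    the pooled slope-comparison test."""

    slope: float
    intercept: float
    n: int
    sse: float
    sxx: float
    pearson_r: float
    event: str | None = None
    temperature_celsius: float | None = None

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    xbar, ybar = x.mean(), y.mean()
    dx, dy = x - xbar, y - ybar
    sxx = float(dx @ dx)
    sxy = float(dx @ dy)
    syy = float(dy @ dy)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    r = 0.0 if syy == 0 else sxy / math.sqrt(sxx * syy)
    return slope, intercept, sse, sxx, r


def event_regression(
    dataset: Dataset, event: str, temperature: float, min_n: int = 3
) -> LinearFit:
    """Per-embryo normalized time of one landmark regressed on oxygen, within
    one temperature.  Embryos are weighted equally (one point per animal)."""
    if event not in EVENT_INDEX:
        raise KeyError(f"unknown event {event!r}")
    xs: list[float] = []
    ys: list[float] = []
    for obs in dataset:
        if abs(obs.condition.temperature_celsius - temperature) > 1e-6:
            continue
        if event not in obs.event_times:
            continue
        if ANCHOR_START not in obs.event_times or ANCHOR_END not in obs.event_times:
            continue
        nt = normalize_timeline(obs)
        xs.append(obs.condition.oxygen_percent)
        ys.append(nt.normalized_times[event])
    if len(xs) < min_n:
        raise SampleSizeError(
            f"{event} at {temperature}C: {len(xs)} usable embryos (< {min_n})"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.unique(x).size < 2:
        raise DegenerateDesignError(
            f"{event} at {temperature}C: a single oxygen level cannot identify a slope"
        )
    slope, intercept, sse, sxx, r = _ols(x, y)
    return LinearFit(
        slope=slope,
        intercept=intercept,
        n=len(xs),
        sse=sse,
        sxx=sxx,
        pearson_r=r,
        event=event,
        temperature_celsius=temperature,
    )


@dataclass
class PairwiseScalingTest:
    """Pooled-variance t-test for equality of two events' oxygen slopes."""

    event_a: str
    event_b: str
    temperature_celsius: float | None
    t_statistic: float
    degrees_of_freedom: int
    p_raw: float
    p_bonferroni: float | None = None
    m_comparisons: int | None = None


def compare_event_slopes(fit_a: LinearFit, fit_b: LinearFit) -> PairwiseScalingTest:
    """Test slope_a == slope_b using the pooled estimate of the variation
    about the two regression lines.

    s2_p = (sse_a + sse_b) / (n_a + n_b - 4);
    t = (slope_a - slope_b) / sqrt(s2_p * (1/sxx_a + 1/sxx_b)), two-sided on
    n_a + n_b - 4 degrees of freedom.
    """
    if fit_a.n + fit_b.n < 5:
        raise SampleSizeError("pooled slope test needs n_a + n_b >= 5")
    df = fit_a.n + fit_b.n - 4
    s2p = (fit_a.sse + fit_b.sse) / df
    dslope = fit_a.slope - fit_b.slope
    if s2p == 0.0:
        if dslope == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, dslope)
            p = 0.0
    else:
        se = math.sqrt(s2p * (1.0 / fit_a.sxx + 1.0 / fit_b.sxx))
        t_stat = dslope / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return PairwiseScalingTest(
        event_a=fit_a.event or "a",
        event_b=fit_b.event or "b",
        temperature_celsius=fit_a.temperature_celsius,
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_raw=p,
    )


def bonferroni(tests: list[PairwiseScalingTest]) -> list[PairwiseScalingTest]:
    """Attach p_bonferroni = min(1, m * p_raw) with m = len(tests)."""
    if not tests:
        raise ValueError("bonferroni correction over an empty family")
    m = len(tests)
    return [
        replace(t, p_bonferroni=min(1.0, m * t.p_raw), m_comparisons=m) for t in tests
    ]


@dataclass
class InversionEstimate:
    """Oxygen level at which two landmarks' fitted lines cross."""

    event_a: str
    event_b: str
    temperature_celsius: float | None
    crossing_oxygen_percent: float | None
    within_observed_range: bool
    parallel: bool


def find_inversion(
    fit_a: LinearFit,
    fit_b: LinearFit,
    observed_range: tuple[float, float] = (10.0, 29.0),
    slope_tol: float = 1e-12,
) -> InversionEstimate:
    """Solve for the oxygen level where two fitted lines cross.

    Parallel lines (|slope difference| <= ``slope_tol``) give a distinguished
    no-inversion result rather than an error.  The observed-range check is on
    the closed interval.
    """
    dslope = fit_a.slope - fit_b.slope
    if abs(dslope) <= slope_tol:
        return InversionEstimate(
            event_a=fit_a.event or "a",
            event_b=fit_b.event or "b",
            temperature_celsius=fit_a.temperature_celsius,
            crossing_oxygen_percent=None,
            within_observed_range=False,
            parallel=True,
        )
    crossing = (fit_b.intercept - fit_a.intercept) / dslope
    lo, hi = observed_range
    return InversionEstimate(
        event_a=fit_a.event or "a",
        event_b=fit_b.event or "b",
        temperature_celsius=fit_a.temperature_celsius,
        crossing_oxygen_percent=crossing,
        within_observed_range=lo <= crossing <= hi,
        parallel=False,
    )


@dataclass
class ScalingResult:
    """All heterochrony results for one temperature."""

    temperature_celsius: float
    fits: dict[str, LinearFit]
    tests: list[PairwiseScalingTest]
    inversions: list[InversionEstimate]
    skipped_events: dict[str, str]


def scaling_analysis(
    dataset: Dataset,
    temperature: float,
    events: tuple[str, ...] = REGRESSABLE_EVENTS,
    observed_range: tuple[float, float] | None = None,
) -> ScalingResult:
    """Fit every regressable event at one temperature, run all pairwise
    slope tests with Bonferroni correction (the family is all event pairs
    within the temperature), and estimate every pairwise crossing."""
    fits: dict[str, LinearFit] = {}
    skipped: dict[str, str] = {}
    for e in events:
        try:
            fits[e] = event_regression(dataset, e, temperature)
        except (SampleSizeError, DegenerateDesignError) as exc:
            skipped[e] = str(exc)
    if observed_range is None:
        o2 = sorted(
            {
                obs.condition.oxygen_percent
                for obs in dataset
                if abs(obs.condition.temperature_celsius - temperature) <= 1e-6
            }
        )
        observed_range = (o2[0], o2[-1]) if o2 else (10.0, 29.0)
    tests = [
        compare_event_slopes(fits[a], fits[b])
        for a, b in itertools.combinations(fits, 2)
    ]
    if tests:
        tests = bonferroni(tests)
    inversions = [
        find_inversion(fits[a], fits[b], observed_range)
        for a, b in itertools.combinations(fits, 2)
    ]
    return ScalingResult(
        temperature_celsius=temperature,
        fits=fits,
        tests=tests,
        inversions=inversions,
        skipped_events=skipped,
    )
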