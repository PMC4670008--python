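"""Stochastic generator of embryo event-time datasets.

The generator is phenomenological: it reproduces the statistical structure the
analysis pipeline assumes, not embryo physiology.

*  Total developmental time (end of cellularization to tracheal filling)
   follows a Monod-style law in oxygen, ``t = a(T) + b(T)/[O2]``, with the
   per-temperature coefficients defaulting to the fitted values for 17.5,
   22.5 and 27.5 degrees C.
*  Each landmark sits at a normalized position ``p(e, O2) = p0_e +
   s_e * ([O2] - 21)`` between the anchors (cellularization end = 0, trachea
   fill = 1); nonzero slopes ``s_e`` are heterochrony.  A per-temperature
   shift on the heart-shaped-midgut baseline moves the head/gut inversion
   point with temperature.
*  Independent Gaussian annotation noise (sd in hours) is added to every
   landmark time, with rejection until the event order is valid
   (rank-preserving, up to the oxygen-dependent head/gut swap).
*  Each embryo draws a fate from a per-condition categorical distribution
   over the five fate bins; non-hatching fates censor the timeline at a
   uniformly drawn landmark inside the bin's stage range.

Generation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .data_model import (
    ANCHOR_END,
    ANCHOR_START,
    EVENT_INDEX,
    EVENTS,
    Condition,
    Dataset,
    EmbryoObservation,
)
from .errors import ConfigError
from .viability import FATE_BINS, FateBin

#: Oxygen levels (% v/v) and temperatures (degrees C) of the full study grid.
DEFAULT_OXYGEN: tuple[float, ...] = (10.0, 14.0, 17.0, 21.0, 25.0, 29.0)
DEFAULT_TEMPERATURES: tuple[float, ...] = (17.5, 22.5, 27.5)

#: Per-temperature Monod coefficients (a, b) for t = a + b/[O2], hours.
DEFAULT_MONOD: dict[float, tuple[float, float]] = {
    17.5: (30.13, 280.92),
    22.5: (17.58, 167.39),
    27.5: (8.55, 204.03),
}

#: Normalized landmark positions at the 21% O2 reference (anchors pinned at 0/1;
#: the pole bud precedes cellularization, hence the negative value).
DEFAULT_EVENT_BASELINE: dict[str, float] = {
    "pole_bud_appearance": -0.14,
    "membrane_reaches_yolk": 0.0,
    "pole_cell_invagination": 0.06,
    "amnioproctodeal_invagination": 0.13,
    "amnioserosa_exposure": 0.52,
    "clypeolabrum_retraction": 0.70,
    "cephalic_lobes_even": 0.81,
    "heart_shaped_midgut": 0.84,
    "trachea_fill": 1.0,
}

#: Heterochrony slopes, normalized units per %O2.  Syncytial development and
#: head involution take proportionally MORE time as oxygen rises (positive
#: trend away from the anchors), gut formation and germ-band retraction less.
DEFAULT_EVENT_SLOPE: dict[str, float] = {
    "pole_bud_appearance": -0.002,
    "membrane_reaches_yolk": 0.0,
    "pole_cell_invagination": 0.0,
    "amnioproctodeal_invagination": 0.0,
    "amnioserosa_exposure": -0.001,
    "clypeolabrum_retraction": 0.003,
    "cephalic_lobes_even": 0.005,
    "heart_shaped_midgut": -0.0025,
    "trachea_fill": 0.0,
}

#: Additive per-temperature shift of the heart-shaped-midgut baseline.  With
#: the default slopes this places the head/gut order inversion at 19% O2
#: (17.5C), 25% (22.5C) and 29% (27.5C).
DEFAULT_MIDGUT_SHIFT: dict[float, float] = {17.5: -0.045, 22.5: 0.0, 27.5: 0.03}

_ANCHOR_IDX = (EVENT_INDEX[ANCHOR_START], EVENT_INDEX[ANCHOR_END])
_SWAP_DIFF = EVENT_INDEX["cephalic_lobes_even"]  # diff index t[7]-t[6]


def default_fate_probs(condition: Condition) -> dict[FateBin, float]:
    """Qualitative per-condition fate distribution.

    Hypoxia shifts failure into mid-embryogenesis (more so when warm), mild
    hypoxia (14-17%) leaves many embryos unable to hatch after completing
    development, hyperoxia (29%) pushes failure to before gastrulation, and
    survival peaks at 25% rather than at atmospheric oxygen.
    """
    o2 = condition.oxygen_percent
    temp = condition.temperature_celsius
    warm = (temp - 22.5) / 5.0  # -1, 0, +1 on the default grid
    if o2 <= 12:
        p = {
            FateBin.PRE_GASTRULATION: 0.05,
            FateBin.GASTRULATION_TO_MIDGUT: 0.40 + 0.05 * warm,
            FateBin.LATE_PRETRACHEAL: 0.12,
            FateBin.HATCHING_FAILURE: 0.08,
            FateBin.HATCHED: 0.35 - 0.05 * warm,
        }
    elif o2 <= 15:
        p = {
            FateBin.PRE_GASTRULATION: 0.05,
            FateBin.GASTRULATION_TO_MIDGUT: 0.12 + 0.04 * warm,
            FateBin.LATE_PRETRACHEAL: 0.06,
            FateBin.HATCHING_FAILURE: 0.17,
            FateBin.HATCHED: 0.60 - 0.04 * warm,
        }
    elif o2 <= 19:
        p = {
            FateBin.PRE_GASTRULATION: 0.06,
            FateBin.GASTRULATION_TO_MIDGUT: 0.05,
            FateBin.LATE_PRETRACHEAL: 0.04,
            FateBin.HATCHING_FAILURE: 0.16,
            FateBin.HATCHED: 0.69,
        }
    elif o2 <= 23:
        p = {
            FateBin.PRE_GASTRULATION: 0.10,
            FateBin.GASTRULATION_TO_MIDGUT: 0.05,
            FateBin.LATE_PRETRACHEAL: 0.04,
            FateBin.HATCHING_FAILURE: 0.06,
            FateBin.HATCHED: 0.75,
        }
    elif o2 <= 27:
        p = {
            FateBin.PRE_GASTRULATION: 0.06,
            FateBin.GASTRULATION_TO_MIDGUT: 0.03,
            FateBin.LATE_PRETRACHEAL: 0.02,
            FateBin.HATCHING_FAILURE: 0.04,
            FateBin.HATCHED: 0.85,
        }
    else:
        p = {
            FateBin.PRE_GASTRULATION: 0.18 + 0.02 * warm,
            FateBin.GASTRULATION_TO_MIDGUT: 0.04,
            FateBin.LATE_PRETRACHEAL: 0.03,
            FateBin.HATCHING_FAILURE: 0.05,
            FateBin.HATCHED: 0.70 - 0.02 * warm,
        }
    return p


def all_hatched_probs(condition: Condition) -> dict[FateBin, float]:
    """Degenerate fate model: every embryo hatches (useful for calibrations)."""
    return {b: (1.0 if b is FateBin.HATCHED else 0.0) for b in FATE_BINS}


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the embryo event-time generator."""

    grid: tuple[Condition, ...]
    n_per_condition: int
    monod_params: Mapping[float, tuple[float, float]]
    event_baseline: Mapping[str, float]
    event_slope: Mapping[str, float]
    midgut_baseline_shift: Mapping[float, float]
    noise_sd: float
    fate_model: Mapping[Condition, Mapping[FateBin, float]]
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_condition < 1:
            raise ConfigError("n_per_condition must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for e in EVENTS:
            if e not in self.event_baseline:
                raise ConfigError(f"event_baseline missing event {e!r}")
            if e not in self.event_slope:
                raise ConfigError(f"event_slope missing event {e!r}")
        if self.event_baseline[ANCHOR_START] != 0.0 or self.event_baseline[ANCHOR_END] != 1.0:
            raise ConfigError("anchor baselines must be exactly 0 (cellularization) and 1 (trachea)")
        if self.event_slope[ANCHOR_START] != 0.0 or self.event_slope[ANCHOR_END] != 0.0:
            raise ConfigError("anchor events define the normalization frame; their slopes must be 0")
        base = [self.event_baseline[e] for e in EVENTS]
        if any(b2 <= b1 for b1, b2 in zip(base, base[1:])):
            raise ConfigError("event_baseline must be strictly increasing in catalog order")
        for cond in self.grid:
            if cond.temperature_celsius not in self.monod_params:
                raise ConfigError(f"no Monod parameters for T={cond.temperature_celsius}")
            if cond not in self.fate_model:
                raise ConfigError(f"no fate distribution for condition {cond}")
            probs = self.fate_model[cond]
            vals = [float(probs.get(b, 0.0)) for b in FATE_BINS]
            if any(v < 0 for v in vals):
                raise ConfigError(f"negative fate probability at {cond}")
            if abs(sum(vals) - 1.0) > 1e-12:
                raise ConfigError(f"fate probabilities at {cond} sum to {sum(vals)}, not 1")


def default_config(
    n_per_condition: int = 20,
    noise_sd: float = 0.5,
    seed: int = 0,
    oxygen_levels: Sequence[float] = DEFAULT_OXYGEN,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    heterochrony: bool = True,
    fate: str = "default",
) -> SyntheticConfig:
    """Study-grid configuration with the published per-temperature Monod
    coefficients as ground truth.

    ``heterochrony=False`` zeroes every event slope and the midgut shift (the
    uniform-scaling null).  ``fate`` is ``"default"`` or ``"all_hatched"``.
    """
    grid = tuple(
        Condition(o, t) for t in temperatures for o in oxygen_levels
    )
    slope = dict(DEFAULT_EVENT_SLOPE)
    shift = dict(DEFAULT_MIDGUT_SHIFT)
    if not heterochrony:
        slope = {e: 0.0 for e in EVENTS}
        shift = {t: 0.0 for t in temperatures}
    else:
        shift = {t: shift.get(t, 0.0) for t in temperatures}
    if fate == "default":
        fate_fn = default_fate_probs
    elif fate == "all_hatched":
        fate_fn = all_hatched_probs
    else:
        raise ConfigError(f"unknown fate model {fate!r}")
    cfg = SyntheticConfig(
        grid=grid,
        n_per_condition=n_per_condition,
        monod_params={t: DEFAULT_MONOD[t] for t in temperatures},
        event_baseline=dict(DEFAULT_EVENT_BASELINE),
        event_slope=slope,
        midgut_baseline_shift=shift,
        noise_sd=noise_sd,
        fate_model={c: fate_fn(c) for c in grid},
        seed=seed,
    )
    cfg.validate()
    return cfg


def true_total_time(config: SyntheticConfig, condition: Condition) -> float:
    """Noiseless cellularization-to-trachea time a(T) + b(T)/[O2], hours."""
    try:
        a, b = config.monod_params[condition.temperature_celsius]
    except KeyError:
        raise ConfigError(
            f"no Monod parameters for T={condition.temperature_celsius}"
        ) from None
    return a + b / condition.oxygen_percent


def event_positions(config: SyntheticConfig, condition: Condition) -> np.ndarray:
    """Noiseless normalized landmark positions at one condition.

    Applies the linear oxygen response and the per-temperature midgut shift,
    then renormalizes so the anchors sit exactly at 0 and 1.
    """
    o2 = condition.oxygen_percent
    temp = condition.temperature_celsius
    p = np.array(
        [
            config.event_baseline[e] + config.event_slope[e] * (o2 - 21.0)
            for e in EVENTS
        ]
    )
    p[EVENT_INDEX["heart_shaped_midgut"]] += config.midgut_baseline_shift.get(temp, 0.0)
    start, end = p[_ANCHOR_IDX[0]], p[_ANCHOR_IDX[1]]
    return (p - start) / (end - start)


def analytic_crossing(
    config: SyntheticConfig, event_a: str, event_b: str, temperature: float
) -> float | None:
    """Ground-truth oxygen level at which two landmarks swap order, or None
    if their oxygen responses are parallel."""
    def line(event: str) -> tuple[float, float]:
        p0 = config.event_baseline[event]
        if event == "heart_shaped_midgut":
            p0 += config.midgut_baseline_shift.get(temperature, 0.0)
        return p0, config.event_slope[event]

    (p0a, sa), (p0b, sb) = line(event_a), line(event_b)
    if abs(sa - sb) < 1e-15:
        return None
    return 21.0 + (p0b - p0a) / (sa - sb)


def sample_fate(
    config: SyntheticConfig, condition: Condition, rng: np.random.Generator
) -> FateBin:
    """Draw one fate bin from the configured categorical distribution."""
    try:
        probs = config.fate_model[condition]
    except KeyError:
        raise ConfigError(f"no fate distribution for condition {condition}") from None
    vals = np.array([float(probs.get(b, 0.0)) for b in FATE_BINS])
    if abs(vals.sum() - 1.0) > 1e-12 or (vals < 0).any():
        raise ConfigError(f"fate probabilities at {condition} are not a distribution")
    return FATE_BINS[int(rng.choice(len(FATE_BINS), p=vals))]


# stage ranges for censoring: a failing embryo's last landmark is drawn
# uniformly from its bin's catalog range
_ARREST_RANGE: dict[FateBin, tuple[int, int]] = {
    FateBin.PRE_GASTRULATION: (0, 3),
    FateBin.GASTRULATION_TO_MIDGUT: (3, 7),
    FateBin.LATE_PRETRACHEAL: (7, 8),
    FateBin.HATCHING_FAILURE: (8, 9),
    FateBin.HATCHED: (8, 9),
}


def _order_valid(times: np.ndarray) -> bool:
    d = np.diff(times)
    if (d > 0).all():
        return True
    # only the head/gut pair may invert
    others = np.concatenate([d[:_SWAP_DIFF], d[_SWAP_DIFF + 1:]])
    return (
        d[_SWAP_DIFF] < 0
        and (others > 0).all()
        and times[_SWAP_DIFF + 1] > times[_SWAP_DIFF - 1]
        and times[_SWAP_DIFF + 2] > times[_SWAP_DIFF]
    )


def _noisy_times(
    base: np.ndarray, sd: float, rng: np.random.Generator, max_tries: int = 10000
) -> np.ndarray:
    if sd == 0.0:
        return base.copy()
    for _ in range(max_tries):
        t = base + rng.normal(0.0, sd, size=base.shape)
        if (t > 0).all() and _order_valid(t):
            return t
    raise ConfigError(
        "noise_sd too large relative to inter-event gaps: could not draw a "
        "rank-preserving timeline"
    )


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Generate a validated dataset; a pure function of (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    observations: list[EmbryoObservation] = []
    for cond in config.grid:
        t_total = true_total_time(config, cond)
        p = event_positions(config, cond)
        # keep the earliest landmark comfortably after the recording start
        offset = 1.0 + max(0.0, -p.min()) * t_total
        base = offset + p * t_total
        for i in range(config.n_per_condition):
            fate = sample_fate(config, cond, rng)
            times = _noisy_times(base, config.noise_sd, rng)
            lo, hi = _ARREST_RANGE[fate]
            last = int(rng.integers(lo, hi)) if hi - lo > 1 else lo
            event_times = {EVENTS[k]: float(times[k]) for k in range(last + 1)}
            observations.append(
                EmbryoObservation(
                    embryo_id=(
                        f"o{cond.oxygen_percent:g}_t{cond.temperature_celsius:g}_{i:04d}"
                    ),
                    condition=cond,
                    event_times=event_times,
                    hatched=(fate is FateBin.HATCHED),
                )
            )
    ds = Dataset(
        observations=observations,
        metadata={"source": "synthetic", "seed": config.seed},
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# YAML (de)serialization


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    doc = {
        "grid": [
            {"oxygen_percent": c.oxygen_percent, "temperature_celsius": c.temperature_celsius}
            for c in config.grid
        ],
        "n_per_condition": config.n_per_condition,
        "monod_params": {float(t): list(ab) for t, ab in config.monod_params.items()},
        "event_baseline": dict(config.event_baseline),
        "event_slope": dict(config.event_slope),
        "midgut_baseline_shift": {float(t): v for t, v in config.midgut_baseline_shift.items()},
        "noise_sd": config.noise_sd,
        "fate_model": [
            {
                "oxygen_percent": c.oxygen_percent,
                "temperature_celsius": c.temperature_celsius,
                "probs": {b.value: float(p.get(b, 0.0)) for b in FATE_BINS},
            }
            for c, p in config.fate_model.items()
        ],
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> SyntheticConfig:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        grid = tuple(
            Condition(float(g["oxygen_percent"]), float(g["temperature_celsius"]))
            for g in doc["grid"]
        )
        fate_model = {
            Condition(float(f["oxygen_percent"]), float(f["temperature_celsius"])): {
                FateBin(k): float(v) for k, v in f["probs"].items()
            }
            for f in doc["fate_model"]
        }
        cfg = SyntheticConfig(
            grid=grid,
            n_per_condition=int(doc["n_per_condition"]),
            monod_params={float(t): tuple(ab) for t, ab in doc["monod_params"].items()},
            event_baseline={str(k): float(v) for k, v in doc["event_baseline"].items()},
            event_slope={str(k): float(v) for k, v in doc["event_slope"].items()},
            midgut_baseline_shift={
                float(t): float(v) for t, v in doc.get("midgut_baseline_shift", {}).items()
            },
            noise_sd=float(doc["noise_sd"]),
            fate_model=fate_model,
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed synthetic config: {exc}") from exc
    cfg.validate()
    return cfg
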