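"""End-to-end report assembly: run the analysis stages on a dataset (read
from CSV or freshly simulated) and write a deterministic report bundle.

Outputs, all under the configured output directory:

* ``scaling.csv``   — one row per fitted event (slope, 95% CI, n) and one row
  per event pair (t, df, raw and Bonferroni-corrected p), per temperature
* ``inversions.csv`` — pairwise fitted-line crossings with range flags
* ``fits.json``     — every candidate rate model per stratum plus the combined
  surface candidate table and the selection decisions
* ``lethality.csv`` — long-format stage-binned fate counts and fractions
* ``summary.txt``   — human-readable digest with the config hash and seed

Floating-point values in the bundle are serialized at 9 significant digits so
byte-level comparison of two runs is meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import rate_models, scaling, viability
from .data_model import Dataset, read_event_table, write_event_table
from .errors import ConfigError, OxyscaleError
from .synthetic import SyntheticConfig, generate_dataset, save_config

logger = logging.getLogger(__name__)

_F = "%.9g"


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return _F % v
    return str(v)


def _round9(obj):
    """Recursively coerce floats to 9 significant digits for stable JSON."""
    if isinstance(obj, float):
        return float(_F % obj)
    if isinstance(obj, dict):
        return {k: _round9(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round9(v) for v in obj]
    return obj


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    outdir: str = "oxyscale_out"
    seed: int = 0
    run_scaling: bool = True
    run_rates: bool = True
    run_viability: bool = True
    run_surface: bool = True
    anchor: str = "cellularization"

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigError("exactly one input source required: a CSV path xor a synthetic config")
        if not (self.run_scaling or self.run_rates or self.run_viability or self.run_surface):
            raise ConfigError("all analysis stages are disabled; nothing to do")
        if self.anchor not in ("cellularization", "polebud"):
            raise ConfigError(f"unknown anchor {self.anchor!r}")


def _config_hash(config: RunConfig) -> str:
    if config.synthetic is not None:
        payload = {
            "synthetic": True,
            "seed": config.synthetic.seed,
            "n_per_condition": config.synthetic.n_per_condition,
            "noise_sd": config.synthetic.noise_sd,
            "grid": [
                (c.oxygen_percent, c.temperature_celsius) for c in config.synthetic.grid
            ],
            "monod": sorted(
                (t, list(ab)) for t, ab in config.synthetic.monod_params.items()
            ),
        }
    else:
        payload = {"input": config.input_path}
    payload["anchor"] = config.anchor
    payload["stages"] = [
        config.run_scaling,
        config.run_rates,
        config.run_viability,
        config.run_surface,
    ]
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _scaling_frames(result: scaling.ScalingResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    ev_rows, pair_rows = [], []
    for e, fit in result.fits.items():
        se = float("nan")
        lo = hi = float("nan")
        if fit.n > 2 and fit.sxx > 0:
            s2 = fit.sse / (fit.n - 2)
            se = (s2 / fit.sxx) ** 0.5
            tcrit = float(sps.t.ppf(0.975, fit.n - 2))
            lo, hi = fit.slope - tcrit * se, fit.slope + tcrit * se
        ev_rows.append(
            {
                "row_type": "event",
                "temperature_celsius": result.temperature_celsius,
                "event": e,
                "slope_per_pct_o2": fit.slope,
                "intercept": fit.intercept,
                "slope_ci_low": lo,
                "slope_ci_high": hi,
                "pearson_r": fit.pearson_r,
                "n": fit.n,
            }
        )
    for t in result.tests:
        pair_rows.append(
            {
                "row_type": "pair",
                "temperature_celsius": result.temperature_celsius,
                "event_a": t.event_a,
                "event_b": t.event_b,
                "t_statistic": t.t_statistic,
                "degrees_of_freedom": t.degrees_of_freedom,
                "p_raw": t.p_raw,
                "p_bonferroni": t.p_bonferroni,
                "m_comparisons": t.m_comparisons,
            }
        )
    return pd.DataFrame(ev_rows), pd.DataFrame(pair_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns a dict with in-memory results and the paths written.
    Deterministic given (input, seed).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)

    if config.synthetic is not None:
        dataset = generate_dataset(config.synthetic)
        write_event_table(dataset, outdir / "simulated.csv")
    else:
        dataset = read_event_table(config.input_path)
    if len(dataset) == 0:
        raise OxyscaleError("no observations in input dataset")

    results: dict = {"dataset": dataset, "config_hash": cfg_hash}
    written: list[Path] = []
    summary: list[str] = [
        "oxyscale pipeline report",
        f"config_hash: {cfg_hash}",
        f"seed: {config.seed}",
        f"observations: {len(dataset)}",
        f"conditions: {len(dataset.conditions())}",
        "",
    ]

    if config.run_scaling:
        ev_frames, pair_frames, inv_rows = [], [], []
        for temp in dataset.temperatures():
            res = scaling.scaling_analysis(dataset, temp)
            results.setdefault("scaling", {})[temp] = res
            ev, pair = _scaling_frames(res)
            ev_frames.append(ev)
            pair_frames.append(pair)
            for inv in res.inversions:
                inv_rows.append(
                    {
                        "temperature_celsius": temp,
                        "event_a": inv.event_a,
                        "event_b": inv.event_b,
                        "crossing_oxygen_percent": inv.crossing_oxygen_percent,
                        "within_observed_range": inv.within_observed_range,
                        "parallel": inv.parallel,
                    }
                )
        scaling_df = pd.concat(ev_frames + pair_frames, ignore_index=True)
        path = outdir / "scaling.csv"
        scaling_df.to_csv(path, index=False, float_format=_F)
        written.append(path)
        inv_df = pd.DataFrame(inv_rows)
        path = outdir / "inversions.csv"
        inv_df.to_csv(path, index=False, float_format=_F)
        written.append(path)
        key_pair = inv_df[
            (inv_df.event_a == "cephalic_lobes_even")
            & (inv_df.event_b == "heart_shaped_midgut")
        ]
        summary.append("head/gut inversion (cephalic_lobes_even vs heart_shaped_midgut):")
        for _, r in key_pair.iterrows():
            c = r.crossing_oxygen_percent
            summary.append(
                f"  T={_fmt(r.temperature_celsius)} C: "
                + ("parallel (no inversion)" if r.parallel else f"crossing at {_fmt(c)}% O2"
                   + ("" if r.within_observed_range else " (outside observed range)"))
            )
        summary.append("")

    fits_doc: dict = {}
    if config.run_rates:
        monod = rate_models.fit_monod_per_temperature(dataset, anchor=config.anchor)
        arrh = rate_models.fit_arrhenius_per_oxygen(dataset, anchor=config.anchor)
        results["monod"] = monod
        results["arrhenius"] = arrh
        fits_doc["monod_per_temperature"] = {
            str(t): {
                "family": f.family,
                "a_hours": f.parameters[0],
                "b_hours_pct": f.parameters[1],
                "pearson_r": f.pearson_r,
                "adjusted_r2": f.adjusted_r2,
                "n": f.n,
            }
            for t, f in monod.items()
        }
        fits_doc["arrhenius_per_oxygen"] = {
            str(o): {
                "family": f.family,
                "a_hours": f.parameters[0],
                "b_celsius": f.parameters[1],
                "pearson_r": f.pearson_r,
                "adjusted_r2": f.adjusted_r2,
                "n": f.n,
            }
            for o, f in arrh.items()
        }
        summary.append("Monod fits t = a + b/[O2] per temperature:")
        for t, f in monod.items():
            summary.append(
                f"  T={_fmt(t)} C: a={_fmt(f.parameters[0])} h, b={_fmt(f.parameters[1])} h*%, "
                f"r={_fmt(f.pearson_r)}, n={f.n}"
            )
        summary.append("")

    if config.run_surface:
        try:
            surface = rate_models.fit_combined_surface(dataset, anchor=config.anchor)
            results["surface"] = surface
            fits_doc["combined_surface"] = {
                "selected_form": surface.form_tag,
                "parameters": list(surface.parameters),
                "adjusted_r2": surface.adjusted_r2,
                "n": surface.n,
                "candidates": surface.candidates,
            }
            summary.append(
                f"combined surface: {surface.form_tag} "
                f"(adjusted R2 = {_fmt(surface.adjusted_r2)}, n={surface.n})"
            )
            summary.append("")
        except OxyscaleError as exc:
            logger.warning("combined surface skipped: %s", exc)
            fits_doc["combined_surface"] = {"error": str(exc)}

    if fits_doc:
        path = outdir / "fits.json"
        path.write_text(json.dumps(_round9(fits_doc), indent=2, sort_keys=True) + "\n")
        written.append(path)

    if config.run_viability:
        table = viability.lethality_table(dataset)
        results["lethality"] = table
        path = outdir / "lethality.csv"
        table.table.to_csv(path, index=False, float_format=_F)
        written.append(path)
        hatched = table.table[table.table.fate_bin == "hatched"]
        overall = hatched["count"].sum() / table.table["count"].sum()
        summary.append(f"overall hatch fraction: {_fmt(float(overall))}")
        summary.append("")

    path = outdir / "summary.txt"
    path.write_text("\n".join(summary) + "\n")
    written.append(path)
    results["written"] = written
    return results
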