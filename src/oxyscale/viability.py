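"""Stage-binned embryonic fate classification and lethality tabulation.

An embryo either hatches or fails, and failures are binned by how far
development proceeded before arrest: before the completion of gastrulation,
between gastrulation and the heart-shaped midgut, late pre-tracheal
development, or after tracheal filling (a hatching failure, where the larva
cannot escape its vitelline membrane).  The boundary for "completion of
gastrulation" is the amnioproctodeal invagination, the last gastrulation
landmark in the catalog; bins are half-open on the right in last-observed
event, so an embryo whose final landmark IS the heart-shaped midgut counts as
a late pre-tracheal failure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .data_model import EVENT_INDEX, Condition, Dataset, EmbryoObservation

_GASTRULATION_DONE = EVENT_INDEX["amnioproctodeal_invagination"]  # 3
_MIDGUT = EVENT_INDEX["heart_shaped_midgut"]  # 7
_TRACHEA = EVENT_INDEX["trachea_fill"]  # 8


class FateBin(str, enum.Enum):
    """Exhaustive, mutually exclusive embryo outcomes."""

    PRE_GASTRULATION = "pre_gastrulation_failure"
    GASTRULATION_TO_MIDGUT = "gastrulation_to_midgut_failure"
    LATE_PRETRACHEAL = "late_pretracheal_failure"
    HATCHING_FAILURE = "hatching_failure"
    HATCHED = "hatched"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed tabulation order.
FATE_BINS: tuple[FateBin, ...] = (
    FateBin.PRE_GASTRULATION,
    FateBin.GASTRULATION_TO_MIDGUT,
    FateBin.LATE_PRETRACHEAL,
    FateBin.HATCHING_FAILURE,
    FateBin.HATCHED,
)


def classify_fate(obs: EmbryoObservation) -> FateBin:
    """Assign one embryo to its fate bin.  Total and deterministic."""
    if obs.hatched:
        return FateBin.HATCHED
    last = obs.last_event_index
    if last < _GASTRULATION_DONE:
        return FateBin.PRE_GASTRULATION
    if last < _MIDGUT:
        return FateBin.GASTRULATION_TO_MIDGUT
    if last < _TRACHEA:
        return FateBin.LATE_PRETRACHEAL
    return FateBin.HATCHING_FAILURE


@dataclass
class LethalityTable:
    """Per-condition fate counts and fractions, long format.

    ``table`` columns: oxygen_percent, temperature_celsius, fate_bin, count,
    fraction.  Every (condition, bin) cell is present, zeros included, and
    per-condition fractions sum to one.
    """

    table: pd.DataFrame

    def counts(self, condition: Condition) -> dict[FateBin, int]:
        sub = self.table[
            (self.table.oxygen_percent == condition.oxygen_percent)
            & (self.table.temperature_celsius == condition.temperature_celsius)
        ]
        return {FateBin(r.fate_bin): int(r["count"]) for _, r in sub.iterrows()}

    def fractions(self, condition: Condition) -> dict[FateBin, float]:
        sub = self.table[
            (self.table.oxygen_percent == condition.oxygen_percent)
            & (self.table.temperature_celsius == condition.temperature_celsius)
        ]
        return {FateBin(r.fate_bin): float(r.fraction) for _, r in sub.iterrows()}

    def margins(self) -> pd.DataFrame:
        """Total embryos per condition."""
        return (
            self.table.groupby(["oxygen_percent", "temperature_celsius"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "n"})
        )


def lethality_table(dataset: Dataset) -> LethalityTable:
    """Exact cross-tabulation of :func:`classify_fate` by condition."""
    if len(dataset) == 0:
        raise ValueError("dataset has no observations")
    records = [
        {
            "oxygen_percent": obs.condition.oxygen_percent,
            "temperature_celsius": obs.condition.temperature_celsius,
            "fate_bin": classify_fate(obs).value,
        }
        for obs in dataset
    ]
    df = pd.DataFrame(records)
    counts = (
        df.groupby(["oxygen_percent", "temperature_celsius", "fate_bin"])
        .size()
        .rename("count")
        .reset_index()
    )
    # densify: every bin for every condition
    conds = df[["oxygen_percent", "temperature_celsius"]].drop_duplicates()
    full = conds.merge(pd.DataFrame({"fate_bin": [b.value for b in FATE_BINS]}), how="cross")
    out = full.merge(counts, on=["oxygen_percent", "temperature_celsius", "fate_bin"], how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    totals = out.groupby(["oxygen_percent", "temperature_celsius"])["count"].transform("sum")
    out["fraction"] = out["count"] / totals
    out = out.sort_values(
        ["temperature_celsius", "oxygen_percent", "fate_bin"],
        key=lambda s: s.map({b.value: i for i, b in enumerate(FATE_BINS)})
        if s.name == "fate_bin"
        else s,
    ).reset_index(drop=True)
    return LethalityTable(table=out)
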