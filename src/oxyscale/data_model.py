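"""Embryo event-time data model and CSV I/O.

The unit of observation is a single embryo followed by time-lapse imaging from
before cellularization to hatching.  Nine hand-annotated morphological
landmarks define its timeline; an embryo that arrests is right-censored, so its
missing landmarks always form a suffix of the catalog order.

One deliberate relaxation of strict catalog ordering: the relative timing of
``cephalic_lobes_even`` (head involution) and ``heart_shaped_midgut`` (gut
formation) depends on ambient oxygen — the two events swap order between
hypoxia and hyperoxia — so that adjacent pair may be recorded in either order.
All other pairs must be strictly ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CensoringError, FormatError, ValidationError

#: Canonical landmark catalog, in developmental order.
EVENTS: tuple[str, ...] = (
    "pole_bud_appearance",
    "membrane_reaches_yolk",
    "pole_cell_invagination",
    "amnioproctodeal_invagination",
    "amnioserosa_exposure",
    "clypeolabrum_retraction",
    "cephalic_lobes_even",
    "heart_shaped_midgut",
    "trachea_fill",
)

EVENT_INDEX: dict[str, int] = {e: i for i, e in enumerate(EVENTS)}

#: End of cellularization anchors normalized time 0.
ANCHOR_START = "membrane_reaches_yolk"
#: Tracheal air filling anchors normalized time 1.
ANCHOR_END = "trachea_fill"

#: The head-involution / gut-formation pair whose completion order inverts
#: with oxygen; exempt from the strict-ordering rule.
SWAPPABLE_PAIR = ("cephalic_lobes_even", "heart_shaped_midgut")
_SWAP_IDX = (EVENT_INDEX[SWAPPABLE_PAIR[0]], EVENT_INDEX[SWAPPABLE_PAIR[1]])

_CSV_COLUMNS = ("embryo_id", "oxygen_percent", "temperature_celsius") + EVENTS + ("hatched",)


@dataclass(frozen=True)
class Condition:
    """A rearing condition: ambient oxygen (% v/v) and temperature (degrees C)."""

    oxygen_percent: float
    temperature_celsius: float

    def __post_init__(self) -> None:
        if not 0.0 < self.oxygen_percent <= 100.0:
            raise ValidationError(
                f"oxygen_percent must be in (0, 100], got {self.oxygen_percent}"
            )
        if not 0.0 < self.temperature_celsius < 45.0:
            raise ValidationError(
                f"temperature_celsius must be in (0, 45), got {self.temperature_celsius}"
            )


@dataclass
class EmbryoObservation:
    """One embryo's condition, landmark times (hours since first frame), and fate.

    ``event_times`` holds only the landmarks the embryo reached; an arrested
    embryo's record simply stops (suffix censoring).
    """

    embryo_id: str
    condition: Condition
    event_times: dict[str, float]
    hatched: bool

    def validate(self) -> None:
        for e in self.event_times:
            if e not in EVENT_INDEX:
                raise ValidationError(f"embryo {self.embryo_id!r}: unknown event {e!r}")
        present = sorted((EVENT_INDEX[e], t) for e, t in self.event_times.items())
        for idx, t in present:
            if not (t == t) or t in (float("inf"), float("-inf")):
                raise ValidationError(f"embryo {self.embryo_id!r}: non-finite time for {EVENTS[idx]}")
            if t < 0:
                raise ValidationError(
                    f"embryo {self.embryo_id!r}: negative time {t} for {EVENTS[idx]}"
                )
        # suffix censoring: present indices must be exactly 0..k
        indices = [i for i, _ in present]
        if indices and indices != list(range(len(indices))):
            missing = next(i for i in range(indices[-1]) if i not in indices)
            raise ValidationError(
                f"embryo {self.embryo_id!r}: interior gap — {EVENTS[missing]} missing "
                f"but a later event is recorded (censoring must be a suffix)"
            )
        # strict order, except the oxygen-dependent swap pair
        for a in range(len(present)):
            ia, ta = present[a]
            for b in range(a + 1, len(present)):
                ib, tb = present[b]
                if tb <= ta and (ia, ib) != _SWAP_IDX:
                    raise ValidationError(
                        f"embryo {self.embryo_id!r}: {EVENTS[ib]} at {tb} h does not follow "
                        f"{EVENTS[ia]} at {ta} h"
                    )
        if self.hatched and ANCHOR_END not in self.event_times:
            raise ValidationError(
                f"embryo {self.embryo_id!r}: hatched but {ANCHOR_END} is not recorded"
            )

    @property
    def last_event_index(self) -> int:
        """Catalog index of the furthest landmark reached, -1 if none."""
        if not self.event_times:
            return -1
        return max(EVENT_INDEX[e] for e in self.event_times)


@dataclass
class Dataset:
    """A collection of embryo observations plus free-text provenance."""

    observations: list[EmbryoObservation]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for obs in self.observations:
            if obs.embryo_id in seen:
                raise ValidationError(f"duplicate embryo_id {obs.embryo_id!r}")
            seen.add(obs.embryo_id)
            obs.validate()

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def conditions(self) -> list[Condition]:
        """Distinct conditions, in first-appearance order."""
        out: list[Condition] = []
        for obs in self.observations:
            if obs.condition not in out:
                out.append(obs.condition)
        return out

    def temperatures(self) -> list[float]:
        out: list[float] = []
        for obs in self.observations:
            t = obs.condition.temperature_celsius
            if t not in out:
                out.append(t)
        return out


def total_dev_time(
    obs: EmbryoObservation,
    start_event: str = ANCHOR_START,
    end_event: str = ANCHOR_END,
) -> float:
    """Elapsed hours between two landmarks of one embryo.

    Raises :class:`CensoringError` if the embryo never reached either landmark.
    """
    for e in (start_event, end_event):
        if e not in EVENT_INDEX:
            raise ValidationError(f"unknown event {e!r}")
        if e not in obs.event_times:
            raise CensoringError(
                f"embryo {obs.embryo_id!r}: event {e!r} not observed (censored)"
            )
    return obs.event_times[end_event] - obs.event_times[start_event]


def _parse_hatched(value, embryo_id: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise FormatError(f"embryo {embryo_id!r}: cannot parse hatched flag {value!r}")


def read_event_table(path: str | Path) -> Dataset:
    """Read a per-embryo event-time CSV into a validated :class:`Dataset`.

    Expected header: embryo_id, oxygen_percent, temperature_celsius, the nine
    landmark columns in catalog order, hatched.  Empty landmark fields mean
    the embryo never reached that event.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"embryo_id": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    observations: list[EmbryoObservation] = []
    for _, row in df.iterrows():
        embryo_id = str(row["embryo_id"])
        cond = Condition(float(row["oxygen_percent"]), float(row["temperature_celsius"]))
        times: dict[str, float] = {}
        for e in EVENTS:
            v = row[e]
            if pd.isna(v):
                continue
            times[e] = float(v)
        observations.append(
            EmbryoObservation(
                embryo_id=embryo_id,
                condition=cond,
                event_times=times,
                hatched=_parse_hatched(row["hatched"], embryo_id),
            )
        )
    ds = Dataset(observations=observations, metadata={"source": str(path)})
    ds.validate()
    return ds


def write_event_table(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as CSV with canonical column order.

    Absent events serialize as empty fields; times use 12 significant digits so
    a read-back reproduces values to well under 1e-9 relative error.
    """
    path = Path(path)
    rows = []
    for obs in dataset.observations:
        row: dict[str, object] = {
            "embryo_id": obs.embryo_id,
            "oxygen_percent": obs.condition.oxygen_percent,
            "temperature_celsius": obs.condition.temperature_celsius,
        }
        for e in EVENTS:
            row[e] = obs.event_times.get(e, None)
        row["hatched"] = "true" if obs.hatched else "false"
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_CSV_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")
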