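"""List-mode event model, two-hit selection, windowing and CSV I/O.

A trigger can contain any number of energy deposits; only "two-hit"
triggers -- exactly one above-threshold hit in a Si scatterer layer and
one in a CdTe absorber layer -- are accepted as Compton events.  Events
may carry an optional ground-truth tag (emission point, incident energy,
background flag) so that synthetic runs support parameter-recovery
tests; every filter passes the tag through untouched.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default hit-discrimination threshold (keV) in both detector classes.
DEFAULT_HIT_THRESHOLD_KEV = 20.0

N_SI_LAYERS = 8
N_CDTE_LAYERS = 4


class Detector(enum.Enum):
    SI = "SI"
    CDTE = "CDTE"


@dataclass(frozen=True)
class Hit:
    """One energy deposit: detector class, layer, lab position (mm), keV."""

    detector: Detector
    layer: int
    position: tuple[float, float, float]
    energy: float

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise ValueError("hit energy must be non-negative")
        n_layers = N_SI_LAYERS if self.detector is Detector.SI else N_CDTE_LAYERS
        if not 0 <= self.layer < n_layers:
            raise ValueError(
                f"layer {self.layer} outside {self.detector.value} stack (0..{n_layers - 1})"
            )


@dataclass(frozen=True)
class GroundTruthTag:
    """Generator-side truth carried through all filters unmodified."""

    emission_point: tuple[float, float, float]
    true_e0: float
    is_background: bool = False


@dataclass(frozen=True)
class TriggerGroup:
    """All deposits recorded for one trigger, before selection."""

    t_s: float
    hits: tuple[Hit, ...]
    truth: Optional[GroundTruthTag] = None


@dataclass(frozen=True)
class ComptonEvent:
    """A selected Si-scatter + CdTe-absorb coincidence."""

    scatter_hit: Hit
    absorb_hit: Hit
    t_s: float = 0.0
    truth: Optional[GroundTruthTag] = None
    event_id: int = -1

    def __post_init__(self) -> None:
        if self.scatter_hit.detector is not Detector.SI:
            raise ValueError("scatter hit must be in the Si stack")
        if self.absorb_hit.detector is not Detector.CDTE:
            raise ValueError("absorb hit must be in the CdTe stack")

    @property
    def total_energy(self) -> float:
        return self.scatter_hit.energy + self.absorb_hit.energy


@dataclass(frozen=True)
class EnergyWindow:
    """Closed summed-energy interval [lo, hi] keV with a display label."""

    label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("energy window requires lo < hi")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, energy: float) -> bool:
        return self.lo <= energy <= self.hi


def select_compton_events(
    raw_events: Iterable[TriggerGroup],
    hit_threshold: float = DEFAULT_HIT_THRESHOLD_KEV,
) -> list[ComptonEvent]:
    """Keep triggers that reduce to exactly one Si hit plus one CdTe hit.

    Deposits below ``hit_threshold`` are discarded first; a trigger then
    survives only if precisely one hit remains in each detector class
    (no pairing heuristics for >=2 surviving same-class hits -- those
    triggers are dropped whole).  Input order is preserved; malformed
    groups are rejected per-record and counted in the log.
    """
    if hit_threshold < 0:
        raise ValueError("hit threshold must be non-negative")
    selected: list[ComptonEvent] = []
    n_rejected_malformed = 0
    for i, group in enumerate(raw_events):
        try:
            surviving = [h for h in group.hits if h.energy >= hit_threshold]
            si = [h for h in surviving if h.detector is Detector.SI]
            cdte = [h for h in surviving if h.detector is Detector.CDTE]
        except (AttributeError, TypeError):
            n_rejected_malformed += 1
            continue
        if len(si) == 1 and len(cdte) == 1:
            selected.append(
                ComptonEvent(
                    scatter_hit=si[0],
                    absorb_hit=cdte[0],
                    t_s=group.t_s,
                    truth=group.truth,
                    event_id=i,
                )
            )
    if n_rejected_malformed:
        log.warning("rejected %d malformed trigger records", n_rejected_malformed)
    return selected


def apply_energy_window(
    events: Sequence[ComptonEvent], window: EnergyWindow
) -> list[ComptonEvent]:
    """Retain events whose summed energy lies inside the closed window."""
    return [ev for ev in events if window.contains(ev.total_energy)]


# ---------------------------------------------------------------------------
# Delimited-text I/O.  One row per Compton event, UTF-8 CSV with a mandatory
# header; optional truth_* columns round-trip the GroundTruthTag.

_BASE_COLUMNS = [
    "event_id", "t_s",
    "det1", "layer1", "x1_mm", "y1_mm", "z1_mm", "e1_keV",
    "det2", "layer2", "x2_mm", "y2_mm", "z2_mm", "e2_keV",
]
_TRUTH_COLUMNS = ["truth_x_mm", "truth_y_mm", "truth_z_mm", "truth_e0_keV", "truth_bg"]
_NUMERIC_COLUMNS = [c for c in _BASE_COLUMNS + _TRUTH_COLUMNS if c not in ("det1", "det2")]


def events_to_frame(events: Sequence[ComptonEvent]) -> pd.DataFrame:
    """Tabulate events; truth columns appear only if any event is tagged."""
    rows = []
    any_truth = any(ev.truth is not None for ev in events)
    for ev in events:
        s, a = ev.scatter_hit, ev.absorb_hit
        row = {
            "event_id": ev.event_id, "t_s": ev.t_s,
            "det1": s.detector.value, "layer1": s.layer,
            "x1_mm": s.position[0], "y1_mm": s.position[1], "z1_mm": s.position[2],
            "e1_keV": s.energy,
            "det2": a.detector.value, "layer2": a.layer,
            "x2_mm": a.position[0], "y2_mm": a.position[1], "z2_mm": a.position[2],
            "e2_keV": a.energy,
        }
        if any_truth:
            t = ev.truth
            row.update(
                truth_x_mm=t.emission_point[0] if t else np.nan,
                truth_y_mm=t.emission_point[1] if t else np.nan,
                truth_z_mm=t.emission_point[2] if t else np.nan,
                truth_e0_keV=t.true_e0 if t else np.nan,
                truth_bg=int(t.is_background) if t else 0,
            )
        rows.append(row)
    columns = _BASE_COLUMNS + (_TRUTH_COLUMNS if any_truth else [])
    return pd.DataFrame(rows, columns=columns)


def write_events(events: Sequence[ComptonEvent], path) -> None:
    """Write the event table as UTF-8 CSV (see :data:`_BASE_COLUMNS`)."""
    events_to_frame(events).to_csv(path, index=False)


def _frame_to_events(df: pd.DataFrame) -> list[ComptonEvent]:
    has_truth = all(c in df.columns for c in _TRUTH_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        truth = None
        if has_truth:
            truth = GroundTruthTag(
                emission_point=(row.truth_x_mm, row.truth_y_mm, row.truth_z_mm),
                true_e0=row.truth_e0_keV,
                is_background=bool(row.truth_bg),
            )
        out.append(
            ComptonEvent(
                scatter_hit=Hit(Detector(row.det1), int(row.layer1),
                                (row.x1_mm, row.y1_mm, row.z1_mm), row.e1_keV),
                absorb_hit=Hit(Detector(row.det2), int(row.layer2),
                               (row.x2_mm, row.y2_mm, row.z2_mm), row.e2_keV),
                t_s=row.t_s,
                truth=truth,
                event_id=int(row.event_id),
            )
        )
    return out


def read_events(path) -> list[ComptonEvent]:
    """Read an event CSV written by :func:`write_events`.

    Unknown columns are ignored with a warning; non-numeric values in
    numeric columns raise an error naming the offending file lines
    (1-based, header included).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in _BASE_COLUMNS + _TRUTH_COLUMNS]
    if unknown:
        warnings.warn(f"{Path(path).name}: ignoring unknown columns {unknown}")
        df = df.drop(columns=unknown)
    bad_lines: set[int] = set()
    for col in df.columns:
        if col in ("det1", "det2"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        bad_lines.update(int(i) + 2 for i in bad)  # +2: header + 1-based
        df[col] = coerced
    if bad_lines:
        raise ValueError(
            f"{path}: non-numeric values on line(s) {sorted(bad_lines)}"
        )
    return _frame_to_events(df)
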