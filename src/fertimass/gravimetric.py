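"""Container mass logs -> irrigation events, transpiration, cumulative water use.

Balances under each container log mass every 10 minutes.  Mass rises
abruptly when a dripper fires and declines smoothly as the plant
transpires (substrate surfaces are covered, so evaporation is neglected).
Transpired water is recovered by splitting the trace at detected
irrigation events and differencing segment endpoints, at 1 g = 1 mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import InvalidInputError

#: Default mass-gain threshold (g) separating dripper events from noise.
DEFAULT_EVENT_THRESHOLD_G = 50.0
#: Default rolling-median window (samples) applied before differencing.
DEFAULT_SMOOTH_WINDOW = 3

GRAMS_PER_LITRE = 1000.0


@dataclass
class MassSeries:
    """Timestamped mass trace (g) for one container at ~10-min cadence."""

    container_id: str
    times: np.ndarray  # datetime64[ns], strictly increasing
    masses: np.ndarray  # g, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.shape != self.masses.shape:
            raise InvalidInputError(
                f"container {self.container_id}: times/masses length mismatch"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times).astype(int) > 0):
            raise InvalidInputError(
                f"container {self.container_id}: timestamps must be strictly increasing"
            )
        if np.any(self.masses < 0) or not np.all(np.isfinite(self.masses)):
            raise InvalidInputError(
                f"container {self.container_id}: masses must be finite and >= 0"
            )

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, container_id: str) -> "MassSeries":
        sub = df.loc[df["container_id"] == container_id]
        return cls(
            container_id=container_id,
            times=pd.to_datetime(sub["timestamp"]).to_numpy(),
            masses=sub["mass_g"].to_numpy(dtype=float),
        )

    def slice_window(self, start: np.datetime64, end: np.datetime64) -> "MassSeries":
        """Sub-series with start <= t <= end (may be empty)."""
        mask = (self.times >= start) & (self.times <= end)
        return MassSeries(self.container_id, self.times[mask], self.masses[mask])


@dataclass(frozen=True)
class IrrigationEvent:
    timestamp: np.datetime64
    mass_gain: float  # g


@dataclass
class TranspirationSummary:
    """Per-segment and per-day water loss for one container, litres."""

    container_id: str
    segments: pd.DataFrame  # columns: start, end, loss_g, loss_L
    daily: pd.Series  # index: date, values: L
    total_L: float


def _smooth(masses: np.ndarray, window: int | None) -> np.ndarray:
    """Rolling-median smoothing; edge samples are preserved for monotone data.

    ``mode='nearest'`` replicates the boundary sample into the window, so a
    noise-free monotone trace passes through unchanged (including its
    endpoints) and isolated spikes are suppressed.
    """
    if window is None or window <= 1 or len(masses) < 3:
        return masses
    return median_filter(masses, size=window, mode="nearest")


def detect_irrigation_events(
    series: MassSeries,
    threshold: float = DEFAULT_EVENT_THRESHOLD_G,
    *,
    smooth_window: int | None = None,
) -> list[IrrigationEvent]:
    """One event per consecutive-sample mass increase >= ``threshold`` grams.

    Smaller increases are treated as balance noise.  The event timestamp is
    the first sample at the raised mass.
    """
    if len(series) == 0:
        raise InvalidInputError("mass series is empty")
    if threshold <= 0:
        raise InvalidInputError("event threshold must be > 0")
    masses = _smooth(series.masses, smooth_window)
    gains = np.diff(masses)
    idx = np.nonzero(gains >= threshold)[0]
    return [
        IrrigationEvent(timestamp=series.times[i + 1], mass_gain=float(gains[i]))
        for i in idx
    ]


def segment_water_loss(
    series: MassSeries,
    events: Sequence[IrrigationEvent],
    *,
    smooth_window: int | None = DEFAULT_SMOOTH_WINDOW,
) -> TranspirationSummary:
    """Water loss per inter-event segment and per calendar day.

    Each segment spans from one event (or the series start) to the last
    sample before the next event.  Loss = segment start mass - end mass
    after median smoothing, clipped at zero (a segment cannot transpire a
    negative volume); converted at 1 g = 1 mL.  Segment losses are
    attributed to the calendar date of the segment start.
    """
    n = len(series)
    if n < 2:
        empty = pd.DataFrame(columns=["start", "end", "loss_g", "loss_L"])
        return TranspirationSummary(
            container_id=series.container_id,
            segments=empty,
            daily=pd.Series(dtype=float),
            total_L=0.0,
        )
    event_times = np.array([e.timestamp for e in events], dtype="datetime64[ns]")
    if len(event_times) > 1 and not np.all(np.diff(event_times).astype(int) > 0):
        raise InvalidInputError("events must be sorted and unique")
    # Map event timestamps to sample indices; events must come from the series.
    bounds = [0]
    for t in event_times:
        pos = np.searchsorted(series.times, t)
        if pos >= n or series.times[pos] != t:
            raise InvalidInputError(
                f"event at {t} does not match a sample timestamp"
            )
        if pos != 0:
            bounds.append(int(pos))
    bounds.append(n)

    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        # Smooth within the segment only: a window straddling an irrigation
        # jump would contaminate the segment-boundary masses.
        seg = _smooth(series.masses[a:b], smooth_window)
        loss_g = max(float(seg[0] - seg[-1]), 0.0)
        rows.append(
            {
                "start": series.times[a],
                "end": series.times[b - 1],
                "loss_g": loss_g,
                "loss_L": loss_g / GRAMS_PER_LITRE,
            }
        )
    segments = pd.DataFrame(rows, columns=["start", "end", "loss_g", "loss_L"])
    if len(segments):
        daily = segments.groupby(pd.to_datetime(segments["start"]).dt.date)[
            "loss_L"
        ].sum()
        daily.index.name = "date"
    else:
        daily = pd.Series(dtype=float)
    return TranspirationSummary(
        container_id=series.container_id,
        segments=segments,
        daily=daily,
        total_L=float(segments["loss_L"].sum()) if len(segments) else 0.0,
    )


def analyze_series(
    series: MassSeries,
    *,
    threshold: float = DEFAULT_EVENT_THRESHOLD_G,
    smooth_window: int | None = DEFAULT_SMOOTH_WINDOW,
) -> tuple[list[IrrigationEvent], TranspirationSummary]:
    """Detect events then summarize water loss in one call."""
    events = detect_irrigation_events(series, threshold)
    return events, segment_water_loss(series, events, smooth_window=smooth_window)


def window_water_loss(
    series: MassSeries,
    date,
    *,
    start_time: str = "07:00",
    end_time: str = "19:00",
    threshold: float = DEFAULT_EVENT_THRESHOLD_G,
    smooth_window: int | None = DEFAULT_SMOOTH_WINDOW,
) -> float:
    """Water loss (L) within a clock window on one date.

    Used for the 12-h uptake-cycle transpired volume: the trace is sliced
    to the window, events inside it are detected and the per-segment losses
    summed, so a refill inside the window does not masquerade as negative
    transpiration.
    """
    day = pd.Timestamp(date)
    lo = np.datetime64(pd.Timestamp(f"{day.date()} {start_time}"))
    hi = np.datetime64(pd.Timestamp(f"{day.date()} {end_time}"))
    sub = series.slice_window(lo, hi)
    if len(sub) < 2:
        return 0.0
    events = detect_irrigation_events(sub, threshold)
    # Drop an event landing on the very first sample: no pre-event span exists.
    events = [e for e in events if e.timestamp != sub.times[0]]
    return segment_water_loss(sub, events, smooth_window=smooth_window).total_L


def cumulative_water_use(summaries: Iterable[TranspirationSummary]) -> float:
    """Total water use (L) over the phase from per-window summaries.

    Summaries must belong to one plant and cover non-overlapping date
    ranges (overlap would double-count transpiration).
    """
    summaries = [s for s in summaries if len(s.daily)]
    spans = sorted(
        ((s.daily.index.min(), s.daily.index.max(), s) for s in summaries),
        key=lambda t: t[0],
    )
    for (_, prev_end, _), (next_start, _, _) in zip(spans, spans[1:]):
        if next_start <= prev_end:
            raise InvalidInputError(
                "transpiration summaries cover overlapping date windows"
            )
    return float(sum(s.total_L for _, _, s in spans))
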