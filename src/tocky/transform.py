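"""Pre-processing and trigonometric transformation of Timer flow data.

A flow-cytometry sample arrives as an event table of compensated
fluorescence (one row per event).  The pipeline is:

1. ``derive_thresholds`` — per-channel detection thresholds from the
   empirical quantile (default 0.999) of a Timer-negative control.
2. ``gate_timer_positive`` — an event is Timer-positive iff its blue OR
   red fluorescence strictly exceeds the channel threshold.
3. ``timer_transform`` — threshold-subtracted fluorescence is normalised
   per channel to [0, 1] against a robust reference (default the 97.5th
   percentile of positive events) and converted to polar coordinates in
   the Blue-Red plane: Timer-Angle (degrees from the Blue axis, 0-90)
   and Timer-Intensity (Euclidean norm of the normalised pair).

Angle 0 means pure blue (new transcription), 90 pure red (arrested),
45 the balanced steady state of persistent transcription.  The angle is
computed on linear threshold-subtracted fluorescence: the 0/45/90-degree
anchors only hold on a ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelMap",
    "ChannelThresholds",
    "TimerEvents",
    "derive_thresholds",
    "gate_timer_positive",
    "timer_transform",
    "polar_from_normalised",
]

BLUE = "timer_blue"
RED = "timer_red"


@dataclass(frozen=True)
class ChannelMap:
    """Maps the cytometer's column names onto blue / red / marker roles.

    FlowJo CSV exports label columns by detector (e.g. "BV421-A"); the
    default map matches the column names this package's simulator emits.
    """

    blue: str = BLUE
    red: str = RED
    markers: tuple[str, ...] = ()

    def require(self, frame: pd.DataFrame) -> None:
        missing = [c for c in (self.blue, self.red, *self.markers) if c not in frame.columns]
        if missing:
            raise KeyError(f"channels missing from event table: {missing}")


@dataclass(frozen=True)
class ChannelThresholds:
    """Per-channel positivity thresholds with their provenance."""

    blue: float
    red: float
    quantile: float
    control_id: str = "control"
    n_control: int = 0


@dataclass
class TimerEvents:
    """Event table annotated through gating and transformation.

    ``data`` gains columns: positive (bool), then after transform
    norm_blue, norm_red in [0, 1], timer_angle (degrees, NaN for
    negative events) and timer_intensity.
    """

    data: pd.DataFrame
    channels: ChannelMap
    thresholds: ChannelThresholds
    norm_quantile: float | None = None
    references: dict = field(default_factory=dict)
    label: str = "sample"

    @property
    def n_positive(self) -> int:
        return int(self.data["positive"].sum())

    def positive(self) -> pd.DataFrame:
        return self.data[self.data["positive"]]

    @property
    def angles(self) -> np.ndarray:
        """Timer-Angle values of positive events (degrees)."""
        return self.positive()["timer_angle"].to_numpy()


def derive_thresholds(
    control: pd.DataFrame,
    quantile: float = 0.999,
    channels: ChannelMap = ChannelMap(),
    control_id: str = "control",
    min_events: int = 100,
) -> ChannelThresholds:
    """Detection thresholds = empirical control quantile per channel.

    The control must be a Timer-negative sample measured under the same
    conditions; at least ``min_events`` events are required for the tail
    quantile to be meaningful.
    """
    channels.require(control)
    if len(control) < min_events:
        raise ValueError(
            f"control has {len(control)} events; at least {min_events} required"
        )
    if not 0.5 < quantile < 1.0:
        raise ValueError("quantile must be in (0.5, 1)")
    blue = float(np.quantile(control[channels.blue].to_numpy(), quantile))
    red = float(np.quantile(control[channels.red].to_numpy(), quantile))
    return ChannelThresholds(
        blue=max(blue, 0.0),
        red=max(red, 0.0),
        quantile=quantile,
        control_id=control_id,
        n_control=len(control),
    )


def gate_timer_positive(
    frame: pd.DataFrame,
    thresholds: ChannelThresholds,
    channels: ChannelMap = ChannelMap(),
    label: str = "sample",
) -> TimerEvents:
    """Flag Timer-positive events: blue OR red strictly above threshold.

    Ties at exactly the threshold count as negative.
    """
    channels.require(frame)
    data = frame.copy()
    if not np.isfinite(data[[channels.blue, channels.red]].to_numpy()).all():
        raise ValueError("non-finite fluorescence values in event table")
    data["positive"] = (data[channels.blue] > thresholds.blue) | (
        data[channels.red] > thresholds.red
    )
    return TimerEvents(data=data, channels=channels, thresholds=thresholds, label=label)


def polar_from_normalised(
    norm_blue: np.ndarray, norm_red: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Timer-Angle (degrees from the Blue axis) and Timer-Intensity.

    angle = arctan(norm_red / norm_blue); 0 when red is zero, 90 when
    blue is zero.  intensity = sqrt(norm_blue^2 + norm_red^2).
    """
    nb = np.asarray(norm_blue, dtype=float)
    nr = np.asarray(norm_red, dtype=float)
    if np.any(nb < 0) or np.any(nr < 0):
        raise ValueError("normalised values must be >= 0")
    angle = np.degrees(np.arctan2(nr, nb))
    intensity = np.hypot(nb, nr)
    return angle, intensity


def _normalise_channel(
    raw: np.ndarray, threshold: float, norm_quantile: float
) -> tuple[np.ndarray, float]:
    """Threshold-subtract and scale one channel over positive events.

    The reference is the norm_quantile-quantile of the positive events'
    raw fluorescence; values clip to [0, 1].  If no event exceeds the
    threshold in this channel, all normalised values are exactly 0 (the
    channel carries no signal).
    """
    excess = np.maximum(raw - threshold, 0.0)
    above = excess > 0
    if not above.any():
        return np.zeros_like(excess), float(threshold)
    reference = float(np.quantile(raw, norm_quantile))
    if reference <= threshold:
        # the above-threshold events are a tail smaller than the quantile
        # allowance (typical of a channel carrying background only, e.g.
        # blue in a long-arrested sample): values above the reference clip
        # to 1, the rest are 0 — the limit of the formula below
        return np.where(above, 1.0, 0.0), reference
    return np.clip(excess / (reference - threshold), 0.0, 1.0), reference


def timer_transform(events: TimerEvents, norm_quantile: float = 0.975) -> TimerEvents:
    """Normalise positive events per channel and compute angle/intensity.

    Operates on Timer-positive events only (negative events get NaN).
    Returns the same TimerEvents with norm_blue, norm_red, timer_angle
    and timer_intensity columns filled and references recorded.
    """
    if "positive" not in events.data.columns:
        raise ValueError("run gate_timer_positive before timer_transform")
    if not 0 < norm_quantile <= 1:
        raise ValueError("norm_quantile must be in (0, 1]")
    pos = events.data["positive"].to_numpy()
    if pos.sum() < 1:
        raise ValueError("no Timer-positive events to transform")

    ch, th = events.channels, events.thresholds
    raw_blue = events.data.loc[pos, ch.blue].to_numpy(dtype=float)
    raw_red = events.data.loc[pos, ch.red].to_numpy(dtype=float)
    nb, ref_b = _normalise_channel(raw_blue, th.blue, norm_quantile)
    nr, ref_r = _normalise_channel(raw_red, th.red, norm_quantile)
    angle, intensity = polar_from_normalised(nb, nr)

    for col in ("norm_blue", "norm_red", "timer_angle", "timer_intensity"):
        events.data[col] = np.nan
    events.data.loc[pos, "norm_blue"] = nb
    events.data.loc[pos, "norm_red"] = nr
    events.data.loc[pos, "timer_angle"] = angle
    events.data.loc[pos, "timer_intensity"] = intensity
    events.norm_quantile = norm_quantile
    events.references = {"blue": ref_b, "red": ref_r}
    return events
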