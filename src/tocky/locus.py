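"""Timer-locus classification and per-sample summaries.

Timer-positive events are assigned to five transcription-dynamics loci
by their Timer-Angle: New (angle 0 — pure blue, transcription just
started), NPt (0-30, new-to-persistent transitional), Persistent (30-60,
balanced blue/red steady state), PAt (60-90, persistent-to-arrested
transitional) and Arrested (angle 90 — pure red, transcription stopped).
Persistent is closed [30, 60]; the transitional bands are open; New and
Arrested are the exact 0/90 anchors widened by an optional tolerance
band, since the measured angle is continuous.

Also provides per-sample locus summaries with the minimum-cell-count QC
rule (samples with fewer than 20 Timer-positive events are excluded from
group statistics by default), a boundary-corrected kernel density of
Timer-Angle on [0, 90], and per-locus marker-MFI profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist

from .transform import TimerEvents

__all__ = [
    "LOCI",
    "classify_locus",
    "LocusSummary",
    "summarize_sample",
    "AngleDensity",
    "angle_density",
    "locus_marker_profile",
]

LOCI = ("New", "NPt", "Persistent", "PAt", "Arrested")

DEFAULT_MIN_N = 20  # minimum Timer+ events for a sample to enter statistics


def classify_locus(angle, tolerance: float = 0.0):
    """Assign Timer loci to angles (degrees in [0, 90]).

    New:        angle <= tolerance        (exactly 0 by default)
    NPt:        tolerance < angle < 30
    Persistent: 30 <= angle <= 60         (boundaries inclusive)
    PAt:        60 < angle < 90 - tolerance
    Arrested:   angle >= 90 - tolerance

    The five intervals partition [0, 90]: every angle receives exactly
    one label.  Scalar in, scalar out; array in, object array out.
    """
    a = np.asarray(angle, dtype=float)
    if not 0 <= tolerance < 30:
        raise ValueError("tolerance must be in [0, 30)")
    if np.any((a < 0) | (a > 90)) or not np.all(np.isfinite(a)):
        raise ValueError("angles must lie in [0, 90]")
    out = np.empty(a.shape, dtype=object)
    out[a <= tolerance] = "New"
    out[(a > tolerance) & (a < 30)] = "NPt"
    out[(a >= 30) & (a <= 60)] = "Persistent"
    out[(a > 60) & (a < 90 - tolerance)] = "PAt"
    out[a >= 90 - tolerance] = "Arrested"
    if a.ndim == 0:
        return out.item()
    return out


@dataclass
class LocusSummary:
    """Per-sample Timer-locus composition and summary statistics."""

    label: str
    n_positive: int
    n_total: int
    fractions: dict[str, float]
    mean_angle: float
    mean_blue_mfi: float
    mean_red_mfi: float
    qc_included: bool
    min_n: int
    tolerance: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        row = {
            "sample": self.label,
            "n_positive": self.n_positive,
            "n_total": self.n_total,
            "mean_angle": self.mean_angle,
            "mean_blue_mfi": self.mean_blue_mfi,
            "mean_red_mfi": self.mean_red_mfi,
            "qc_included": self.qc_included,
            "min_n": self.min_n,
        }
        for locus in LOCI:
            row[f"frac_{locus}"] = self.fractions[locus]
        return pd.DataFrame([row])


def summarize_sample(
    events: TimerEvents,
    min_n: int = DEFAULT_MIN_N,
    tolerance: float = 0.0,
) -> LocusSummary:
    """Locus fractions, mean angle and mean raw MFIs over positive events.

    Samples with fewer than ``min_n`` Timer-positive events are flagged
    ``qc_included=False`` and should be excluded from group statistics;
    their summary values are still reported (NaN when undefined).
    """
    if "timer_angle" not in events.data.columns:
        raise ValueError("events must be transformed before summarising")
    pos = events.positive()
    n_pos = len(pos)
    if n_pos == 0:
        fractions = {locus: float("nan") for locus in LOCI}
        mean_angle = mean_b = mean_r = float("nan")
    else:
        labels = classify_locus(pos["timer_angle"].to_numpy(), tolerance)
        counts = pd.Series(labels).value_counts()
        fractions = {locus: float(counts.get(locus, 0)) / n_pos for locus in LOCI}
        mean_angle = float(pos["timer_angle"].mean())
        mean_b = float(pos[events.channels.blue].mean())
        mean_r = float(pos[events.channels.red].mean())
    return LocusSummary(
        label=events.label,
        n_positive=n_pos,
        n_total=len(events.data),
        fractions=fractions,
        mean_angle=mean_angle,
        mean_blue_mfi=mean_b,
        mean_red_mfi=mean_r,
        qc_included=n_pos >= min_n,
        min_n=min_n,
        tolerance=tolerance,
    )


@dataclass
class AngleDensity:
    """Kernel-density estimate of Timer-Angle on the bounded support [0, 90]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle": self.grid, "density": self.density})


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * len(x) ** (-0.2)


def angle_density(
    angles: Sequence[float],
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> AngleDensity:
    """Gaussian KDE of Timer-Angle with boundary reflection at 0 and 90.

    Probability mass that a plain Gaussian kernel would spill below 0 or
    above 90 is folded back by reflecting the data about both boundaries,
    so the density is supported on [0, 90] and integrates to 1 there.
    Bandwidth defaults to Silverman's rule (degrees); a degenerate sample
    (all angles identical) requires an explicit bandwidth.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 angles for a density estimate")
    if np.any((a < 0) | (a > 90)):
        raise ValueError("angles must lie in [0, 90]")
    if bandwidth is None:
        bandwidth = _silverman_bandwidth(a)
        if bandwidth <= 0:
            raise ValueError(
                "degenerate sample (zero spread): supply an explicit bandwidth"
            )
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    grid = np.linspace(0.0, 90.0, grid_size)
    dens = np.zeros_like(grid)
    h = float(bandwidth)
    # reflected images about 0 and 90 fold escaping mass back into [0, 90]
    norm_const = 1.0 / (a.size * h * np.sqrt(2.0 * np.pi))
    for chunk in np.array_split(a, max(1, a.size // 2000)):
        for data in (chunk, -chunk, 180.0 - chunk):
            z = (grid[:, None] - data[None, :]) / h
            dens += norm_const * np.exp(-0.5 * z**2).sum(axis=1)
    # residual leakage beyond the single reflection is O(exp(-(90/h)^2/2));
    # renormalise numerically so the integral over [0, 90] is exactly 1
    integral = np.trapezoid(dens, grid)
    dens /= integral
    return AngleDensity(grid=grid, density=dens, bandwidth=h, n=a.size)


def locus_marker_profile(
    events: TimerEvents,
    markers: Sequence[str],
    tolerance: float = 0.0,
    standardize: bool = False,
    cluster_markers: bool = False,
):
    """Mean marker MFI per Timer locus (loci as rows, markers as columns).

    Loci with no events are kept as all-NaN rows and reported in the
    ``missing`` attribute rather than imputed.  With ``standardize`` each
    marker column is z-scored across loci (heatmap convention).  With
    ``cluster_markers`` the columns are ordered by complete-linkage
    hierarchical clustering on the (standardised) locus profiles,
    computed on non-missing loci only.
    """
    unknown = [m for m in markers if m not in events.data.columns]
    if unknown:
        raise KeyError(f"unknown marker channels: {unknown}")
    pos = events.positive().copy()
    if "timer_angle" not in pos.columns:
        raise ValueError("events must be transformed first")
    pos["locus"] = classify_locus(pos["timer_angle"].to_numpy(), tolerance)
    table = (
        pos.groupby("locus")[list(markers)].mean().reindex(list(LOCI))
    )
    table.index.name = "locus"
    missing = [locus for locus in LOCI if locus not in pos["locus"].values]
    if standardize:
        table = (table - table.mean(axis=0)) / table.std(axis=0, ddof=0)
    if cluster_markers and len(markers) > 2:
        complete_rows = table.dropna(axis=0)
        dist = pdist(complete_rows.to_numpy().T)
        order = leaves_list(complete(dist))
        table = table.iloc[:, order]
    table.attrs["missing"] = missing
    return table
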