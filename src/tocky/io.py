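"""CSV I/O in the FlowJo-export convention (header row of channel names,
one row per event) and tidy decay-series tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .kinetics import DecaySeries, PopulationSample

__all__ = ["write_events_csv", "read_events_csv", "write_decay_csv", "read_decay_csv"]


def write_events_csv(sample: PopulationSample, directory: str | Path) -> tuple[Path, Path]:
    """Write a sample and its paired negative control as CSV event tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    events_path = directory / f"{sample.label}.csv"
    control_path = directory / f"{sample.label}_control.csv"
    sample.events.to_csv(events_path, index=False)
    sample.control.to_csv(control_path, index=False)
    return events_path, control_path


def read_events_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty event table: {path}")
    return frame


def write_decay_csv(series: dict[str, DecaySeries], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tidy = pd.concat(
        [s.to_frame().assign(series=name) for name, s in series.items()], ignore_index=True
    )
    tidy.to_csv(path, index=False)
    return path


def read_decay_csv(path: str | Path) -> dict[str, DecaySeries]:
    tidy = pd.read_csv(path)
    out = {}
    for name, grp in tidy.groupby("series"):
        out[name] = DecaySeries(
            times=grp["time_h"].to_numpy(),
            values=grp["value"].to_numpy(),
            readout=str(grp["readout"].iloc[0]),
            replicate=grp["replicate"].to_numpy(),
        )
    return out
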