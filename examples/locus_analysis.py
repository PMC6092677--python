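"""Simulate a mixed T-cell sample and run the full Timer-Angle analysis.

Builds a population with three transcriptional behaviours (newly induced,
persistent, long arrested), gates it against its paired negative control,
applies the trigonometric Blue-Red transform and summarises the locus
composition.
"""

import numpy as np

from tocky import (
    MeasurementModel,
    MixtureComponent,
    TimerKineticParams,
    TranscriptionProgram,
    angle_density,
    derive_thresholds,
    gate_timer_positive,
    simulate_population,
    summarize_sample,
    timer_transform,
)

params = TimerKineticParams()
mixture = [
    MixtureComponent(TranscriptionProgram.new_onset(0.0), 0.15, onset_age=(0.5, 4.0)),
    MixtureComponent(TranscriptionProgram.persistent(), 0.45, onset_age=(100.0, 400.0)),
    MixtureComponent(TranscriptionProgram.arrested(t_stop=50.0), 0.40, onset_age=(100.0, 300.0)),
]
sample = simulate_population(
    mixture, n_cells=3000, params=params, noise=MeasurementModel(), seed=42, label="dLN"
)

thresholds = derive_thresholds(sample.control, quantile=0.999)
events = gate_timer_positive(sample.events, thresholds, label="dLN")
events = timer_transform(events, norm_quantile=0.975)
summary = summarize_sample(events, min_n=20)

print(f"thresholds: blue {thresholds.blue:.0f}, red {thresholds.red:.0f} (q=0.999)")
print(f"Timer+ events: {summary.n_positive}/{summary.n_total}  "
      f"mean angle {summary.mean_angle:.1f} deg  QC pass: {summary.qc_included}")
for locus, frac in summary.fractions.items():
    print(f"  {locus:<10s} {100 * frac:5.1f} %")

dens = angle_density(events.angles)
peak = dens.grid[np.argmax(dens.density)]
print(f"angle density peak at {peak:.1f} deg (bandwidth {dens.bandwidth:.1f} deg)")

# Low angles mark cells that switched transcription on within hours;
# ~45 degrees marks the balanced persistent state; 90 degrees cells whose
# transcription stopped more than a few blue half-lives ago.
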