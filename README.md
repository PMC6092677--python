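# tocky

Kinetic simulation and flow-cytometry analysis of Fluorescent-Timer
("Tocky") reporter data.

## The problem

Fluorescent Timer protein is translated as an unstable blue fluorophore
that matures spontaneously and irreversibly into a long-lived red form.
Driven by the promoter of a gene of interest (e.g. *Foxp3* in regulatory
T cells), blue fluorescence therefore reports transcription happening
*now*, while red fluorescence integrates transcription *history*. A
two-colour flow-cytometry measurement of a single cell thus encodes the
temporal dynamics of that gene: pure blue means transcription began
within the last few hours; balanced blue/red means ongoing persistent
transcription; pure red means transcription stopped long ago.

This package provides the full analysis chain for such data, plus an
exact kinetic simulator that generates realistic synthetic samples for
testing and power analysis:

* **`tocky.kinetics`** — the mRNA → Blue → Red cascade

  $$\frac{dB}{dt} = a\,s(t) - k_B B, \qquad \frac{dR}{dt} = m B - \delta_R R$$

  with piecewise-constant transcription programmes $s(t)$ (new onset,
  persistent, arrested, intermittent), solved exactly per segment by
  matrix exponential. $k_B = \ln 2 / 4.1\,\mathrm{h}$ is the combined
  maturation + degradation loss of the blue form, $\delta_R = \ln 2 /
  122\,\mathrm{h}$ the red decay rate, and $m \le k_B$ the maturation
  flux. Includes noisy population sampling with paired negative
  controls and the three blockade experiments used for calibration
  (cycloheximide chase, red washout, actinomycin-D qPCR).
* **`tocky.transform`** — control-quantile thresholding, per-channel
  normalisation and the trigonometric transform: Timer-Angle
  $\theta = \arctan(\text{red}/\text{blue}) \in [0^\circ, 90^\circ]$
  from the Blue axis and Timer-Intensity
  $\sqrt{\text{blue}^2 + \text{red}^2}$.
* **`tocky.locus`** — classification into the five transcription-dynamics
  loci — New ($\theta = 0$), NPt ($0<\theta<30$), Persistent
  ($30 \le \theta \le 60$), PAt ($60<\theta<90$), Arrested
  ($\theta = 90$) — with per-sample summaries, boundary-corrected
  Timer-Angle kernel densities and per-locus marker profiling.
* **`tocky.halflife`** — log-linear and Ct-slope half-life estimators
  and delta-Ct relative expression.
* **`tocky.stats`** — the group-comparison conventions (Mann-Whitney,
  Kruskal-Wallis + Dunn, t-test, ANOVA + Tukey) with the minimum-cell
  QC rule: samples with fewer than 20 Timer-positive events are
  excluded before testing and listed in the audit trail.
* **`tocky.pipeline` / `tocky` CLI** — config-driven end-to-end runs
  with full provenance logging.

## Worked example

```python
from tocky import (TimerKineticParams, simulate_decay_experiment,
                   fit_log_linear_halflife)

params = TimerKineticParams()          # blue 4.1 h, red 122 h, mRNA 1.14 h
chx = simulate_decay_experiment("chx", params, [0, 2, 4, 6, 8, 12])
fit = fit_log_linear_halflife(chx["blue_mfi"])
print(f"{fit.halflife:.1f} h, r^2 = {fit.r_squared:.4f}")
```

prints `4.1 h, r^2 = 1.0000`: after a simulated cycloheximide block the
blue fluorescence decays first-order and the estimator recovers the
configured half-life exactly. `examples/locus_analysis.py` runs the full
chain on a simulated mixed sample and prints, among other lines,

```
Timer+ events: 3000/3000  mean angle 54.6 deg  QC pass: True
  New          0.2 %
  NPt         20.1 %
  Persistent  39.5 %
  PAt          0.7 %
  Arrested    39.4 %
```

— the locus composition separates recently induced, persistently
transcribing and arrested cells in the mixture. The other scripts in
`examples/` cover half-life calibration, new-expressor red-acquisition
timing, marker heatmaps and group comparisons with QC exclusions.

## Command line

```sh
tocky run --config examples/pipeline.yaml --out runs/demo --seed 1
tocky decay chx --out chx.csv && tocky halflife chx.csv
```
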