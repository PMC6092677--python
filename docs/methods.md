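# Methods

## Kinetic model

A cell's Timer content is modelled as a linear cascade driven by a
piecewise-constant transcription rate $s(t)$ (transcription units per
hour):

$$
\frac{dM}{dt} = s(t) - k_M M,\qquad
\frac{dB}{dt} = a\,M - k_B B,\qquad
\frac{dR}{dt} = m\,B - \delta_R R .
$$

$B$ is the immature blue form, $R$ the mature red form. All rates are
expressed as half-lives in hours:

| parameter | default | meaning |
|---|---|---|
| `mrna_halflife` | 1.14 h | reporter mRNA turnover, measured by the actinomycin-D Ct assay |
| `blue_loss_halflife` | 4.1 h | combined maturation + degradation loss of blue, $k_B = \ln2/4.1$ |
| `maturation_fraction` | 1.0 | share of blue loss converted to red, $m = f \cdot k_B$ |
| `red_halflife` | 122 h | red decay, $\delta_R = \ln2/122$ |
| `translation_rate` | 1 | blue units per mRNA unit per hour (sets the overall scale only) |

Two modelling choices deserve comment. First, blue loss is a single
first-order rate: a translation-blockade chase measures only the *sum*
of maturation and degradation, so the two are not separately
identifiable; `maturation_fraction` partitions the sum and defaults to
1 (all loss matures to red), which reproduces the calibration readouts
and keeps mass balance exact. Second, the mRNA stage is lumped into the
synthesis term by default because its half-life (≈1.1 h) is well below
the blue half-life (4.1 h); it can be switched on
(`include_mrna_stage=True`), and the actinomycin-D simulation models
the mRNA level directly through the Ct readout regardless.

Because $s(t)$ is piecewise constant the system is linear
time-invariant on every segment, and the state is propagated exactly by
$x(t_0+\tau) = x^* + e^{A\tau}(x_0 - x^*)$ with $x^* = -A^{-1}b$.
There is no step-size error; agreement with an adaptive numerical
integrator is verified to relative error $<10^{-8}$ over random
programmes and parameter sets. The cascade is linear in $s$, so
per-cell rate multipliers scale a cached unit-rate trajectory — this is
what makes population simulation cheap.

Steady state under constant transcription satisfies $B^* = a s/k_B$,
$R^* = m B^*/\delta_R$, giving $R^*/B^* = f \cdot 122/4.1 \approx 29.8$
at defaults: at equilibrium most Timer protein is red, which is why the
*normalised* Blue-Red plane, not the raw one, carries the angle
semantics.

## Synthetic populations and the measurement model

`simulate_population` draws, per cell: a transcription programme from a
weighted mixture, a lognormal multiplier on its rate (cell-to-cell
expression heterogeneity, default CV 0.3 — real samples show broad
per-cell Timer levels), and an onset age saying how long the programme
has been running at measurement (fixed, uniform range, or the sample
time itself for a synchronised cohort). Measured signal per channel is

$$\text{signal} = \text{scale} \cdot \text{protein} \cdot
\mathrm{LogNormal}(\mathrm{CV}) + \mathcal N(\mu_{af}, \sigma_{af}),$$

floored at zero, with a paired Timer-negative control (background only)
always emitted. Defaults: background mean 100, SD 30 arbitrary units,
measurement CV 0.2, and `signal_scale` 5000, which puts the
steady-state blue signal roughly 150-fold above the 99.9th background
percentile — a bright, well-resolved reporter. For experiments that
are specified relative to the detection limit,
`calibrated_measurement_model` sets the scale so that steady-state blue
sits an exact fold (default 50×) above the expected control threshold.
All randomness flows from explicit integer seeds; identical seed and
inputs give bit-identical tables.

What the generator emulates: programme mixtures, broad per-cell
expression, autofluorescence background, paired controls, blockade
experiments. What it does not: spectral spillover/compensation (inputs
are assumed compensated), cell division and death, doublets, acquisition
drift, spatial effects. Tests passing on these data therefore validate
the *analysis chain and its calibration logic*, not instrument-specific
artefacts.

## Blockade experiments

* **Cycloheximide (`chx`)** — translation stops at $t=0$ in cells that
  have transcribed for `pretreatment_hours` (default 24 h: activated
  cells whose blue is at steady state but whose red is still
  accumulating, about one tenth of $R^*$). Blue then decays exactly
  exponentially at $k_B$; red transiently *rises* (residual blue keeps
  maturing) before declining — the qualitative signature seen in the
  red channel after a chase. Readouts: blue/red MFI and %blue-positive
  (the latter gated against the expected control threshold using a
  broad per-cell spread, CV 1.0).
* **Red washout (`red_washout`)** — a sorted pure-red population
  without transcription: red MFI decays at $\delta_R$.
* **Actinomycin D (`actd`)** — transcription stops and the qPCR cycle
  threshold rises by one cycle per template halving:
  $Ct(t) = Ct(0) + t/t_{1/2,\mathrm{mRNA}}$.

## Thresholding, normalisation and the transform

Per-channel detection thresholds are the empirical `quantile` (default
0.999) of the paired negative control; an event is Timer-positive iff
blue or red *strictly* exceeds its threshold. Normalisation is per
channel over positive events: subtract the threshold, divide by
(reference − threshold) where the reference is the 0.975 quantile of
positive-event fluorescence, clip to [0, 1]. The quantile reference was
chosen as a robust stand-in for the channel maximum; it is configurable
and recorded in the output, and its correctness is validated
behaviourally — a noise-free homogeneous persistent-steady-state
population must map to exactly 45° — rather than claimed as the
original instrument pipeline's literal procedure. Two degenerate cases
are well-defined rather than fatal: a channel where no positive event
exceeds threshold normalises to exactly 0 (silent channel), and a
channel where only a sub-tail smaller than the quantile allowance
exceeds threshold (e.g. blue in a long-arrested sample, where the
reference quantile lands in the background) clips that tail to 1 and
the rest to 0 — the continuous limit of the formula.

Timer-Angle is computed on the linear, threshold-subtracted scale as
$\theta = \mathrm{atan2}(\text{norm red}, \text{norm blue})$ in
degrees; the 0°/45°/90° anchors only hold on a ratio scale, which is
why no log transform is applied first. Intensity is the Euclidean norm
of the normalised pair.

## Loci

New is $\theta \le$ `tolerance` (default 0: exactly 0°, i.e. red at or
below threshold), Arrested $\theta \ge 90-$`tolerance`, Persistent the
closed interval [30°, 60°], NPt and PAt the open intervals between.
Closing the Persistent boundaries (and leaving the transitional bands
open) is a determinism choice where the verbal definition ("areas
between") is open; it is pinned by tests. The tolerance parameter
exists because measured angles are continuous; note that in noise-free
simulations blue decays exponentially and never reaches exactly zero,
so classifying a long-arrested cell as Arrested requires either a
nonzero threshold (any realistic background) or a small tolerance.

Because normalisation references come from the sample itself, a
homogeneous population always self-normalises to 45°; locus enrichment
statements about a cohort are therefore evaluated inside mixtures
containing a persistent steady-state anchor population, mirroring real
samples that span the full Blue-Red range.

## Angle densities

The Timer-Angle KDE uses a Gaussian kernel with boundary reflection
about 0° and 90° (data mirrored to $-\theta$ and $180°-\theta$), so no
probability mass leaks off the support; the curve is renormalised
numerically to integrate to 1 over [0°, 90°] within $10^{-6}$.
Bandwidth defaults to Silverman's rule in degrees; a zero-spread sample
requires an explicit bandwidth. The estimator is a ~20-line direct
implementation because reflection with a caller-fixed bandwidth in
degrees and zero-variance handling are needed.

## Half-life estimators

`fit_log_linear_halflife` regresses $\ln v$ on $t$ (OLS, replicates
entering individually) and reports $t_{1/2} = \ln 2/(-\text{slope})$
with Pearson r on the fitted scale; slope ≥ 0 is flagged non-decaying
with $t_{1/2} = \infty$. A linear-scale variant (time for the fitted
straight line to fall to half its intercept) is provided because decay
fits are sometimes published on the raw scale; on noise-free
exponential data over a short window the two agree and the calibration
checks use exactly that regime. `fit_ct_halflife` regresses Ct on time
and reports $1/\text{slope}$ — one cycle per halving, no efficiency
correction. Parameter recovery is verified stochastically: with 5%
lognormal noise, 3 replicates per point and six time points spanning
three half-lives, all of 500 simulated fits per truth (1.14, 4.1,
122 h) land within 10%.

## Group comparisons and QC

`compare_groups` removes samples with fewer than `min_n` (default 20)
Timer-positive events *before* testing and records each exclusion with
the rule that removed it; a group losing all its samples is an explicit
error naming the group. Tests delegate to scipy/statsmodels
(Mann-Whitney U, Kruskal-Wallis, t, one-way ANOVA with Tukey HSD);
Dunn's rank-based post hoc (z statistics on mean ranks with tie
correction, Bonferroni-adjusted) is implemented here because none of
the installed statistics packages provides it. Two-factor ANOVA with
Sidak correction is not wrapped: it applies to two-way designs (e.g.
treatment × time courses) outside the per-sample locus-metric surface
this module serves.

## Problem sizes and numerical choices

Default simulations use 300–3000 cells per sample and ≤ 1000-cell
cohorts sampled at 30-minute resolution; these sizes give locus
fractions and crossing times with sampling error well below the effects
of interest while keeping any analysis interactive. Trajectory
propagation is exact (matrix exponential per constant-rate segment);
tiny negative round-off is floored at zero. Quantiles use linear
interpolation (NumPy default). Ties at a detection threshold count as
negative. Seeds are explicit everywhere; there is no global random
state.

## Known limitations

* The blue channel conflates maturation and degradation by design; only
  their sum is calibrated.
* Angle semantics depend on each sample containing cells that span the
  Blue-Red range (the normalisation is per sample); sorting a narrow
  subpopulation and re-normalising it will recentre its angles.
* The simulator does not model division dilution; an effective extra
  first-order loss can emulate it by shortening the configured
  half-lives, but no dedicated bookkeeping exists.
* %positive readouts saturate when signal sits far above threshold —
  as in real bright reporters — and are then uninformative for decay
  fitting; MFI readouts are the primary calibration route.
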