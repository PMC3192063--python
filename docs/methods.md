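# Methods

## Model

`wntclock` integrates a ten-species mass-action model of Wnt/β-catenin
signalling in one presomitic-mesoderm (PSM) cell. The negative feedback
runs: Wnt signalling forms the membrane complex LGA (LRP5/6–Axin–GSK3β),
where Axin is phosphorylated and degraded (rate `v`, releasing L and G);
less Axin means less destruction complex C, so β-catenin B accumulates;
B drives *dkk1* transcription cooperatively (Hill exponent `h = 3`,
non-saturating term `k_tx·B^h`); Dkk1 protein binds LRP5/6 into the
tight, slowly dissociating LD complex (`k⁻_LD = 0.02 min⁻¹`), starving
LGA formation of receptor and letting Axin recover. CK1α, APC, TCF/LEF-1
and Dishevelled are not explicit species; their dynamics are absorbed
into the rate constants of the steps they participate in.

Model conventions that were genuinely open, and the choices made:

- **Degradation of C returns GA** (not free G + A): β-catenin is
  degraded inside the destruction complex and the Axin–GSK3β core is
  recycled.
- **Degradation of LGA returns L + G**: Axin is the degraded component;
  its partners are released.
- **Only free Dkk1 decays** (lifetime `τ_D`); Dkk1 bound in LD is
  protected. The tiny dissociation rate of LD models a stable
  inhibitory complex.
- **Transcription is non-saturating** (`k_tx·B^h`, no half-saturation
  constant, no basal term). A saturating Hill form can be introduced by
  subclassing the right-hand side, but none of the packaged experiments
  needs it.
- **All ten species are integrated explicitly.** The two conservation
  laws (total GSK3β 45 nM, total LRP5/6 15 nM) are asserted rather than
  used to eliminate variables, so conservation doubles as an
  integration-quality check. Along the reference trajectory both totals
  hold to better than 1e-12 nM.
- **Units** are nM and minutes throughout; there is no unit-conversion
  layer. The printed unit strings of the transcription/translation pair
  in the source table are mutually inconsistent; they are reconciled
  dimensionally as `k_tx` in nM^(1−h)·min⁻¹ and `k_tl` in min⁻¹ (each
  value kept with its named process). Because Dkk1 mRNA feeds nothing
  but translation, every observable except the mRNA level depends on the
  two rates only through their product, so the assignment is
  observationally irrelevant.

## Numerics

Integration uses `scipy`'s LSODA (adaptive, stiff-capable) at relative
tolerance 1e-8 and absolute tolerance 1e-10 nM, sampled on a uniform
1-min grid. The default initial state is `G = G_tot`, `L = L_tot`, all
other species zero — the unique state satisfying both conservation laws
with no preformed complexes. The first 2000 min are discarded before any
measurement; halving the output grid moves the measured period by less
than 1e-4 min.

Oscillation statistics: local extrema by three-point comparison with
quadratic interpolation (plateaus break ties at their first sample);
period = mean inter-maximum interval; amplitude = mean(maxima) −
mean(minima), i.e. **peak-to-trough** by default, with the half-range
(mean-to-peak) reading available as `half_range_amplitude`. For
β-catenin the half-range reading (≈4.6 nM) is the one that matches the
commonly quoted ≈5 nM figure; the peak-to-trough value is twice that.
`sustained` requires ≥4 maxima, an inter-peak coefficient of variation
below 1%, and amplitude above 1e-3 nM. Oscillation death at scan
extremes is reported as `sustained=False` with an absent period, never
as an error.

Front-period detection: the determination-front series is sampled at the
coarse budding spacing `R`, where direct peak-picking is unstable, so
the series is linearly detrended and autocorrelated over lags
`2R … (n/2)·R`; the period is the highest autocorrelation peak (with
quadratic lag interpolation) provided the peak reaches 0.35. Measured
peak heights separate cleanly: constant, fully randomized and
white-noise fronts peak below ≈0.17, clean periodic fronts above 0.85,
and weakly jittered fronts near 0.45 — phase diffuses as multiplicative
jitter compounds from cell to cell, which caps the peak well below 1, so
a 0.5 cut-off would misclassify fronts that are still visibly periodic.
0.35 sits in the wide gap between the regimes.

## Wavefront schedules

The Wnt gradient enters as a multiplier on the LGA formation rate
(quasi-steady-state receptor occupancy `W/(K_W + W)`), not as explicit
Wnt and Wnt–LRP5/6 species: no binding constants for Wnt–LRP5/6 are
established, and under the steady-state assumption the two forms are
equivalent. When the explicit form is requested, `K_W` defaults to 1 nM
(placeholder). Profiles: Gaussian `exp(−t²/2σ²)` with
`σ = T/√(2 ln F)` (diffusion-shaped gradient; default fold `F = 2` over
a transit `T = 1200` min) and exponential `exp(−t ln F / T)`
(half-life-controlled gradient); both normalised to the same endpoints.
A schedule can alternatively target the β-catenin source `S_B` for the
graded-source variant. Tail-bud drift is a linear, clamped map from a
cell's budding time to the start level of its schedule.

The transit time of 1200 min follows from somite geometry: ≈100 µm
somites, a ≈1 mm PSM (ten somite lengths) and a ≈120-min clock give a
residence of ≈1100–1300 min; 1200 min is the midpoint and an exact
multiple of the budding interval.

## Elongating embryo

Cells are independent after initialization; synchronization is applied
once, at budding, by policy: `copy_neighbor` (verbatim copy of the
anterior neighbour's state — the default, standing in for Delta-Notch
coupling), `identical` (all cells share one stored state; control for a
flat front), `jitter(ε)` (copy with independent multiplicative noise
drawn uniformly from [1−ε, 1+ε] per species, default ε = 0.1, clipped
non-negative), and `random_full` (each species drawn uniformly from its
limit-cycle range, computed from a 6000-min reference run; a flag
restricts randomization to Dkk1 alone, but the default randomizes all
species since a one-species draw leaves the rest synchronized). The
founder cell is pre-run for 4000 min at its birth modifier so it starts
on the limit cycle. A cell's wavefront position is identified with its
age since budding (constant anterior drift in the constant-length PSM
stage), and the front readout is taken once per budding event, at age
`T_transit` exactly. All randomness flows from one recorded seed;
identical seeds give bit-identical results.

## Synthetic inputs

The scenario module generates every input the experiments need, so
nothing is downloaded: builtin scenario configs for each experiment
(reference run, eight sensitivity scans spanning ×/÷4 around each
reference value, static Wnt-level scan, synchronized/identical/
jittered/randomized elongation runs, tail-bud decrease 1.0 → 0.5 and
increase 1.0 → 10× drifts), log-normally perturbed parameter sets
(median 1, log-sd up to 0.5; totals and `h` untouched; log-normal keeps
rates positive without clipping bias), and synthetic front series
(periodic, constant, noisy-periodic, aperiodic) for exercising the
period detector. The `hill2` scenario is a placeholder: the parameter
set for `h = 2` (which requires a much higher β-catenin affinity for the
GSK3β–Axin complex to oscillate) is not bundled, and the scenario fails
with an explanatory message unless values are supplied.

What the generator emulates — and does not: it reproduces the study's
in-silico conditions (budding every 10 min, fold-2 gradients, seeded
desynchronization), not real PSM tissue. There is no cell division, no
ongoing intercellular coupling, no transcriptional noise, no 2-D/3-D
geometry, and no oscillation-arrest biochemistry at the front. Passing
tests therefore certify the model's dynamics and the simulator's
bookkeeping, not biological prediction beyond the model's scope.

## Problem sizes

Defaults used by the packaged experiments: 6000-min single-cell runs
(2000-min transient), 180–420 budded cells per elongation run (180 gives
the front detector ≈36 clock cycles; 420 spans the tail-bud drift
window), 20-point logarithmic scans. These sizes put every reported
number well inside its asymptotic regime — doubling any of them moves
the measured periods by less than the printed precision.

## Known limitations

- Increasing the Wnt multiplier slows the clock (period 117 → ≈155 min)
  until the limit cycle dies near ≈150× reference via a Hopf
  bifurcation; no parameter regime of this model yields sustained
  fast (≈30 min) oscillations at high Wnt, and past the bifurcation the
  stable focus rings at 165–190 min. Claims of very short periods under
  strong tail-bud Wnt increase are, in this implementation, attainable
  only as apparent (Doppler-like) front-series periods under extremely
  fast drifts, not as intrinsic clock periods.
- Under the packaged tail-bud decrease (1.0 → 0.5), the front period
  tracks the slightly *shorter* intrinsic period at lower Wnt while the
  front amplitude falls; the period-lengthening sometimes attributed to
  Wnt downregulation does not emerge from this model at these endpoints.
- The front-period detector's lag resolution is set by the budding
  interval; series shorter than ≈200 samples resolve a 120-min period
  to roughly ±10 min under jitter.
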