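# Methods

## The adaptive metronome

The engine models an event-driven metronome with nominal inter-onset
interval IOI (default 500 ms). Taps are attributed to the nearest tone via
a half-IOI window on either side; the window is half-open on the right,
`[t − IOI/2, t + IOI/2)`, so a tap exactly half an IOI after a tone belongs
to the next window — the defining description gives only "± half the IOI",
and the half-open convention makes boundary assignment unambiguous. Once a
window closes, the next tone is scheduled at

    t[n+1] = t[n] + IOI + α · mean_i(async[n, i])

where `async = t_tap − t_tone` for each registered tapper and a missed tap
contributes 0, so a fully missed window leaves the tempo at the default
IOI. With one tapper the mean reduces to the individual asynchrony. The
first two intervals are always exactly the IOI: they establish the tempo
and participants join at the third tone, so adaptation starts with the
interval leading to tone 4 (0-based index 3). At extreme α a very early
group asynchrony can schedule the next tone at or before the current
window's close; the engine allows this and logs it rather than clamping,
since clamping would silently change the adaptation law.

Missing is a first-class state: the engine substitutes 0 only for
*adaptation*, while the stored record keeps the distinction so that
metrics can exclude misses instead (zero-filling would bias SDs toward 0).
A tap arriving outside every window is dropped with a warning, not
reassigned — hardware registers taps only within the current window.

Times are real-valued ms throughout the engine; integer truncation happens
only at packet serialization (see `format.md`).

## Virtual tappers

Tappers follow a two-level timing model: a central timekeeper with white
Gaussian interval noise (SD `sigma_timekeeper`) plus an independent
Gaussian motor delay per tap (SD `sigma_motor`), which induces the
characteristic MA(1) structure in inter-tap intervals. Linear phase
correction with gain `beta` closes the loop:

    tap[k+1] = tap[k] + IOI − β · async[k] + T[k] + (M[k+1] − M[k])

`beta` is the human-side analogue of the metronome's α. Misses are
Bernoulli(`p_miss`) per window; a missed tap is unregistered but the
tapper keeps its internal cycle going and corrects from the covert
asynchrony, as people do when a tap fails to register. Each tapper owns an
independent RNG stream spawned from the trial seed, consumed in a fixed
order (timekeeper, motor, miss draw), so trials are bit-reproducible.

By default the timekeeper targets the *nominal* IOI (`period_mode =
"nominal"`) and never re-estimates tempo; a `tracking` mode that targets
the last observed inter-tone interval is available but off by default,
because the closed-form analysis below holds only for the nominal path.

**Stationary oracle.** Coupling the two linear rules gives the asynchrony
recursion

    a[k+1] = φ a[k] + T[k] + M[k+1] − M[k],    φ = 1 − α − β

Since `a[k]` carries `M[k]` with coefficient +1, `Cov(a[k], M[k]) = σ_M²`,
and the stationary variance solves to

    Var(a) = (σ_T² + 2 (1 − φ) σ_M²) / (1 − φ²),   valid for |φ| < 1.

This expression was re-derived from the recursion and verified against
10⁵-window simulations across a grid of (α, β) before being adopted as the
test oracle; the acceptance suite repeats that comparison at 3 Monte-Carlo
standard errors (block-means SE, 50 blocks). It predicts the U-shape that
motivates the adaptive metronome: with β = 0.2 and σ_T = σ_M = 10 ms, the
stationary SD is 19.7 ms at α = 0, 16.2 ms at α = 0.35, and 18.8 ms at
α = 1 — moderate adaptivity helps, full adaptivity over-corrects.

**Default parameters.** β = 0.2, σ_T = σ_M = 10 ms, p_miss = 0.02. These
are a plausible regime for practiced tapping at a 500 ms period (per-tap
variability on the order of 2–4% of the IOI, equal central and peripheral
contributions, occasional missed registrations). No claim is made that
they match any particular participant pool: the simulator emulates the
*mechanics* of the task — windowed registration, misses, phase correction,
group averaging — not human perception, audition, attention or learning.
Consequently, passing tests show that the device logic and analysis
pipeline behave as specified under a standard timing model, not that human
effect sizes are reproduced. Auditory-feedback conditions exist only as
metadata tags on trials; users who want to emulate feedback effects can do
so by supplying different tapper parameter sets per condition (e.g. lower
β or higher σ without feedback).

## Experiment designs

Presets mirror the two design families: single-tapper runs of 10 rounds at
each of five adaptivity levels (0, 0.25, 0.5, 0.75, 1), 25 tones per round
(~13 s at 500 ms IOI), and four-tapper group runs of 6 rounds at each of
four levels (0, 0.35, 0.7, 1). Group rounds last about 30 s; we use 60
tones per round (60 × 0.5 s), configurable. Level order is an unconstrained
seeded permutation of the full factorial list. Per-trial seeds derive from
`SeedSequence((master_seed, trial_index))`, giving independent,
reproducible streams; optional practice rounds (always α = 0) are
generated but excluded from the analysis CSV.

## Metrics

All SDs use the population form (denominator N), matching the defining
formulas, with a sample-SD variant behind `ddof=1`. Per trial:

- individual and group-mean asynchrony series, with missed windows
  excluded from each series (window indices are preserved);
- SD asynchrony of each series; the group SD asynchrony is the primary
  stability measure;
- per-tapper SD asynchrony difference (individual − group), each series
  over its own retained windows;
- within-window cross-tapper SD and its SD over windows ("SD of SD"),
  indexing mutual tracking independent of the metronome;
- tapper ranks by absolute SD difference (1 = smallest), ties broken by
  tapper index for determinism;
- adaptivity benefit: mean SD asynchrony at a baseline level minus at the
  optimal level, positive = improvement.

A window in which nobody tapped is excluded from the group series and
flagged. For one tapper the group series equals the individual series and
the SD difference is identically zero.

## Cleaning

Single-tapper rule order: participants missing ≥ 30% of required taps
overall are dropped; then rounds missing > 30% are discarded; then
participants left with an empty adaptivity-condition cell are dropped.
Group rule: groups missing ≥ 30% pooled across the whole group are
dropped, then the round-level rule applies to pooled round misses. The
asymmetry between the inclusive participant/group threshold (≥) and the
strict round threshold (>) is preserved deliberately. "Required taps"
counts every window by default, including the two lead-in tones nobody
taps to; `exclude_lead_in` removes them from the accounting. Cleaning is
idempotent and thresholds are configurable.

## Ratings and enjoyment

Ratings (5-point scales: groove, synchrony with the metronome, synchrony
with the group where applicable, liking, difficulty, felt influence) are
z-scored within each participant × scale across trials using the sample SD
(N−1); a zero-SD scale maps to 0 with a warning. Group designs then
average z-scores across the group per trial. The enjoyment score is the
loading-weighted sum of z-scored items, with fixed default loadings
(single designs: groove 0.663, synchrony 0.836, liking 0.460, difficulty
−0.772; group designs: groove 0.893, synchrony w/metronome 0.937,
synchrony w/group 0.823, liking 0.517, difficulty −0.792); felt influence
loads < 0.3 and is excluded. This is a documented approximation to
regression-method factor scores, which would require the fitted factor
model; user-supplied weights plug in directly. Estimating the factor model
itself is out of scope — any standard statistics package does that from
the exported tables.

## Numerical and design choices

- Missing-tap sentinel in the binary format: −32768, outside any legal
  window; endianness little-endian. The original firmware's conventions
  are not printed anywhere we know of; these are declared choices.
- Engine determinism contract: replaying a recorded trial's taps through
  the engine regenerates the identical tone schedule; the metric pipeline
  is invariant under replay.
- Group metrics are exchangeable in tapper order; the simulator's RNG
  streams are positional, so exchangeability is asserted at the metric
  level (permuting recorded tap slots), not by re-running the simulation.
- Config files are YAML; validation is performed by the dataclass
  constructors with explicit error messages rather than a JSON-schema
  layer.
- Degenerate inputs: empty asynchrony series yield NaN SDs; empty datasets
  clean to empty with a report; an all-missed window contributes no group
  observation.

## Problem sizes in the test suite

The stationary-oracle comparison uses 10⁵-window single-tapper trials over
an 18-point (α, β) grid with a 5 000-window burn-in; the U-shape check
uses 200 simulated four-tapper group trials of 60 tones per adaptivity
level with paired sign tests; metric-formula agreement uses 100 random
small trials at 10⁻⁹ relative tolerance. The whole suite runs in well
under a minute on one CPU.

## Known limitations

- No perceptual or neural modeling: auditory feedback, attention and
  learning effects are outside the generator; human headline effect sizes
  are therefore direction targets only, not quantitative ones.
- The closed-form oracle covers the default nominal-period path; no
  closed form is provided for `tracking` mode or for miss-censored series.
- No inferential statistics: the package exports tidy tables for ANOVA /
  mixed-model work in external tools rather than reimplementing them.
- Sub-window multi-tap debouncing and real-time audio are out of scope.
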