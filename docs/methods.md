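# Methods

## Scope

`sphase` estimates S-phase duration by tracking an EdU-labeled cohort of
nuclei through DNA-content space: per-sample relative movement (RM),
pooled across replicates, fit with a one-breakpoint segmented
regression; the breakpoint and the extrapolation of the first segment to
RM = 1.0 give lower and upper duration estimates. A synthetic population
generator with known ground truth stands in for wet-lab time courses.

## Population model (`sphase.simulate`)

Each cycling cell moves deterministically through G1 → S → G2/M with
fixed phase durations (`t_g1`, `t_s`, `t_g2m`, hours); stochasticity
enters only through the initial age draw, subpopulation assignment, and
measurement noise. DNA content is 2C in G1, `2C·(1 + s)` at replicated
fraction `s` in S, 4C in G2/M. At the end of G2/M a cell divides into
two 2C daughter nuclei, each carrying half the parent's label signal
(nuclei, not cells, are the measured unit); daughters traverse G1 and
may re-enter S. With `divide_labeled=false` division is disabled and
cells park at 4C — the no-division oracle configuration.

Key choices, with defaults and rationale:

* **Initial ages** — uniform over the cycle (default), so the S-phase
  cohort is uniform in `s` and the RM = 0.5 pulse-end theory is exact.
  `exponential_growth` weights ages by `2^(−a/T_C)` as a robustness
  option.
* **Phase durations** — defaults `t_g1 = 1.0`, `t_s = 2.7`,
  `t_g2m = 3.5` h: a fast monocot root-tip cycle in which labeled nuclei
  begin returning to 2C between 3 and 4 h, and G1 is short enough that
  some returned nuclei start a second round of synthesis within a 7 h
  window. Tests that require a cohort free of relabeling use a long G1
  (5 h) instead.
* **Pulse** — `pulse_len = 0.5` h at full incorporation efficiency;
  label amount equals the fraction of the genome synthesized while
  precursor was available (a full S traverse scores 1.0). The
  `pulse_len = 0` limit marks cells in S at t = 0 with a unit saturating
  label: the zero-length overlap would otherwise leave the cohort dark
  and ungateable, while the limit's kinetic content (no cohort
  advancement during the pulse) is preserved.
* **Residual labeling** — imperfect chase is a single phenomenological
  rate: cells in S accrue label at `residual_rate` times the pulse rate,
  decaying as `exp(−t/residual_decay)` with `residual_decay = 1.0` h.
  With the default label background (0.2 % of the full-genome signal)
  this places the dim "arm" 10–100-fold below the pulse-labeled cohort
  across `residual_rate ∈ [0.01, 0.1]`, the separation the method's
  arm-exclusion gate is designed for. Both constants were fixed
  analytically from that requirement before any test was run.
* **Slow / arrested cells** — `slow_fraction` of cycling cells traverse
  S at `1/slow_factor` of the normal rate *during the chase*;
  `slow_factor = inf` freezes them at their current replicated fraction.
  The pulse labels them normally: the phenotype of interest is a labeled
  subpopulation that stalls part way through S, as in suspension-culture
  material.
* **Non-cycling nuclei** — `noncycling_fraction = 0.5` of nuclei are
  static, 80 % at 2C and 20 % at 4C (`noncycling_g2_fraction = 0.2`).
  Without them a fully cycling population cannot sustain the unlabeled
  G2/M anchor through the chase: every pre-pulse G2/M cell divides
  within `t_g2m`, and every later G2/M entrant was in S during the pulse
  and is therefore labeled, so `F_G2/M` would degenerate to late-S
  contamination. Real root-segment preparations are dominated by
  differentiated (static) nuclei, which is what keeps both anchor peaks
  populated in published cytograms.
* **Measurement** — DNA-stain value `dapi_gain · DNA · (1 + ε)` with
  `ε ~ N(0, dapi_cv)`, `dapi_cv = 0.04` (a typical DAPI histogram CV);
  label value `background + gain · amount · (1 + ε′)` with label CV
  0.10. Debris events (default 5 %) get sub-2C DNA values uniform on
  (0.2, 1.8) C. A single `numpy` Generator keyed by `seed` drives
  everything; the chase is one simulated trajectory sampled at each
  chase time, so identical seed and configuration give bit-identical
  event tables.

The closed form `RM(u) = 0.5 + u − u²/2` (u = t/t_s ∈ [0, 1]) is the
noise-free, zero-pulse, no-division cohort mean: positions `min(f + u, 1)`
averaged over initial fractions `f ~ U(0, 1)`. It anchors the
simulator tests (against a brute-force integration oracle) and the
pipeline's theoretical RM(0) = 0.5 check.

### What the generator does not emulate

Cycle-time heterogeneity between cells (each subpopulation is
deterministic), S-entry/exit rate modulation (synthesis is strictly
constant-rate), endoreduplication (> 4C), doublets, spectral spillover,
and thymidine-concentration pharmacology (the chase imperfection is one
rate). A green simulation test therefore establishes correctness of the
*pipeline* under the stated kinetic model, not realism of that model for
any particular tissue.

## Gating (`sphase.gating`)

Gates are derived once from each replicate's 0 h sample and reused
across its time points.

* The DNA-stain density is a 2048-bin histogram smoothed with a
  Silverman-bandwidth Gaussian kernel (kernel capped at 25 bins so sharp
  2C/4C peaks are not blurred into the S arc); the two highest modes
  separated by at least 1.4× in position are taken as G1 and G2/M, with
  parabolic refinement. Their ratio must fall in [1.8, 2.2] or gating
  fails.
* The peak CV is the robust spread (1.4826 × MAD) of events within
  ±10 % of the G1 mode, floored at half a bin (so noise-free delta peaks
  still yield a valid box) and capped at 0.12. Boxes span ±3 estimated
  CVs around each mode — ≥ 99 % of a Gaussian peak without bridging the
  clusters.
* `label_threshold` is the one-sided 99.5 % point of the unlabeled label
  distribution, estimated robustly as median + 2.576 × 1.4826 × MAD over
  G1-box events (the box contains a few percent of bright early-S
  nuclei; a raw percentile would land inside the labeled cluster).
* `full_label_threshold` is 0.1 × the median label of the 0 h labeled
  cohort: events below it (the residual arm, 10–100-fold dimmer) are
  excluded from the cohort mean.
* `debris_floor` is 0.5 × the G1 mode.
* Cohort DNA bounds: at 0 h the gate spans the whole arc (from the G1
  box's lower edge); after 0 h it starts strictly above the G1 box's
  upper edge, excluding labeled nuclei that divided and returned to 2C.

`gated_stats` computes `F_G1`, `F_G2/M` over unlabeled events
(label ≤ threshold) inside each box and `F_L` over cohort events; an
empty unlabeled gate is an error, an empty cohort is a flagged missing
point. `assemble_series` additionally drops points whose cohort holds
fewer than 50 events: once the whole cohort has divided, the gate
contains only measurement-noise tails of returned daughters and its
mean is meaningless (the standard minimum-events rule of flow QC).

## RM series (`sphase.kinetics`)

One RM point per (time, replicate); replicates are pooled, not averaged,
into the regression series (per-time averaging is available as
`pooling="averaged"`), so replicate scatter propagates into the slope
confidence intervals. Per-gate counts travel with each point to support
optional count-weighted fitting (default unweighted). RM is returned
unclamped — values slightly outside [0, 1] under noise are information,
not errors.

## Segmented regression (`sphase.segreg`)

`fit_segmented` minimizes the RSS of `y = β₀ + β₁t + β₂(t − ψ)₊` over
the breakpoint ψ constrained to `(t_min + δ, t_max − δ)`, δ the smallest
inter-time gap:

1. coarse initialization at the best of 10 interior time quantiles
   (ties toward the smaller ψ);
2. iterative linearization — refit with an added `−1(t > ψ)` column and
   update ψ by the ratio of its coefficient to β₂ — until the update
   falls below 1e−6 × range (max 50 iterations);
3. an exhaustive safety net: within every inter-knot interval, a 9-point
   scan plus golden-section refinement; the best solution found wins
   (this also serves as the fallback when step 2 does not converge,
   reported via `converged=False`);
4. a final fixpoint polish: near the optimum the RSS is flat to machine
   precision over ~1e−8 in ψ, so comparison-based search cannot localize
   further, but the linearization fixpoint (gap coefficient = 0) is
   sharp and exactly shift/scale equivariant, making the reported ψ
   path-independent. Tests verify the fit matches a 1e−3-step exhaustive
   scan and that shifting/scaling the time axis moves (ψ, slopes)
   exactly as units dictate, to 1e−9.

Slope CIs come from the OLS covariance at the final ψ with n − 4
residual degrees of freedom (the breakpoint consumes one); the second
slope is β₁ + β₂ with the delta-method variance. R² = 1 − RSS/TSS.
These intervals are conditional on the estimated breakpoint and
undercover somewhat when ψ itself is noisy (MC coverage ≈ 0.85–0.95 on
the bundled fixtures); no breakpoint CI is reported.

### Davies test

With the breakpoint unidentified under the one-line null, the slope
change is screened by the Davies sup-statistic: the largest absolute
Wald statistic M of the hinge term over k = 10 evenly spaced interior
candidates. The p-value bound used here is the small-sample form

```
p = min(1, 2·P(t_df > M) + (V/c₁) · (1 + M²/df)^(−df/2) / √(2π))
```

with df = n − 3, `c₁ = E[1/s] = √(df/2)·Γ((df−1)/2)/Γ(df/2)`, and V the
total variation of the statistic sequence evaluated on a 10× refinement
of the candidate grid (a coarse grid underestimates the continuum
crossing measure). This is the Kac–Rice level-crossing bound for a
Gaussian process divided by a shared χ_df variance estimate; it reduces
to the classic normal-theory formula `2Φ(−M) + V·e^(−M²/2)/√(8π)` as
df → ∞ (that formula is one-sided in its crossing term and uses normal
tails, and is measurably anti-conservative at n ≈ 24). Monte-Carlo
calibration: type-I error 0.034–0.051 at nominal 0.05 for n = 8–24;
power 1.0 against the bundled kinked alternative at σ = 0.03. A
residual-permutation alternative (`method="permutation"`) provides an
assumption-free cross-check.

## Duration estimates (`sphase.duration`)

`t_lower = ψ`, `t_upper = (1 − β₀)/β₁` (requires β₁ > 0),
`RM(ψ) = β₀ + β₁ψ`. Values are reported at full precision and rounded
half-up to one decimal hour / two-decimal RM, the precision at which
such estimates are tabulated. Both estimates are always reported as a
lower/upper pair, never a single "best" number.

A structural property worth knowing: for the *ideal* uniform
constant-rate cohort, the least-squares two-line corner of the concave
trajectory `0.5 + u − u²/2` sits at ≈ 0.6–0.7 × t_s on practical
sampling grids (derived numerically in the tests), and the extrapolation
estimate behaves similarly. Both estimators are faithful to their
definitions — they recover the two-line corner of whatever trajectory
the data follow — but on ideally concave kinetics they bound t_s from
below. Empirical RM curves rise far more linearly than the ideal model
(shallower first segments), which is why published breakpoints track
cohort completion times more closely.

## Determinism and error handling

All randomness flows from explicit seeds; reports are serialized with
sorted keys so identical inputs give byte-identical JSON. Every stage
raises a typed exception (`GatingError`, `StatisticsError`,
`FittingInsufficiencyError`, `NoProgressionError`, ...) so pipeline
failures carry stage attribution.
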