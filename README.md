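# sphase

Estimation of S-phase duration from EdU pulse–chase bivariate flow
cytometry, for plant cell-cycle researchers (and anyone tracking a
labeled replicating cohort through DNA-content space).

## The method

A brief EdU pulse marks every nucleus that is synthesizing DNA. During
the chase, the labeled cohort moves from intermediate DNA contents
(between 2C and 4C) toward 4C. On a bivariate cytogram (label
fluorescence, log, versus DNA-stain fluorescence, linear) the cohort
forms an arc above the unlabeled G1 and G2/M clusters. Its progress is
summarized per sample by the **relative movement** statistic

```
RM = (F_L − F_G1) / (F_G2/M − F_G1)
```

where `F_L`, `F_G1`, `F_G2/M` are the mean DNA-stain fluorescences of the
labeled cohort and of the unlabeled G1 and G2/M gates. For a cohort
initially uniform across S and synthesizing at a constant rate, RM is 0.5
at the end of the pulse and reaches 1.0 when the whole cohort has
finished replicating.

Pooled RM values from all biological replicates are fit with a
one-breakpoint segmented regression

```
RM(t) = β₀ + β₁·t + β₂·(t − ψ)₊ + ε
```

after a Davies test screens for a genuine change of slope. Two duration
estimates are reported:

* **t_lower = ψ** — the breakpoint, read as the time at which the main
  cohort completes S;
* **t_upper = (1 − β₀)/β₁** — the first segment extrapolated to the
  theoretical ceiling RM = 1.0.

`RM(ψ) = β₀ + β₁·ψ` (the RM value at the breakpoint) diagnoses how far
the plateau falls short of 1.0 — re-replicating or arrested
subpopulations lower it.

Because no public event-level data accompany the published time courses,
the package ships a synthetic population generator (`sphase.simulate`)
with known ground truth: cell-cycle progression with division and G1
return, residual low-level labeling (the dim "arm"), slow/arrested
subpopulations, non-cycling nuclei, debris, and multiplicative
measurement noise. Every analysis stage is validated against it.

## Worked example

Simulate a clean eight-point hourly time course (true t_s = 2.7 h, long
G1 so no relabeling within the window) and run the full pipeline:

```
$ cat sim.yaml
t_g1: 5.0
t_g2m: 4.5
t_s: 2.7
n_cells: 30000

$ sphase simulate --config sim.yaml --out sim --seed 3
wrote sim/manifest.yaml
$ sphase run --manifest sim/manifest.yaml --out out
t_lower = 1.6 h, t_upper = 1.6 h, RM at breakpoint = 1.00 (Davies p = 0.000282, R^2 = 0.994)
```

Reading the numbers: the Davies p-value (2.8e-4) confirms a real slope
change; R² = 0.994 matches the fit quality typical of such courses. Both
duration estimates land at 1.6 h, the least-squares corner of the ideal
cohort trajectory `0.5 + u − u²/2` (u = t/t_s) on this sampling grid —
for a perfectly uniform constant-rate cohort the two-line corner sits
well below t_s, which is why the breakpoint is interpreted as a *lower*
bound on S-phase duration. RM at the breakpoint is 1.00 here because no
subpopulation stalls; adding an arrested fraction
(`slow_fraction: 0.3`, `slow_factor: .inf`) lowers it and splits the two
estimates apart, reproducing the contrast seen between root-tip and
suspension-culture material.

`out/` contains `report.json` (all fit parameters, gates, and both
estimates at full precision and rounded), `rm_series.tsv`, and
`rm_fit.png` — the RM plot with both fitted segments, the dashed
extrapolation to the dotted RM = 1.0 line, and the breakpoint arrow.

The same pipeline accepts real data: per-sample CSV (`dapi,label,ssc`
columns) or list-mode FCS 3.0/3.1 files plus a YAML/JSON manifest of
`{time_h, replicate, path}` records (see `sphase ingest --help`).

## Library surface

```python
from sphase import (SimConfig, simulate_time_course,   # synthetic courses
                    read_events, load_manifest,        # CSV/FCS + manifests
                    auto_gates, gated_stats,           # gating
                    relative_movement, assemble_series,# RM series
                    fit_segmented, davies_test,        # broken-line fit
                    estimate_duration, run_pipeline)   # durations
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline check from
scratch: it simulates an ideal labeled cohort (uniform between 2C and
4C, no noise, no division, 100 000 nuclei), gates it automatically, and
reports the relative movement at chase time 0, which theory fixes at
0.5. Run it as

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the population model, the gating rules and
their parameters, the breakpoint search and its numerical guarantees,
the small-sample Davies bound used here, and known limitations.
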