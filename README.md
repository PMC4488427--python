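# antegress

Analysis of egress dynamics in single-exit evacuation experiments with ants.

When ~30 ants are driven out of a small chamber by a repellent, they do not
jam at the exit the way pedestrian models predict; instead the outflow
breaks into bursts ("groups") separated by long pauses. `antegress` turns
tables of per-ant escape times — recorded for six exit widths *d* (0.5–3.0
cm, where 1w = 0.5 cm passes a single ant) under a repellent and a water
control — into the statistics that characterize this behavior:

- **Inter-escape intervals (headways).** The time between one ant
  completely passing the exit and the next, measured from the first escape
  (time zero) to the last. The mean interval per width is the reciprocal of
  the mean flow rate *Q* (ants/s).
- **Exponential interval-frequency law.** The relative-frequency histogram
  of intervals Δt decays as

  &nbsp;&nbsp;&nbsp;&nbsp;*p*<sub>f</sub>(Δt) = α·exp(−Δt/β) + ε

  with one (α, β, ε) per exit width, fitted by nonlinear least squares.
  The decay scale β (seconds) shrinks as the exit widens; the package fits
  the OLS trend of β on *d*. The cumulative escape count is likewise fitted
  with the saturating form y(x) = A1·exp(−x/t1) + y0.
- **Group segmentation and the group flow rate.** Consecutive escapers
  whose headway is strictly below the width's mean interval (the
  "mathematical expectation" threshold) form one group. A group of N ants
  spanning t_S = t_N − t_1 has group flow rate **Q_S = (N−1)/t_S**; a
  simultaneous pair (t_S = 0) makes Q_S infinite and is excluded, which is
  why wider exits use the N ≥ 3 cut (N ≥ 2 at the single-ant-wide exit).
- **Comparative statistics.** Welch t-tests of pooled intervals between
  every pair of widths and of per-trial escaped counts between repellent
  and control, annotated with stars (p < 0.05 / 0.01 / 0.001, strict);
  Pearson correlation between group size S and Q_S.

A seeded synthetic generator reproduces the full experimental design
(6 widths × 6 repellent + 3 control repetitions, 30±2 ants, escape times
on a 25 fps grid, exponential headways with width-dependent β), so the
whole pipeline runs and is tested without any external data.

## Worked example

```python
from antegress import SimulationConfig, simulate_experiment, run_analysis

dataset = simulate_experiment(SimulationConfig(seed=42))
report = run_analysis(dataset)

for row in report["per_width"]:
    print(f"d={row['width_cm']:.1f} cm  mean interval={row['mean_interval_s']:.2f} s  "
          f"Q={row['Q']:.3f} ants/s  beta={row['beta']:.2f} s  "
          f"mean Q_S={row['mean_QS']:.2f} ants/s")
trend = report["beta_trend"]
print(f"beta trend: slope={trend['slope']:.3f} s/cm  r^2={trend['r_squared']:.3f}")
sig = sum(t["stars"] >= 1 for t in report["escaped_count_tests"])
print(f"repellent vs control significant at {sig}/6 widths")
```

prints

```
d=0.5 cm  mean interval=3.12 s  Q=0.320 ants/s  beta=2.76 s  mean Q_S=1.22 ants/s
d=1.0 cm  mean interval=3.41 s  Q=0.294 ants/s  beta=3.02 s  mean Q_S=0.85 ants/s
d=1.5 cm  mean interval=2.51 s  Q=0.398 ants/s  beta=2.77 s  mean Q_S=1.19 ants/s
d=2.0 cm  mean interval=1.72 s  Q=0.581 ants/s  beta=1.56 s  mean Q_S=1.71 ants/s
d=2.5 cm  mean interval=1.41 s  Q=0.712 ants/s  beta=1.42 s  mean Q_S=1.94 ants/s
d=3.0 cm  mean interval=1.56 s  Q=0.642 ants/s  beta=1.62 s  mean Q_S=1.73 ants/s
beta trend: slope=-0.666 s/cm  r^2=0.734
repellent vs control significant at 6/6 widths
```

Reading the numbers: narrow exits have long mean headways (low *Q*) and a
heavy long-interval tail (large β); both shrink as the exit widens, and the
fitted β-on-*d* line slopes downward. At every width the mean group flow
rate Q_S exceeds the overall *Q* — within a burst the ants exit much faster
than the trial-wide average — and repellent trials release significantly
more ants than water controls.

The same pipeline runs from the shell:

```bash
antegress simulate --seed 42 --out egress.csv
antegress analyze egress.csv --out-dir results/
antegress report results/report.json
```

`analyze` accepts CSV/TSV event tables (`trial_id, condition,
exit_width_cm, n_initial, egress_time_s`) or an XLSX sheet with an explicit
column mapping in the `--config` file, and writes tidy CSV summaries plus a
schema-validated `report.json`.

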