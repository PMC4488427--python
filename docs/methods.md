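# Methods

## Data model

One trial is an ordered series of escape times (seconds) for a chamber
with a single exit of width *d* cm, under either a citronella-style
repellent (all ants leave) or a water control (few leave). Times are
relative to the first complete passage through the exit ("time zero");
input tables may carry absolute clock times, which the reader re-references
per trial. Times are stored as reals and are not snapped to the 25 fps
video grid on input — deposited data may have been transcribed at other
precisions — while the synthetic generator emits exact grid multiples.

## Interval statistics

For a trial with k events the k−1 successive differences are its headway
intervals; per-width analyses pool the intervals of all repetitions of that
width and condition. The mean interval ("mathematical expectation") is the
arithmetic mean of the raw pooled intervals, not a histogram-weighted mean,
so it does not depend on the binning rule; the mean flow rate is its
reciprocal, Q = 1/⟨Δt⟩.

### Histogram binning

Default rule: Sturges, k = ⌈1 + log₂ n⌉ equal-width bins spanning
[0, max Δt], last bin right-closed. Scott's rule and a fixed bin width are
available because the fitted decay scale is sensitive to binning; the rule
used is recorded in the report provenance.

### The interval-frequency fit

The model p_f(Δt) = α·exp(−Δt/β) + ε is fitted to (bin midpoint, relative
frequency = count/n) pairs by unweighted nonlinear least squares
(trust-region reflective, β bounded positive). The exponent is Δt/β — the
dimensionally consistent reading, with β in seconds comparable to the mean
interval. ε is a fitting nuisance that absorbs binning and tail effects;
it is not part of the generative model. Start values are moment-matched
and deterministic: ε₀ = min frequency, α₀ = max − ε₀, β₀ = the
frequency-weighted mean midpoint (the histogram analogue of the sample
mean interval). Non-convergence is reported (`converged=False`, start
values and SSE retained), never raised, so one bad width cannot abort a
run.

With ~170 pooled intervals per width (the full design) the β̂ estimator is
essentially unbiased but has a relative standard deviation near 20%: three
parameters against ~9 binned frequencies leave a strong ε–β trade-off in
the sparse tail. Parameter-recovery checks therefore assert the median
relative error across widths and a small fixed battery of seeds (0, 1, 2)
rather than a per-width bound, which sampling noise alone would break at
these sample sizes. The raw-mean estimate of β (exponential mean = scale)
is much tighter (~7.5% standard error) and is checked at 10%.

### Cumulative escape curve

y(x) = A1·exp(−x/t1) + y0 (A1 < 0) fitted to the right-continuous step
function sampled at event times, i.e. the pairs (tᵢ, i). The fitted y0
estimates the total number of escapers when the process actually
saturates; at least 4 events are required.

### Width trend

Ordinary least squares of the per-width β̂ on *d*, reported as slope,
intercept, and r². A negative slope is the expected signature: wider exits
shorten the long-interval tail.

## Group segmentation and Q_S

Two consecutive escapers are in the same group when their headway is
**strictly below** the width's threshold; a headway exactly at the
threshold splits (ties are documented and tested). The threshold is the
pooled repellent-condition mean interval of the width, recomputed from the
data under analysis, with a per-width override available to pin external
values. Segmentation yields a partition — every event in exactly one
maximal run, singletons retained.

For a group of N members spanning t_S = t_N − t₁, Q_S = (N−1)/t_S. A
group with t_S = 0 (simultaneous escapes, possible at wider exits and,
in synthetic data, whenever an interval rounds to zero frames) has no
finite Q_S: it is excluded from all means and counted in
`n_singular_excluded`. The default size cut is N ≥ 2 at the 0.5 cm exit
(only one ant fits at a time, so zero-span pairs cannot occur physically)
and N ≥ 3 at wider exits; both are configurable. Because every
within-group headway is below the threshold 1/Q, each group's Q_S exceeds
Q, so mean Q_S > Q is a structural property whenever qualifying groups
exist — the tests verify it end to end rather than assuming it.

## Comparison statistics

Pairwise width comparisons use the t-test on pooled intervals (all
repetitions per width). Welch's unequal-variance form is the default —
the safer choice for unequal n and variance — with the pooled-variance
form behind a flag. Stars: 3 if p < 0.001, 2 if p < 0.01, 1 if p < 0.05,
strict inequalities on the unrounded p. No multiple-testing correction is
applied by default; Bonferroni/Holm adjustments are available.

A sample must have ≥ 2 values, and the two samples must not *both* be
constant. A single constant sample is allowed: the Welch statistic is
well defined with one zero variance, and per-trial escaped-count data
routinely produce a constant control sample (three small counts tie
easily), which should yield a result, not an error.

The S–Q_S association is the product-moment correlation with a two-tailed
p from the t transform on n−2 df; it requires ≥ 3 pairs and non-constant
inputs. Treatment-vs-control comparisons are t-tests on per-trial escaped
counts (≥ 2 trials per arm).

## Synthetic generator

Defaults reproduce the design: widths 0.5–3.0 cm in 0.5 steps, 6
repellent and 3 control repetitions per width, 30 ± 2 agents (uniform
integer jitter), frame grid 0.04 s, control escape probability 0.1
(≈ 3 of 30 escape without the repellent, enough to keep per-trial counts
small but nonzero). Headways are i.i.d. exponential with the width's β —
the simplest process whose interval-frequency histogram shows the modelled
decay; ε is deliberately not generative. Default β per width (3.17, 2.95,
2.79, 1.81, 1.47, 1.50 s) are the characteristic fitted scales for these
exit widths, so default runs show the qualitative width dependence.
Rounding headways to the frame grid creates occasional zero intervals and
hence simultaneous escapes; no extra tie mechanism is added.

What the generator does **not** emulate: serial correlation between
headways (real bursts may be self-reinforcing), any spatial or
repellent-concentration dynamics, and a saturating escape rate (headways
are i.i.d., so synthetic cumulative curves grow linearly rather than
levelling off — escape-curve fits are exercised on explicitly saturating
test processes instead). Passing tests therefore demonstrate that the
pipeline recovers the parameters of data obeying its own model
assumptions, not that real colonies obey them.

Randomness: one root seed; each series uses an independent stream derived
from (seed, width, condition, repetition), so any subset of the design
reproduces in isolation.

## Pipeline and report

Stages run in order (intervals → histograms → decay fits → expectations
and Q → grouping → Q_S → trend → comparisons); a failure in one stage is
recorded in the report's `notes` and nulls the affected fields instead of
aborting. The report is deterministic given dataset and options apart
from its timestamp, carries provenance (source, seed, binning rule,
config hash), and validates against the JSON schema shipped with the
package (a small built-in structural validator covers the schema subset
used). XLSX import requires an explicit column mapping — deposited
spreadsheets have no fixed layout and guessing risks silent misparses.

## Known limitations

- β̂ from binned fits is noisy at ~170 intervals per width (see above);
  trust the raw mean interval where the two disagree.
- Whether real headways are i.i.d. is unknown; the exponential-law tests
  say nothing about serial structure.
- The exact binning rule behind the original histograms is not
  recoverable; Sturges is the package's documented default and the rule is
  part of the report provenance for exactly this reason.
- Problem sizes in the test suite (full design ≈ 54 trials, ~1000-series
  oracle sweeps, 20-seed power checks) were chosen to make the stochastic
  assertions stable at comfortable margins while keeping the default suite
  fast.
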