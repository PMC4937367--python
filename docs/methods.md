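# Methods

## Model and test

Two aligned binary channels are treated as event streams sampled at a
fixed interval. The unit of analysis is the *event of relation* (ER): the
joint occurrence of an effect event at time *t* and a candidate cause
event at *t − τ*. Writing *K*_τ for the number of ERs at lag τ over the
record, the test compares each *K*_τ (τ ≥ 1) against the zero-lag count
*K*₀ under the premise that no interaction is instantaneous: at an
adequate sampling rate a genuine cause can only inflate counts at positive
lags, while for unrelated channels every lag — including 0 — estimates the
same joint rate.

The comparison is a binomial test simplified to its Poisson
approximation: with *p*_τ = *F*(*K*_τ | *K*₀) the Poisson CDF at mean
*K*₀,

- `increase` tail (default): flag τ when *p*_τ > 1 − α (the cause raises
  the effect's event probability — the usual excitatory case);
- `decrease` tail: flag when *p*_τ < α (suppressive, "negative"
  causality);
- `two-sided`: α/2 per tail.

Direction is inferred by running the scan in both orderings of the pair
with identical parameters; both share the symmetric *K*₀. Because every
quantity is a count of co-occurrences within one record, nothing about
either channel's marginal process — stationarity included — enters the
null distribution.

### Assumptions

- Delays are at least one sample: sampling must be fast enough that cause
  and effect do not land in the same bin. When it is not, *K*₀ absorbs the
  interaction mass; the optional zero-lag diagnostic on
  `bidirectional_scan` reports "related, direction undetermined" when
  *K*₀ itself exceeds the threshold implied by the mean of the lagged
  counts (off by default).
- The Poisson approximation needs a non-trivial reference count. With
  *K*₀ < 5 (`MIN_EVENTS`) the result status is `insufficient-events` and
  no lags are flagged: *F*(k | 0) = 1 for every k, so a near-empty
  reference would otherwise flag everything.
- Interactions are pairwise; a third node is never conditioned on. On
  chains, pairwise scans reflect ancestry (a sufficiently strong indirect
  path can reach significance at the compounded delays).

### Numerical conventions

- **Shift convention.** Linear, non-circular: *K*_τ is counted over the
  overlap *t* ∈ [τ, n−1], with effective length *n* − τ. A circular shift
  would wrap causes past the end of the record to positions *after* their
  effects, contradicting temporal precedence.
- **Reference scaling.** By default raw counts are compared (valid in the
  designed regime τ_max ≪ n; the deficit E[*K*_τ] ≈ *K*₀·(n−τ)/n is a
  fraction of a count at the benchmark sizes and is conservative for the
  increase tail). `overlap_correction=True` rescales the reference to
  *K*₀·(n−τ)/n.
- **Multiple testing.** No correction across lags by default — the scan
  reproduces the plain per-lag test, and error control is exercised by
  choosing a small α. `bonferroni=True` divides α by the number of
  scanned lags.
- **Thresholds.** The `upper limit` drawn on lag profiles is the smallest
  count *k\** with *F*(*k\** | *K*₀) > 1 − α; flagging at *p*_τ > 1 − α is
  equivalent to *K*_τ ≥ *k\**. The CDF is evaluated through the
  regularised incomplete gamma function (scipy), stable far beyond the
  count magnitudes produced here; the test suite checks it against a
  60-digit decimal direct summation to 1e−10.
- **Defaults.** α = 0.005, τ_max = 20 (every bundled scenario designs
  delays ≤ 6), tail = `increase`. Lags are integers in samples; the
  optional `dt` metadata only converts for display.

## Simulator

Each node fires spontaneously per sample with probability *p*ₜ — constant
(stationary) or a bounded random walk (non-stationary). A directed
interaction (source, target, interaction probability, delay distribution)
makes every source event induce a target event with the interaction
probability after a delay drawn *independently per source event* from a
discrete distribution (per-event draws are what place mass at several
lags of one run's profile under bimodal or discrete-Gaussian delays).
Induced events landing on existing events are idempotent; events induced
past the end of the record are discarded; graphs must be acyclic and are
simulated in topological order so chains propagate induced events
downstream.

Benchmark conditions used throughout the tests: event probability 0.3,
n = 5000 samples, interaction probabilities {0.2, 0.4, 0.6, 0.8}, delay
families fixed (τ = 4), bimodal ({2, 5} at ½/½), discrete-Gaussian
({2..6} at {0.015, 0.21, 0.55, 0.21, 0.015} and {2,3,4} at
{0.225, 0.55, 0.225}), and wide-uniform (1..100, the "arbitrary delay"
control).

The non-stationary driver is a Gaussian random walk with step sd 0.005
per sample, reflected into [0.05, 0.6], starting at 0.3. The scale was
chosen so that a few-thousand-sample record drifts visibly while the
firing probability stays well inside (0, 1); all three parameters are
configurable. **Caveat:** the reflecting bounds make the walk only
approximately unit-root — an augmented Dickey–Fuller test fails to reject
on about 78% of 10000-sample draws (the rest are folded often enough to
look mean-reverting). Note the ADF convention: its null *is* the unit
root, so non-stationarity is certified when the test *fails to reject*
(p > 0.05); rejection labels the series stationary, and constant input is
reported `degenerate`.

What the simulator does not emulate: refractory periods, burst
structure, autocorrelated spontaneous firing, inhibitory links, common
drive with continuous coupling, and measurement noise such as dropped or
jittered events. Green Monte-Carlo results here show the test's behaviour
under independent-increment firing with superimposed delayed induction —
not under every failure mode of real recordings.

## Monte-Carlo evaluation

Each replicate of a two-node scenario is scanned both ways and classified
into exactly one outcome. For causal ground truth: `error_type_I` when
the reverse direction has any significant lag (direction error dominates,
keeping categories exclusive); else `strongly_correct` when all flagged
lags lie inside the designed delay support, `weakly_correct` when some
fall outside, `missing_detection` when nothing is flagged. Truly
non-causal pairs (interaction 0) are `error_type_II` on any detection and
`true_negative` otherwise; since a causal two-node scenario cannot
produce a false *pair* detection, false-detection rates are estimated
from matched null companions (same parameters, interaction 0). One scan
per replicate is re-thresholded across all requested α levels (the
p-values do not depend on α). Default replicate budget is 2000 per cell
(configurable); the bundled studies use 200–10000 depending on the
precision the quantity needs.

### Known limitations of the error control

The Poisson comparison conditions on *K*₀ as if it were a fixed mean,
ignoring that it is itself a binomial draw (sd ≈ 21 at the benchmark's
mean ≈ 450). Two measurable consequences, both reproduced independently
of this package by a direct numpy/scipy simulation:

- In the far tail the per-lag null rejection rate saturates near
  0.0008 regardless of nominal α below ~0.005 — conservative at α = 0.005
  but slightly *anti*-conservative at α = 0.0005, because replicates that
  draw a low *K*₀ depress the threshold for every lag at once. The
  family-wise false-detection rate of a bidirectional 10-lag scan at
  α = 0.0005 is ≈ 0.8% (one direction alone: ≈ 0.6%).
- Scanning many lags without correction multiplies exposure: over 100
  lags at α = 0.005 roughly 8% of *null* replicates show at least one
  count above the upper limit (1 − (1 − 0.0008)¹⁰⁰). The wide-uniform
  delay control therefore shows an occasional spurious single-lag
  exceedance at exactly the null rate; its interaction mass (~1% of the
  interaction probability per lag) is far too dilute to add to it.

Both behaviours are properties of the plain per-lag test, not of this
implementation; the Bonferroni option restores family-wise control when
many lags are scanned.

## Problem sizes

Test-suite and acceptance-script simulation budgets (n = 5000 samples
per channel throughout): 10000 replicates for the null family-wise rate,
500 for detection-rate checks, 200 for the wide-uniform and three-node
chain studies, 1000 per interaction level for the wrong-direction error
grid. These sizes put the binomial standard error of each reported rate
well below the margin being asserted.
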