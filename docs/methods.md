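# Methods

This note documents the models, the parameter choices that matter, and the
limits of what the synthetic validation shows.

## Trace analysis

**Baseline.** F₀ is the mode of the raw fluorescence histogram over the
session, estimated with Freedman–Diaconis bin widths and a floor of 20 bins
over the data range; the mode bin's center is returned, ties going to the
lower bin. The mode is robust to sparse transients (which only thicken the
upper tail) but its error grows with the per-frame noise: at 10% raw noise
the baseline is typically recovered to within 1–2%, which propagates into a
comparable multiplicative error on ΔF/F₀. A constant trace returns its own
value. Both the binning rule's floor and the tie direction are fixed
constants of `DetectionParams`.

**Event detection.** A transient is a maximal run of at least
`min_run_frames` = 3 consecutive frames (strictly more than two) with
ΔF/F₀ above `sd_multiplier` = 3 × σ. σ is the robust SD
(1.4826 × median absolute deviation) of the analyzed trace itself: with
sparse events this approximates the noise SD while being insensitive to the
event frames; whether the original rule's SD included event frames is not
determinable, so the robust choice is the default and the multiplier is
configurable. If the MAD is exactly zero on a non-constant trace the sample
SD is used; a constant trace yields no events.

**Spine-specific decomposition.** Dendritic transients invade spines, so a
spine trace is modelled as `spine ≈ a·shaft + spine-specific + noise` with
`a ≥ 0`. The scale `a` minimizes squared error restricted to frames inside
detected shaft events — the fit is driven by the invading transients, not
by baseline noise — falling back to all frames when the shaft is silent.
Events are then detected in the residual with the same 3σ/3-frame rule, σ
taken from the residual. A residual whose robust SD is below 10⁻¹² of the
spine trace's range is treated as exact proportionality (silence), which
prevents the SD-relative threshold from chasing floating-point dust.
"Occasions" on which a spine exceeds the dendritic signal are counted as
discrete residual events (not single suprathreshold frames); a spine with
at least `active_spine_min_exceedances` = 4 of them (strictly more than
three) is active. Counting single frames instead would make the criterion
depend on frame rate and event duration; the event reading is the default
and the threshold is one config constant.

**Dendrite categories.** A dendrite with ≥ 1 active spine is
`dendritic_plus_synaptic`; otherwise `dendritic_only` if the shaft produced
≥ 1 transient; otherwise `none`. Classification is invariant to a common
positive rescaling of all traces and to additive offsets of the raw traces
(up to mode-bin tolerance).

## Spine turnover

**Inclusion.** A protrusion is a spine when a head is visible and both
head/neck diameter and head/neck fluorescence ratios are strictly above
1.2. Records exactly at 1.2 are rejected. Out-of-plane visibility is
abstracted into the supplied `has_head` flag.

**Matching.** Positions are 1-D arc-length coordinates along the dendrite
relative to a fixed landmark (3-D tracing and landmark registration happen
upstream). Two sessions are matched greedily by increasing positional
distance under a tolerance of 1.0 μm (ties: lower before-position, then
lower after-position), each spine pairing at most once; unmatched
before-spines are eliminated, unmatched after-spines generated. The
tolerance is a package choice — below typical inter-spine spacing, above
realistic registration jitter — and is configurable. Pairs of spines
within one tolerance of each other trigger a logged warning; the greedy
order keeps the result deterministic.

**Rates.** Both rates use the earlier session's count as denominator:
elimination is then a proper fraction and both rates share one baseline.
The alternative convention (generation over the later count) is available
as `gen_denominator="after"`. Group summaries are unweighted means ± SEM
over intervals, the interval being the unit of analysis; a single interval
has SEM 0 by convention.

## Statistics

All tests are two-sided and use mid-ranks for ties.

- **Fisher r×c**: exact conditional p — the total multivariate-
  hypergeometric mass of margin-compatible tables no more probable than the
  observed one, probabilities compared with 10⁻¹² relative tolerance.
  Enumeration is depth-first with forced last row/column; beyond 10⁷ tables
  a seeded Monte-Carlo over column-label permutations (default 10⁵ draws)
  reports p with its standard error.
- **Kruskal–Wallis**: tie-corrected H against χ²(k−1) (delegated to scipy);
  all-identical data return H = 0, p = 1.
- **Steel's many-to-one test**: per treatment, the standardized Wilcoxon
  rank-sum statistic z_t on control ∪ treatment (tie-corrected variance).
  Family-wise adjusted p-values come from the permutation distribution of
  max_t |z_t| under seeded permutations of the pooled observations (default
  10 000; below 1000 a warning is raised). Classical critical tables vary
  between sources, so permutation is the reference mode; a multivariate-
  normal approximation (correlation λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀))) is provided
  for cross-checking. Unadjusted p-values are computed from the same draws,
  so adjusted ≥ unadjusted holds exactly; p-values use the add-one
  estimator (1+hits)/(1+N), which is slightly conservative but never zero.
  The pooled sample is sorted before permuting so the seeded result is
  invariant to input order.
- **Mann–Whitney**: exact enumeration of all group assignments when both
  n ≤ 8 (handles ties exactly); otherwise the tie-corrected normal
  approximation (scipy).

## Synthetic generators

The generators emulate the imaging and turnover structure the pipeline was
built for, with every default chosen once as a realistic value:

| parameter | default | rationale |
|---|---|---|
| frame_rate_hz | 12 | mid-range of 10–15 frames/s resonant imaging |
| duration_s | 240 | 4-min session |
| kernel_rise_s / decay_s | 0.18 / 1.2 | GCaMP6s-like kinetics |
| shaft_event_rate_hz | 0.05 | ~12 dendritic transients per session |
| spine_specific_rate_hz | 0.02 | sparse synaptic events, ~5 per session |
| amp_shaft / amp_spine | 2.0 / 1.5 ΔF/F | large GCaMP6s transients |
| noise_sd | 0.1 ΔF/F | ~10% per-frame ROI noise |
| baseline_f0 | 100 | arbitrary raw-fluorescence units |
| p_gen / p_elim | 0.05 | basal 2-day turnover of ~5% |
| n_sessions | 5 | imaging days 1, 3, 5, 7, 9 |
| dendrite_length_um | 400 | realistic analyzed shaft length; ~0.25 spines/μm at 100 spines |

Transients are a difference of exponentials normalized to unit peak,
placed at Poisson times; every shaft transient appears in every spine trace
scaled by `invasion_gain` (default 1), spine-specific transients add on top
of that, and raw traces are `baseline_f0 × (1 + ΔF/F + noise)`. Populations
evolve by per-interval Bernoulli elimination and Binomial(count, p_gen)
birth at fresh positions at least 1 μm from existing spines; survivors
jitter by a truncated Gaussian (SD 0.2 μm, |jitter| ≤ 0.5 μm, half the
matching tolerance), so per-interval matching is unambiguous by
construction although drift accumulates across sessions as a random walk.
Spine ids are never reused. All randomness flows from one seed through
spawned substreams; identical parameters give bit-identical output.

**What the generator does not model:** pixel-level movies, motion
artifacts, photobleaching, slow baseline drift, bursting/correlated event
times, amplitude variability, anesthesia state, and spine-volume dynamics.
Passing the synthetic benchmarks therefore demonstrates algorithmic
correctness against the stated model — not robustness to every failure
mode of real recordings; in particular, the mode baseline and MAD-based σ
will behave differently under strong drift or dense activity.

## Validation problem sizes

The standing benchmarks (`spinedyn.benchmarks`, exercised by the test
suite and `scripts/acceptance.py`) use: 200 four-minute traces at 12
frames/s with transient peaks at 5× the noise SD for detection fidelity;
200 mixed-regime dendrites (5 spines each, amplitudes ≥ 5× noise) for
classification accuracy; 500 two-day intervals of 100-spine populations at
p_gen = p_elim = 0.05 for turnover recovery; 2000 null simulations (3–4
groups of 10) for test calibration with 1000 permutations per Steel call;
and 100 seeded end-to-end runs at 15 intervals/group for the
enrichment-power study. Detection is scored with overlap windows (1 s
rise/peak for recall, 3 s extent for precision) so that decay-tail
re-crossings of one true transient are not miscounted as false positives.

## Known limitations

- Detection power at the 3σ/3-frame rule degrades sharply below ~5× peak
  amplitude to noise; near that boundary baseline-mode error (at 10% raw
  noise) consumes a visible fraction of the margin.
- Greedy positional matching can mispair when a spine is born within the
  tolerance of a just-eliminated spine's position; at the benchmark
  densities this biases recovered rates downward by ≲ 0.2 percentage
  points, well inside the validation band.
- The r×c Fisher enumeration is exponential in table size; large, dense
  tables fall back to Monte-Carlo with a reported standard error.
- Steel's permutation p-values are Monte-Carlo estimates; with the default
  10 000 permutations their standard error near p = 0.05 is ≈ 0.002.
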