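# spinedyn

Quantification of dendritic-spine dynamics from longitudinal two-photon
imaging: calcium-transient detection in spine and shaft ROIs, spine-specific
signal decomposition, morphology-based spine identification, cross-session
spine matching with generation/elimination (turnover) rates, and the
nonparametric group statistics used in this experimental design — plus a
synthetic-data generator with known ground truth so the entire chain is
testable end to end.

## The scientific problem

Dendritic spines host most excitatory synapses in cortex. Chronic two-photon
imaging of GCaMP-labelled pyramidal neurons lets one ask whether the basal
rates at which spines appear (generation) and disappear (elimination) are
driven by neuronal Ca²⁺ activity or persist as intrinsic dynamics when
signaling is blocked. Answering this requires two quantitative chains:

**Activity chain.** For each ROI (oval over a spine, polygon over the
dendritic shaft), the fluorescence trace F is converted to

    ΔF/F₀ = (F − F₀) / F₀,   F₀ = mode of F over the 4-min session

A dendritic-shaft transient is a run of **more than two consecutive frames**
above **3 standard deviations** (robust SD = 1.4826 × MAD). Dendritic
transients invade spines, so the shaft trace is scaled as far as possible
into each spine trace (nonnegative least squares over shaft-event frames);
transients detected in the residual are *spine-specific* (synaptic). A spine
whose residual exceeds threshold on **more than three occasions** is an
active spine, and each dendrite is categorized as *dendritic + synaptic
Ca²⁺ transients*, *dendritic Ca²⁺ transients*, or *no Ca²⁺ transients*.

**Structural chain.** A protrusion counts as a spine only with an apparent
head: head/neck diameter ratio **> 1.2** and head/neck fluorescence ratio
**> 1.2** (filopodia are excluded). Spines are matched across sessions 2
days apart by their position along the dendrite relative to stable
landmarks; the generation and elimination rates of an interval are

    gen% = 100 · n_generated / n_before,   elim% = 100 · n_eliminated / n_before

and are averaged over intervals within a group (the interval is the unit of
analysis). Group comparisons use Fisher's exact test (r×c, full enumeration
or seeded Monte-Carlo), Kruskal–Wallis, Steel's many-to-one test against a
control arm (permutation of the maximum standardized rank-sum statistic),
and Mann–Whitney (exact enumeration for small samples).

## Worked example

```python
from spinedyn import (
    SimParams, simulate_trace_set, simulate_spine_population,
    compute_dff, detect_shaft_events, classify_dendrite,
    turnover_over_sessions, aggregate_group,
)

params = SimParams(seed=42, n_spines_per_dendrite=5)
traces, truth = simulate_trace_set(params)
dff = compute_dff(traces.shaft)
events = detect_shaft_events(dff)
print(f"shaft transients: {len(events)} detected, {truth.shaft_event_times.size} injected")
print(f"dendrite pattern: {classify_dendrite(traces).value}")

sessions, _ = simulate_spine_population(
    SimParams(seed=42, n_spines_per_dendrite=100, n_sessions=6)
)
summary = aggregate_group(turnover_over_sessions(sessions))
print(f"generation  {summary.mean_gen_pct:.2f} +/- {summary.sem_gen_pct:.2f} % per 2 days")
print(f"elimination {summary.mean_elim_pct:.2f} +/- {summary.sem_elim_pct:.2f} % per 2 days")
print(f"n = {summary.n_intervals} intervals")
```

prints

```
shaft transients: 16 detected, 17 injected
dendrite pattern: dendritic_plus_synaptic
generation  5.03 +/- 1.05 % per 2 days
elimination 3.62 +/- 0.68 % per 2 days
n = 5 intervals
```

One injected transient fell too close to another to resolve as a separate
event; the dendrite carries spine-specific transients, so it lands in the
*dendritic + synaptic* category. The turnover rates estimate the generator's
per-interval probabilities (both 5% here) from five 2-day intervals of a
100-spine dendrite.

The same chain is available from a shell:

```bash
spinedyn simulate traces --seed 1 --out run/
spinedyn detect --traces run/traces.csv --out run/
spinedyn classify --events run/events.csv --out run/
spinedyn simulate population --seed 1 --out run/
spinedyn turnover --population run/population.csv --tolerance-um 1.0 --out run/
spinedyn run --config examples/experiment.yaml --out run/full
```

## Layout

- `spinedyn.simulate` — trace-set, spine-population and morphology generators
- `spinedyn.events` — ΔF/F₀, event detection, scaling, spine/dendrite classification
- `spinedyn.turnover` — morphology filter, session matching, turnover rates
- `spinedyn.stats` — Fisher r×c, Kruskal–Wallis, Steel, Mann–Whitney
- `spinedyn.io` — CSV/JSON schemas, optional TIFF + ROI ingestion
- `spinedyn.pipeline` / `spinedyn.cli` — multi-condition orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
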