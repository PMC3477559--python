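# Methods

## Model and pipeline

`dynfc` estimates *event-related* functional connectivity: synchrony is
computed **across trials** at each latency, not across time within one
recording.  The underlying assumption is that a stimulus-locked neural
interaction reproduces, trial after trial, a consistent phase relationship
between two regions at a fixed latency; trial-varying background activity
averages out.  The pipeline is

1. band-pass filter → Hilbert phases per ROI and trial;
2. moving-window across-trial PLV or PLI per ROI pair;
3. Rayleigh significance + per-latency Benjamini–Hochberg trimming → a
   weighted graph per latency;
4. weighted local efficiency per graph; sequential dominant-set
   partitioning, cohesive-index ranking, dominant-cluster timeline, and
   strongest-edge extraction.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `cc` (cycle criterion) | 2 | cycles of f_low | window must span full cycles of the slowest rhythm it analyzes; W_L = (cc/f_low)·fs + 1 samples, rounded to the nearest odd integer (ties up) so the window is symmetric about its center |
| `step` | 5 | samples | latency resolution of the graph series |
| `q` (FDR level) | 0.001 | — | expected false-positive fraction among retained edges |
| `k_percent` | 5 | % of N(N−1)/2 | strongest-edge extraction for graph displays |
| filter order | 4 | — | Butterworth band-pass, applied forward-backward (zero phase); effective order 8 |
| `support_eps` | 1e-5 | — | replicator components outside the dominant set decay geometrically; anything above this threshold is support |
| `tol`, `max_iter` | 1e-10 (L1), 10 000 | — | replicator stopping rule; a convergence criterion subsumes a fixed iteration count and is reproducible |

Band presets: δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz; `wide` = 1–45 Hz
with f_low = 1 Hz governing the window width (configurable — wideband
windowing is a genuine free choice and other effective f_low values are
reachable by passing an explicit `WindowSpec`).

## Design choices where the design was open

- **PLI sign convention.** The estimator takes the absolute value around
  the *full* trial × window sum of sign(sin Δφ).  Inner absolute values
  would make the statistic identically 1; the outer-only form is the one
  consistent with the defining property that coupling at 0 mod π lag
  yields PLI = 0.
- **Rayleigh significance for PLI.** p = exp(−N_trials·SM²) is applied to
  both measures.  The Rayleigh null is derived for resultant-length
  statistics like PLV; for PLI it is an approximation kept for methodological
  consistency, and the FDR trimming dominates the final edge selection.
- **Within-window samples are equally weighted.** Consecutive phase
  samples inside a window are autocorrelated; no effective-sample
  correction is applied because the estimator definitions average
  uniformly.  This makes the Rayleigh p conservative after windowing
  (the null PLV of smoothed phases is smaller than the unsmoothed
  Rayleigh form assumes), which is the safe direction for edge trimming.
- **BH scope.** Trimming is per latency across the N(N−1)/2 pairs: each
  latency's graph is trimmed as its own family.
- **Weight→length map for efficiency.** Shortest paths use d = 1/w, the
  standard choice for synchrony weights in [0, 1]; with weights ≤ 1 all
  inverse path lengths are ≤ 1, so 0 ≤ LE ≤ 1.  Nodes with fewer than two
  neighbors contribute 0 (not NaN), and pairs unreachable within a
  neighborhood contribute 0 inverse distance — the fault-tolerance
  reading of the metric, and the convention that keeps LE defined on
  sparse trimmed graphs.
- **Replicator initialization.** Default is the simplex barycenter
  y = 1/N — a strictly positive deterministic start that makes the whole
  pipeline bit-reproducible; a seeded random-positive initialization is
  available (`rng=` / `random_state=`).  Replicator dynamics ascend
  F(y) = yᵀWy to a *local* maximizer; when two near-equally cohesive
  groups compete, different initializations can select different ones.
  The test oracles therefore certify global-optimum agreement on graphs
  with a separated dominant group, where local and global maximizers
  coincide.
- **Partition termination.** After each extraction the algorithm recurses
  on the remaining vertices; remaining nodes with zero within-residue
  weight become singleton clusters (in index order), guaranteeing
  termination and an exhaustive disjoint labeling.
- **Dominant-cluster selection.** Timelines mark the cluster with the
  *highest cohesive index*, which usually but not necessarily is the
  first-extracted set.
- **Tie-breaks.** Strongest-edge extraction sorts by descending weight
  with ties resolved by pair index; CI ties resolve to the lowest label.

## The synthetic generator

The generator emulates the statistical structure the estimators consume:
each ROI is a band-limited oscillator with a fresh uniform phase per trial
over additive white (optionally 1/f) noise; a coupling event locks the
driven ROI's phase to the driver's minus a lag, within a latency window,
with von-Mises jitter of concentration κ = κ₀·s/(1−s) mapping strength
s ∈ [0, 1] continuously from uncoupled to perfectly locked.  Phase
transitions at event edges use 20 ms smoothstep ramps to avoid broadband
discontinuities.  Default study-scale conditions used throughout the
validation suite: 12 ROIs, 36 trials, 500 Hz sampling, 800 ms epochs with
onset at 200 ms, noise SD 0.3 (≈ −7 dB relative to the unit-amplitude
oscillation), one full-strength γ-band event at lag π/2 spanning
100–300 ms.

What it deliberately does **not** emulate: biophysical forward models,
sensor mixing/volume conduction, heterogeneous ROI spectra, amplitude
dynamics, or nonstationary noise.  Passing the recovery tests therefore
demonstrates that the estimator chain is correct and sensitive under its
own assumptions — not that those assumptions hold in any given recording.

## Numerical notes

- Window sums use prefix sums over the trial-summed phasor/sign series;
  agreement with an explicit double loop is asserted to 1e−12.
- Filters are rejected (with a diagnostic) when the band is so narrow
  that the filter's transient (3 pole-decay constants) exceeds the epoch.
- A constant (all-zero) signal has undefined phase and is rejected rather
  than silently mapped to 0.
- Latencies whose window would overrun the epoch are skipped, not padded:
  windows never include filter/Hilbert edge artifacts.
- Shortest paths within neighborhood subgraphs use Dijkstra
  (`scipy.sparse.csgraph`); the exhaustive path-enumeration oracle lives
  only in the test suite.

## Problem sizes in the validation suite

Recovery and null checks run at the study-scale defaults above (74-latency
γ-band series; the null FDR check uses 12 independent-noise ROIs at 200 Hz
with >1,500 α-band latencies, giving >100,000 pair-latency tests).  Oracle
equivalence uses graphs of up to 6 nodes, where exhaustive enumeration is
exact.

## Known limitations

- The Rayleigh p-value ignores within-window autocorrelation (conservative,
  see above) and is asymptotic in N_trials.
- Replicator dynamics find local maximizers of set compactness; the
  sequential partition is greedy and has no global optimality guarantee.
- Across-trial estimators need tens of trials; with few trials the PLV
  chance level (≈ 1/√N_trials before windowing) is substantial.
- The generator's phase-driving construction makes the driven ROI's
  marginal statistics identical to the uncoupled case, but transitive
  coupling arises when one driver locks several targets (used
  deliberately in the triangle-recovery tests).
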