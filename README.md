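# dynfc — event-related dynamic functional connectivity

`dynfc` tracks how brain networks reorganize around a stimulus.  Given
multi-trial region-of-interest (ROI) time series — e.g. source-space MEG/EEG
reconstructions, one epoch per trial — it builds a *time-varying* functional
connectivity graph (FCG): at every latency, a weighted undirected graph over
ROIs whose edges carry across-trial phase synchrony.  The graph series is
then characterized by weighted local efficiency and segmented into cohesive
modules by dominant-set clustering, yielding latency-resolved pictures of
network reconfiguration.  It is intended for researchers analyzing
event-related neuroimaging experiments at the single-subject level, and
ships a synthetic coupled-oscillator generator so every stage can be
validated against a known ground truth.

## Method

Signals are band-pass filtered (δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz,
or wideband) and instantaneous phases φ(n, k) extracted via the Hilbert
transform (latency n, trial k).  A window of W_L = (CC/f_low)·f_s + 1
samples (CC = 2 cycles of the band's lowest frequency) slides in 5-sample
steps.  For each ROI pair (u, v) with phase difference Δφ = φᵘ − φᵛ:

- **PLV** (phase locking value):
  `PLV(n) = (1/N_trials) |Σ_k (1/W_L) Σ_{n′∈win(n)} exp(i Δφ(n′,k))|`
- **PLI** (phase lag index):
  `PLI(n) = |(1/(N_trials·W_L)) Σ_k Σ_{n′} sign(sin Δφ(n′,k))|`

Both lie in [0, 1]; PLI is blind to coupling at 0 mod π lag, making it
insensitive to volume conduction.  Each value is tested with a Rayleigh
significance p = exp(−N_trials·SM²), and the N(N−1)/2 pairwise tests per
latency are trimmed by Benjamini–Hochberg FDR at q ≤ 0.001; survivors fill
the weighted adjacency matrix W.

Each trimmed graph is summarized by **weighted local efficiency**
`LE = (1/N) Σ_i [Σ_{j≠h∈G_i} d_jh⁻¹] / (k_i(k_i−1))` (shortest paths within
each node's neighborhood subgraph, edge length 1/w), and partitioned by
**sequential dominant-set clustering**: the replicator recursion
`y_i ← y_i (Wy)_i / (yᵀWy)` climbs the set-compactness F(y) = yᵀWy on the
simplex; the support of the fixed point is the dominant set, which is
removed and the process repeated.  Clusters are ranked by cohesive index
(mean within-cluster strength), and the highest-CI cluster per latency
forms the dominant-cluster timeline.

## Worked example

Plant a single γ-band coupling event (pair (0, 1), lag π/2, full strength,
100–300 ms after stimulus onset) among 12 ROIs and recover it:

```python
import math
import numpy as np
from dynfc import (CouplingEvent, CouplingGroundTruth, generate_trials,
                   build_fcg_series, le_timecourse, dominant_timeline)

event = CouplingEvent(pair=(0, 1), band_freq=35.0, phase_lag=math.pi / 2,
                      strength=1.0, onset_ms=100.0, offset_ms=300.0)
truth = CouplingGroundTruth(events=(event,), noise_sd=0.3, seed=11)
data = generate_trials(truth, n_roi=12, n_samples=400, n_trials=36,
                       fs=500.0, onset_sample=100)

fcgs = build_fcg_series(data, "gamma", measure="plv", q=0.001)
t = int(np.argmin(np.abs(fcgs.latencies_ms - 200.0)))
W = fcgs.adjacency[t]
tl = dominant_timeline(fcgs)
active = np.flatnonzero(tl.membership.any(axis=0))
print(f"window: {fcgs.window.w_l} samples, {fcgs.n_latencies} latencies")
print(f"at {fcgs.latencies_ms[t]:.0f} ms: strongest edge PLV = {W.max():.3f}")
print(f"dominant cluster at 200 ms: ROIs {np.flatnonzero(tl.membership[:, t]).tolist()}")
print(f"dominant cluster active {fcgs.latencies_ms[active[0]]:.0f}"
      f"-{fcgs.latencies_ms[active[-1]]:.0f} ms (true event: 100-300 ms)")
```

prints

```
window: 35 samples, 74 latencies
at 204 ms: strongest edge PLV = 0.993
dominant cluster at 200 ms: ROIs [0, 1]
dominant cluster active 94-304 ms (true event: 100-300 ms)
```

The planted pair carries near-unit PLV inside its window (0.993 at 204 ms),
it alone forms the dominant cluster there, and the cluster's active span
(94–304 ms) recovers the true 100–300 ms event to within half a window
width (the 35-sample window spans 70 ms, so estimates bleed ~35 ms past
each boundary).

The same pipeline is scriptable from a shell:

```sh
dynfc simulate --n-roi 12 --n-trials 36 --fs 500 --events events.json --seed 11 --out data
dynfc run --in data --bands gamma --measure plv --out bundle/
```

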