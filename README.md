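# neurotrack

Multi-session single-neuron tracking for *in vivo* calcium imaging.

Long-term calcium-imaging experiments (miniscope or 2-photon) record the
same field of view over days to weeks. Each session is processed by a
source-extraction pipeline (e.g. CNMF-E) into spatial footprints `A`
(d pixels × K neurons) and fluorescence traces `C` (K × T, ΔF/F). The
scientific question — *which neuron in session 2 is the same cell as neuron
k in session 1?* — is hard whenever footprints move between sessions,
extractions miss neurons, or extra "neurons" are false discoveries.
`neurotrack` answers it by combining **spatial** and **temporal** evidence
inside a probabilistic consensus-clustering framework, and ships a full
synthetic-recording generator so every part of the pipeline can be
validated against ground truth without any real recording.

## Method

For every pair of sessions, candidate neuron pairs (non-zero footprint
overlap, centroid distance ≤ `max_dist`) are scored with six metrics:

| metric | type | definition |
| --- | --- | --- |
| centroid distance | spatial | ‖c₁ − c₂‖₂ (pixels) |
| footprint overlap | spatial | cos(a, b) of binarized supports |
| JS divergence | spatial | Jensen–Shannon divergence of normalized footprints (bits) |
| SNR difference | temporal | \|log SNR₁ − log SNR₂\|, SNR = Var(signal)/Var(noise) |
| decay difference | temporal | \|τ₁ − τ₂\| of the fitted transient decay constant |
| link correlation | temporal | best connecting-neuron correlation through a short recording spanning the session boundary |

Each metric's population of values over all candidate pairs is split into
"same cell" and "different cell" groups by an identification model —
percentile ranks, a two-component Gaussian mixture `h(x) = w·f(x) +
(1−w)·g(x)` fit to a boundary-reflected kernel density estimate (posterior
`w·f/(w·f + (1−w)·g)`), or fuzzy two-means memberships. A weight vector
turns per-metric probabilities into one aggregated similarity per pair
(entries below `min_prob` are zeroed, same-session pairs are forbidden with
a −10000 sentinel). Each connected component of the resulting similarity
graph is partitioned by a switch/swap clustering algorithm constrained so
no cluster holds two neurons of one session and every multi-member cluster
keeps mean similarity ≥ `chain_prob`. The weight vector is then perturbed
(N(0, 0.12), clipped, renormalized; 30 vectors), the component is
re-clustered per weight vector, the co-clustering frequencies form a
consensus matrix, and a final clustering of that matrix yields the **cell
register**: one row per tracked cell, one column per session, plus a row
confidence. Traces of registered cells can be concatenated across sessions
(missing sessions are NaN-masked).

The package also contains:

* `neurotrack.simulator` — the synthetic-recording generator (Gaussian
  footprints, Bernoulli spiking convolved with
  `g(t) = exp(−t/τ_d) − exp(−t/τ_r)`, background blobs and blood vessels,
  four dataset styles including per-neuron non-rigid warps, ring-shaped
  2-photon footprints, and 5–7 px individual shifts) with full ground truth;
* `neurotrack.evaluation` — register scoring: PDR (percent discovery rate),
  FDR (fraction of tracked rows with ≥ 1 wrong member),
  `F1 = 2·PDR·(1−FDR)/((1−FDR)+PDR)`, per-cluster Jaccard similarity, and
  cluster-size JS divergence;
* `neurotrack.placefields` — linear-track place fields (20 bins over the
  middle 80% of the track), spatial information scores
  `Σ pᵢ λᵢ log₂ λᵢ`, circular-shift shuffle percentiles, and cross-session
  place-field stability statistics.

## Worked example

Generate a two-session recording in which every footprint is independently
shifted by 5–7 pixels (≈ 30–40% of a neuron's width) in the second session
— the regime where spatial metrics alone start to fail — then track and
score against ground truth:

```python
from neurotrack import evaluation, simulator, tracker

config = simulator.style_config("individual_shift", n_neurons=30, seed=1)
sessions, links, truth, _ = simulator.make_dataset("individual_shift", config)

tracker_config = tracker.TrackerConfig(min_prob=0.5, chain_prob=0.5, seed=1)
register = tracker.track(sessions, links, tracker_config)

score = evaluation.score_register(register, truth.register)
print(f"tracked cells:     {len(register)}")
print(f"PDR:               {score.pdr:.3f}")
print(f"FDR:               {score.fdr:.3f}")
print(f"F1:                {score.f1:.3f}")
```

Output:

```
tracked cells:     30
PDR:               1.000
FDR:               0.000
F1:                1.000
```

All 30 ground-truth cells are recovered despite the shifts (PDR = 1), no
register row contains a wrong member (FDR = 0), so the tracking quality
F1 is perfect. Dropping the temporal metrics
(`metrics=("centroid_dist", "overlap", "js_div")`) on the same data lowers
mean F1 to ≈ 0.76 over ten simulated recordings — the temporal evidence is
what disambiguates shifted neighbors.

The same pipeline is available from the shell:

```bash
neurotrack simulate --style individual_shift --out data/ --seed 1
neurotrack track --sessions data/session0.h5 --sessions data/session1.h5 \
    --links data/link0.h5 --out register.csv --seed 1
neurotrack evaluate --proposed register.csv --truth data/truth_register.csv
```

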