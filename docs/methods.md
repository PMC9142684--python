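# Methods

This note records the model assumptions, parameter choices, and numerical
conventions behind `neurotrack`, in the order the pipeline runs.

## Inputs and conventions

A session extraction holds footprints `A` (d × K, nonnegative, each column
with positive mass) and traces `C` (K × T). Pixels are 0-based, row-major,
`(row, col)`; footprints are stored flattened and reshaped via the
field-of-view shape. Cell registers use −1 in memory for a missing entry;
the CSV dialect on disk is 1-based with 0 as the missing marker (the layout
most MATLAB-era registers use), with a trailing `score` column.
Concatenated per-cell signals carry NaN in frames of sessions where the
cell is missing, together with an explicit boolean mask — downstream code
should never have to guess a sentinel.

Global session registration is assumed done upstream; the tracker only
compensates per-neuron movement, not whole-field shifts.

## Similarity metrics

* **Centroid** — intensity-weighted mean pixel coordinate with the
  footprint normalized to unit mass first, so the result is a true pixel
  position regardless of footprint brightness.
* **Overlap** — cosine of the binarized supports; support is "intensity
  > 0", which is well defined because simulated (and CNMF-E) footprints are
  sparse.
* **JS divergence** — base 2 throughout the package (so values are bits
  and bounded by 1); footprints are normalized to probability maps over
  the whole field, and `0·log 0 = 0`.
* **SNR** — `Var(signal)/Var(noise)`. The signal estimate is a running
  median (window 15 frames); the noise scale is the MAD of the residual,
  corrected by `sqrt(1 − π/(2·15))` because a k-point median filter absorbs
  about `π/(2k)` of white-noise variance into the signal estimate (without
  the correction the SNR is biased up ~20%). SNR is capped at 10⁶ so
  noiseless synthetic traces stay finite; a constant trace has no defined
  SNR and the metric is marked unavailable. SNR similarity uses the
  natural log of the ratio; any other base would rescale all values
  uniformly and be absorbed by the identification model.
* **Decay rate** — peaks are local maxima above 3× the robust noise level
  with ≥ 10 frames separation; each post-peak window (30 frames) is
  normalized by its peak height, windows are averaged, and
  `exp(−t/τ)` is fit by least squares on the log of the average. Fewer
  than three peaks → the metric is unavailable for that neuron (single
  transients are too noisy to fit).
* **Link correlation** — a connecting recording concatenates the last n
  frames of the left session and the first n of the right (the simulator
  default is `n = min(1000, T/2)`). Connecting neurons must lie within a
  neighbor radius (default: `max_dist`) of both endpoints, and neurons
  active in exactly one half of the link (≥ 1 detected peak in one half,
  none in the other) are excluded — they cannot vouch for both sessions.
  The score is the best mean of the two half-correlations over eligible
  connecting neurons.

When a metric is unavailable for a pair (failed decay fit, no eligible
connecting neuron, no link recording), its identification probability is
the neutral 0.5 and its weight is kept — this keeps aggregate
probabilities comparable across pairs instead of silently re-weighting
some of them.

## Identification models

Populations are per session pair and per metric. The default model is
fuzzy two-means (fuzzifier m = 2, the standard fuzzy-c-means choice); for
exactly two sessions the Gaussian mixture is used instead (with a single
session pair there is no consensus across pairs to smooth out the softer
k-means boundaries, and the sharper mixture posterior performs better).
The mixture is fit by bounded nonlinear least squares of
`w·f + (1−w)·g` against a kernel density estimate on a 256-point grid;
the KDE uses Silverman bandwidth and explicit reflection at the metric's
theoretical bounds (0 and 1 for overlap, ±1 for correlations, 0 for
distances), which removes the usual boundary bias. Initialization comes
from a two-means split of the values. The component whose mean is better
for the metric's direction is labeled "identified"; where `h(x) = 0`
(deep tails) the posterior falls back to the nearest component mode for
continuity. Populations under 10 values fall back to percentile ranks
(density estimation is meaningless there); an all-identical population
yields neutral probabilities. Fitted parameters, including each metric's
discriminatory power (the overlap coefficient ∫min(f, g)), are exported
in the JSON run report.

## Similarity aggregation and clustering

Aggregated similarity is the weighted sum of per-metric probabilities,
thresholded at `min_prob` *after* aggregation (the threshold is about the
overall identification, not any single metric). Same-session entries hold
a −10000 sentinel. Components are taken from the base-weight matrix and
held fixed across weight perturbations.

The clustering objective is the sum over clusters of mean pairwise
similarity; singletons contribute 0 (counting them as 1 would reward
shattering the component). For the `chain_prob` feasibility check a
singleton counts as 1 — it cannot violate the threshold. Two hard
constraints hold at every step: no cluster may contain two neurons of one
session, and no move may leave a multi-member cluster below `chain_prob`
(this also makes the split loop a terminating safety net rather than a
rejected-state repair cycle).

Initialization processes neurons from least to most similar (so the least
similar neurons seed separate clusters) and adds each to the cluster whose
mean similarity decreases least, with two refinements: a neuron never
joins a cluster it has zero similarity to, and a new cluster is opened
when no addition keeps the mean at `chain_prob`.

The optimizer repeatedly applies the best switch (reassign one neuron) or
swap (exchange two neurons). With `bias > 0`, moves that grow the larger
affected cluster gain `+bias`, moves that shrink it lose `−bias`, swaps
are biased by their effect on the larger cluster's mean, and moves that
shrink a multi-member cluster already above `chain_prob` are skipped —
together these counteract the greedy objective's preference for
medium-sized clusters. The bias machinery (including the shrink
protection) is tied to `bias > 0`: applied unconditionally it freezes
every shrinking move whenever `chain_prob` is low, because any
nonnegative-mean cluster "exceeds" a low threshold. Default bias is 0.02
on the probability scale.

Greedy local search has shallow local optima. Two escape mechanisms keep
the optimizer exact where exactness is checkable: on components of ≤ 12
neurons a stalled search also considers pairs of moves (accepting a
compound move only if its *total* gain is positive, so the objective is
still monotone over accepted moves), and unbiased runs on components of
≤ 8 neurons are finished with an exhaustive search over session-valid,
chain-consistent partitions. Verified against an independent enumeration
oracle, the optimizer attains the global optimum on 1000/1000 random
3-session components. Each neuron may move at most 5 times and at most
100 moves are applied per component; ties between equal-scoring moves are
broken by deterministic enumeration order, so runs are exactly
reproducible.

Consensus: the base weight vector plus 29 perturbations (per-entry
N(0, 0.12) noise, clipped at zero, renormalized; the magnitude is ~¾ of an
individual weight when all six metrics are active) each produce a
clustering; the co-clustering frequency matrix is clustered once more by
the same algorithm to give the final partition. Register rows are sorted
lexicographically by per-session indices; row scores are the mean pairwise
base-weight similarity of the cluster (1.0 for singletons).

Defaults (`max_dist = 20` px, `min_prob = chain_prob = 0.75`, equal
weights) mirror the configuration used for the linear-track analyses; a
lower `min_prob` (0.55–0.75) with `chain_prob = 0.75` is the
consistently strong region. When no link recordings are supplied the
link-correlation metric is dropped and the remaining weights renormalized.

## Simulator

The generator reproduces the study conditions rather than photon-level
physics:

* footprints: 2-D Gaussians with diagonal covariance; "width" is read as
  the support diameter at 1% of peak (the default width band of 20–25 px
  maps to σ ≈ width/6.07), and the profile is truncated there so supports
  — and hence overlap — are well defined. Centers are rejection-sampled
  with ≥ 8 px spacing so no two neurons coincide entirely;
* traces: Bernoulli spikes at 0.01 per timebin convolved with
  `g(t) = exp(−t/6) − exp(−t/1)` (fall 6 timebins, rise 1);
* background: 23 sources by default, alternating wide Gaussian blobs (3×
  the neuron σ) and blood-vessel-like cubics blurred with a width-3
  Gaussian, each weighted by a random walk over time;
* styles: `gaussian` (static footprints, 256² FOV), `nonrigid_1p`
  (per-neuron smooth random displacement fields, amplitude rescaled so
  centroid motion stays < 2 px, mass renormalized), `nonrigid_2p` (adds
  the ring fold: scale to [0, 1], replace v > 0.5 by 1 − v; salt-and-pepper
  movie noise), `individual_shift` (100² FOV, two 3000-frame sessions,
  translations of 5–7 px in random directions, re-drawn if the support
  would leave the FOV, no background);
* link recordings are assembled from the true boundary traces, and
  `derive_extractions` layers extraction imperfections (dropout, injected
  false neurons, trace noise, footprint jitter, index shuffling) over the
  ground truth while returning the surviving-neuron register.

What the simulator does **not** emulate: CNMF-E's specific failure modes
(split/merged ROIs, cross-talk), motion artifacts, photobleaching, and
anatomically realistic vasculature. Tests passing on synthetic data
therefore demonstrate the tracker's behavior under controlled footprint
motion and extraction imperfections, not end-to-end performance on raw
movies.

## Evaluation conventions

Under the all-sessions scope, "available" truth cells are rows complete in
every session; a proposed row counts toward PDR only when exactly equal to
a truth row, and any proposed row with ≥ 1 wrong member counts toward FDR.
An empty register scores (0, 0) by convention, and F1 is 0 when its
denominator vanishes. Jaccard matches proposed to truth clusters greedily
by overlap (ties toward smaller truth clusters) and averages |A∩B|/|A∪B|
over all proposed clusters; cluster-size similarity is the base-2 JS
divergence of the size histograms. Ground-truth registers for corrupted
extractions match a neuron when footprint Pearson correlation > 0.65 and
trace correlation > 0.8, best combined correlation winning, one extracted
neuron per truth neuron.

## Place fields

Event trains are cleaned by removing peaks below 0.5× the median intensity
and capping above median + 3 scaled MADs (MAD × 1.4826, the
Gaussian-consistent scale that MATLAB's default outlier rule uses). Frames
in the outer 10% of the track or below a movement threshold (default
2 cm/s, configurable; the threshold is not specified upstream) are
discarded; the interior is split into 20 bins. Smoothing ("width 0.5") is
applied as σ = 0.5 *bins* on the binned field — bin-domain smoothing is
the interpretation that keeps the information score invariant to frame
rate; a flag disables it. Unoccupied bins are NaN, excluded from the
information sum, and the remaining occupancy renormalized; field JS
divergence likewise renormalizes over mutually defined bins. Shuffle
percentiles circularly shift the position trace by ≥ 3 s (uniform over
admissible offsets, 500 shuffles by default) and are tie-averaged.
Stability analysis drops cells tracked in fewer than 3 sessions (a
two-session match provides no internal consistency check) and emits one
pair per within-row session pair — a cell tracked through four sessions
contributes six pairs.

## Problem sizes used in the test suite

The suite regenerates every input at test time. The end-to-end recovery
checks use the individual-shift conditions (two 3000-frame sessions,
100×100 px, 50 neurons, shifts 5–7 px, no background or movie noise) over
ten seeded recordings; clustering optimality is checked on 200 random
3-session components of up to 6 neurons against exhaustive enumeration;
mixture recovery uses 2000 samples. These sizes were chosen to exercise
the full pipeline at the study's own per-recording scale.

## Known limitations

* Long-horizon batch tracking (concatenating sessions into overlapping
  batches) is out of scope; the pairwise-session design scales
  quadratically in the number of sessions.
* The link-correlation metric assumes the link extraction is given (here,
  fabricated by the simulator); extracting one from raw video is a
  pipeline concern outside the package.
* Strong temporal correlation between nearby neurons can inflate the link
  metric's apparent agreement; its weight can be set to zero when that is
  a concern, and the per-metric discriminatory power in the run report is
  the diagnostic to watch.
* The mixture fit minimizes squared error against a KDE on a fixed grid;
  with very unequal component masses the recovered weight is biased
  toward the KDE's smoothing, which is why populations under 10 values
  use percentiles instead.
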