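"""Place fields, spatial information scores, and cross-session stability.

A place field is the occupancy-normalized event-rate map of one neuron over
a linear track: frames near the track ends (outer 10%) or below a movement
speed threshold are discarded, the middle 80% of the track is divided into
20 bins, and per-bin event mass is divided by per-bin occupancy.

The spatial information score is ``sum_i p_i * lambda_i * log2(lambda_i)``
where ``p_i`` is the occupancy probability of bin i and ``lambda_i`` the
ratio of the bin's firing rate to the mean rate.  Significance is assessed
against a null built by circularly shifting the position trace by at least
3 seconds, 500 times.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter1d

_MAD_SCALE = 1.4826  # Gaussian-consistent MAD factor

DEFAULT_N_BINS = 20
DEFAULT_EDGE_FRACTION = 0.10
DEFAULT_SPEED_THRESHOLD = 0.02  # m/s
DEFAULT_N_SHUFFLES = 500
DEFAULT_MIN_SHIFT_S = 3.0


class EmptyFieldError(ValueError):
    """No events survive preprocessing / no occupied frames remain."""


@dataclasses.dataclass
class TrackRun:
    """Behavior and per-neuron event trains for one linear-track session.

    ``events`` is a (K, T) array of event intensities per frame (zero where
    no event); ``position`` in meters along the track; ``speed`` in m/s
    (derived from position if omitted).
    """

    position: np.ndarray
    events: np.ndarray
    track_length: float = 1.0
    frame_rate: float = 30.0
    speed: np.ndarray | None = None
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.events = np.atleast_2d(np.asarray(self.events, dtype=float))
        if self.events.shape[1] != self.position.size:
            raise ValueError("events and position must cover the same frames")
        if np.any(self.position < 0) or np.any(self.position > self.track_length):
            raise ValueError("position outside [0, track_length]")
        if np.any(self.events < 0):
            raise ValueError("event intensities must be nonnegative")
        if self.speed is None:
            self.speed = np.abs(np.gradient(self.position)) * self.frame_rate
        else:
            self.speed = np.asarray(self.speed, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.position.size

    @property
    def n_neurons(self) -> int:
        return self.events.shape[0]


@dataclasses.dataclass
class PlaceField:
    """Occupancy-normalized activity map with its information statistics."""

    field: np.ndarray  # activity / occupancy per bin (NaN where unoccupied)
    occupancy: np.ndarray  # occupancy probability per bin
    information_score: float
    information_percentile: float | None = None


def preprocess_peaks(intensities: np.ndarray) -> np.ndarray:
    """Clean a train of event peak intensities.

    Low outliers (< 0.5 * median) are removed (zeroed); high outliers
    (> median + 3 scaled MADs) are capped at that bound.
    """
    x = np.asarray(intensities, dtype=float).copy()
    active = x > 0
    if not np.any(active):
        raise EmptyFieldError("no events in train")
    vals = x[active]
    med = np.median(vals)
    low = 0.5 * med
    mad = _MAD_SCALE * np.median(np.abs(vals - med))
    high = med + 3.0 * mad
    x[active & (x < low)] = 0.0
    np.clip(x, None, high, out=x)
    x[~active] = 0.0
    if not np.any(x > 0):
        raise EmptyFieldError("no events survive preprocessing")
    return x


def _valid_frames(run: TrackRun, edge_fraction: float, speed_threshold: float,
                  position: np.ndarray | None = None) -> np.ndarray:
    pos = run.position if position is None else position
    lo = edge_fraction * run.track_length
    hi = (1.0 - edge_fraction) * run.track_length
    return (pos >= lo) & (pos <= hi) & (run.speed >= speed_threshold)


def compute_place_field(
    run: TrackRun,
    neuron: int,
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    smooth_sigma_bins: float = 0.5,
    preprocess: bool = True,
    _position_override: np.ndarray | None = None,
) -> PlaceField:
    """Binned occupancy-normalized place field of one neuron.

    Frames in the outer ``edge_fraction`` of the track or slower than
    ``speed_threshold`` are excluded; the interior is split into
    ``run.n_bins`` bins.  The binned field is smoothed with a Gaussian of
    ``smooth_sigma_bins`` bins; bins never occupied are NaN and excluded
    from the information sum.
    """
    events = run.events[neuron]
    if preprocess:
        events = preprocess_peaks(events)
    pos = run.position if _position_override is None else _position_override
    valid = _valid_frames(run, edge_fraction, speed_threshold, pos)
    if not np.any(valid):
        raise EmptyFieldError("no frames survive the speed/edge filter")
    lo = edge_fraction * run.track_length
    hi = (1.0 - edge_fraction) * run.track_length
    edges = np.linspace(lo, hi, run.n_bins + 1)
    which = np.clip(np.digitize(pos[valid], edges) - 1, 0, run.n_bins - 1)
    occupancy = np.bincount(which, minlength=run.n_bins).astype(float)
    activity = np.bincount(which, weights=events[valid], minlength=run.n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        field = np.where(occupancy > 0, activity / np.maximum(occupancy, 1), np.nan)
    defined = occupancy > 0
    if smooth_sigma_bins > 0 and defined.any():
        sm = field.copy()
        sm[defined] = _smooth_defined(field[defined], smooth_sigma_bins)
        field = sm
    occ_prob = np.where(defined, occupancy / occupancy.sum(), 0.0)
    score = information_score(field, occ_prob)
    return PlaceField(field=field, occupancy=occ_prob, information_score=score)


def _smooth_defined(values: np.ndarray, sigma: float) -> np.ndarray:
    return gaussian_filter1d(values, sigma=sigma, mode="nearest")


def information_score(field: np.ndarray, occupancy: np.ndarray) -> float:
    """Spatial information ``sum p_i lambda_i log2 lambda_i`` in bits.

    ``field`` is the per-bin rate (NaN = undefined bin), ``occupancy`` the
    per-bin probability.  Undefined bins are excluded and the remaining
    occupancy renormalized; 0 * log 0 = 0.  NaN if total firing is zero.
    """
    field = np.asarray(field, dtype=float)
    occupancy = np.asarray(occupancy, dtype=float)
    defined = np.isfinite(field) & (occupancy > 0)
    if not defined.any():
        return float("nan")
    p = occupancy[defined] / occupancy[defined].sum()
    rate = field[defined]
    mean_rate = float((p * rate).sum())
    if mean_rate <= 0:
        return float("nan")
    lam = rate / mean_rate
    pos = lam > 0
    return float(np.sum(p[pos] * lam[pos] * np.log2(lam[pos])))


def information_percentile(
    run: TrackRun,
    neuron: int,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    min_shift_s: float = DEFAULT_MIN_SHIFT_S,
    seed: int = 0,
    **field_kwargs,
) -> float:
    """Percentile of the neuron's information score in a circular-shift null.

    The position trace is circularly shifted by a uniform offset of at
    least ``min_shift_s`` seconds (either direction), ``n_shuffles`` times;
    the percentile is the tie-averaged fraction of null scores below the
    unshifted score.
    """
    min_shift = int(round(min_shift_s * run.frame_rate))
    t = run.n_frames
    if t <= 2 * min_shift:
        raise ValueError("run too short for the requested minimum shift")
    events = preprocess_peaks(run.events[neuron])
    rng = np.random.default_rng(seed)

    def score_with(position):
        pf = compute_place_field(
            run, neuron, preprocess=False, _position_override=position,
            **field_kwargs,
        )
        return pf.information_score

    run = dataclasses.replace(run, events=run.events.copy())
    run.events[neuron] = events
    actual = score_with(run.position)
    null = np.empty(n_shuffles)
    shifts = rng.integers(min_shift, t - min_shift, size=n_shuffles)
    for k, shift in enumerate(shifts):
        null[k] = score_with(np.roll(run.position, int(shift)))
    null = null[np.isfinite(null)]
    if null.size == 0 or not np.isfinite(actual):
        return float("nan")
    below = np.sum(null < actual)
    ties = np.sum(null == actual)
    return float((below + 0.5 * ties) / null.size)


# ---------------------------------------------------------------------------
# cross-session stability


def field_js_divergence(field_a: np.ndarray, field_b: np.ndarray) -> float:
    """JS divergence (bits) between two place fields, renormalized over the
    bins defined in both."""
    from .metrics import js_divergence

    a = np.asarray(field_a, dtype=float)
    b = np.asarray(field_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any() or a[ok].sum() <= 0 or b[ok].sum() <= 0:
        return float("nan")
    return js_divergence(a[ok], b[ok])


def placefield_stability(
    register,
    fields_per_session: list[list[PlaceField | None]],
    js_threshold: float = 0.05,
    percentile_threshold: float | None = 0.95,
    score_threshold: float | None = None,
    min_sessions: int = 3,
):
    """Place-field stability statistics over a cell register.

    ``fields_per_session[s][i]`` is the place field of neuron ``i`` in
    session ``s`` (None when not computed).  Register rows tracked in fewer
    than ``min_sessions`` sessions are dropped (rows seen in only two
    sessions are noisy); every remaining within-row session pair
    contributes one identified cell pair.

    Returns a dict with the per-pair JS divergences, the fraction below
    ``js_threshold`` among pairs where at least one member passes the
    percentile/score threshold, and the fraction of pairs whose place/non-
    place classification matches across sessions.
    """
    from .io import MISSING

    pair_js: list[float] = []
    pair_pass: list[bool] = []
    pair_consistent: list[bool] = []
    for _, row in register.table.iterrows():
        entries = [(s, int(v)) for s, v in enumerate(row.to_numpy()) if v != MISSING]
        if len(entries) < min_sessions:
            continue
        for a in range(len(entries)):
            for b in range(a + 1, len(entries)):
                sa, ia = entries[a]
                sb, ib = entries[b]
                fa = fields_per_session[sa][ia]
                fb = fields_per_session[sb][ib]
                if fa is None or fb is None:
                    continue
                js = field_js_divergence(fa.field, fb.field)
                if not np.isfinite(js):
                    continue
                pair_js.append(js)
                passes = _passes(fa, percentile_threshold, score_threshold) or \
                    _passes(fb, percentile_threshold, score_threshold)
                pair_pass.append(passes)
                pair_consistent.append(
                    _passes(fa, percentile_threshold, score_threshold)
                    == _passes(fb, percentile_threshold, score_threshold)
                )
    pair_js_arr = np.asarray(pair_js)
    pass_arr = np.asarray(pair_pass, dtype=bool)
    cons_arr = np.asarray(pair_consistent, dtype=bool)
    n_pass = int(pass_arr.sum())
    return {
        "pair_js": pair_js_arr,
        "mean_js": float(pair_js_arr.mean()) if pair_js_arr.size else float("nan"),
        "fraction_below_threshold": (
            float((pair_js_arr[pass_arr] < js_threshold).mean()) if n_pass else float("nan")
        ),
        "fraction_consistent_classification": (
            float(cons_arr.mean()) if cons_arr.size else float("nan")
        ),
        "n_pairs": int(pair_js_arr.size),
    }


def _passes(pf: PlaceField, percentile_threshold, score_threshold) -> bool:
    if percentile_threshold is not None and pf.information_percentile is not None:
        return pf.information_percentile >= percentile_threshold
    if score_threshold is not None:
        return pf.information_score >= score_threshold
    return False
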