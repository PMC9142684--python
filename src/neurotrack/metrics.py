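"""Pairwise cell-cell similarity metrics between neurons of two sessions.

Six metrics are computed per candidate pair: three spatial (centroid
distance, binarized-footprint overlap, Jensen-Shannon divergence of the
normalized footprints) and three temporal (absolute log-SNR difference,
absolute decay-rate difference, and a correlation score routed through a
connecting recording that spans the session boundary).

Distance-type metrics (smaller = more similar): centroid_dist, js_div, snr,
decay.  Similarity-type (larger = more similar): overlap, link_corr.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, medfilt

from .io import LinkExtraction, SessionExtraction

#: metric name -> direction ("distance" | "similarity")
METRIC_DIRECTIONS = {
    "centroid_dist": "distance",
    "overlap": "similarity",
    "js_div": "distance",
    "snr": "distance",
    "decay": "distance",
    "link_corr": "similarity",
}

SNR_CAP = 1e6  # upper bound on SNR so noiseless traces stay finite

_MAD_TO_SD = 1.4826  # Gaussian-consistent scale of the median absolute deviation


class DegenerateInputError(ValueError):
    """Raised on inputs with no usable mass/variance (e.g. all-zero footprint)."""


# ---------------------------------------------------------------------------
# spatial metrics


def centroid(footprint: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted mean pixel coordinate (row, col) of a footprint.

    The footprint is normalized to unit mass before weighting, so the result
    is a true pixel coordinate.
    """
    fp = np.asarray(footprint, dtype=float)
    mass = fp.sum()
    if mass <= 0:
        raise DegenerateInputError("footprint has no positive mass")
    rows, cols = np.indices(fp.shape)
    w = fp / mass
    return float((w * rows).sum()), float((w * cols).sum())


def centroid_distance(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Euclidean distance (pixels) between two footprint centroids."""
    ca = centroid(fp_a)
    cb = centroid(fp_b)
    return float(np.hypot(ca[0] - cb[0], ca[1] - cb[1]))


def spatial_overlap(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Cosine similarity of the binarized footprint supports, in [0, 1]."""
    a = (np.ravel(fp_a) > 0).astype(float)
    b = (np.ravel(fp_b) > 0).astype(float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateInputError("footprint with empty support")
    return float(np.dot(a, b) / (na * nb))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2, in bits) of two nonnegative maps.

    Inputs are normalized to probability distributions; 0*log(0) = 0.
    Bounded by 1 bit.
    """
    p = np.ravel(np.asarray(p, dtype=float))
    q = np.ravel(np.asarray(q, dtype=float))
    if p.sum() <= 0 or q.sum() <= 0:
        raise DegenerateInputError("zero-mass distribution")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


# ---------------------------------------------------------------------------
# temporal metrics


def _robust_noise_sd(residual: np.ndarray) -> float:
    med = np.median(residual)
    return _MAD_TO_SD * float(np.median(np.abs(residual - med)))


def snr_of_trace(trace: np.ndarray, detrend_window: int = 15) -> float | None:
    """Signal-to-noise ratio Var(signal)/Var(noise) of a fluorescence trace.

    The signal estimate is a running median (window ``detrend_window``
    frames); the noise variance is the squared robust (MAD-based) spread of
    the residual.  Capped at ``SNR_CAP``; returns None for a constant trace.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < detrend_window or np.ptp(trace) == 0:
        return None
    signal = medfilt(trace, kernel_size=detrend_window)
    # the filter absorbs ~pi/(2k) of the noise variance; undo that bias
    correction = np.sqrt(max(1.0 - np.pi / (2.0 * detrend_window), 0.5))
    noise_sd = _robust_noise_sd(trace - signal) / correction
    sig_var = float(np.var(signal))
    if sig_var == 0:
        return None
    if noise_sd == 0:
        return SNR_CAP
    return float(min(sig_var / noise_sd**2, SNR_CAP))


def snr_similarity(snr1: float, snr2: float) -> float:
    """Absolute difference of log SNRs (natural log)."""
    if snr1 <= 0 or snr2 <= 0:
        raise ValueError("SNR values must be positive")
    return abs(float(np.log(snr1) - np.log(snr2)))


def detect_peaks(
    trace: np.ndarray,
    noise_factor: float = 3.0,
    min_separation: int = 10,
) -> np.ndarray:
    """Indices of transient peaks: local maxima above ``noise_factor`` x the
    robust noise level, at least ``min_separation`` frames apart."""
    trace = np.asarray(trace, dtype=float)
    signal = medfilt(trace, kernel_size=15) if trace.size >= 15 else trace
    noise_sd = _robust_noise_sd(trace - signal)
    height = noise_factor * noise_sd if noise_sd > 0 else 0.0
    peaks, _ = find_peaks(trace, height=height if height > 0 else None,
                          distance=min_separation)
    return peaks


def estimate_decay_rate(
    trace: np.ndarray,
    fit_frames: int = 30,
    min_peaks: int = 3,
) -> float | None:
    """Decay constant tau (timebins) of the average calcium transient.

    Peaks are detected, each post-peak window is normalized by its peak
    height, windows are averaged, and exp(-t/tau) is fit by least squares on
    the log of the averaged transient.  Returns None when fewer than
    ``min_peaks`` peaks are found (the metric is then unavailable).
    """
    trace = np.asarray(trace, dtype=float)
    peaks = detect_peaks(trace)
    peaks = peaks[trace[peaks] > 0]
    if len(peaks) < min_peaks:
        return None
    windows = []
    for p in peaks:
        w = trace[p: p + fit_frames + 1]
        norm = np.full(fit_frames + 1, np.nan)
        norm[: len(w)] = w / trace[p]
        windows.append(norm)
    avg = np.nanmean(np.asarray(windows), axis=0)
    t = np.arange(fit_frames + 1, dtype=float)
    good = np.isfinite(avg) & (avg > 0)
    if good.sum() < 3:
        return None
    slope, _ = np.polyfit(t[good], np.log(avg[good]), 1)
    if slope >= 0:
        return None
    return float(-1.0 / slope)


def decay_similarity(dec1: float | None, dec2: float | None) -> float | None:
    """Absolute difference of decay constants; None if either is unavailable."""
    if dec1 is None or dec2 is None:
        return None
    return abs(float(dec1) - float(dec2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _active_in_half(half_trace: np.ndarray) -> bool:
    return len(detect_peaks(half_trace)) > 0


def link_correlation(
    i: int,
    j: int,
    session_a: SessionExtraction,
    session_b: SessionExtraction,
    link: LinkExtraction,
    neighbor_radius: float,
) -> float | None:
    """Correlation similarity between neuron ``i`` of session A and ``j`` of
    session B, routed through the connecting recording.

    Candidate connecting neurons are those of the link extraction whose
    centroids lie within ``neighbor_radius`` of both footprints; connecting
    neurons active in exactly one half of the link recording are excluded.
    The score is the best, over eligible connecting neurons N_c, of the mean
    of corr(tail of i, first half of N_c) and corr(second half of N_c,
    head of j).  None when no eligible connecting neuron exists.
    """
    n = link.n_frames_each_side
    if session_a.n_frames < n or session_b.n_frames < n:
        raise ValueError("link halves longer than session tails/heads")
    tail = session_a.traces[i, -n:]
    head = session_b.traces[j, :n]
    ca = centroid(session_a.footprint_image(i))
    cb = centroid(session_b.footprint_image(j))
    best = None
    for c in range(link.extraction.n_neurons):
        cc = centroid(link.extraction.footprint_image(c))
        if np.hypot(cc[0] - ca[0], cc[1] - ca[1]) > neighbor_radius:
            continue
        if np.hypot(cc[0] - cb[0], cc[1] - cb[1]) > neighbor_radius:
            continue
        first = link.first_half(c)
        second = link.second_half(c)
        active_first = _active_in_half(first)
        active_second = _active_in_half(second)
        if active_first != active_second:  # active in exactly one half
            continue
        score = 0.5 * (_pearson(tail, first) + _pearson(second, head))
        if best is None or score > best:
            best = score
    return best


# ---------------------------------------------------------------------------
# candidate pairs


@dataclasses.dataclass
class CandidatePairSet:
    """Neuron pairs of two sessions that pass the spatial candidate filter:
    centroid distance <= max_dist and non-zero binarized overlap."""

    pairs: list[tuple[int, int]]
    max_dist: float


def candidate_pairs(
    session_a: SessionExtraction,
    session_b: SessionExtraction,
    max_dist: float,
) -> CandidatePairSet:
    """All (i, j) with centroid distance <= ``max_dist`` and overlapping
    binarized footprints.  Sessions are assumed globally registered."""
    cents_a = [centroid(session_a.footprint_image(i)) for i in range(session_a.n_neurons)]
    cents_b = [centroid(session_b.footprint_image(j)) for j in range(session_b.n_neurons)]
    supp_a = session_a.footprints > 0
    supp_b = session_b.footprints > 0
    pairs = []
    for i, ca in enumerate(cents_a):
        for j, cb in enumerate(cents_b):
            if np.hypot(ca[0] - cb[0], ca[1] - cb[1]) > max_dist:
                continue
            if not np.any(supp_a[:, i] & supp_b[:, j]):
                continue
            pairs.append((i, j))
    return CandidatePairSet(pairs=pairs, max_dist=max_dist)


def pair_metric_values(
    session_a: SessionExtraction,
    session_b: SessionExtraction,
    pairs: Sequence[tuple[int, int]],
    link: LinkExtraction | None = None,
    neighbor_radius: float | None = None,
    max_dist: float | None = None,
) -> dict[str, list[float | None]]:
    """Evaluate all six metrics for the given candidate pairs.

    Returns a dict metric-name -> list aligned with ``pairs``; None marks a
    pair where the metric is unavailable (failed decay fit, no connecting
    neuron, or no link recording supplied).
    """
    if neighbor_radius is None:
        neighbor_radius = max_dist if max_dist is not None else np.inf
    link_cache = None
    if link is not None:
        cents_a = np.array([centroid(session_a.footprint_image(i))
                            for i in range(session_a.n_neurons)])
        cents_b = np.array([centroid(session_b.footprint_image(j))
                            for j in range(session_b.n_neurons)])
        n_link = link.extraction.n_neurons
        cents_l = np.array([centroid(link.extraction.footprint_image(c))
                            for c in range(n_link)]).reshape(n_link, 2)
        eligible = np.array([
            _active_in_half(link.first_half(c)) == _active_in_half(link.second_half(c))
            for c in range(n_link)
        ], dtype=bool)
        link_cache = (cents_a, cents_b, cents_l, eligible)
    snrs_a = [snr_of_trace(session_a.traces[i]) for i in range(session_a.n_neurons)]
    snrs_b = [snr_of_trace(session_b.traces[j]) for j in range(session_b.n_neurons)]
    decs_a = [estimate_decay_rate(session_a.traces[i]) for i in range(session_a.n_neurons)]
    decs_b = [estimate_decay_rate(session_b.traces[j]) for j in range(session_b.n_neurons)]
    out: dict[str, list] = {name: [] for name in METRIC_DIRECTIONS}
    for i, j in pairs:
        fa = session_a.footprint_image(i)
        fb = session_b.footprint_image(j)
        out["centroid_dist"].append(centroid_distance(fa, fb))
        out["overlap"].append(spatial_overlap(fa, fb))
        out["js_div"].append(js_divergence(fa, fb))
        if snrs_a[i] is None or snrs_b[j] is None:
            out["snr"].append(None)
        else:
            out["snr"].append(snr_similarity(snrs_a[i], snrs_b[j]))
        out["decay"].append(decay_similarity(decs_a[i], decs_b[j]))
        if link is None:
            out["link_corr"].append(None)
        else:
            cents_a, cents_b, cents_l, eligible = link_cache
            near = (
                eligible
                & (np.hypot(*(cents_l - cents_a[i]).T) <= neighbor_radius)
                & (np.hypot(*(cents_l - cents_b[j]).T) <= neighbor_radius)
            )
            n = link.n_frames_each_side
            tail = session_a.traces[i, -n:]
            head = session_b.traces[j, :n]
            best = None
            for c in np.flatnonzero(near):
                score = 0.5 * (
                    _pearson(tail, link.first_half(c))
                    + _pearson(link.second_half(c), head)
                )
                if best is None or score > best:
                    best = score
            out["link_corr"].append(best)
    return out
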