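"""Synthetic multi-session calcium-recording generator with ground truth.

Recordings are built from first principles: neuron footprints are 2-D
Gaussian intensity profiles (diagonal covariance, width 20-25 pixels,
truncated at 1% of peak), spike trains are Bernoulli per timebin (p = 0.01)
convolved with the double-exponential calcium kernel
``g(t) = exp(-t / tau_d) - exp(-t / tau_r)`` (fall 6 timebins, rise 1), and
background comes from wide Gaussian blobs and blood-vessel-like cubic
curves blurred with a width-3 Gaussian, each fluctuating as a random walk.

Four dataset styles reproduce distinct tracking difficulties:

* ``gaussian`` — footprints static across sessions, 256 x 256 FOV;
* ``nonrigid_1p`` — every footprint warped in place per session by an
  individual non-rigid deformation (centroid displacement < 2 px);
* ``nonrigid_2p`` — the non-rigid style with footprints folded into rings
  and salt-and-pepper movie noise;
* ``individual_shift`` — footprints independently translated by 5-7 px in
  later sessions, 100 x 100 FOV, no background sources.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import MISSING, CellRegister, LinkExtraction, SessionExtraction

STYLES = ("gaussian", "nonrigid_1p", "nonrigid_2p", "individual_shift")

#: Gaussian intensity falls to 1% of peak at this many sigma from center
_WIDTH_SIGMA = 2.0 * np.sqrt(2.0 * np.log(100.0))  # support diameter = width


class PlacementError(RuntimeError):
    """Field of view too small to place the requested neurons."""


@dataclasses.dataclass
class SimulationConfig:
    fov_shape: tuple[int, int] = (256, 256)
    n_neurons: int = 50
    n_sessions: int = 2
    frames_per_session: int = 2000
    footprint_width: tuple[float, float] = (20.0, 25.0)
    spike_prob: float = 0.01
    tau_d: float = 6.0
    tau_r: float = 1.0
    n_background: int = 23
    noise: str = "gaussian"  # 'gaussian' | 'salt_pepper' | 'none'
    noise_level: float = 0.02
    transform: str = "none"  # 'none' | 'nonrigid' | 'ring_nonrigid' | 'individual_shift'
    shift_range: tuple[float, float] = (5.0, 7.0)
    min_center_spacing: float = 8.0
    background_sigma_factor: float = 3.0  # local-background sigma / neuron sigma
    link_frames: int | None = None  # None -> min(1000, T // 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.spike_prob < 1.0):
            raise ValueError("spike_prob must lie in [0, 1)")
        if not (self.tau_d > self.tau_r > 0):
            raise ValueError("require tau_d > tau_r > 0")
        for name in ("n_neurons", "n_sessions", "frames_per_session"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def style_config(style: str, **overrides) -> SimulationConfig:
    """Per-style defaults matching the four dataset definitions."""
    if style == "gaussian":
        base = dict(fov_shape=(256, 256), n_neurons=50, n_sessions=4,
                    frames_per_session=2000, transform="none", noise="gaussian")
    elif style == "nonrigid_1p":
        base = dict(fov_shape=(256, 256), n_neurons=50, n_sessions=4,
                    frames_per_session=2000, transform="nonrigid", noise="gaussian")
    elif style == "nonrigid_2p":
        base = dict(fov_shape=(256, 256), n_neurons=50, n_sessions=4,
                    frames_per_session=2000, transform="ring_nonrigid",
                    noise="salt_pepper")
    elif style == "individual_shift":
        base = dict(fov_shape=(100, 100), n_neurons=50, n_sessions=2,
                    frames_per_session=3000, transform="individual_shift",
                    noise="none", n_background=0)
    else:
        raise ValueError(f"unknown style {style!r}; choose from {STYLES}")
    base.update(overrides)
    return SimulationConfig(**base)


@dataclasses.dataclass
class GroundTruth:
    """Per-session true footprints/traces and the true cell register."""

    footprints: list[np.ndarray]  # one (d, K) matrix per session
    traces: list[np.ndarray]  # one (K, T) matrix per session
    register: CellRegister
    config: SimulationConfig
    centers: np.ndarray  # (K, 2) base footprint centers (row, col)


# ---------------------------------------------------------------------------
# footprints


def _gaussian_footprint(fov: tuple[int, int], center, sigma) -> np.ndarray:
    rows, cols = np.indices(fov)
    fp = np.exp(
        -0.5 * (((rows - center[0]) / sigma[0]) ** 2 + ((cols - center[1]) / sigma[1]) ** 2)
    )
    fp[fp < 0.01] = 0.0  # truncate support at 1% of peak -> width = diameter
    return fp


def simulate_footprints(config: SimulationConfig, rng=None) -> np.ndarray:
    """Place ``n_neurons`` Gaussian footprints, returning a (d, K) matrix.

    Widths (support diameter at 1% of peak) are uniform in
    ``footprint_width``; centers are rejection-sampled with a minimal
    spacing so no two neurons coincide completely.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    h, w = config.fov_shape
    margin = config.footprint_width[1] / 2.0
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("field of view smaller than one footprint")
    centers: list[tuple[float, float]] = []
    max_attempts = 2000 * config.n_neurons
    attempts = 0
    while len(centers) < config.n_neurons:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {config.n_neurons} neurons with spacing "
                f"{config.min_center_spacing} in a {h}x{w} FOV"
            )
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all(np.hypot(c[0] - r, c[1] - q) >= config.min_center_spacing
               for r, q in centers):
            centers.append(c)
    cols = []
    for c in centers:
        width = rng.uniform(*config.footprint_width)
        # mild ellipticity: per-axis width within the configured band
        wr = np.clip(width + rng.uniform(-1.0, 1.0), *config.footprint_width)
        wc = np.clip(width + rng.uniform(-1.0, 1.0), *config.footprint_width)
        sigma = (wr / _WIDTH_SIGMA, wc / _WIDTH_SIGMA)
        cols.append(_gaussian_footprint(config.fov_shape, c, sigma).ravel())
    return np.stack(cols, axis=1), np.asarray(centers)


# ---------------------------------------------------------------------------
# traces


def calcium_kernel(tau_d: float, tau_r: float, length: int | None = None) -> np.ndarray:
    """Double-exponential kernel g(t) = exp(-t/tau_d) - exp(-t/tau_r)."""
    if length is None:
        length = int(np.ceil(25 * tau_d))  # tail below 1e-10 of peak
    t = np.arange(length, dtype=float)
    return np.exp(-t / tau_d) - np.exp(-t / tau_r)


def simulate_traces(
    config: SimulationConfig,
    n_frames: int | None = None,
    rng=None,
    spikes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli spike trains convolved with the calcium kernel.

    Returns ``(spikes, traces)``, both of shape (K, T); traces are
    nonnegative.  A spike matrix may be injected directly (``spikes``),
    bypassing the Bernoulli draw.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t = n_frames or config.frames_per_session
    if spikes is None:
        spikes = (rng.random((config.n_neurons, t)) < config.spike_prob).astype(float)
    else:
        spikes = np.atleast_2d(np.asarray(spikes, dtype=float))
        t = spikes.shape[1]
    kernel = calcium_kernel(config.tau_d, config.tau_r)
    traces = np.stack(
        [np.convolve(row, kernel)[:t] for row in spikes]
    )
    return spikes, np.clip(traces, 0.0, None)


# ---------------------------------------------------------------------------
# background


def simulate_background(
    config: SimulationConfig, n_frames: int | None = None, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Background sources: wide Gaussian blobs and blurred cubic blood
    vessels, each with random-walk temporal weights.

    Returns ``(footprints (d, B), weights (B, T))``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t = n_frames or config.frames_per_session
    h, w = config.fov_shape
    neuron_sigma = np.mean(config.footprint_width) / _WIDTH_SIGMA
    cols = []
    for b in range(config.n_background):
        if b % 2 == 0:  # local background blob
            sigma = config.background_sigma_factor * neuron_sigma
            center = (rng.uniform(0, h), rng.uniform(0, w))
            fp = _gaussian_footprint((h, w), center, (sigma, sigma))
        else:  # blood vessel: cubic curve blurred by a width-3 Gaussian
            x = np.arange(w, dtype=float)
            coeff = rng.normal(0.0, [h / 2, 1.0, 4.0 / w, 8.0 / w**2])
            y = h / 2 + coeff[0] / 2 + coeff[1] * (x - w / 2) \
                + coeff[2] * (x - w / 2) ** 2 + coeff[3] * (x - w / 2) ** 3
            img = np.zeros((h, w))
            yi = np.round(y).astype(int)
            ok = (yi >= 0) & (yi < h)
            img[yi[ok], x.astype(int)[ok]] = 1.0
            fp = ndimage.gaussian_filter(img, sigma=3.0)
        cols.append(fp.ravel())
    if not cols:
        return np.zeros((h * w, 0)), np.zeros((0, t))
    walks = np.cumsum(rng.normal(0.0, 1.0, size=(config.n_background, t)), axis=1)
    walks -= walks.min(axis=1, keepdims=True)  # keep fluorescence nonnegative
    return np.stack(cols, axis=1), 0.1 * walks


# ---------------------------------------------------------------------------
# footprint transforms


def apply_ring_transform(footprint: np.ndarray) -> np.ndarray:
    """Fold a footprint into a ring: scale intensities to [0, 1], then
    replace every value v > 0.5 by 1 - v (the center becomes a trough)."""
    fp = np.asarray(footprint, dtype=float)
    peak = fp.max()
    if peak <= 0:
        raise ValueError("cannot ring-transform a zero footprint")
    v = fp / peak
    return np.where(v > 0.5, 1.0 - v, v)


def apply_nonrigid_warp(
    footprint_img: np.ndarray,
    rng,
    amplitude: float = 1.5,
    n_control: int = 3,
    max_centroid_shift: float = 2.0,
) -> np.ndarray:
    """Warp one footprint in place with a smooth random displacement field.

    The field is a sum of ``n_control`` Gaussian bumps with random vectors;
    its amplitude is rescaled if necessary so the centroid moves less than
    ``max_centroid_shift`` pixels, and the warped footprint is renormalized
    to its original mass.
    """
    fp = np.asarray(footprint_img, dtype=float)
    support = np.argwhere(fp > 0)
    if len(support) == 0:
        return fp.copy()
    lo = support.min(axis=0)
    hi = support.max(axis=0)
    scale = max((hi - lo).max() / 2.0, 2.0)
    rows, cols = np.indices(fp.shape)
    disp_r = np.zeros(fp.shape)
    disp_c = np.zeros(fp.shape)
    for _ in range(n_control):
        c = lo + rng.random(2) * (hi - lo)
        v = rng.normal(0.0, amplitude, size=2)
        bump = np.exp(-(((rows - c[0]) ** 2 + (cols - c[1]) ** 2) / (2 * scale**2)))
        disp_r += v[0] * bump
        disp_c += v[1] * bump

    def _warp(fr, fc):
        out = ndimage.map_coordinates(fp, [rows - fr, cols - fc], order=1, mode="constant")
        mass = out.sum()
        if mass > 0:
            out *= fp.sum() / mass
        return out

    warped = _warp(disp_r, disp_c)
    shift = _centroid_shift(fp, warped)
    if shift >= max_centroid_shift and shift > 0:
        factor = 0.9 * max_centroid_shift / shift
        warped = _warp(disp_r * factor, disp_c * factor)
    return warped


def _centroid_shift(a: np.ndarray, b: np.ndarray) -> float:
    def cen(x):
        rows, cols = np.indices(x.shape)
        m = x.sum()
        return np.array([(x * rows).sum() / m, (x * cols).sum() / m])

    return float(np.linalg.norm(cen(a) - cen(b)))


def apply_individual_shift(
    footprints: np.ndarray,
    fov_shape: tuple[int, int],
    shift_range: tuple[float, float],
    rng,
    max_retries: int = 50,
) -> np.ndarray:
    """Translate each footprint independently by a random displacement of
    magnitude in ``shift_range`` (random direction).  Shifts that would push
    the support outside the field of view are re-drawn."""
    h, w = fov_shape
    out = np.empty_like(footprints)
    for k in range(footprints.shape[1]):
        img = footprints[:, k].reshape(fov_shape)
        support = np.argwhere(img > 0)
        lo = support.min(axis=0)
        hi = support.max(axis=0)
        for _attempt in range(max_retries):
            mag = rng.uniform(*shift_range)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            dr, dc = mag * np.sin(ang), mag * np.cos(ang)
            if (lo[0] + dr >= 0 and hi[0] + dr <= h - 1
                    and lo[1] + dc >= 0 and hi[1] + dc <= w - 1):
                break
        else:
            dr = dc = 0.0
        shifted = ndimage.shift(img, (dr, dc), order=1, mode="constant")
        shifted[shifted < 0] = 0.0
        out[:, k] = shifted.ravel()
    return out


# ---------------------------------------------------------------------------
# dataset assembly


def _transform_session(
    base_fp: np.ndarray, config: SimulationConfig, session: int, rng
) -> np.ndarray:
    fov = config.fov_shape
    if config.transform == "none":
        return base_fp.copy()
    if config.transform == "individual_shift":
        if session == 0:
            return base_fp.copy()
        return apply_individual_shift(base_fp, fov, config.shift_range, rng)
    if config.transform in ("nonrigid", "ring_nonrigid"):
        cols = []
        for k in range(base_fp.shape[1]):
            img = base_fp[:, k].reshape(fov)
            warped = apply_nonrigid_warp(img, rng)
            if config.transform == "ring_nonrigid":
                warped = apply_ring_transform(warped)
            cols.append(warped.ravel())
        return np.stack(cols, axis=1)
    raise ValueError(f"unknown transform {config.transform!r}")


def make_dataset(
    style: str,
    config: SimulationConfig | None = None,
    render_movies: bool = False,
):
    """Generate a full multi-session dataset with ground truth.

    Returns ``(sessions, links, truth, movies)``: per-session extractions
    built from the true footprints and traces, connecting-recording
    extractions for each consecutive session pair (their traces are the
    concatenated boundary frames of the true traces), the ground truth, and
    rendered movies (``footprints @ traces + background + noise``) when
    ``render_movies`` is set, else None.
    """
    config = config if config is not None else style_config(style)
    rng = np.random.default_rng(config.seed)
    base_fp, centers = simulate_footprints(config, rng)
    k = config.n_neurons
    t = config.frames_per_session

    session_fps = [_transform_session(base_fp, config, s, rng)
                   for s in range(config.n_sessions)]
    session_traces = [simulate_traces(config, t, rng)[1]
                      for _ in range(config.n_sessions)]

    session_ids = [f"session{s}" for s in range(config.n_sessions)]
    sessions = [
        SessionExtraction(
            footprints=session_fps[s], traces=session_traces[s],
            fov_shape=config.fov_shape, session_id=session_ids[s],
        )
        for s in range(config.n_sessions)
    ]

    n_link = config.link_frames or min(1000, t // 2)
    links = []
    for s in range(config.n_sessions - 1):
        link_traces = np.concatenate(
            [session_traces[s][:, -n_link:], session_traces[s + 1][:, :n_link]],
            axis=1,
        )
        link_fp = 0.5 * (session_fps[s] + session_fps[s + 1])
        links.append(
            LinkExtraction(
                extraction=SessionExtraction(
                    footprints=link_fp, traces=link_traces,
                    fov_shape=config.fov_shape,
                    session_id=f"link{s}_{s + 1}",
                ),
                n_frames_each_side=n_link,
                left_session_id=session_ids[s],
                right_session_id=session_ids[s + 1],
            )
        )

    table = pd.DataFrame({sid: np.arange(k) for sid in session_ids})
    truth = GroundTruth(
        footprints=session_fps, traces=session_traces,
        register=CellRegister(table), config=config, centers=centers,
    )

    movies = None
    if render_movies:
        movies = [render_movie(sessions[s], config, rng)
                  for s in range(config.n_sessions)]
    return sessions, links, truth, movies


def render_movie(
    session: SessionExtraction, config: SimulationConfig, rng=None
) -> np.ndarray:
    """Render frames ``A @ C + background + noise`` as a (T, H, W) stack."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t = session.n_frames
    movie = session.footprints @ session.traces  # (d, T)
    bg_fp, bg_w = simulate_background(config, t, rng)
    if bg_fp.shape[1]:
        movie = movie + bg_fp @ bg_w
    movie = movie.T.reshape(t, *session.fov_shape)
    if config.noise == "gaussian" and config.noise_level > 0:
        movie = movie + rng.normal(0.0, config.noise_level, movie.shape)
    elif config.noise == "salt_pepper" and config.noise_level > 0:
        flips = rng.random(movie.shape) < config.noise_level
        salt = rng.random(movie.shape) < 0.5
        hi = movie.max() if movie.max() > 0 else 1.0
        movie = np.where(flips, np.where(salt, hi, 0.0), movie)
    return movie.astype(np.float32)


def write_movie(movie: np.ndarray, path) -> None:
    """Write a rendered movie as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, movie, photometric="minisblack")


# ---------------------------------------------------------------------------
# extraction imperfections


def derive_extractions(
    truth: GroundTruth,
    dropout_rate: float = 0.0,
    false_discovery_rate: float = 0.0,
    trace_noise: float = 0.0,
    footprint_jitter: float = 0.0,
    shuffle: bool = True,
    seed: int = 0,
):
    """Emulate imperfect source extraction on top of the ground truth.

    Per session: each true neuron is dropped with ``dropout_rate``; spurious
    neurons are injected so they make up roughly ``false_discovery_rate`` of
    the output; traces get additive Gaussian noise (sd ``trace_noise``);
    footprints are translated by N(0, ``footprint_jitter``) pixels.

    Returns ``(sessions, register)`` where the register maps each surviving
    true neuron to its index in every session's extraction (injected neurons
    appear in no register row).
    """
    for name, rate in (("dropout_rate", dropout_rate),
                       ("false_discovery_rate", false_discovery_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    config = truth.config
    k = config.n_neurons
    sessions = []
    columns = {}
    for s in range(len(truth.footprints)):
        keep = rng.random(k) >= dropout_rate
        fp = truth.footprints[s][:, keep]
        tr = truth.traces[s][keep]
        n_kept = int(keep.sum())
        n_false = int(round(n_kept * false_discovery_rate / (1 - false_discovery_rate))) \
            if false_discovery_rate > 0 else 0
        if n_false:
            sub = dataclasses.replace(
                config, n_neurons=n_false, seed=int(rng.integers(2**31))
            )
            false_fp, _ = simulate_footprints(sub, rng)
            _, false_tr = simulate_traces(sub, tr.shape[1] or config.frames_per_session, rng)
            fp = np.concatenate([fp, false_fp], axis=1)
            tr = np.concatenate([tr, false_tr], axis=0)
        if trace_noise > 0:
            tr = np.clip(tr + rng.normal(0.0, trace_noise, tr.shape), 0.0, None)
        if footprint_jitter > 0:
            jittered = np.empty_like(fp)
            for c in range(fp.shape[1]):
                img = fp[:, c].reshape(config.fov_shape)
                dr, dc = rng.normal(0.0, footprint_jitter, 2)
                out = ndimage.shift(img, (dr, dc), order=1, mode="constant")
                jittered[:, c] = np.clip(out, 0.0, None).ravel()
            fp = jittered
        # shuffle output order so extraction indices carry no information
        perm = rng.permutation(fp.shape[1]) if shuffle else np.arange(fp.shape[1])
        fp = fp[:, perm]
        tr = tr[perm]
        inv = np.argsort(perm)
        col = np.full(k, MISSING)
        col[keep] = inv[:n_kept]
        columns[truth.register.sessions[s]] = col
        sessions.append(
            SessionExtraction(
                footprints=fp, traces=tr, fov_shape=config.fov_shape,
                session_id=truth.register.sessions[s],
            )
        )
    table = pd.DataFrame(columns)
    present = (table.to_numpy() != MISSING).any(axis=1)
    register = CellRegister(table[present])
    return sessions, register
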