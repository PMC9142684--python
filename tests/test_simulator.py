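import numpy as np
import pytest

from neurotrack import simulator
from neurotrack.io import MISSING
from neurotrack.simulator import (
    SimulationConfig,
    apply_individual_shift,
    apply_nonrigid_warp,
    apply_ring_transform,
    make_dataset,
    simulate_background,
    simulate_footprints,
    simulate_traces,
    style_config,
)


# ---------------------------------------------------------------------------
# footprints


def test_footprint_widths_and_determinism():
    cfg = SimulationConfig(fov_shape=(120, 120), n_neurons=12, seed=4)
    fps, centers = simulate_footprints(cfg)
    assert fps.shape == (120 * 120, 12)
    for k in range(12):
        img = fps[:, k].reshape(120, 120)
        assert img.min() >= 0 and img.max() > 0
        support = np.argwhere(img > 0)
        extent = (support.max(axis=0) - support.min(axis=0)).max() + 1
        # support diameter ~ footprint width (20-25 px), grid tolerance
        assert 17 <= extent <= 27
        # unimodal: the peak is unique and at the sampled center
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert np.hypot(peak[0] - centers[k, 0], peak[1] - centers[k, 1]) <= 1.0
    fps2, _ = simulate_footprints(SimulationConfig(fov_shape=(120, 120),
                                                   n_neurons=12, seed=4))
    np.testing.assert_array_equal(fps, fps2)


def test_footprint_center_spacing():
    cfg = SimulationConfig(fov_shape=(150, 150), n_neurons=30, seed=0)
    _, centers = simulate_footprints(cfg)
    d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).T)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= cfg.min_center_spacing


def test_footprint_placement_error_when_fov_too_small():
    with pytest.raises(simulator.PlacementError):
        simulate_footprints(SimulationConfig(fov_shape=(30, 30), n_neurons=50))


# ---------------------------------------------------------------------------
# traces


def test_spike_rate_within_binomial_bounds():
    cfg = SimulationConfig(n_neurons=40, frames_per_session=2000, seed=9)
    spikes, traces = simulate_traces(cfg)
    t = 2000
    expected = cfg.spike_prob * t
    sd = np.sqrt(t * cfg.spike_prob * (1 - cfg.spike_prob))
    mean_count = spikes.sum(axis=1).mean()
    assert abs(mean_count - expected) <= 3 * sd / np.sqrt(40)
    assert np.all(traces >= 0)


def test_zero_spike_prob_gives_silent_traces():
    cfg = SimulationConfig(n_neurons=5, frames_per_session=300, spike_prob=1e-12,
                           seed=0)
    cfg = SimulationConfig(n_neurons=5, frames_per_session=300, spike_prob=0.0,
                           seed=0)
    _, traces = simulate_traces(cfg)
    assert not traces.any()


def test_single_spike_matches_kernel_closed_form():
    cfg = SimulationConfig(n_neurons=1, frames_per_session=200, seed=0)
    spikes = np.zeros((1, 200))
    t0 = 50
    spikes[0, t0] = 1.0
    _, traces = simulate_traces(cfg, spikes=spikes)
    t = np.arange(200 - t0, dtype=float)
    expected = np.exp(-t / 6.0) - np.exp(-t / 1.0)  # tau_d = 6, tau_r = 1
    np.testing.assert_allclose(traces[0, t0:], np.clip(expected, 0, None),
                               atol=1e-12)
    assert traces[0, :t0].sum() == 0
    assert np.argmax(traces[0]) > t0  # peak strictly after the spike


# ---------------------------------------------------------------------------
# background


def test_background_counts():
    cfg = SimulationConfig(n_background=0, seed=0)
    fp, w = simulate_background(cfg, n_frames=50)
    assert fp.shape[1] == 0 and w.shape[0] == 0
    cfg = SimulationConfig(fov_shape=(60, 60), n_background=23, seed=0)
    fp, w = simulate_background(cfg, n_frames=50)
    assert fp.shape[1] == 23 and w.shape == (23, 50)


def test_background_random_walk_variance_grows_linearly():
    cfg = SimulationConfig(fov_shape=(30, 30), n_background=200, seed=2)
    _, w = simulate_background(cfg, n_frames=400)
    # variance of increments is stationary; cumulative variance across
    # sources grows ~ linearly in t (the random-walk signature)
    increments = np.diff(w, axis=1)
    var_inc = increments.var()
    walks = np.cumsum(increments, axis=1)
    late = walks[:, -1].var()
    assert late == pytest.approx(var_inc * (walks.shape[1]), rel=0.35)


# ---------------------------------------------------------------------------
# transforms


def test_ring_transform_folds_peak():
    fp = np.array([[0.2, 0.5], [0.8, 1.0]])
    out = apply_ring_transform(fp)
    assert out[1, 1] == 0.0  # peak (scaled 1.0) -> 0
    assert out[0, 0] == pytest.approx(0.2)  # <= 0.5 unchanged
    assert out[1, 0] == pytest.approx(0.2)  # 0.8 -> 1 - 0.8
    assert np.all(out <= 0.5 + 1e-12)
    with pytest.raises(ValueError):
        apply_ring_transform(np.zeros((2, 2)))


def test_ring_transform_keeps_subthreshold_values():
    fp = np.array([[0.5, 0.2], [0.3, 1.0]])
    out = apply_ring_transform(fp)
    # scaled values <= 0.5 pass through untouched; the peak folds to 0
    assert out[0, 0] == pytest.approx(0.5)
    assert out[0, 1] == pytest.approx(0.2)
    assert out[1, 0] == pytest.approx(0.3)
    assert out[1, 1] == 0.0


def test_individual_shift_magnitudes_and_identity():
    cfg = SimulationConfig(fov_shape=(100, 100), n_neurons=10, seed=5)
    fps, _ = simulate_footprints(cfg)
    rng = np.random.default_rng(5)
    shifted = apply_individual_shift(fps, (100, 100), (5.0, 7.0), rng)
    from neurotrack.metrics import centroid

    for k in range(10):
        a = fps[:, k].reshape(100, 100)
        b = shifted[:, k].reshape(100, 100)
        ca, cb = centroid(a), centroid(b)
        disp = np.hypot(ca[0] - cb[0], ca[1] - cb[1])
        assert 4.5 <= disp <= 7.5
    same = apply_individual_shift(fps, (100, 100), (5.0, 7.0),
                                  np.random.default_rng(5))
    np.testing.assert_array_equal(shifted, same)
    ident = apply_individual_shift(fps, (100, 100), (0.0, 0.0),
                                   np.random.default_rng(0))
    np.testing.assert_allclose(ident, fps, atol=1e-12)


def test_nonrigid_warp_bounds_and_identity():
    cfg = SimulationConfig(fov_shape=(80, 80), n_neurons=6, seed=8)
    fps, _ = simulate_footprints(cfg)
    from neurotrack.metrics import centroid

    for k in range(6):
        img = fps[:, k].reshape(80, 80)
        rng = np.random.default_rng(k)
        warped = apply_nonrigid_warp(img, rng)
        ca, cb = centroid(img), centroid(warped)
        assert np.hypot(ca[0] - cb[0], ca[1] - cb[1]) < 2.0
        assert warped.sum() == pytest.approx(img.sum(), rel=0.05)
        rng2 = np.random.default_rng(k)
        np.testing.assert_array_equal(warped, apply_nonrigid_warp(img, rng2))
    zero = apply_nonrigid_warp(fps[:, 0].reshape(80, 80),
                               np.random.default_rng(0), amplitude=0.0)
    np.testing.assert_allclose(zero, fps[:, 0].reshape(80, 80), atol=1e-12)


# ---------------------------------------------------------------------------
# datasets


def test_individual_shift_dataset_layout():
    cfg = style_config("individual_shift", n_neurons=10, frames_per_session=400,
                       seed=3)
    assert cfg.fov_shape == (100, 100)
    assert cfg.n_background == 0
    sessions, links, truth, movies = make_dataset("individual_shift", cfg)
    assert len(sessions) == 2 and len(links) == 1
    assert movies is None
    n_link = links[0].n_frames_each_side
    np.testing.assert_array_equal(
        links[0].extraction.traces[:, :n_link], truth.traces[0][:, -n_link:]
    )
    np.testing.assert_array_equal(
        links[0].extraction.traces[:, n_link:], truth.traces[1][:, :n_link]
    )
    # ground-truth register is the identity over surviving neurons
    assert truth.register.table.shape == (10, 2)


def test_dataset_determinism():
    cfg = style_config("nonrigid_1p", n_neurons=6, n_sessions=2,
                       frames_per_session=200, seed=12)
    a = make_dataset("nonrigid_1p", cfg)
    b = make_dataset("nonrigid_1p", cfg)
    for sa, sb in zip(a[0], b[0]):
        np.testing.assert_array_equal(sa.footprints, sb.footprints)
        np.testing.assert_array_equal(sa.traces, sb.traces)


def test_rendered_movie_is_product_plus_background():
    cfg = style_config("individual_shift", n_neurons=4, frames_per_session=50,
                       seed=1)
    sessions, _, _, movies = make_dataset("individual_shift", cfg,
                                          render_movies=True)
    # no background, no noise: the movie is exactly A @ C
    expected = (sessions[0].footprints @ sessions[0].traces).T.reshape(50, 100, 100)
    np.testing.assert_allclose(movies[0], expected.astype(np.float32), atol=1e-5)


def test_derive_extractions_identity_and_corruption():
    cfg = style_config("individual_shift", n_neurons=20, frames_per_session=300,
                       seed=6)
    _, _, truth, _ = make_dataset("individual_shift", cfg)
    clean, reg = simulator.derive_extractions(truth, shuffle=False, seed=0)
    for s in range(2):
        np.testing.assert_array_equal(clean[s].footprints, truth.footprints[s])
        np.testing.assert_array_equal(clean[s].traces, truth.traces[s])
    assert reg == truth.register

    corrupted, reg2 = simulator.derive_extractions(
        truth, dropout_rate=0.3, false_discovery_rate=0.2, seed=1
    )
    kept = (reg2.table.to_numpy() != MISSING).sum(axis=0)
    # ~30% dropped per session, within 3 binomial sd
    sd = np.sqrt(20 * 0.3 * 0.7)
    assert all(abs(20 - k - 6) <= 3 * sd for k in kept)
    # register rows are internally consistent: both sessions' entries point
    # at extracted traces belonging to the same underlying truth neuron
    def truth_id_of(session_idx, trace):
        matches = np.flatnonzero(
            np.all(np.isclose(truth.traces[session_idx], trace), axis=1)
        )
        assert len(matches) == 1
        return matches[0]

    tbl = reg2.table.to_numpy()
    for row in tbl:
        ids = [
            truth_id_of(s, corrupted[s].traces[row[s]])
            for s in range(2)
            if row[s] != MISSING
        ]
        assert len(set(ids)) == 1
    # injected false neurons are absent from the register
    for s, sess in enumerate(corrupted):
        col = reg2.table.iloc[:, s].to_numpy()
        assert sess.n_neurons > (col != MISSING).sum()
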