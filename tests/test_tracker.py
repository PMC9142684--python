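import numpy as np
import pytest

from neurotrack import simulator, tracker
from neurotrack.io import MISSING
from neurotrack.tracker import (
    ClusterAssignment,
    SAME_SESSION_SENTINEL,
    TrackerConfig,
    build_consensus_matrix,
    build_similarity_matrix,
    cluster_component,
    graph_components,
    initialize_clusters,
    partition_objective,
    perturb_weights,
    switch_swap_optimize,
)

from _oracles import (
    best_valid_partition_objective,
    bfs_components,
    random_small_component,
)


# ---------------------------------------------------------------------------
# similarity matrix


def _simple_pair_probs(p_by_metric, pairs=((0, 0),)):
    return {
        (0, 1): {
            "pairs": list(pairs),
            "probs": {m: [v] * len(pairs) for m, v in p_by_metric.items()},
        }
    }


def test_similarity_matrix_convexity_threshold_sentinel():
    names = ["a", "b", "c"]
    probs = _simple_pair_probs({"a": 0.8, "b": 0.8, "c": 0.8})
    sim = build_similarity_matrix(probs, [2, 1], np.array([0.2, 0.3, 0.5]),
                                  names, min_prob=0.5)
    assert sim.matrix[0, 2] == pytest.approx(0.8)  # convex combination
    assert sim.matrix[2, 0] == pytest.approx(0.8)  # symmetric
    assert sim.matrix[0, 1] == SAME_SESSION_SENTINEL  # same session
    assert sim.matrix[1, 2] == 0.0  # non-candidate

    low = _simple_pair_probs({"a": 0.55, "b": 0.55, "c": 0.55})
    sim2 = build_similarity_matrix(low, [2, 1], np.ones(3) / 3, names, min_prob=0.6)
    assert sim2.matrix[0, 2] == 0.0  # below min_prob -> zeroed


def test_similarity_matrix_weight_count_mismatch():
    with pytest.raises(ValueError):
        build_similarity_matrix(_simple_pair_probs({"a": 1.0}), [1, 1],
                                np.array([0.5, 0.5]), ["a"], 0.5)


def test_graph_components_match_bfs_oracle(rng):
    for _ in range(20):
        n_per = [3, 3, 2]
        n = sum(n_per)
        session_of = np.repeat(np.arange(3), n_per)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if session_of[i] != session_of[j] and rng.random() < 0.25:
                    mat[i, j] = mat[j, i] = rng.uniform(0.5, 1.0)
        mat[session_of[:, None] == session_of[None, :]] = SAME_SESSION_SENTINEL
        sim = tracker.SimilarityMatrix(
            matrix=mat, session_of=session_of,
            offsets=np.concatenate([[0], np.cumsum(n_per)[:-1]]),
        )
        got = [sorted(c.tolist()) for c in graph_components(sim)]
        adj = (mat > 0) & (session_of[:, None] != session_of[None, :])
        assert sorted(got) == sorted(bfs_components(adj))


# ---------------------------------------------------------------------------
# clustering


def test_initialize_two_neurons():
    s = np.array([[0.0, 0.9], [0.9, 0.0]])
    sessions = np.array([0, 1])
    merged = initialize_clusters(s, sessions, chain_prob=0.75)
    assert sorted(map(len, merged.clusters)) == [2]
    weak = np.array([[0.0, 0.5], [0.5, 0.0]])
    split = initialize_clusters(weak, sessions, chain_prob=0.75)
    assert sorted(map(len, split.clusters)) == [1, 1]


def test_initialization_is_session_valid(rng):
    for _ in range(30):
        s, sessions = random_small_component(rng)
        initialize_clusters(s, sessions, chain_prob=0.3).validate()


def test_switch_swap_fixed_point():
    s = np.array([
        [0.0, 0.9, 0.0, 0.0],
        [0.9, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.8],
        [0.0, 0.0, 0.8, 0.0],
    ])
    sessions = np.array([0, 1, 0, 1])
    optimal = ClusterAssignment(clusters=[{0, 1}, {2, 3}], sessions=sessions)
    out = switch_swap_optimize(optimal, s)
    assert sorted(map(sorted, out.clusters)) == [[0, 1], [2, 3]]


def test_switch_swap_attains_bruteforce_optimum(rng):
    for _ in range(50):
        s, sessions = random_small_component(rng)
        assignment = cluster_component(s, sessions, chain_prob=0.0, bias=0.0)
        got = partition_objective(s, assignment.clusters)
        opt = best_valid_partition_objective(s, sessions)
        assert got >= opt - 1e-9


def test_objective_monotone_across_accepted_moves(rng):
    """Hill-climb from a deliberately bad start never decreases the
    objective (bias excluded)."""
    s, sessions = random_small_component(rng, max_per_session=2)
    start = ClusterAssignment(clusters=[{i} for i in range(len(sessions))],
                              sessions=sessions)
    before = partition_objective(s, start.clusters)
    out = switch_swap_optimize(start, s, exact_refine_size=0, lookahead_size=0)
    assert partition_objective(s, out.clusters) >= before - 1e-9


def test_bias_prefers_growing_larger_cluster():
    # node 2 sits in a zero-similarity pair {2,3}; joining the pair {0,1}
    # has exactly zero objective gain (its similarities to both members
    # equal the pair's mean), as does ejecting it to a singleton.  Only the
    # bias distinguishes the tied moves: growth is rewarded, shrinking to a
    # singleton is penalized.
    s = np.zeros((4, 4))
    sessions = np.array([0, 1, 2, 0])
    s[0, 1] = s[1, 0] = 0.8
    s[0, 2] = s[2, 0] = 0.8
    s[1, 2] = s[2, 1] = 0.8
    start = ClusterAssignment(clusters=[{0, 1}, {2, 3}], sessions=sessions)
    unbiased = switch_swap_optimize(start, s, bias=0.0, chain_prob=0.0,
                                    exact_refine_size=0)
    assert sorted(map(len, unbiased.clusters)) == [2, 2]  # no strict gain
    biased = switch_swap_optimize(start, s, bias=0.05, chain_prob=0.0,
                                  exact_refine_size=0)
    triple = max(biased.clusters, key=len)
    assert sorted(triple) == [0, 1, 2]
    assert sorted(map(len, biased.clusters)) == [1, 3]


def test_chain_prob_split_and_monotone_max_size(rng):
    for _ in range(10):
        s, sessions = random_small_component(rng, n_sessions=4, max_per_session=2)
        sizes = []
        for chain in (0.0, 0.5, 0.9):
            out = cluster_component(s, sessions, chain_prob=chain, bias=0.0)
            for c in out.clusters:
                if len(c) >= 2:
                    assert tracker._cluster_mean(s, c) >= chain - 1e-9
            sizes.append(max(map(len, out.clusters)))
        # raising chain_prob never increases the maximum cluster size
        assert sizes[0] >= sizes[1] >= sizes[2]


# ---------------------------------------------------------------------------
# consensus


def test_perturb_weights_properties():
    base = np.full(6, 1 / 6)
    out = perturb_weights(base, n_samples=30, sd=0.12, seed=5)
    assert len(out) == 30
    np.testing.assert_allclose(out[0], base)
    for w in out:
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)
    again = perturb_weights(base, n_samples=30, sd=0.12, seed=5)
    for a, b in zip(out, again):
        np.testing.assert_array_equal(a, b)
    frozen = perturb_weights(base, n_samples=5, sd=0.0, seed=1)
    for w in frozen:
        np.testing.assert_allclose(w, base)


def test_consensus_matrix_fractions():
    sessions = np.array([0, 1, 2])
    c1 = ClusterAssignment(clusters=[{0, 1}, {2}], sessions=sessions)
    c2 = ClusterAssignment(clusters=[{0, 2}, {1}], sessions=sessions)
    consensus = build_consensus_matrix([c1, c2])
    assert consensus[0, 1] == pytest.approx(0.5)
    assert consensus[0, 2] == pytest.approx(0.5)
    assert consensus[1, 2] == pytest.approx(0.0)
    np.testing.assert_allclose(consensus, consensus.T)
    np.testing.assert_allclose(np.diag(consensus), 1.0)
    same = build_consensus_matrix([c1, c1])
    assert set(np.unique(same)) <= {0.0, 1.0}
    with pytest.raises(ValueError):
        build_consensus_matrix([])


# ---------------------------------------------------------------------------
# full pipeline


def _lenient_config(seed=7, **kw):
    kw.setdefault("min_prob", 0.5)
    kw.setdefault("chain_prob", 0.5)
    kw.setdefault("n_weight_samples", 10)
    return TrackerConfig(seed=seed, **kw)


def test_track_recovers_unmoved_ground_truth():
    cfg = simulator.style_config("individual_shift", transform="none",
                                 n_neurons=12, frames_per_session=600, seed=11)
    sessions, links, truth, _ = simulator.make_dataset("individual_shift", cfg)
    register = tracker.track(sessions, links, _lenient_config(seed=11))
    assert sorted(map(tuple, register.table.to_numpy().tolist())) == \
        sorted(map(tuple, truth.register.table.to_numpy().tolist()))


def test_track_register_is_session_valid_and_bounded(tiny_dataset):
    sessions, links, truth = tiny_dataset
    register = tracker.track(sessions, links, _lenient_config())
    tbl = register.table.to_numpy()
    n_sessions = tbl.shape[1]
    for col in range(n_sessions):
        present = tbl[:, col][tbl[:, col] != MISSING]
        assert len(np.unique(present)) == len(present)
    assert ((tbl != MISSING).sum(axis=1) <= n_sessions).all()
    assert np.all((register.scores >= 0) & (register.scores <= 1))


def test_track_deterministic_under_seed(tiny_dataset):
    sessions, links, _ = tiny_dataset
    r1 = tracker.track(sessions, links, _lenient_config(seed=3))
    r2 = tracker.track(sessions, links, _lenient_config(seed=3))
    assert r1 == r2


def test_track_deletion_propagates():
    cfg = simulator.style_config("individual_shift", transform="none",
                                 n_neurons=10, frames_per_session=600, seed=21)
    sessions, links, truth, _ = simulator.make_dataset("individual_shift", cfg)
    # delete neuron 0 from session 2 (and from the link's second half view)
    s2 = sessions[1]
    from neurotrack.io import SessionExtraction

    reduced = SessionExtraction(
        footprints=s2.footprints[:, 1:], traces=s2.traces[1:],
        fov_shape=s2.fov_shape, session_id=s2.session_id,
    )
    register = tracker.track([sessions[0], reduced], links, _lenient_config(seed=21))
    col0 = register.table.iloc[:, 0].to_numpy()
    col1 = register.table.iloc[:, 1].to_numpy()
    row = np.flatnonzero(col0 == 0)
    assert len(row) == 1 and col1[row[0]] == MISSING


def test_track_requires_two_sessions(tiny_dataset):
    sessions, links, _ = tiny_dataset
    with pytest.raises(ValueError):
        tracker.track(sessions[:1], None, _lenient_config())


def test_config_validation():
    with pytest.raises(ValueError):
        TrackerConfig(min_prob=1.5)
    with pytest.raises(ValueError):
        TrackerConfig(n_weight_samples=0)
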