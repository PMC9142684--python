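"""Multi-session cell tracking: similarity aggregation, switch/swap
clustering, weight-perturbation consensus, and cell-register assembly.

The tracker proceeds in four steps:

1. for every session pair, candidate neuron pairs are filtered spatially and
   each metric's values are converted into identification probabilities by a
   population model (``ident_models``);
2. per-metric probabilities are aggregated with a metric-weight vector into
   an ``n_cells x n_cells`` similarity matrix (entries below ``min_prob``
   zeroed; same-session pairs held at a -10000 sentinel);
3. each connected component of the base-weight similarity graph is clustered
   with a switch/swap hill-climb under the constraints that no cluster holds
   two neurons of one session and every multi-member cluster keeps mean
   pairwise similarity >= ``chain_prob``; the weight vector is randomly
   perturbed (N(0, 0.12), clipped, renormalized; 30 vectors in total) and
   the per-weight clusterings are combined into a co-clustering consensus
   matrix, which is clustered once more;
4. final clusters become rows of a cell register with per-row mean
   similarity scores.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from . import ident_models, metrics as _metrics
from .io import MISSING, CellRegister, LinkExtraction, SessionExtraction

logger = logging.getLogger(__name__)

SAME_SESSION_SENTINEL = -10_000.0
NEUTRAL_PROB = 0.5  # probability of a pair for an unavailable metric
_EPS = 1e-9

#: theoretical metric bounds used for density reflection
METRIC_BOUNDS = {
    "centroid_dist": (0.0, np.inf),
    "overlap": (0.0, 1.0),
    "js_div": (0.0, 1.0),
    "snr": (0.0, np.inf),
    "decay": (0.0, np.inf),
    "link_corr": (-1.0, 1.0),
}


@dataclasses.dataclass
class TrackerConfig:
    """Tunable parameters of the tracker.

    Defaults mirror the configuration used for linear-track experiments:
    equal metric weights, ``min_prob = chain_prob = 0.75``, ``max_dist = 20``
    pixels.
    """

    max_dist: float = 20.0
    min_prob: float = 0.75
    chain_prob: float = 0.75
    weights: dict[str, float] | None = None  # None -> equal weights
    metrics: tuple[str, ...] = tuple(_metrics.METRIC_DIRECTIONS)
    n_weight_samples: int = 30
    perturbation_sd: float = 0.12
    bias: float = 0.02
    max_iters: int = 100
    per_neuron_move_limit: int = 5
    method: str = "auto"  # 'auto' | 'percentile' | 'mixture' | 'soft_kmeans'
    fuzzifier: float = 2.0
    link_neighbor_radius: float | None = None  # None -> max_dist
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("min_prob", self.min_prob), ("chain_prob", self.chain_prob)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_weight_samples < 1:
            raise ValueError("n_weight_samples must be >= 1")

    def resolved_weights(self, active_metrics: Sequence[str]) -> np.ndarray:
        """Weight vector over ``active_metrics``, normalized to sum 1."""
        if self.weights is None:
            w = np.ones(len(active_metrics))
        else:
            w = np.array([self.weights.get(m, 0.0) for m in active_metrics], float)
        if w.sum() <= 0:
            raise ValueError("weights sum to zero over the active metrics")
        return w / w.sum()


# ---------------------------------------------------------------------------
# step 2: similarity matrices


@dataclasses.dataclass
class SimilarityMatrix:
    """Aggregated identification probabilities over all neurons of all
    sessions.  ``session_of[i]`` gives the session index of global neuron i;
    same-session entries hold the sentinel."""

    matrix: np.ndarray
    session_of: np.ndarray
    offsets: np.ndarray  # first global index of each session

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def local_index(self, global_idx: int) -> tuple[int, int]:
        s = int(self.session_of[global_idx])
        return s, int(global_idx - self.offsets[s])


def build_similarity_matrix(
    pair_probs: dict[tuple[int, int], dict],
    n_per_session: Sequence[int],
    weights: np.ndarray,
    metric_names: Sequence[str],
    min_prob: float,
) -> SimilarityMatrix:
    """Aggregate per-metric probabilities into one similarity matrix.

    ``pair_probs[(s, t)]`` holds ``pairs`` (local index pairs) and
    ``probs`` (metric name -> aligned probability array).  Cross-session
    entries are the weighted sum of metric probabilities, zeroed below
    ``min_prob``; non-candidate pairs are 0; same-session entries get the
    sentinel.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(metric_names):
        raise ValueError("one weight per metric required")
    offsets = np.concatenate([[0], np.cumsum(n_per_session)]).astype(int)
    n_cells = int(offsets[-1])
    session_of = np.concatenate(
        [np.full(k, s, dtype=int) for s, k in enumerate(n_per_session)]
    )
    mat = np.zeros((n_cells, n_cells))
    for (s, t), entry in pair_probs.items():
        if not entry["pairs"]:
            continue
        probs = np.stack([np.asarray(entry["probs"][m], float) for m in metric_names])
        agg = weights @ probs
        agg = np.where(agg < min_prob, 0.0, agg)
        for (i, j), p in zip(entry["pairs"], agg):
            gi = offsets[s] + i
            gj = offsets[t] + j
            mat[gi, gj] = mat[gj, gi] = p
    same = session_of[:, None] == session_of[None, :]
    mat[same] = SAME_SESSION_SENTINEL
    return SimilarityMatrix(matrix=mat, session_of=session_of, offsets=offsets[:-1])


def graph_components(sim: SimilarityMatrix) -> list[np.ndarray]:
    """Connected components of the graph with edges where the cross-session
    similarity is positive.  Returned as sorted global-index arrays."""
    adj = (sim.matrix > 0) & (sim.session_of[:, None] != sim.session_of[None, :])
    n, labels = _cc(csr_matrix(adj), directed=False)
    return [np.flatnonzero(labels == k) for k in range(n)]


# ---------------------------------------------------------------------------
# step 3: switch/swap clustering


def partition_objective(s_local: np.ndarray, clusters: Sequence[set[int]]) -> float:
    """Sum over clusters of the mean pairwise similarity (singletons add 0)."""
    total = 0.0
    for c in clusters:
        if len(c) < 2:
            continue
        idx = np.fromiter(c, int)
        sub = s_local[np.ix_(idx, idx)]
        npairs = len(idx) * (len(idx) - 1) / 2
        total += float(np.triu(sub, 1).sum()) / npairs
    return total


def _cluster_mean(s_local: np.ndarray, c: set[int]) -> float:
    """Mean pairwise similarity of a cluster; singletons count as 1 (they
    cannot violate a chain threshold)."""
    if len(c) < 2:
        return 1.0
    idx = np.fromiter(c, int)
    sub = s_local[np.ix_(idx, idx)]
    return float(np.triu(sub, 1).sum()) / (len(idx) * (len(idx) - 1) / 2)


def _valid_addition(c: set[int], node: int, sessions: np.ndarray) -> bool:
    return all(sessions[m] != sessions[node] for m in c)


@dataclasses.dataclass
class ClusterAssignment:
    """Partition of a component's neurons (local indices) into clusters."""

    clusters: list[set[int]]
    sessions: np.ndarray  # session label per local neuron

    def validate(self) -> None:
        seen: set[int] = set()
        n_sessions = len(np.unique(self.sessions))
        for c in self.clusters:
            if len(c) > n_sessions:
                raise ValueError("cluster larger than number of sessions")
            sess = [self.sessions[m] for m in c]
            if len(set(sess)) != len(sess):
                raise ValueError("two neurons of one session in a cluster")
            seen.update(c)
        if len(seen) != len(self.sessions):
            raise ValueError("partition does not cover the component")

    def labels(self) -> np.ndarray:
        lab = np.empty(len(self.sessions), dtype=int)
        for k, c in enumerate(self.clusters):
            for m in c:
                lab[m] = k
        return lab


def initialize_clusters(
    s_local: np.ndarray, sessions: np.ndarray, chain_prob: float
) -> ClusterAssignment:
    """Greedy dissimilarity-first initialization.

    Neurons are processed from least to most similar (by mean similarity to
    the rest of the component), so the least similar neurons seed separate
    clusters; each remaining neuron joins the cluster whose mean similarity
    decreases least, or a new cluster when no addition keeps the mean at or
    above ``chain_prob``.  A neuron never joins a cluster it has no positive
    similarity to (a zero-similarity merge binds nothing and only blocks
    later moves).
    """
    n = len(sessions)
    cross = np.where(sessions[:, None] != sessions[None, :], s_local, 0.0)
    order = np.argsort(cross.sum(axis=1), kind="stable")  # least similar first
    clusters: list[set[int]] = []
    for node in order:
        best = None
        best_mean = -np.inf
        for c in clusters:
            if not _valid_addition(c, node, sessions):
                continue
            if not any(s_local[node, m] > 0 for m in c):
                continue
            mean = _cluster_mean(s_local, c | {node})
            if mean > best_mean + _EPS:
                best, best_mean = c, mean
        if best is not None and best_mean >= chain_prob - _EPS:
            best.add(int(node))
        else:
            clusters.append({int(node)})
    assignment = ClusterAssignment(clusters=clusters, sessions=sessions)
    assignment.validate()
    return assignment


def _enumerate_moves(
    clusters: list[set[int]],
    s_local: np.ndarray,
    sessions: np.ndarray,
    chain_prob: float,
    bias: float,
    frozen: set[int],
):
    """Yield (score, objective_gain, kind, payload) for all legal moves.

    A move is legal if it keeps clusters session-disjoint and never leaves a
    multi-member cluster below ``chain_prob``.  With ``bias > 0``, switch
    scores are biased toward growing the larger affected cluster, swap
    scores toward improving the larger cluster's mean, and moves that shrink
    a satisfied multi-member cluster are skipped.
    """
    means = [_cluster_mean(s_local, c) for c in clusters]

    def cscore(c: set[int]) -> float:
        return _cluster_mean(s_local, c) if len(c) >= 2 else 0.0

    scores = [cscore(c) for c in clusters]
    member_of = {m: k for k, c in enumerate(clusters) for m in c}

    n = len(sessions)
    for node in range(n):
        if node in frozen:
            continue
        a = member_of[node]
        if bias > 0 and len(clusters[a]) >= 2 and means[a] > chain_prob:
            continue  # do not erode satisfied clusters
        src_new = clusters[a] - {node}
        if len(src_new) >= 2 and _cluster_mean(s_local, src_new) < chain_prob - _EPS:
            continue
        src_gain = (cscore(src_new) if src_new else 0.0) - scores[a]
        targets = list(range(len(clusters))) + [-1]  # -1 = new singleton
        for t in targets:
            if t == a:
                continue
            if t == -1:
                if len(clusters[a]) == 1:
                    continue  # already a singleton
                dst_gain = 0.0
                new_sizes = (len(clusters[a]) - 1, 1)
            else:
                if not _valid_addition(clusters[t], node, sessions):
                    continue
                dst_new = clusters[t] | {node}
                if _cluster_mean(s_local, dst_new) < chain_prob - _EPS:
                    continue
                dst_gain = cscore(dst_new) - scores[t]
                new_sizes = (len(clusters[a]) - 1, len(clusters[t]) + 1)
            gain = src_gain + dst_gain
            score = gain
            if bias > 0:
                old_max = max(len(clusters[a]), len(clusters[t]) if t >= 0 else 1)
                new_max = max(new_sizes)
                if new_max > old_max:
                    score += bias
                elif new_max < old_max:
                    score -= bias
            yield score, gain, "switch", (node, a, t)

    for i in range(n):
        if i in frozen:
            continue
        for j in range(i + 1, n):
            if j in frozen:
                continue
            a, b = member_of[i], member_of[j]
            if a == b:
                continue
            na = (clusters[a] - {i}) | {j}
            nb = (clusters[b] - {j}) | {i}
            if not _valid_addition(clusters[a] - {i}, j, sessions):
                continue
            if not _valid_addition(clusters[b] - {j}, i, sessions):
                continue
            ma, mb = _cluster_mean(s_local, na), _cluster_mean(s_local, nb)
            if (len(na) >= 2 and ma < chain_prob - _EPS) or (
                len(nb) >= 2 and mb < chain_prob - _EPS
            ):
                continue
            gain = (
                (ma if len(na) >= 2 else 0.0)
                + (mb if len(nb) >= 2 else 0.0)
                - scores[a]
                - scores[b]
            )
            score = gain
            if bias > 0 and len(clusters[a]) != len(clusters[b]):
                big, big_new = (
                    (a, ma) if len(clusters[a]) > len(clusters[b]) else (b, mb)
                )
                if big_new < means[big] - _EPS:
                    score -= bias
                elif big_new > means[big] + _EPS:
                    score += bias
            yield score, gain, "swap", (i, j, a, b)


def _apply_move(clusters: list[set[int]], kind: str, payload) -> list[int]:
    """Apply a move in place; returns the neurons it moved."""
    if kind == "switch":
        node, a, t = payload
        clusters[a].discard(node)
        if t == -1:
            clusters.append({node})
        else:
            clusters[t].add(node)
        return [node]
    i, j, a, b = payload
    clusters[a].discard(i)
    clusters[b].discard(j)
    clusters[a].add(j)
    clusters[b].add(i)
    return [i, j]


def _session_valid_partitions(sessions: np.ndarray):
    """All partitions of the component with session-disjoint clusters."""
    n = len(sessions)

    def rec(node, clusters):
        if node == n:
            yield [set(c) for c in clusters]
            return
        for c in clusters:
            if all(sessions[m] != sessions[node] for m in c):
                c.add(node)
                yield from rec(node + 1, clusters)
                c.discard(node)
        clusters.append({node})
        yield from rec(node + 1, clusters)
        clusters.pop()

    yield from rec(0, [])


def _exact_refine(
    clusters: list[set[int]],
    s_local: np.ndarray,
    sessions: np.ndarray,
    chain_prob: float,
) -> list[set[int]]:
    """Exhaustive search over session-valid, chain-consistent partitions.

    Used as a finisher on small components when no bias is in play: the
    hill-climb's postcondition is global optimality there, and greedy moves
    alone cannot guarantee it.
    """
    best = [set(c) for c in clusters]
    best_obj = partition_objective(s_local, best)
    for part in _session_valid_partitions(sessions):
        if any(
            len(c) >= 2 and _cluster_mean(s_local, c) < chain_prob - _EPS
            for c in part
        ):
            continue
        obj = partition_objective(s_local, part)
        if obj > best_obj + _EPS:
            best, best_obj = part, obj
    return best


def switch_swap_optimize(
    assignment: ClusterAssignment,
    s_local: np.ndarray,
    bias: float = 0.0,
    chain_prob: float = 0.0,
    max_iters: int = 100,
    per_neuron_move_limit: int = 5,
    lookahead_size: int = 12,
    exact_refine_size: int = 8,
) -> ClusterAssignment:
    """Greedy switch/swap hill-climb on the partition objective.

    At each iteration every legal switch (reassign one neuron) and swap
    (exchange two neurons) is scored by its objective gain plus, when
    ``bias > 0``, a constant bias toward larger clusters; the best move is
    applied if its unbiased gain is nonnegative and its biased score is
    positive.  When the single-move search stalls on a component of at most
    ``lookahead_size`` neurons, pairs of moves are searched and a compound
    move with strictly positive total gain may be applied (a depth-2 escape
    from shallow local optima; its intermediate step may dip, the accepted
    compound never does).  Each neuron moves at most
    ``per_neuron_move_limit`` times, guaranteeing termination; the
    objective never decreases over accepted (possibly compound) moves, bias
    excluded.

    Without bias, components of at most ``exact_refine_size`` neurons are
    finished with an exhaustive search over session-valid partitions, so
    the returned objective is globally optimal on these sizes.  (With
    ``bias > 0`` the target is deliberately not the raw objective, so the
    finisher is skipped.)
    """
    clusters = [set(c) for c in assignment.clusters if c]
    sessions = assignment.sessions
    n = len(sessions)
    move_count = np.zeros(n, dtype=int)

    def find_single(frozen):
        best = None
        for score, gain, kind, payload in _enumerate_moves(
            clusters, s_local, sessions, chain_prob, bias, frozen
        ):
            if gain < -_EPS or score <= _EPS:
                continue
            if best is None or score > best[0] + _EPS:
                best = (score, gain, kind, payload)
        return best

    def find_pair(frozen):
        # depth-2: tolerate a first move with bounded negative gain if the
        # best follow-up makes the pair strictly improving overall
        best = None
        first_moves = list(_enumerate_moves(
            clusters, s_local, sessions, chain_prob, bias, frozen
        ))
        for _, gain1, kind1, payload1 in first_moves:
            trial = [set(c) for c in clusters]
            _apply_move(trial, kind1, payload1)
            trial = [c for c in trial if c]
            for _, gain2, kind2, payload2 in _enumerate_moves(
                trial, s_local, sessions, chain_prob, bias, frozen
            ):
                total = gain1 + gain2
                if total <= _EPS:
                    continue
                if best is None or total > best[0] + _EPS:
                    best = (total, (kind1, payload1), (kind2, payload2))
        return best

    iters = 0
    while iters < max_iters:
        iters += 1
        frozen = set(np.flatnonzero(move_count >= per_neuron_move_limit))
        best = find_single(frozen)
        if best is not None:
            _, _, kind, payload = best
            for node in _apply_move(clusters, kind, payload):
                move_count[node] += 1
            clusters = [c for c in clusters if c]
            continue
        if n <= lookahead_size:
            pair = find_pair(frozen)
            if pair is not None:
                _, (kind1, payload1), (kind2, payload2) = pair
                moved = _apply_move(clusters, kind1, payload1)
                clusters = [c for c in clusters if c]
                moved += _apply_move(clusters, kind2, payload2)
                clusters = [c for c in clusters if c]
                for node in moved:
                    move_count[node] += 1
                continue
        break
    else:
        logger.warning("switch/swap did not converge within max_iters; "
                       "returning best-so-far assignment")
    if bias == 0 and n <= exact_refine_size:
        clusters = _exact_refine(clusters, s_local, sessions, chain_prob)
    out = ClusterAssignment(clusters=[c for c in clusters if c], sessions=sessions)
    out.validate()
    return out


def split_until_consistent(
    assignment: ClusterAssignment,
    s_local: np.ndarray,
    chain_prob: float,
    **optimize_kwargs,
) -> ClusterAssignment:
    """Split loop: while any multi-member cluster falls below ``chain_prob``,
    eject the least similar member of the worst cluster into a new singleton
    and re-optimize.  Moves themselves never create violations, so this is a
    terminating safety net."""
    clusters = [set(c) for c in assignment.clusters]
    sessions = assignment.sessions
    for _ in range(len(sessions) ** 2 + 1):
        worst_k, worst_mean = None, np.inf
        for k, c in enumerate(clusters):
            if len(c) < 2:
                continue
            m = _cluster_mean(s_local, c)
            if m < chain_prob - _EPS and m < worst_mean:
                worst_k, worst_mean = k, m
        if worst_k is None:
            break
        c = clusters[worst_k]
        idx = sorted(c)
        sims = [
            (np.sum([s_local[i, j] for j in c if j != i]), i) for i in idx
        ]
        _, loner = min(sims)
        c.discard(loner)
        clusters.append({loner})
        assignment = switch_swap_optimize(
            ClusterAssignment(clusters=clusters, sessions=sessions),
            s_local,
            chain_prob=chain_prob,
            **optimize_kwargs,
        )
        clusters = [set(c) for c in assignment.clusters]
    out = ClusterAssignment(clusters=clusters, sessions=sessions)
    out.validate()
    return out


def cluster_component(
    s_local: np.ndarray,
    sessions: np.ndarray,
    chain_prob: float,
    bias: float = 0.0,
    max_iters: int = 100,
    per_neuron_move_limit: int = 5,
) -> ClusterAssignment:
    """Initialize, hill-climb, and split one component."""
    assignment = initialize_clusters(s_local, sessions, chain_prob)
    assignment = switch_swap_optimize(
        assignment, s_local, bias=bias, chain_prob=chain_prob,
        max_iters=max_iters, per_neuron_move_limit=per_neuron_move_limit,
    )
    return split_until_consistent(
        assignment, s_local, chain_prob,
        bias=bias, max_iters=max_iters,
        per_neuron_move_limit=per_neuron_move_limit,
    )


# ---------------------------------------------------------------------------
# consensus


def perturb_weights(
    weights: np.ndarray,
    n_samples: int = 30,
    sd: float = 0.12,
    seed: int = 0,
    max_retries: int = 100,
) -> list[np.ndarray]:
    """Base weight vector plus ``n_samples - 1`` random perturbations.

    Each perturbation adds N(0, sd) noise per entry, clips at zero, and
    renormalizes; an all-zero draw is resampled (bounded retries).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0 or np.any(weights < 0):
        raise ValueError("base weights must be nonnegative with positive sum")
    base = weights / weights.sum()
    rng = np.random.default_rng(seed)
    out = [base.copy()]
    for _ in range(n_samples - 1):
        for _attempt in range(max_retries):
            w = np.clip(base + rng.normal(0.0, sd, size=base.shape), 0.0, None)
            if w.sum() > 0:
                out.append(w / w.sum())
                break
        else:
            raise RuntimeError("could not draw a nonzero perturbed weight vector")
    return out


def build_consensus_matrix(clusterings: Sequence[ClusterAssignment]) -> np.ndarray:
    """Co-clustering frequency matrix over repeated clusterings of one
    component.  Symmetric with unit diagonal."""
    if not clusterings:
        raise ValueError("no clusterings supplied")
    n = len(clusterings[0].sessions)
    acc = np.zeros((n, n))
    for assignment in clusterings:
        lab = assignment.labels()
        acc += lab[:, None] == lab[None, :]
    acc /= len(clusterings)
    np.fill_diagonal(acc, 1.0)
    return acc


# ---------------------------------------------------------------------------
# step 1 + full pipeline


def compute_pair_probabilities(
    sessions: Sequence[SessionExtraction],
    links: Sequence[LinkExtraction] | None,
    config: TrackerConfig,
):
    """Steps (1): candidate pairs, metric values, and per-metric
    identification probabilities for every session pair.

    Returns ``(pair_probs, active_metrics, report)`` where ``pair_probs``
    maps ``(s, t)`` to pairs + aligned probability arrays and ``report``
    records the fitted model parameters per session pair and metric.
    """
    n_sessions = len(sessions)
    active = list(config.metrics)
    if (links is None or not links) and "link_corr" in active:
        active.remove("link_corr")  # no connecting recordings available
    method = config.method
    if method == "auto":
        method = "mixture" if n_sessions == 2 else "soft_kmeans"
    link_by_left = {}
    if links:
        for k, link in enumerate(links):
            link_by_left[k] = link
    pair_probs: dict[tuple[int, int], dict] = {}
    report: dict[str, dict] = {}
    for s in range(n_sessions):
        for t in range(s + 1, n_sessions):
            cand = _metrics.candidate_pairs(sessions[s], sessions[t], config.max_dist)
            link = link_by_left.get(s) if t == s + 1 else None
            values = _metrics.pair_metric_values(
                sessions[s], sessions[t], cand.pairs, link=link,
                neighbor_radius=config.link_neighbor_radius or config.max_dist,
            )
            probs: dict[str, np.ndarray] = {}
            models: dict[str, dict] = {}
            for m in active:
                vals = values[m]
                avail = np.array([v is not None for v in vals], dtype=bool)
                p = np.full(len(vals), NEUTRAL_PROB)
                if avail.sum() >= 1:
                    pop = np.array([v for v in vals if v is not None], dtype=float)
                    model = ident_models.fit_identification_model(
                        pop,
                        method=method,
                        direction=_metrics.METRIC_DIRECTIONS[m],
                        bounds=METRIC_BOUNDS[m],
                        fuzzifier=config.fuzzifier,
                        seed=config.seed % (2**31),
                    )
                    p[avail] = np.atleast_1d(model.posterior(pop))
                    models[m] = model.to_dict()
                probs[m] = p
            pair_probs[(s, t)] = {"pairs": cand.pairs, "probs": probs}
            report[f"sessions_{s}_{t}"] = {
                "n_candidate_pairs": len(cand.pairs),
                "models": models,
            }
    return pair_probs, active, report


def track(
    sessions: Sequence[SessionExtraction],
    links: Sequence[LinkExtraction] | None = None,
    config: TrackerConfig | None = None,
    return_report: bool = False,
):
    """Run the full tracking pipeline and return a :class:`CellRegister`.

    ``links``, when given, must cover consecutive session pairs in order
    (links[k] bridges sessions k and k+1).  With identical inputs and seed
    the register is reproduced exactly.
    """
    if len(sessions) < 2:
        raise ValueError("at least two sessions required")
    config = config or TrackerConfig()
    pair_probs, active, report = compute_pair_probabilities(sessions, links, config)
    n_per_session = [s.n_neurons for s in sessions]
    base_w = config.resolved_weights(active)
    weight_vectors = perturb_weights(
        base_w, config.n_weight_samples, config.perturbation_sd,
        seed=config.seed % (2**31),
    )
    sims = [
        build_similarity_matrix(pair_probs, n_per_session, w, active, config.min_prob)
        for w in weight_vectors
    ]
    base = sims[0]
    components = graph_components(base)
    if all(len(c) == 1 for c in components):
        logger.warning("no candidate pairs above min_prob; register is singleton-only")

    session_names = [s.session_id or str(k) for k, s in enumerate(sessions)]
    rows = []
    scores = []
    for comp in components:
        sess_labels = base.session_of[comp]
        if len(comp) == 1:
            final = ClusterAssignment(clusters=[{0}], sessions=sess_labels)
        else:
            clusterings = []
            for sim in sims:
                s_local = sim.matrix[np.ix_(comp, comp)]
                clusterings.append(
                    cluster_component(
                        s_local, sess_labels, config.chain_prob, config.bias,
                        config.max_iters, config.per_neuron_move_limit,
                    )
                )
            consensus = build_consensus_matrix(clusterings)
            final = cluster_component(
                consensus, sess_labels, config.chain_prob, config.bias,
                config.max_iters, config.per_neuron_move_limit,
            )
        s_base = base.matrix[np.ix_(comp, comp)]
        for c in final.clusters:
            row = {name: MISSING for name in session_names}
            for local in sorted(c):
                sess_idx, neuron_idx = base.local_index(int(comp[local]))
                row[session_names[sess_idx]] = neuron_idx
            rows.append(row)
            scores.append(np.clip(_cluster_mean(s_base, c), 0.0, 1.0))

    table = pd.DataFrame(rows, columns=session_names)
    if len(table):
        order = np.lexsort(
            [table[c].to_numpy() for c in reversed(session_names)]
        )
        table = table.iloc[order].reset_index(drop=True)
        scores = list(np.asarray(scores)[order])
    register = CellRegister(table, scores)
    if return_report:
        report["config"] = dataclasses.asdict(config)
        report["active_metrics"] = active
        report["n_components"] = len(components)
        return register, report
    return register
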