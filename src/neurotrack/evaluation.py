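"""Scoring a proposed cell register against a ground-truth register.

Conventions (fixed here and exercised by the test fixtures):

* *available* neurons under the all-sessions scope are the truth rows
  complete in every session; a proposed row counts toward the discovery
  rate only when it is exactly correct, while any row with at least one
  wrong member feeds the false-discovery rate;
* F1 combines the two rates as ``2 * PDR * (1 - FDR) / ((1 - FDR) + PDR)``;
* Jaccard similarity is averaged over proposed clusters after a greedy
  maximum-overlap matching to truth clusters;
* cluster-size similarity uses the Jensen-Shannon divergence (bits)
  between the normalized cluster-size histograms.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import MISSING, CellRegister, SessionExtraction
from .metrics import js_divergence
from .simulator import GroundTruth


@dataclasses.dataclass
class RegisterScore:
    pdr: float
    fdr: float
    f1: float
    jaccard: float
    size_js_divergence: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _complete_rows(register: CellRegister) -> list[frozenset]:
    n_sessions = len(register.sessions)
    return [r for r in register.row_sets() if len(r) == n_sessions]


def pdr_fdr(
    proposed: CellRegister,
    truth: CellRegister,
    scope: str = "all_sessions_only",
) -> tuple[float, float]:
    """Percent discovery rate and false discovery rate of a register.

    PDR = correctly tracked truth rows / available truth rows.
    FDR = proposed rows containing >= 1 wrong member / proposed rows.
    Scope ``all_sessions_only`` keeps only rows complete in every session;
    ``all_clusters`` keeps every multi-member row.
    """
    if list(proposed.sessions) != list(truth.sessions):
        raise ValueError("registers cover different sessions")
    if scope == "all_sessions_only":
        prop = _complete_rows(proposed)
        true = _complete_rows(truth)
    elif scope == "all_clusters":
        prop = [r for r in proposed.row_sets() if len(r) >= 2]
        true = [r for r in truth.row_sets() if len(r) >= 2]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not prop:
        return 0.0, 0.0
    true_set = set(true)
    n_correct = sum(1 for r in prop if r in true_set)
    pdr = n_correct / len(true) if true else 0.0
    fdr = (len(prop) - n_correct) / len(prop)
    return float(pdr), float(fdr)


def f1_score(pdr: float, fdr: float) -> float:
    """F1 = 2 * PDR * (1 - FDR) / ((1 - FDR) + PDR); 0 when undefined."""
    denom = (1.0 - fdr) + pdr
    if denom <= 0:
        return 0.0
    return 2.0 * pdr * (1.0 - fdr) / denom


def score_register(
    proposed: CellRegister, truth: CellRegister, scope: str = "all_sessions_only"
) -> RegisterScore:
    pdr, fdr = pdr_fdr(proposed, truth, scope)
    return RegisterScore(
        pdr=pdr,
        fdr=fdr,
        f1=f1_score(pdr, fdr),
        jaccard=jaccard_register(proposed, truth),
        size_js_divergence=cluster_size_js(proposed, truth),
    )


def _row_neuron_sets(register: CellRegister) -> list[set]:
    return [set(r) for r in register.row_sets()]


def jaccard_register(proposed: CellRegister, truth: CellRegister) -> float:
    """Mean Jaccard similarity |A n B| / |A u B| between proposed clusters
    and their greedily matched (maximum-overlap, ties broken toward smaller
    truth clusters) ground-truth clusters.  Includes all clusters; an
    unmatched proposed cluster scores 0."""
    prop = _row_neuron_sets(proposed)
    true = _row_neuron_sets(truth)
    if not prop:
        return 0.0
    # greedy maximum-overlap assignment, largest overlaps first
    candidates = []
    for i, a in enumerate(prop):
        for j, b in enumerate(true):
            ov = len(a & b)
            if ov:
                candidates.append((-ov, len(b), i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    scores = np.zeros(len(prop))
    for negov, _, i, j in candidates:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        a, b = prop[i], true[j]
        scores[i] = len(a & b) / len(a | b)
    return float(scores.mean())


def cluster_size_js(proposed: CellRegister, truth: CellRegister) -> float:
    """Jensen-Shannon divergence (bits) between the cluster-size
    distributions of two registers."""
    sizes_p = [len(r) for r in proposed.row_sets()]
    sizes_t = [len(r) for r in truth.row_sets()]
    if not sizes_p or not sizes_t:
        raise ValueError("registers must be nonempty")
    top = max(max(sizes_p), max(sizes_t))
    hist_p = np.bincount(sizes_p, minlength=top + 1)[1:]
    hist_t = np.bincount(sizes_t, minlength=top + 1)[1:]
    return js_divergence(hist_p, hist_t)


# ---------------------------------------------------------------------------
# ground-truth register from (possibly corrupted) extractions


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])


def ground_truth_register(
    extractions: list[SessionExtraction],
    truth: GroundTruth,
    spatial_threshold: float = 0.65,
    temporal_threshold: float = 0.8,
) -> CellRegister:
    """Match extracted neurons to ground-truth neurons session by session.

    An extracted neuron is identified with a truth neuron when the Pearson
    correlation of their footprints exceeds ``spatial_threshold`` *and* that
    of their traces exceeds ``temporal_threshold``; among several passing
    candidates the best combined correlation wins, one extracted neuron per
    truth neuron.
    """
    import pandas as pd

    columns = {}
    for s, ext in enumerate(extractions):
        true_fp = truth.footprints[s]
        true_tr = truth.traces[s]
        k_true = true_fp.shape[1]
        col = np.full(k_true, MISSING)
        taken: set[int] = set()
        for g in range(k_true):
            best, best_score = None, -np.inf
            for e in range(ext.n_neurons):
                if e in taken:
                    continue
                sp = _pearson(true_fp[:, g], ext.footprints[:, e])
                if sp <= spatial_threshold:
                    continue
                tc = _pearson(true_tr[g], ext.traces[e])
                if tc <= temporal_threshold:
                    continue
                if sp + tc > best_score:
                    best, best_score = e, sp + tc
            if best is not None:
                col[g] = best
                taken.add(best)
        columns[ext.session_id or str(s)] = col
    table = pd.DataFrame(columns)
    present = (table.to_numpy() != MISSING).any(axis=1)
    return CellRegister(table[present])
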