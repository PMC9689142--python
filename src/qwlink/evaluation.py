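"""Train/probe edge splits and AUC / precision@L evaluation.

The protocol: the observed edge set E is randomly partitioned into a
training set E_T (fraction η) and a probe set E_P.  Scores are computed
on the training graph only.  Accuracy is judged by

* sampled AUC — the probability that a uniformly drawn probe link
  outscores a uniformly drawn nonexistent pair (a pair in neither E_T
  nor E_P), ties counting 0.5, estimated from n independent
  with-replacement draws (default n = 672,400, which pins the
  Monte-Carlo error below 1e-3);
* precision@L — the fraction of true probe links among the L top-ranked
  non-training candidate pairs, with L defaulting to ⌊|E_T|/3⌋.

``benchmark`` repeats split → score → evaluate for a list of algorithms
and reports per-algorithm means and standard deviations.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .base import get_scorer
from .network import Network

__all__ = [
    "EdgeSplit",
    "AUCResult",
    "PrecisionResult",
    "split_edges",
    "auc_sampled",
    "auc_exhaustive",
    "precision_at",
    "benchmark",
    "DEFAULT_N_SAMPLES",
    "TIE_TOLERANCE",
]

DEFAULT_N_SAMPLES = 672_400
TIE_TOLERANCE = 1e-12
EXHAUSTIVE_GUARD = 10_000_000


@dataclass
class EdgeSplit:
    """Partition of observed edges into training and probe sets."""

    eta: float
    train_edges: list[tuple[int, int]]
    probe_edges: list[tuple[int, int]]
    seed: int | None = None

    def training_network(self, net: Network) -> Network:
        """The training graph: all nodes, training edges only."""
        return net.subgraph_with_edges(self.train_edges)


@dataclass
class AUCResult:
    """Tally of probe-vs-nonexistent comparisons.

    ``n1`` strict wins, ``n2`` ties; auc = (n1 + 0.5 n2)/n.
    """

    n: int
    n1: int
    n2: int
    auc: float = field(init=False)
    std_error: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n1 + self.n2 > self.n:
            raise ValueError("n1 + n2 cannot exceed n")
        self.auc = (self.n1 + 0.5 * self.n2) / self.n
        second_moment = (self.n1 + 0.25 * self.n2) / self.n
        var = max(second_moment - self.auc**2, 0.0)
        self.std_error = float(np.sqrt(var / self.n))


@dataclass
class PrecisionResult:
    """Hits among the top-L ranked candidates."""

    L: int
    l: int
    precision: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.l <= self.L:
            raise ValueError("need 0 <= l <= L")
        self.precision = self.l / self.L


def split_edges(net: Network, eta: float, seed: int | None = None) -> EdgeSplit:
    """Uniform random partition of edges with |E_T| = round(η·M)."""
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must lie in (0, 1), got {eta}")
    m = net.num_edges
    if m < 2:
        raise ValueError("need at least 2 edges to split")
    edges = sorted(net.edges)
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    n_train = int(np.floor(eta * m + 0.5))
    train = [edges[i] for i in order[:n_train]]
    probe = [edges[i] for i in order[n_train:]]
    return EdgeSplit(eta=eta, train_edges=train, probe_edges=probe, seed=seed)


def _pair_pools(
    net: Network, split: EdgeSplit, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score arrays for the probe pool and the nonexistent pool (E_U − E)."""
    probe = np.asarray(split.probe_edges, dtype=int)
    if probe.size == 0:
        raise ValueError("probe set is empty")
    probe_scores = scores[probe[:, 0], probe[:, 1]]
    n = net.num_nodes
    observed = np.zeros((n, n), dtype=bool)
    for j, k in net.edges:
        observed[j, k] = True
    iu, ju = np.triu_indices(n, k=1)
    mask = ~observed[iu, ju]
    if not mask.any():
        raise ValueError("no nonexistent pairs to sample")
    neg_scores = scores[iu[mask], ju[mask]]
    return probe_scores, neg_scores


def _tally(pos: np.ndarray, neg: np.ndarray) -> tuple[int, int]:
    diff = pos - neg
    n2 = int(np.count_nonzero(np.abs(diff) <= TIE_TOLERANCE))
    n1 = int(np.count_nonzero(diff > TIE_TOLERANCE))
    return n1, n2


def auc_sampled(
    scores: np.ndarray,
    net: Network,
    split: EdgeSplit,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | None = None,
) -> AUCResult:
    """Monte-Carlo AUC over independent (probe, nonexistent) draws.

    ``net`` is the full observed network (training + probe edges);
    ``scores`` must come from a scorer fitted on the training graph.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    probe_scores, neg_scores = _pair_pools(net, split, scores)
    rng = np.random.default_rng(seed)
    pos = probe_scores[rng.integers(0, probe_scores.size, size=n_samples)]
    neg = neg_scores[rng.integers(0, neg_scores.size, size=n_samples)]
    n1, n2 = _tally(pos, neg)
    return AUCResult(n=n_samples, n1=n1, n2=n2)


def auc_exhaustive(scores: np.ndarray, net: Network, split: EdgeSplit) -> AUCResult:
    """Exact AUC over all probe × nonexistent comparisons (sampler oracle)."""
    probe_scores, neg_scores = _pair_pools(net, split, scores)
    total = probe_scores.size * neg_scores.size
    if total > EXHAUSTIVE_GUARD:
        raise ValueError(f"{total} comparisons exceed the exhaustive guard")
    neg_sorted = np.sort(neg_scores)
    # strict wins: negatives strictly below score - tol
    n1 = int(np.searchsorted(neg_sorted, probe_scores - TIE_TOLERANCE, side="left").sum())
    hi = np.searchsorted(neg_sorted, probe_scores + TIE_TOLERANCE, side="right")
    lo = np.searchsorted(neg_sorted, probe_scores - TIE_TOLERANCE, side="left")
    n2 = int((hi - lo).sum())
    return AUCResult(n=total, n1=n1, n2=n2)


def precision_at(
    scores: np.ndarray,
    net: Network,
    split: EdgeSplit,
    L: int | None = None,
) -> PrecisionResult:
    """Fraction of probe links among the top-L non-training candidates.

    Candidates are all pairs outside E_T (probe edges included).  Ties
    are broken by ascending index pair for reproducibility.  L defaults
    to ⌊|E_T|/3⌋.
    """
    if L is None:
        L = len(split.train_edges) // 3
    if L < 1:
        raise ValueError("L must be at least 1")
    n = net.num_nodes
    train = set(split.train_edges)
    iu, ju = np.triu_indices(n, k=1)
    train_mask = np.zeros(iu.size, dtype=bool)
    if train:
        tarr = np.asarray(sorted(train), dtype=int)
        flat_train = tarr[:, 0] * n + tarr[:, 1]
        flat_all = iu * n + ju
        train_mask = np.isin(flat_all, flat_train)
    ci, cj = iu[~train_mask], ju[~train_mask]
    if L > ci.size:
        raise ValueError(f"L={L} exceeds the {ci.size} candidate pairs")
    cand_scores = scores[ci, cj]
    # stable sort on index pair then descending score => deterministic ties
    order = np.lexsort((cj, ci, -cand_scores))[:L]
    probe = set(split.probe_edges)
    hits = sum(1 for j, k in zip(ci[order], cj[order]) if (j, k) in probe)
    return PrecisionResult(L=L, l=hits)


def benchmark(
    net: Network,
    algorithms: list[str],
    eta: float = 0.9,
    repetitions: int = 10,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | None = None,
    L: int | None = None,
    scorer_options: dict[str, dict] | None = None,
) -> dict:
    """Split/score/evaluate every algorithm over repeated random splits.

    Returns a JSON-serialisable report with per-algorithm AUC and
    precision means and standard deviations.  Unknown algorithm names
    fail before any computation.
    """
    scorers = {name: get_scorer(name, **(scorer_options or {}).get(name, {}))
               for name in algorithms}
    rng = np.random.default_rng(seed)
    auc: dict[str, list[float]] = {name: [] for name in algorithms}
    prec: dict[str, list[float]] = {name: [] for name in algorithms}
    for _ in range(repetitions):
        split = split_edges(net, eta, seed=int(rng.integers(0, 2**31 - 1)))
        train_net = split.training_network(net)
        # per-algorithm sampler seed derived from the name so results do
        # not depend on the order algorithms are listed in
        auc_base = int(rng.integers(0, 2**31 - 1))
        for name in algorithms:
            scores = scorers[name].fit(train_net).scores_
            a = auc_sampled(
                scores, net, split, n_samples=n_samples,
                seed=(auc_base + zlib.crc32(name.encode())) % (2**31 - 1),
            )
            p = precision_at(scores, net, split, L=L)
            auc[name].append(a.auc)
            prec[name].append(p.precision)
    report = {
        "network": {"num_nodes": net.num_nodes, "num_edges": net.num_edges},
        "eta": eta,
        "repetitions": repetitions,
        "n_samples": n_samples,
        "seed": seed,
        "algorithms": {
            name: {
                "auc_mean": float(np.mean(auc[name])),
                "auc_sd": float(np.std(auc[name], ddof=1)) if repetitions > 1 else 0.0,
                "precision_mean": float(np.mean(prec[name])),
                "precision_sd": float(np.std(prec[name], ddof=1)) if repetitions > 1 else 0.0,
            }
            for name in algorithms
        },
    }
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a benchmark report into one row per algorithm."""
    rows = [
        {"algorithm": name, **vals} for name, vals in report["algorithms"].items()
    ]
    return pd.DataFrame(rows)


def write_report(report: dict, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    if tsv_path is not None:
        report_to_frame(report).to_csv(tsv_path, sep="\t", index=False)
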