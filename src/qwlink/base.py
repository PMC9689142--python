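"""Estimator base class and algorithm registry for pairwise link scorers.

All predictors follow the scikit-learn estimator protocol: construct
with hyper-parameters, ``fit`` on a training :class:`~qwlink.network.Network`,
then read the fitted symmetric score matrix from ``scores_`` or query
individual candidate pairs with ``predict``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .network import Network

__all__ = ["PairwiseScorer", "get_scorer", "available_algorithms"]


class PairwiseScorer(BaseEstimator):
    """Base class for link predictors producing a symmetric score matrix.

    Subclasses implement :meth:`_score_matrix`; ``fit`` validates the
    input, computes the matrix, zeroes the diagonal and stores it as
    ``scores_``.
    """

    def fit(self, network: Network, y=None) -> "PairwiseScorer":
        if not isinstance(network, Network):
            raise TypeError(f"expected a Network, got {type(network).__name__}")
        scores = np.asarray(self._score_matrix(network), dtype=float)
        n = network.num_nodes
        if scores.shape != (n, n):
            raise ValueError(f"scorer produced shape {scores.shape}, expected {(n, n)}")
        np.fill_diagonal(scores, 0.0)
        self.network_ = network
        self.n_nodes_ = n
        self.scores_ = scores
        return self

    def _score_matrix(self, network: Network) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict(self, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
        """Scores for an iterable of (j, k) index pairs."""
        if not hasattr(self, "scores_"):
            raise RuntimeError("scorer is not fitted")
        idx = np.asarray(list(pairs), dtype=int)
        if idx.ndim != 2 or idx.shape[1] != 2:
            raise ValueError("pairs must be a sequence of (j, k) tuples")
        return self.scores_[idx[:, 0], idx[:, 1]]

    def fit_predict_candidates(self, network: Network) -> pd.DataFrame:
        """Fit and rank all candidate (non-edge) pairs, highest score first."""
        self.fit(network)
        return self.candidate_table()

    def candidate_table(self) -> pd.DataFrame:
        """Ranked non-edge candidates with original labels.

        Sorted by descending score; ties broken by the (j, k) index pair,
        which follows first-appearance label order, so output is fully
        deterministic.
        """
        net = self.network_
        pairs = net.non_edges()
        rows = [
            (net.node_labels[j], net.node_labels[k], self.scores_[j, k], j, k)
            for j, k in pairs
        ]
        df = pd.DataFrame(rows, columns=["node_label_1", "node_label_2", "score", "_j", "_k"])
        df = df.sort_values(["score", "_j", "_k"], ascending=[False, True, True])
        return df.drop(columns=["_j", "_k"]).reset_index(drop=True)

    def write_scores_tsv(self, path: str | Path) -> None:
        self.candidate_table().to_csv(path, sep="\t", index=False)


_REGISTRY: dict[str, tuple[type, dict]] = {}


def register(name: str, cls: type, **kwargs) -> None:
    _REGISTRY[name] = (cls, kwargs)


def available_algorithms() -> list[str]:
    return sorted(_REGISTRY)


def get_scorer(name: str, **overrides) -> PairwiseScorer:
    """Instantiate a registered scorer by name (e.g. ``"CN"``, ``"sqwalk"``)."""
    try:
        cls, kwargs = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown algorithm {name!r}; available: {', '.join(available_algorithms())}"
        ) from None
    return cls(**{**kwargs, **overrides})
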