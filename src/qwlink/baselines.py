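"""Classical similarity indices used as link-prediction baselines.

Fourteen indices grouped by the information they use:

* local neighbourhood: CN, Salton, Jaccard, Sorenson, HPI, HDI, PA, AA, RA
* paths: LP (A² + αA³) and Katz ((I − αA)⁻¹ − I)
* Laplacian / random walk: ACT (reciprocal commute distance) and Cos+
  (cosine similarity under the Laplacian pseudoinverse)
* neighbour-contribution random walk: NC at horizon 3

Every index is exposed as an estimator and via the thin functional
wrappers ``local_index`` / ``path_index`` / ``laplacian_index`` /
``nc_index``.  All matrices are symmetric with zero diagonal; ratio
indices return 0 where the denominator vanishes.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy.linalg import pinvh

from .base import PairwiseScorer, register
from .network import Network, common_neighbor_matrix

__all__ = [
    "LOCAL_INDEX_NAMES",
    "LocalIndexScorer",
    "PathIndexScorer",
    "LaplacianIndexScorer",
    "NeighborContributionScorer",
    "local_index",
    "path_index",
    "laplacian_index",
    "nc_index",
    "default_katz_alpha",
]

LOCAL_INDEX_NAMES = (
    "CN",
    "Salton",
    "Jaccard",
    "Sorenson",
    "HPI",
    "HDI",
    "PA",
    "AA",
    "RA",
)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0 wherever den == 0."""
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den != 0)
    return out


class LocalIndexScorer(PairwiseScorer):
    """Common-neighbour-family index selected by name.

    CN = |Γ|; Salton = CN/√(d_j d_k); Jaccard = CN/|N(j)∪N(k)|;
    Sorenson = 2CN/(d_j+d_k); HPI = CN/min(d_j,d_k); HDI = CN/max;
    PA = d_j·d_k; AA = Σ_{z∈Γ} 1/ln d_z; RA = Σ_{z∈Γ} 1/d_z.
    """

    def __init__(self, index: str = "CN") -> None:
        self.index = index

    def _score_matrix(self, network: Network) -> np.ndarray:
        name = self.index
        if name not in LOCAL_INDEX_NAMES:
            raise ValueError(f"unknown local index {name!r}")
        a = network.adjacency
        d = network.degrees
        cn = common_neighbor_matrix(network)
        np.fill_diagonal(cn, 0.0)
        if name == "CN":
            return cn
        if name == "PA":
            return np.outer(d, d)
        if name == "Salton":
            return _safe_div(cn, np.sqrt(np.outer(d, d)))
        if name == "Jaccard":
            return _safe_div(cn, d[:, None] + d[None, :] - cn)
        if name == "Sorenson":
            return _safe_div(2.0 * cn, d[:, None] + d[None, :])
        if name == "HPI":
            return _safe_div(cn, np.minimum(d[:, None], d[None, :]))
        if name == "HDI":
            return _safe_div(cn, np.maximum(d[:, None], d[None, :]))
        # AA and RA weight each common neighbour z by 1/ln d_z or 1/d_z.
        # A degree-<=1 node can never be a common neighbour of a distinct
        # pair, but guard the weight anyway.
        if name == "AA":
            with np.errstate(divide="ignore"):
                log_d = np.log(d, out=np.zeros_like(d), where=d > 0)
            w = np.zeros_like(d)
            ok = log_d > 0
            w[ok] = 1.0 / log_d[ok]
            if np.any((d == 1) & a.any(axis=1)):
                warnings.warn("degree-1 nodes contribute 0 to the AA sum")
        else:  # RA
            w = np.zeros_like(d)
            w[d > 0] = 1.0 / d[d > 0]
        return (a * w[None, :]) @ a


def default_katz_alpha(net: Network) -> float:
    """min(0.01, 0.85/λ_max) — safely inside the Katz convergence radius."""
    lam = np.max(np.abs(np.linalg.eigvalsh(net.adjacency))) if net.num_edges else 0.0
    return min(0.01, 0.85 / lam) if lam > 0 else 0.01


class PathIndexScorer(PairwiseScorer):
    """Path-count indices: LP = A² + αA³ or Katz = (I − αA)⁻¹ − I.

    ``alpha=None`` uses 0.001 for LP and min(0.01, 0.85/λ_max) for Katz.
    """

    def __init__(self, index: str = "LP", alpha: float | None = None) -> None:
        self.index = index
        self.alpha = alpha

    def _score_matrix(self, network: Network) -> np.ndarray:
        a = network.adjacency
        if self.index == "LP":
            alpha = 0.001 if self.alpha is None else self.alpha
            a2 = a @ a
            return a2 + alpha * (a2 @ a)
        if self.index == "Katz":
            alpha = default_katz_alpha(network) if self.alpha is None else self.alpha
            lam = np.max(np.abs(np.linalg.eigvalsh(a))) if network.num_edges else 0.0
            if alpha * lam >= 1.0:
                raise ValueError(
                    f"Katz series diverges: alpha*lambda_max = {alpha * lam:.4f} >= 1"
                )
            n = network.num_nodes
            return np.linalg.inv(np.eye(n) - alpha * a) - np.eye(n)
        raise ValueError(f"unknown path index {self.index!r}")


class LaplacianIndexScorer(PairwiseScorer):
    """Laplacian-pseudoinverse indices: ACT or Cos+.

    With L⁺ = pinv(D − A): commute distance between j and k is
    proportional to l⁺_jj + l⁺_kk − 2l⁺_jk; ACT scores its reciprocal so
    larger means more similar.  Cos+ is l⁺_jk/√(l⁺_jj l⁺_kk).  Pairs in
    different components score 0.
    """

    def __init__(self, index: str = "ACT") -> None:
        self.index = index

    def _score_matrix(self, network: Network) -> np.ndarray:
        if network.num_edges < 1:
            raise ValueError("Laplacian indices need at least one edge")
        a = network.adjacency
        lap = np.diag(network.degrees) - a
        lplus = pinvh(lap)
        diag = np.diag(lplus)
        if self.index == "ACT":
            dist = diag[:, None] + diag[None, :] - 2.0 * lplus
            scores = _safe_div(np.ones_like(dist), dist)
        elif self.index == "CosPlus":
            scores = _safe_div(lplus, np.sqrt(np.outer(diag, diag)))
        else:
            raise ValueError(f"unknown Laplacian index {self.index!r}")
        # zero out cross-component pairs (pseudoinverse couples components
        # numerically but they carry no random-walk similarity)
        comp = np.empty(network.num_nodes, dtype=int)
        for ci, nodes in enumerate(nx.connected_components(network.to_networkx())):
            comp[list(nodes)] = ci
        scores[comp[:, None] != comp[None, :]] = 0.0
        return scores


class NeighborContributionScorer(PairwiseScorer):
    """Neighbour-contribution random walk index at horizon 3.

    s(j,k) = Σ_{l=2}^{3} [w_j π_jk(l) + w_k π_kj(l)] with node weight
    w_j = Σ_{z∈N(j)} d_z / (d_max · 2M) and π(l) the l-step transition
    probabilities of the simple random walk (D⁻¹A)^l.
    """

    def __init__(self, steps: int = 3) -> None:
        self.steps = steps

    def _score_matrix(self, network: Network) -> np.ndarray:
        if network.num_edges < 1:
            raise ValueError("NC needs at least one edge")
        if self.steps != 3:
            raise ValueError("NC walk horizon is fixed at 3")
        a = network.adjacency
        d = network.degrees
        m = network.num_edges
        p = np.zeros_like(a)
        nz = d > 0
        p[nz] = a[nz] / d[nz, None]
        p2 = p @ p
        p_sum = p2 + p2 @ p
        w = (a @ d) / (d.max() * 2.0 * m)
        half = w[:, None] * p_sum
        return half + half.T


def local_index(net: Network, name: str) -> np.ndarray:
    return LocalIndexScorer(index=name).fit(net).scores_


def path_index(net: Network, name: str, alpha: float | None = None) -> np.ndarray:
    return PathIndexScorer(index=name, alpha=alpha).fit(net).scores_


def laplacian_index(net: Network, name: str) -> np.ndarray:
    return LaplacianIndexScorer(index=name).fit(net).scores_


def nc_index(net: Network) -> np.ndarray:
    return NeighborContributionScorer().fit(net).scores_


for _name in LOCAL_INDEX_NAMES:
    register(_name, LocalIndexScorer, index=_name)
register("LP", PathIndexScorer, index="LP")
register("Katz", PathIndexScorer, index="Katz")
register("ACT", LaplacianIndexScorer, index="ACT")
register("CosPlus", LaplacianIndexScorer, index="CosPlus")
register("NC", NeighborContributionScorer)
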