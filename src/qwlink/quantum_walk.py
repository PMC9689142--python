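"""Simplified discrete-time quantum walk for missing-link scoring.

The walk lives in a 2N-dimensional space: each node contributes a coin
state |0⟩ (stay on a self-loop) and |1⟩ (move toward its neighbours
treated as a whole).  One step applies a Grover-style coin built from
adjacency and common-neighbour counts,

    G[j, k] = -A[j, k] + 2 |Γ(j, k)|,        Γ(j, k) = N(j) ∩ N(k),

followed by a block-diagonal shift [[I, 0], [0, D^-1 A]].  The evolution
is deliberately non-unitary: amplitudes accumulate similarity mass
rather than conserving probability, and after t steps (default 2) the
score of a candidate pair (j, k) is

    P(j, k) = (|Γ(j, k)| / |E_T|) · (ψ0(t)[j] + ψ1(t)[j]),

zero whenever the pair shares no common neighbour.  All amplitudes stay
real throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import PairwiseScorer
from .network import Network, common_neighbor_matrix

__all__ = [
    "WalkState",
    "WalkOperators",
    "ScoreMatrix",
    "QuantumWalkScorer",
    "build_coin",
    "build_shift",
    "build_evolution",
    "build_operators",
    "initial_state",
    "evolve",
    "score_link",
    "score_all",
]

AMPLITUDE_CONVENTIONS = ("inv_sqrt_n", "inv_n")
SYMMETRIZATIONS = ("mean", "sum", "none")


@dataclass
class WalkState:
    """Real amplitude vector over the coin ⊗ position space.

    ``amplitudes`` has length 2N laid out as two N-blocks [ψ0; ψ1] for
    the coin basis states |0⟩ and |1⟩.
    """

    amplitudes: np.ndarray
    step: int
    init_amplitude: float

    @property
    def num_nodes(self) -> int:
        return self.amplitudes.size // 2

    @property
    def psi0(self) -> np.ndarray:
        return self.amplitudes[: self.num_nodes]

    @property
    def psi1(self) -> np.ndarray:
        return self.amplitudes[self.num_nodes :]


@dataclass
class WalkOperators:
    """Coin G, shift S and evolution U = S · blockdiag(G, G)."""

    coin: np.ndarray
    shift: np.ndarray
    evolution: np.ndarray


@dataclass
class ScoreMatrix:
    """Symmetric pairwise link scores with the walk configuration used."""

    scores: np.ndarray
    walk_steps: int
    training_edge_count: int


def build_coin(net: Network) -> np.ndarray:
    """Grover-style coin: entry (j, k) is -A[j,k] + 2|Γ(j,k)|.

    Since |Γ(j,k)| = (A²)[j,k] (including the diagonal, where it equals
    the degree), the full matrix is -A + 2A².
    """
    a = net.adjacency
    return -a + 2.0 * (a @ a)


def build_shift(net: Network) -> np.ndarray:
    """Block-diagonal shift [[I, 0], [0, D⁻¹A]].

    Rows of the lower block for dangling nodes (degree 0) are all zero:
    amplitude in the |1⟩ sector of an isolated node simply vanishes.
    """
    n = net.num_nodes
    a = net.adjacency
    d = net.degrees
    lower = np.zeros_like(a)
    nz = d > 0
    lower[nz] = a[nz] / d[nz, None]
    s = np.zeros((2 * n, 2 * n))
    s[:n, :n] = np.eye(n)
    s[n:, n:] = lower
    return s


def build_evolution(coin: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """U = S · blockdiag(G, G); equals [[G, 0], [0, (D⁻¹A)·G]]."""
    n = coin.shape[0]
    if coin.shape != (n, n) or shift.shape != (2 * n, 2 * n):
        raise ValueError(
            f"dimension mismatch: coin {coin.shape}, shift {shift.shape}"
        )
    doubled = np.zeros_like(shift)
    doubled[:n, :n] = coin
    doubled[n:, n:] = coin
    return shift @ doubled


def build_operators(net: Network) -> WalkOperators:
    coin = build_coin(net)
    shift = build_shift(net)
    return WalkOperators(coin=coin, shift=shift, evolution=build_evolution(coin, shift))


def initial_state(net: Network, amplitude_convention: str = "inv_sqrt_n") -> WalkState:
    """Equal superposition over all 2N basis states.

    The default amplitude is 1/√N; the 1/N convention is available and
    rescales every score by a global constant, leaving rankings intact.
    """
    if amplitude_convention not in AMPLITUDE_CONVENTIONS:
        raise ValueError(f"unknown amplitude convention {amplitude_convention!r}")
    n = net.num_nodes
    alpha = 1.0 / np.sqrt(n) if amplitude_convention == "inv_sqrt_n" else 1.0 / n
    return WalkState(amplitudes=np.full(2 * n, alpha), step=0, init_amplitude=alpha)


def evolve(ops: WalkOperators, state: WalkState, steps: int) -> WalkState:
    """Apply the evolution operator `steps` times."""
    if steps < 0:
        raise ValueError("steps must be non-negative")
    amps = state.amplitudes.copy()
    for _ in range(steps):
        amps = ops.evolution @ amps
    return WalkState(
        amplitudes=amps, step=state.step + steps, init_amplitude=state.init_amplitude
    )


def score_link(
    net: Network,
    ops: WalkOperators,
    state0: WalkState,
    j: int,
    k: int,
    training_edge_count: int,
    steps: int = 2,
) -> float:
    """Ordered score for (j, k): reads the evolved amplitude at node j.

    Asymmetric in (j, k) — only the common-neighbour prefactor involves k.
    """
    if j == k:
        raise ValueError("link score requires two distinct nodes")
    if training_edge_count < 1:
        raise ValueError("training_edge_count must be >= 1")
    gamma = len(net.neighbor_sets[j] & net.neighbor_sets[k])
    if gamma == 0:
        return 0.0
    st = evolve(ops, state0, steps)
    return gamma / training_edge_count * float(st.psi0[j] + st.psi1[j])


def score_all(
    net: Network,
    training_edge_count: int | None = None,
    steps: int = 2,
    symmetrization: str = "mean",
    amplitude_convention: str = "inv_sqrt_n",
) -> ScoreMatrix:
    """Score every unordered node pair of the training graph.

    ``symmetrization`` combines the two ordered scores: "mean" (default),
    "sum", or "none" (keep the row-ordered asymmetric matrix).
    """
    scorer = QuantumWalkScorer(
        steps=steps,
        symmetrization=symmetrization,
        amplitude_convention=amplitude_convention,
        training_edge_count=training_edge_count,
    ).fit(net)
    return ScoreMatrix(
        scores=scorer.scores_,
        walk_steps=steps,
        training_edge_count=scorer.training_edge_count_,
    )


class QuantumWalkScorer(PairwiseScorer):
    """Two-step simplified quantum walk link predictor.

    Parameters
    ----------
    steps : int, default 2
        Number of walk steps; 2 damps traceback oscillation while
        keeping superposition.
    symmetrization : {"mean", "sum", "none"}, default "mean"
        How the two ordered pair scores are combined.
    amplitude_convention : {"inv_sqrt_n", "inv_n"}, default "inv_sqrt_n"
        Initial amplitude 1/√N or 1/N; a pure rescaling of all scores.
    training_edge_count : int or None
        |E_T| in the score prefactor; defaults to the edge count of the
        fitted (training) graph.
    """

    def __init__(
        self,
        steps: int = 2,
        symmetrization: str = "mean",
        amplitude_convention: str = "inv_sqrt_n",
        training_edge_count: int | None = None,
    ) -> None:
        self.steps = steps
        self.symmetrization = symmetrization
        self.amplitude_convention = amplitude_convention
        self.training_edge_count = training_edge_count

    def _score_matrix(self, network: Network) -> np.ndarray:
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.symmetrization not in SYMMETRIZATIONS:
            raise ValueError(f"unknown symmetrization {self.symmetrization!r}")
        m_t = self.training_edge_count
        if m_t is None:
            m_t = network.num_edges
        if m_t < 1:
            raise ValueError("training graph must have at least one edge")
        self.training_edge_count_ = int(m_t)

        ops = build_operators(network)
        self.operators_ = ops
        state = evolve(ops, initial_state(network, self.amplitude_convention), self.steps)
        gamma = common_neighbor_matrix(network)
        np.fill_diagonal(gamma, 0.0)
        node_amp = state.psi0 + state.psi1
        # ordered score: row j reads the amplitude at j
        ordered = gamma / self.training_edge_count_ * node_amp[:, None]
        if self.symmetrization == "mean":
            return 0.5 * (ordered + ordered.T)
        if self.symmetrization == "sum":
            return ordered + ordered.T
        return ordered
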