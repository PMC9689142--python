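"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorised code paths: operators
are assembled from literal outer products of basis vectors, and indices
from explicit neighbour-set arithmetic.
"""

import numpy as np

from qwlink import Network


def basis(n: int, j: int) -> np.ndarray:
    e = np.zeros(n)
    e[j] = 1.0
    return e


def literal_shift(net: Network) -> np.ndarray:
    """Sum over nodes of |0,j><j,0| + (1/|N(j)|) sum_k |1,j><k,1|."""
    n = net.num_nodes
    s = np.zeros((2 * n, 2 * n))
    e2 = [basis(2, c) for c in range(2)]
    for j in range(n):
        v0j = np.kron(e2[0], basis(n, j))
        s += np.outer(v0j, v0j)
        nbrs = net.neighbor_sets[j]
        if nbrs:
            v1j = np.kron(e2[1], basis(n, j))
            for k in nbrs:
                v1k = np.kron(e2[1], basis(n, k))
                s += np.outer(v1j, v1k) / len(nbrs)
    return s


def literal_coin(net: Network) -> np.ndarray:
    """Entrywise -A[j,k] + 2|N(j) ∩ N(k)| via explicit set intersections."""
    n = net.num_nodes
    g = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            gamma = len(net.neighbor_sets[j] & net.neighbor_sets[k])
            g[j, k] = -net.adjacency[j, k] + 2 * gamma
    return g


def literal_evolution(net: Network) -> np.ndarray:
    """S · (coin on both coin blocks), built as a Kronecker product."""
    return literal_shift(net) @ np.kron(np.eye(2), literal_coin(net))


def brute_local_index(net: Network, name: str, j: int, k: int) -> float:
    """Set-arithmetic recomputation of one local-index entry."""
    nj, nk = net.neighbor_sets[j], net.neighbor_sets[k]
    gamma = nj & nk
    cn = len(gamma)
    dj, dk = len(nj), len(nk)
    if name == "CN":
        return cn
    if name == "PA":
        return dj * dk
    if name == "Salton":
        return cn / np.sqrt(dj * dk) if dj and dk else 0.0
    if name == "Jaccard":
        union = len(nj | nk)
        return cn / union if union else 0.0
    if name == "Sorenson":
        return 2 * cn / (dj + dk) if dj + dk else 0.0
    if name == "HPI":
        m = min(dj, dk)
        return cn / m if m else 0.0
    if name == "HDI":
        m = max(dj, dk)
        return cn / m if m else 0.0
    if name == "AA":
        return sum(1 / np.log(len(net.neighbor_sets[z]))
                   for z in gamma if len(net.neighbor_sets[z]) > 1)
    if name == "RA":
        return sum(1 / len(net.neighbor_sets[z]) for z in gamma)
    raise ValueError(name)


def katz_series(net: Network, alpha: float, terms: int = 50) -> np.ndarray:
    """Truncated Neumann series sum_{l>=1} alpha^l A^l."""
    a = net.adjacency
    out = np.zeros_like(a)
    power = np.eye(net.num_nodes)
    coef = 1.0
    for _ in range(terms):
        power = power @ a
        coef *= alpha
        out += coef * power
    return out
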