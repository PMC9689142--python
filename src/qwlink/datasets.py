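"""Synthetic test networks and the packaged karate-club fixture.

Generators produce simple undirected graphs with controllable
common-neighbour structure; ``planted_partition`` graphs in particular
have dense blocks whose removed edges retain many common neighbours —
exactly the signal the similarity-based predictors exploit.  All
generation is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import Network

__all__ = [
    "GeneratorSpec",
    "generate",
    "erdos_renyi",
    "planted_partition",
    "small_world",
    "karate_fixture",
    "DEFAULT_PLANTED_SPEC",
]

MODELS = ("erdos_renyi", "planted_partition", "small_world")


@dataclass(frozen=True)
class GeneratorSpec:
    """Configuration for a synthetic network model."""

    model: str
    num_nodes: int
    edge_density: float | None = None  # erdos_renyi p; small_world rewiring p
    p_in: float | None = None
    p_out: float | None = None
    num_blocks: int | None = None
    ring_neighbors: int | None = None  # small_world: each node joins k nearest
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.num_nodes < 4:
            raise ValueError("num_nodes must be >= 4")
        for p in (self.edge_density, self.p_in, self.p_out):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


#: Default planted-partition benchmark: strong 4-block community structure
#: at a size where the full multi-algorithm benchmark runs in seconds.
DEFAULT_PLANTED_SPEC = GeneratorSpec(
    model="planted_partition",
    num_nodes=120,
    num_blocks=4,
    p_in=0.4,
    p_out=0.02,
    seed=0,
)


def generate(spec: GeneratorSpec) -> Network:
    """Build a Network from a GeneratorSpec (seed-deterministic)."""
    if spec.model == "erdos_renyi":
        p = 0.1 if spec.edge_density is None else spec.edge_density
        g = nx.gnp_random_graph(spec.num_nodes, p, seed=spec.seed)
    elif spec.model == "planted_partition":
        blocks = spec.num_blocks or 4
        if spec.num_nodes % blocks:
            raise ValueError("num_nodes must be divisible by num_blocks")
        g = nx.planted_partition_graph(
            blocks,
            spec.num_nodes // blocks,
            0.4 if spec.p_in is None else spec.p_in,
            0.02 if spec.p_out is None else spec.p_out,
            seed=spec.seed,
        )
    else:  # small_world
        k = spec.ring_neighbors or 4
        p = 0.1 if spec.edge_density is None else spec.edge_density
        g = nx.watts_strogatz_graph(spec.num_nodes, k, p, seed=spec.seed)
    return Network.from_networkx(g)


def erdos_renyi(num_nodes: int, p: float, seed: int | None = None) -> Network:
    return generate(GeneratorSpec("erdos_renyi", num_nodes, edge_density=p, seed=seed))


def planted_partition(
    num_nodes: int,
    num_blocks: int,
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> Network:
    return generate(
        GeneratorSpec(
            "planted_partition",
            num_nodes,
            num_blocks=num_blocks,
            p_in=p_in,
            p_out=p_out,
            seed=seed,
        )
    )


def small_world(
    num_nodes: int, ring_neighbors: int, rewire_p: float, seed: int | None = None
) -> Network:
    return generate(
        GeneratorSpec(
            "small_world",
            num_nodes,
            ring_neighbors=ring_neighbors,
            edge_density=rewire_p,
            seed=seed,
        )
    )


def karate_fixture() -> Network:
    """The canonical Zachary karate-club graph (34 nodes, 78 edges)."""
    return Network.from_networkx(nx.karate_club_graph())
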