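"""Seeded generators of anatomically structured test networks.

Two generators emulate the statistical structure the head analysis assumes:

* a planted-partition model (predefined blocks, within-block edge probability
  ``p_in``, between-block probability ``p_out``) — the standard benchmark for
  community recovery; and
* a bilateral variant producing mirrored left/right copies of the blocks with
  a tunable number of midline connector edges between mirror-image node pairs,
  mimicking the contrast between side-split orofacial modules and a single
  midline-bridged upper-face module.

Tissue labels are decorative (sampled by ``tissue_mix``) and never influence
edge placement; they exist so tissue subsetting can be exercised.  All
randomness flows from a single :func:`numpy.random.default_rng` stream per
call, so a fixed seed reproduces the exact edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .community_detection import ParameterError
from .network_model import AnatomicalNetwork, ConnectionRecord, NodeRecord, build_network


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-module / bilateral network generator."""

    block_sizes: tuple[int, ...]
    p_in: float = 0.9
    p_out: float = 0.02
    tissue_mix: float = 0.75
    bilateral: bool = False
    midline_edges: int = 0
    midline_blocks: tuple[int, ...] | None = None  # block indices; None = all
    seed: int = 0

    def __post_init__(self):
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ParameterError("block_sizes must be non-empty positive integers")
        for name in ("p_in", "p_out", "tissue_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.midline_edges < 0:
            raise ParameterError("midline_edges must be non-negative")

    @property
    def n_nodes(self) -> int:
        total = sum(self.block_sizes)
        return 2 * total if self.bilateral else total


def _tissue_labels(rng: np.random.Generator, n: int, tissue_mix: float) -> list[str]:
    return ["muscle" if u < tissue_mix else "bone" for u in rng.random(n)]


def _sample_block_edges(
    rng: np.random.Generator, blocks: Sequence[Sequence[int]],
    p_in: float, p_out: float,
) -> list[tuple[int, int]]:
    block_of = {}
    for b, members in enumerate(blocks):
        for u in members:
            block_of[u] = b
    nodes = sorted(block_of)
    edges = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            p = p_in if block_of[u] == block_of[v] else p_out
            if p > 0 and rng.random() < p:
                edges.append((u, v))
    return edges


def generate_planted_network(
    spec: SyntheticSpec,
) -> tuple[AnatomicalNetwork, dict[int, int]]:
    """Sample a planted-partition network; returns (network, node -> block truth).

    Each within-block pair is an edge independently with probability ``p_in``,
    each between-block pair with ``p_out``.  Node ids are 1..n, blocks are
    contiguous id ranges in the order given.
    """
    if spec.bilateral:
        raise ParameterError("spec.bilateral is set; use generate_bilateral_network")
    rng = np.random.default_rng(spec.seed)
    blocks: list[list[int]] = []
    nid = 1
    for size in spec.block_sizes:
        blocks.append(list(range(nid, nid + size)))
        nid += size
    truth = {u: b for b, members in enumerate(blocks) for u in members}
    tissues = _tissue_labels(rng, nid - 1, spec.tissue_mix)
    nodes = [
        NodeRecord(u, f"unit-{u}", tissues[u - 1], "median")
        for u in range(1, nid)
    ]
    edges = [
        ConnectionRecord(u, v)
        for u, v in _sample_block_edges(rng, blocks, spec.p_in, spec.p_out)
    ]
    return build_network(nodes, edges), truth


def generate_bilateral_network(
    spec: SyntheticSpec,
) -> tuple[AnatomicalNetwork, dict[int, tuple[int, str]]]:
    """Sample mirrored left/right copies of the planted blocks plus midline edges.

    Left nodes get ids 1..n, the mirror-image right nodes n+1..2n; each side's
    edges are sampled independently with the same block probabilities.  Exactly
    ``midline_edges`` distinct connectors are then drawn uniformly among the
    cross-side pairs of the designated midline blocks (all blocks by default):
    any left node may connect to any right node of the same block.  Truth maps
    node -> (block index, side).
    """
    if not spec.bilateral:
        raise ParameterError("spec.bilateral is not set; use generate_planted_network")
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.block_sizes)
    blocks: list[list[int]] = []
    nid = 1
    for size in spec.block_sizes:
        blocks.append(list(range(nid, nid + size)))
        nid += size

    midline_blocks = (
        tuple(range(len(blocks))) if spec.midline_blocks is None else spec.midline_blocks
    )
    if any(b < 0 or b >= len(blocks) for b in midline_blocks):
        raise ParameterError(f"midline_blocks out of range: {midline_blocks}")
    # connectors may join any left node to any right node of the same midline
    # block (the strict mirror pair u-u' included), so a block of size s offers
    # s^2 candidate midline contacts
    cross_pairs = sorted(
        (u, v + n) for b in midline_blocks for u in blocks[b] for v in blocks[b]
    )
    if spec.midline_edges > len(cross_pairs):
        raise ParameterError(
            f"midline_edges={spec.midline_edges} exceeds the "
            f"{len(cross_pairs)} available cross-side pairs of the midline blocks"
        )

    tissues = _tissue_labels(rng, n, spec.tissue_mix)
    nodes = [
        NodeRecord(u, f"unit-{u} left", tissues[u - 1], "left") for u in range(1, n + 1)
    ] + [
        NodeRecord(u + n, f"unit-{u} right", tissues[u - 1], "right")
        for u in range(1, n + 1)
    ]
    left_edges = _sample_block_edges(rng, blocks, spec.p_in, spec.p_out)
    right_edges = [
        (u + n, v + n) for u, v in _sample_block_edges(rng, blocks, spec.p_in, spec.p_out)
    ]
    chosen = rng.choice(len(cross_pairs), size=spec.midline_edges, replace=False)
    midline = [cross_pairs[i] for i in sorted(chosen)]

    edges = [ConnectionRecord(u, v) for u, v in left_edges + right_edges + midline]
    truth: dict[int, tuple[int, str]] = {}
    for b, members in enumerate(blocks):
        for u in members:
            truth[u] = (b, "left")
            truth[u + n] = (b, "right")
    return build_network(nodes, edges), truth
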