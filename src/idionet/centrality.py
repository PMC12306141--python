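"""Strength and bridge centrality for contemporaneous and temporal networks.

Six statistics per node: contemporaneous strength and bridge strength
(undirected network), and temporal InStrength, OutStrength, bridge
InStrength, bridge OutStrength (directed network). Bridge variants restrict
the sums to edges crossing between the two pre-defined communities (ED vs
SUI), so a high bridge value flags a symptom linking eating pathology and
suicidality.

Default conventions: sums are of absolute edge weights, and temporal
self-loops (autoregressive edges) are excluded from In/OutStrength — an
effect of a symptom on its own future is not influence on other symptoms.
A signed "expected influence" variant and self-loop inclusion are available
behind flags, and the chosen conventions travel with the output table.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .data import Community, EMAValidationError
from .gvar import NetworkPair

__all__ = [
    "BridgeDirection",
    "strength",
    "in_out_strength",
    "bridge_strength",
    "centrality_table",
    "STATISTICS",
]

STATISTICS = [
    "contemporaneous_strength",
    "contemporaneous_bridge_strength",
    "in_strength",
    "out_strength",
    "bridge_in_strength",
    "bridge_out_strength",
]


class BridgeDirection(str, Enum):
    UNDIRECTED = "undirected"
    INCOMING = "incoming"
    OUTGOING = "outgoing"


def _node_index(nodes: list[str], node: str) -> int:
    try:
        return nodes.index(node)
    except ValueError:
        raise EMAValidationError(f"node {node!r} not in network {nodes}")


def _mass(weights: np.ndarray, signed: bool) -> float:
    return float(np.sum(weights) if signed else np.sum(np.abs(weights)))


def strength(pair: NetworkPair, node: str, signed: bool = False) -> float:
    """Contemporaneous strength: sum of |edge weights| incident to the node."""
    i = _node_index(pair.nodes, node)
    row = np.delete(pair.contemporaneous[i], i)
    return _mass(row, signed)


def in_out_strength(
    pair: NetworkPair, node: str, signed: bool = False, include_self_loops: bool = False
) -> tuple[float, float]:
    """Temporal (InStrength, OutStrength): incoming / outgoing |weight| sums.

    ``temporal[i, j]`` is the edge j -> i, so incoming edges of node i are
    row i and outgoing edges are column i.
    """
    i = _node_index(pair.nodes, node)
    incoming = pair.temporal[i, :].copy()
    outgoing = pair.temporal[:, i].copy()
    if not include_self_loops:
        incoming = np.delete(incoming, i)
        outgoing = np.delete(outgoing, i)
    return _mass(incoming, signed), _mass(outgoing, signed)


def bridge_strength(
    pair: NetworkPair,
    partition: Mapping[str, Community],
    node: str,
    direction: BridgeDirection = BridgeDirection.UNDIRECTED,
    signed: bool = False,
) -> float:
    """Strength restricted to edges crossing into the other community."""
    unmapped = [n for n in pair.nodes if n not in partition]
    if unmapped:
        raise EMAValidationError(f"nodes missing from community partition: {unmapped}")
    i = _node_index(pair.nodes, node)
    own = Community(partition[node])
    other = np.array([Community(partition[n]) is not own for n in pair.nodes])
    other[i] = False  # a node never bridges to itself
    direction = BridgeDirection(direction)
    if direction is BridgeDirection.UNDIRECTED:
        weights = pair.contemporaneous[i, other]
    elif direction is BridgeDirection.INCOMING:
        weights = pair.temporal[i, other]
    else:
        weights = pair.temporal[other, i]
    return _mass(weights, signed)


def centrality_table(
    pair: NetworkPair,
    partition: Mapping[str, Community],
    signed: bool = False,
    include_self_loops: bool = False,
) -> pd.DataFrame:
    """All six statistics per node, raw and z-scored across nodes.

    z-columns (suffix ``_z``) standardize each statistic over the nodes with
    the n-1 denominator, matching how centrality profiles are usually
    plotted; a constant column gets z = 0.
    """
    rows = []
    for node in pair.nodes:
        in_s, out_s = in_out_strength(pair, node, signed, include_self_loops)
        rows.append(
            {
                "node": node,
                "community": Community(partition[node]).value,
                "contemporaneous_strength": strength(pair, node, signed),
                "contemporaneous_bridge_strength": bridge_strength(
                    pair, partition, node, BridgeDirection.UNDIRECTED, signed
                ),
                "in_strength": in_s,
                "out_strength": out_s,
                "bridge_in_strength": bridge_strength(
                    pair, partition, node, BridgeDirection.INCOMING, signed
                ),
                "bridge_out_strength": bridge_strength(
                    pair, partition, node, BridgeDirection.OUTGOING, signed
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    for stat in STATISTICS:
        values = table[stat].to_numpy()
        sd = values.std(ddof=1) if len(values) > 1 else 0.0
        table[f"{stat}_z"] = 0.0 if sd == 0 else (values - values.mean()) / sd
    table.attrs["signed"] = signed
    table.attrs["include_self_loops"] = include_self_loops
    return table
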