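import numpy as np
import pytest

from idionet.centrality import (
    STATISTICS,
    BridgeDirection,
    bridge_strength,
    centrality_table,
    in_out_strength,
    strength,
)
from idionet.data import Community, EMAValidationError
from idionet.gvar import NetworkPair


def make_pair(contemporaneous, temporal, nodes):
    return NetworkPair(
        contemporaneous=np.asarray(contemporaneous, dtype=float),
        temporal=np.asarray(temporal, dtype=float),
        nodes=list(nodes),
    )


def random_pair(seed, p=8):
    rng = np.random.default_rng(seed)
    C = rng.uniform(-0.6, 0.6, (p, p)) * (rng.random((p, p)) < 0.5)
    C = (C + C.T) / 2
    np.fill_diagonal(C, 0.0)
    T = rng.uniform(-0.8, 0.8, (p, p)) * (rng.random((p, p)) < 0.5)
    nodes = [f"n{i}" for i in range(p)]
    partition = {n: (Community.ED if i < p // 2 else Community.SUI) for i, n in enumerate(nodes)}
    return make_pair(C, T, nodes), partition


def test_three_node_toy_strength():
    C = [[0, 0.5, -0.3], [0.5, 0, 0], [-0.3, 0, 0]]
    pair = make_pair(C, np.zeros((3, 3)), ["a", "b", "c"])
    assert strength(pair, "a") == pytest.approx(0.8)
    assert strength(pair, "b") == pytest.approx(0.5)


def test_empty_network_all_strengths_zero():
    pair = make_pair(np.zeros((3, 3)), np.zeros((3, 3)), ["a", "b", "c"])
    for node in pair.nodes:
        assert strength(pair, node) == 0.0
        assert in_out_strength(pair, node) == (0.0, 0.0)


def test_single_directed_edge_in_out():
    T = np.zeros((2, 2))
    T[1, 0] = 0.4  # a -> b
    pair = make_pair(np.zeros((2, 2)), T, ["a", "b"])
    assert in_out_strength(pair, "a") == (0.0, pytest.approx(0.4))
    assert in_out_strength(pair, "b") == (pytest.approx(0.4), 0.0)


def test_pure_autoregressive_network_has_zero_in_out():
    pair = make_pair(np.zeros((3, 3)), np.diag([0.5, 0.3, 0.9]), ["a", "b", "c"])
    for node in pair.nodes:
        assert in_out_strength(pair, node) == (0.0, 0.0)
    in_with, out_with = in_out_strength(pair, "a", include_self_loops=True)
    assert in_with == out_with == pytest.approx(0.5)


def test_bridge_restricted_to_inter_community_edges():
    C = [[0, 0.4, 0.2], [0.4, 0, 0], [0.2, 0, 0]]
    pair = make_pair(C, np.zeros((3, 3)), ["a", "b", "c"])
    partition = {"a": Community.ED, "b": Community.ED, "c": Community.SUI}
    assert bridge_strength(pair, partition, "a") == pytest.approx(0.2)
    assert strength(pair, "a") == pytest.approx(0.6)


def test_disconnected_communities_have_zero_bridge():
    C = [[0, 0.7], [0.7, 0]]
    pair = make_pair(C, np.zeros((2, 2)), ["a", "b"])
    partition = {"a": Community.ED, "b": Community.ED}
    # no SUI nodes at all: nothing can bridge
    assert bridge_strength(pair, partition, "a") == 0.0


@pytest.mark.parametrize("seed", range(20))
def test_statistics_match_brute_force_oracles(seed):
    pair, partition = random_pair(seed)
    p = len(pair.nodes)
    for i, node in enumerate(pair.nodes):
        s = sum(abs(pair.contemporaneous[i, j]) for j in range(p) if j != i)
        assert strength(pair, node) == pytest.approx(s, abs=1e-12)
        in_s, out_s = in_out_strength(pair, node)
        assert in_s == pytest.approx(
            sum(abs(pair.temporal[i, j]) for j in range(p) if j != i), abs=1e-12
        )
        assert out_s == pytest.approx(
            sum(abs(pair.temporal[j, i]) for j in range(p) if j != i), abs=1e-12
        )
        other = [j for j in range(p) if partition[pair.nodes[j]] != partition[node]]
        assert bridge_strength(pair, partition, node) == pytest.approx(
            sum(abs(pair.contemporaneous[i, j]) for j in other), abs=1e-12
        )
        assert bridge_strength(pair, partition, node, BridgeDirection.OUTGOING) == pytest.approx(
            sum(abs(pair.temporal[j, i]) for j in other), abs=1e-12
        )


@pytest.mark.parametrize("seed", range(10))
def test_global_conservation_and_bridge_bounds(seed):
    pair, partition = random_pair(seed + 100)
    table = centrality_table(pair, partition)
    assert table.in_strength.sum() == pytest.approx(table.out_strength.sum(), abs=1e-12)
    assert table.bridge_in_strength.sum() == pytest.approx(
        table.bridge_out_strength.sum(), abs=1e-12
    )
    assert (table[STATISTICS] >= 0).all().all()
    assert (table.contemporaneous_bridge_strength <= table.contemporaneous_strength + 1e-12).all()
    assert (table.bridge_in_strength <= table.in_strength + 1e-12).all()
    assert (table.bridge_out_strength <= table.out_strength + 1e-12).all()


def test_community_relabeling_leaves_bridge_values_unchanged():
    pair, partition = random_pair(7)
    swapped = {
        n: (Community.SUI if c is Community.ED else Community.ED) for n, c in partition.items()
    }
    for node in pair.nodes:
        for direction in BridgeDirection:
            assert bridge_strength(pair, partition, node, direction) == pytest.approx(
                bridge_strength(pair, swapped, node, direction), abs=1e-15
            )


def test_table_is_complete_and_self_consistent():
    pair, partition = random_pair(42)
    table = centrality_table(pair, partition)
    assert list(table.index) == pair.nodes
    for node in pair.nodes:
        assert table.loc[node, "contemporaneous_strength"] == pytest.approx(strength(pair, node))
        in_s, out_s = in_out_strength(pair, node)
        assert table.loc[node, "in_strength"] == pytest.approx(in_s)
        assert table.loc[node, "out_strength"] == pytest.approx(out_s)
    # z-columns exist for plotting parity and are standardized
    for stat in STATISTICS:
        z = table[f"{stat}_z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)


def test_unknown_node_and_unmapped_partition_errors():
    pair, partition = random_pair(3)
    with pytest.raises(EMAValidationError, match="not in network"):
        strength(pair, "nope")
    del partition[pair.nodes[0]]
    with pytest.raises(EMAValidationError, match="missing from community partition"):
        bridge_strength(pair, partition, pair.nodes[1])


from hypothesis import given, settings, strategies as st


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=6))
def test_conservation_holds_for_arbitrary_directed_networks(seed, half_p):
    """Total incoming and outgoing strength balance for any temporal network,
    overall and restricted to inter-community edges."""
    pair, partition = random_pair(seed, p=2 * half_p)
    table = centrality_table(pair, partition)
    assert table.in_strength.sum() == pytest.approx(table.out_strength.sum(), abs=1e-10)
    assert table.bridge_in_strength.sum() == pytest.approx(
        table.bridge_out_strength.sum(), abs=1e-10
    )


def test_signed_variant_sums_raw_weights():
    C = [[0, 0.5, -0.3], [0.5, 0, 0], [-0.3, 0, 0]]
    pair = make_pair(C, np.zeros((3, 3)), ["a", "b", "c"])
    assert strength(pair, "a", signed=True) == pytest.approx(0.2)
    assert strength(pair, "a", signed=False) == pytest.approx(0.8)
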