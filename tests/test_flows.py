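import itertools

import numpy as np
import pandas as pd
import pytest

from geneflows import (
    ConditionSeries,
    FlowPattern,
    MembershipTensor,
    combined_gene_membership,
    compute_flows,
    enumerate_paths,
    export_sankey,
    flow_weights,
    path_membership,
    select_flows,
    top_genes,
)
from geneflows.flows import per_cluster_membership
from geneflows.fuzzify import triangular_memberships

from conftest import random_tensor

LEVELS4 = ("NotExpressed", "Low", "Medium", "High")


def make_tensor(mu_values, levels=None):
    """Tensor from explicit per-(gene, cluster, condition) level memberships."""
    mu = np.asarray(mu_values, dtype=float)
    n_genes, n_clusters, n_conditions, n_levels = mu.shape
    return MembershipTensor(
        mu=mu,
        genes=[f"g{i:03d}" for i in range(n_genes)],
        clusters=[f"c{i}" for i in range(n_clusters)],
        conditions=ConditionSeries(tuple(f"t{i}" for i in range(n_conditions))),
        levels=levels or tuple(f"L{i}" for i in range(n_levels)),
    )


# ---------------------------------------------------------------------------
# enumeration


def test_enumerate_paths_counts_and_order():
    assert len(enumerate_paths(4, 3)) == 64
    assert enumerate_paths(2, 2) == [(0, 0), (0, 1), (1, 0), (1, 1)]


def test_enumerate_paths_cap():
    with pytest.raises(ValueError, match="cap"):
        enumerate_paths(4, 11, cap=10 ** 6)


# ---------------------------------------------------------------------------
# path membership


def test_path_membership_hand_product():
    mu = np.zeros((1, 1, 2, 4))
    mu[0, 0, 0] = [0.2, 0.8, 0.0, 0.0]
    mu[0, 0, 1] = [0.0, 0.0, 0.3, 0.7]
    tensor = make_tensor(mu, levels=LEVELS4)
    value = path_membership(tensor, "g000", "c0", (1, 3))
    assert value == pytest.approx(0.8 * 0.7)


def test_crisp_memberships_select_exactly_one_path():
    mu = np.zeros((1, 1, 3, 3))
    crisp_path = (2, 0, 1)
    for t, l in enumerate(crisp_path):
        mu[0, 0, t, l] = 1.0
    tensor = make_tensor(mu)
    for path in enumerate_paths(3, 3):
        expected = 1.0 if path == crisp_path else 0.0
        for combiner in ("product", "min"):
            assert path_membership(tensor, "g000", "c0", path, combiner) == expected


def test_zero_membership_annihilates_path():
    mu = np.zeros((1, 1, 2, 2))
    mu[0, 0, 0] = [1.0, 0.0]
    mu[0, 0, 1] = [0.5, 0.5]
    tensor = make_tensor(mu)
    for combiner in ("product", "min"):
        assert path_membership(tensor, "g000", "c0", (1, 1), combiner) == 0.0


# ---------------------------------------------------------------------------
# flow weights


def test_flow_weights_crisp_two_genes():
    mu = np.zeros((2, 1, 2, 2))
    mu[:, 0, 0, 0] = 1.0
    mu[:, 0, 1, 1] = 1.0
    tensor = make_tensor(mu)
    weights = flow_weights(tensor, "c0")
    assert weights[(0, 1)] == 2.0
    assert weights.drop(index=[(0, 1)]).eq(0).all()


def test_factorized_weights_equal_bruteforce_enumeration():
    tensor = random_tensor(200, 1, 3, 3, seed=9)
    weights = flow_weights(tensor, "c0")
    for path in enumerate_paths(3, 3):
        brute = sum(
            path_membership(tensor, g, "c0", path) for g in tensor.genes
        )
        assert weights[path] == pytest.approx(brute, abs=1e-12)


def test_flow_weight_conservation_identity():
    tensor = random_tensor(150, 2, 3, 4, seed=10)
    for cluster in tensor.clusters:
        weights = flow_weights(tensor, cluster)
        assert abs(weights.sum() - tensor.n_genes) <= 1e-9 * tensor.n_genes


def test_per_gene_membership_over_all_paths_is_one():
    tensor = random_tensor(20, 1, 3, 3, seed=11)
    paths = enumerate_paths(3, 3)
    table = per_cluster_membership(tensor, paths)
    np.testing.assert_allclose(table["c0"], 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# pattern selection


@pytest.mark.parametrize(
    "direction,min_final,n_levels,n_conditions,expected",
    [
        ("final_above_all_prior", "Medium", 4, 3, 13),
        ("final_above_all_prior", "High", 4, 2, 3),
        ("constant", None, 4, 3, 4),
        ("any", None, 3, 2, 9),
    ],
)
def test_select_flow_counts(direction, min_final, n_levels, n_conditions, expected):
    pattern = FlowPattern(direction=direction, min_final_level=min_final)
    selected = select_flows(pattern, n_levels, n_conditions, levels=LEVELS4)
    assert len(selected) == expected


def test_select_flows_matches_exhaustive_predicate_check():
    pattern = FlowPattern(direction="final_above_all_prior", min_final_level=2)
    selected = set(select_flows(pattern, 4, 3))
    oracle = {
        p for p in itertools.product(range(4), repeat=3)
        if p[-1] >= 2 and all(p[-1] > l for l in p[:-1])
    }
    assert selected == oracle


def test_monotone_directions():
    nondec = select_flows(FlowPattern(direction="nondecreasing"), 3, 3)
    noninc = select_flows(FlowPattern(direction="nonincreasing"), 3, 3)
    assert all(a <= b for p in nondec for a, b in zip(p, p[1:]))
    assert all(a >= b for p in noninc for a, b in zip(p, p[1:]))
    assert set(nondec) & set(noninc) == {(0, 0, 0), (1, 1, 1), (2, 2, 2)}


# ---------------------------------------------------------------------------
# combined membership and ranking


def test_combined_membership_crisp_gene_on_selected_path():
    mu = np.zeros((1, 2, 3, 4))
    for c in range(2):
        for t, l in enumerate((0, 0, 3)):
            mu[0, c, t, l] = 1.0
    tensor = make_tensor(mu, levels=LEVELS4)
    pattern = FlowPattern(direction="final_above_all_prior", min_final_level="Medium")
    selected = select_flows(pattern, 4, 3, levels=LEVELS4)
    combined = combined_gene_membership(tensor, selected, scope="all_clusters")
    assert combined["g000"] == pytest.approx(1.0)


def test_all_clusters_scope_takes_minimum():
    tensor = random_tensor(10, 3, 2, 3, seed=12)
    paths = [(0, 1), (0, 2)]
    table = per_cluster_membership(tensor, paths)
    combined = combined_gene_membership(tensor, paths, scope="all_clusters")
    np.testing.assert_allclose(combined, table.min(axis=1))
    single = combined_gene_membership(tensor, paths, scope="c1")
    np.testing.assert_allclose(single, table["c1"])


def test_scope_any_dominates_scope_all():
    tensor = random_tensor(50, 4, 3, 3, seed=13)
    paths = select_flows(FlowPattern(direction="nondecreasing"), 3, 3)
    m_all = combined_gene_membership(tensor, paths, scope="all_clusters")
    m_any = combined_gene_membership(tensor, paths, scope="any_cluster")
    assert (m_any >= m_all - 1e-12).all()


def test_selected_plus_complement_partition_unity():
    tensor = random_tensor(40, 2, 3, 3, seed=14)
    all_paths = enumerate_paths(3, 3)
    selected = all_paths[:10]
    complement = all_paths[10:]
    total = (per_cluster_membership(tensor, selected)
             + per_cluster_membership(tensor, complement))
    np.testing.assert_allclose(total.to_numpy(), 1.0, atol=1e-12)


def test_empty_selection_is_error():
    tensor = random_tensor(5, 1, 2, 2, seed=15)
    with pytest.raises(ValueError, match="empty"):
        combined_gene_membership(tensor, [])


def test_top_genes_tie_break_and_overflow():
    m = pd.Series({"C": 0.9, "B": 0.1, "A": 0.9})
    ranked = top_genes(m, 2)
    assert ranked["gene"].tolist() == ["A", "C"]
    assert len(top_genes(m, 10)) == 3


def test_increasing_final_expression_never_decreases_membership():
    """A gene's membership in final-above-all-prior flows is monotone in its
    final-condition expression (on a grid of inputs)."""
    anchors = (0.0, 1.0, 2.0, 4.0)
    pattern = FlowPattern(direction="final_above_all_prior", min_final_level="Medium")
    selected = select_flows(pattern, 4, 3, levels=LEVELS4)
    prior = triangular_memberships(np.array([0.5, 0.8]), anchors)
    grid = np.linspace(0, 5, 101)
    values = []
    for x in grid:
        mu = np.concatenate([prior, triangular_memberships(np.array([x]), anchors)])
        tensor = make_tensor(mu[None, None, :, :], levels=LEVELS4)
        values.append(combined_gene_membership(tensor, selected, scope="c0")["g000"])
    assert (np.diff(values) >= -1e-12).all()


# ---------------------------------------------------------------------------
# compute_flows and sankey export


def test_compute_flows_weight_table(small_profile):
    from geneflows import fit_fuzzy_spec, fuzzify

    mu = fuzzify(small_profile, fit_fuzzy_spec(small_profile))
    pattern = FlowPattern(min_final_level="Medium")
    result = compute_flows(mu, pattern)
    totals = result.weights.groupby("cluster")["weight"].sum()
    np.testing.assert_allclose(totals, mu.n_genes, rtol=1e-12)
    assert result.weights["selected"].sum() == len(result.selected_paths) * 3
    assert result.membership.between(0, 1 + 1e-12).all()


def test_sankey_throughput_and_marginalization():
    tensor = random_tensor(60, 1, 3, 4, seed=16)
    doc = export_sankey(tensor, "c0")
    nodes = pd.DataFrame(doc["nodes"])
    links = pd.DataFrame(doc["links"])
    by_condition = nodes.groupby("condition")["throughput"].sum()
    np.testing.assert_allclose(by_condition, tensor.n_genes, atol=1e-9)
    outgoing = links.groupby("source")["weight"].sum()
    for _, node in nodes.iterrows():
        if node["condition"] == tensor.conditions.labels[-1]:
            continue  # the last condition has no outgoing links
        np.testing.assert_allclose(
            outgoing[node["id"]], node["throughput"], atol=1e-9
        )


def test_sankey_crisp_single_gene_is_unit_chain():
    mu = np.zeros((1, 1, 3, 3))
    for t, l in enumerate((0, 1, 2)):
        mu[0, 0, t, l] = 1.0
    tensor = make_tensor(mu)
    doc = export_sankey(tensor, "c0", selected_paths=[(0, 1, 2)])
    links = [l for l in doc["links"] if l["weight"] > 0]
    assert len(links) == 2
    assert all(l["weight"] == 1.0 and l["selected"] for l in links)
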