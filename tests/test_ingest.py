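import numpy as np
import pandas as pd
import pytest

from geneflows import (
    AdtMatrix,
    ConditionSeries,
    ExpressionMatrix,
    call_cells,
    downsample_and_pool,
    generate_adt_mixture,
    pseudobulk,
    read_expression,
    read_gmt,
    umi_filter,
    write_expression,
)
from geneflows.ingest import background_quantile_thresholds, normalize_counts

from conftest import simple_expression


# ---------------------------------------------------------------------------
# readers


def test_dense_csv_read_back(tmp_path):
    path = tmp_path / "counts.csv"
    path.write_text("gene,cellA,cellB\ng1,5,0\ng2,0,3\ng3,1,1\n")
    em = read_expression(path)
    assert em.gene_ids == ["g1", "g2", "g3"]
    assert em.cell_ids == ["cellA", "cellB"]
    np.testing.assert_array_equal(em.dense(), [[5, 0], [0, 3], [1, 1]])


def test_mtx_triplet_matches_dense(tmp_path):
    d = tmp_path / "mtx"
    d.mkdir()
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n2 2 2\n1 1 5\n2 2 3\n"
    )
    (d / "features.tsv").write_text("g1\ng2\n")
    (d / "barcodes.tsv").write_text("c1\nc2\n")
    em = read_expression(d)
    np.testing.assert_array_equal(em.dense(), [[5, 0], [0, 3]])


def test_negative_count_is_error_not_clamp(tmp_path):
    path = tmp_path / "neg.csv"
    path.write_text("gene,c1\ng1,-2\n")
    with pytest.raises(ValueError, match="negative"):
        read_expression(path)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        ExpressionMatrix(counts=np.zeros((2, 1), dtype=int),
                         gene_ids=["g1", "g1"], cell_ids=["c1"])


@pytest.mark.parametrize("fmt", ["mtx", "csv"])
def test_write_read_roundtrip_exact(tmp_path, fmt):
    rng = np.random.default_rng(0)
    em = simple_expression(rng.poisson(2.0, size=(20, 15)))
    target = tmp_path / ("out" if fmt == "mtx" else "out.csv")
    write_expression(em, target, format=fmt)
    back = read_expression(target, format=fmt)
    np.testing.assert_array_equal(back.dense(), em.dense())
    assert back.gene_ids == em.gene_ids and back.cell_ids == em.cell_ids


def test_mtx_orientation_autodetected(tmp_path):
    d = tmp_path / "mtx"
    d.mkdir()
    # stored cells x genes: 2 cells, 3 genes
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n2 3 2\n1 3 7\n2 1 4\n"
    )
    (d / "features.tsv").write_text("g1\ng2\ng3\n")
    (d / "barcodes.tsv").write_text("c1\nc2\n")
    em = read_expression(d)
    np.testing.assert_array_equal(em.dense(), [[0, 4], [0, 0], [7, 0]])


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("S1\tdesc\tA\tB\tA\nS2\tother\tC\n")
    with pytest.warns(UserWarning, match="duplicate"):
        coll = read_gmt(path)
    assert len(coll) == 2
    assert coll["S1"] == {"A", "B"}

    bad = tmp_path / "bad.gmt"
    bad.write_text("S1\tdesc\tA\nS2\tdesc\n")
    with pytest.raises(ValueError, match="bad.gmt:2"):
        read_gmt(bad)


# ---------------------------------------------------------------------------
# cell calling


def test_call_cells_all_zero_matrix_calls_nothing():
    adt = AdtMatrix(counts=np.zeros((2, 5), dtype=int),
                    antibody_ids=["CD45", "MHC1"], cell_ids=[f"c{i}" for i in range(5)])
    mask = call_cells(adt, ["CD45", "MHC1"], {"CD45": 1, "MHC1": 1})
    assert not mask.any()


def test_call_cells_recovers_stained_population():
    adt, labels = generate_adt_mixture(seed=3)
    thresholds = background_quantile_thresholds(adt, ["CD45", "MHC1"], ~labels, 0.99)
    mask = call_cells(adt, ["CD45", "MHC1"], thresholds)
    assert (mask != labels).mean() <= 0.01


def test_call_cells_monotone_in_thresholds():
    adt, labels = generate_adt_mixture(n_stained=100, n_background=100, seed=5)
    base = {"CD45": 5.0, "MHC1": 5.0}
    mask = call_cells(adt, ["CD45", "MHC1"], base)
    for ab in ["CD45", "MHC1"]:
        for bump in [1, 10, 50]:
            higher = dict(base, **{ab: base[ab] + bump})
            raised = call_cells(adt, ["CD45", "MHC1"], higher)
            assert not (raised & ~mask).any(), "raising a threshold added a cell"


def test_call_cells_missing_antibody_is_config_error():
    adt = AdtMatrix(counts=np.ones((1, 3), dtype=int),
                    antibody_ids=["CD45"], cell_ids=["a", "b", "c"])
    with pytest.raises(ValueError, match="absent"):
        call_cells(adt, ["CD45", "MHC1"], {"CD45": 1, "MHC1": 1})


def test_low_rna_high_antibody_cell_kept_by_calling_not_by_umi():
    """Antibody calling rescues a transcriptionally quiet cell that the
    conventional 100-UMI cutoff would discard."""
    rng = np.random.default_rng(0)
    counts = rng.poisson(5, size=(50, 10))
    counts[:, 0] = 0
    counts[0, 0] = 50  # total RNA = 50 < 100
    rna = simple_expression(counts)
    adt = AdtMatrix(counts=np.full((2, 10), 120, dtype=int),
                    antibody_ids=["CD45", "MHC1"], cell_ids=rna.cell_ids)
    called = call_cells(adt, ["CD45", "MHC1"], {"CD45": 10, "MHC1": 10})
    kept = umi_filter(rna, 100)
    assert called[0] and not kept[0]


# ---------------------------------------------------------------------------
# UMI filter


def test_umi_filter_boundary_inclusive():
    counts = np.zeros((1, 3), dtype=int)
    counts[0] = [99, 100, 101]
    mask = umi_filter(simple_expression(counts), 100)
    assert mask.tolist() == [False, True, True]


def test_umi_filter_cutoff_one_keeps_everything_nonzero():
    rng = np.random.default_rng(1)
    counts = rng.poisson(3, size=(30, 40)) + 1  # no all-zero columns
    assert umi_filter(simple_expression(counts), 1).all()


def test_umi_filter_matches_per_cell_recount():
    rng = np.random.default_rng(2)
    counts = rng.poisson(1.0, size=(80, 200))
    rna = simple_expression(counts)
    cutoff = 75
    mask = umi_filter(rna, cutoff)
    oracle = np.array([sum(counts[g, j] for g in range(80)) >= cutoff
                       for j in range(200)])
    np.testing.assert_array_equal(mask, oracle)


# ---------------------------------------------------------------------------
# downsampling


def test_downsample_pool_exact_size_and_sample_ids():
    rng = np.random.default_rng(0)
    sizes = [30, 5, 100, 17]
    tables = [
        pd.DataFrame({"sample_id": f"s{i}", "value": rng.normal(size=n)})
        for i, n in enumerate(sizes)
    ]
    cap = 20
    with pytest.warns(UserWarning):
        pooled = downsample_and_pool(tables, cap, seed=7)
    assert len(pooled) == sum(min(cap, n) for n in sizes)
    assert set(pooled["sample_id"]) == {f"s{i}" for i in range(4)}
    assert (pooled["sample_id"] == "s1").sum() == 5  # small sample kept whole


def test_downsample_pool_is_deterministic():
    tables = [pd.DataFrame({"sample_id": "s0", "value": np.arange(50)})]
    a = downsample_and_pool(tables, 10, seed=3)
    b = downsample_and_pool(tables, 10, seed=3)
    pd.testing.assert_frame_equal(a, b)
    c = downsample_and_pool(tables, 10, seed=4)
    assert not a["value"].equals(c["value"])


def test_downsample_pool_empty_input_is_error():
    with pytest.raises(ValueError):
        downsample_and_pool([], 10, seed=0)


# ---------------------------------------------------------------------------
# pseudobulk


def _annotation(cell_ids, clusters, conditions):
    return pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": "s0",
        "condition": conditions,
        "cluster": clusters,
    })


def test_pseudobulk_singleton_group():
    counts = np.array([[0, 4], [2, 0]])
    rna = simple_expression(counts)
    ann = _annotation(rna.cell_ids, ["k", "k"], ["t0", "t1"])
    profile = pseudobulk(rna, ann, ConditionSeries(("t0", "t1")))
    norm = normalize_counts(counts)
    np.testing.assert_allclose(profile.mean_expr[("k", "t0")], norm[:, 0])
    assert set(profile.frac_expr.to_numpy().ravel()) <= {0.0, 1.0}
    assert profile.n_cells[("k", "t0")] == 1


def test_pseudobulk_fraction_expressing():
    counts = np.array([[0, 4]])
    rna = simple_expression(counts)
    ann = _annotation(rna.cell_ids, ["k", "k"], ["t0", "t0"])
    # a second condition is required for a series; give it one cell too
    counts = np.array([[0, 4, 1]])
    rna = simple_expression(counts)
    ann = _annotation(rna.cell_ids, ["k", "k", "k"], ["t0", "t0", "t1"])
    profile = pseudobulk(rna, ann, ConditionSeries(("t0", "t1")))
    assert profile.frac_expr[("k", "t0")].iloc[0] == 0.5


def test_pseudobulk_matches_bruteforce_oracle():
    """Group means equal an independently coded normalize-then-average loop."""
    rng = np.random.default_rng(3)
    counts = rng.poisson(2.0, size=(40, 50))
    rna = simple_expression(counts)
    clusters = rng.choice(["a", "b"], size=50)
    conditions = rng.choice(["t0", "t1"], size=50)
    ann = _annotation(rna.cell_ids, clusters, conditions)
    profile = pseudobulk(rna, ann, ConditionSeries(("t0", "t1")))

    for cl in ["a", "b"]:
        for cond in ["t0", "t1"]:
            member = np.flatnonzero((clusters == cl) & (conditions == cond))
            per_cell = []
            for j in member:
                total = counts[:, j].sum()
                per_cell.append(np.log1p(counts[:, j] * (10_000.0 / total)))
            oracle = np.mean(per_cell, axis=0)
            np.testing.assert_allclose(
                profile.mean_expr[(cl, cond)].to_numpy(), oracle, atol=1e-12
            )


def test_pseudobulk_invariant_to_cell_order():
    rng = np.random.default_rng(4)
    counts = rng.poisson(1.0, size=(30, 60))
    rna = simple_expression(counts)
    clusters = rng.choice(["a", "b"], size=60)
    conditions = rng.choice(["t0", "t1"], size=60)
    ann = _annotation(rna.cell_ids, clusters, conditions)
    series = ConditionSeries(("t0", "t1"))
    profile = pseudobulk(rna, ann, series)

    perm = rng.permutation(60)
    rna2 = ExpressionMatrix(counts=counts[:, perm],
                            gene_ids=rna.gene_ids,
                            cell_ids=[rna.cell_ids[j] for j in perm])
    profile2 = pseudobulk(rna2, ann, series)
    pd.testing.assert_frame_equal(profile.mean_expr, profile2.mean_expr)


def test_pseudobulk_unknown_condition_is_error():
    rna = simple_expression(np.ones((2, 2), dtype=int))
    ann = _annotation(rna.cell_ids, ["k", "k"], ["t0", "weird"])
    with pytest.raises(ValueError, match="not in the declared series"):
        pseudobulk(rna, ann, ConditionSeries(("t0", "t1")))
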