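"""CLR transform, MB neighborhood selection, StARS, SparCC and correlation nets."""

import numpy as np
import pandas as pd
import pytest

from mdmnet.community import CommunityTable
from mdmnet.inference import (
    StARSConfig,
    build_network,
    clr_transform,
    correlation_network,
    mb_neighborhoods,
    pearson_correlation,
    sparcc,
    stars_select,
    stars_select_matrix,
    symmetrize,
    _standardize,
)
from mdmnet.synthetic import (
    CommunitySpec,
    _cov2cor,
    _planted_adjacency,
    _precision_from_adjacency,
    generate_community,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# CLR


def test_clr_constant_sample_is_zero():
    table = make_table([[1], [1], [1], [1]])
    clr = clr_transform(table, pseudocount=7.0)
    assert np.allclose(clr.values, 0.0)


def test_clr_hand_computed_values():
    table = make_table([[1], [2], [4]])
    clr = clr_transform(table, pseudocount=0.0)
    assert clr.values[0] == pytest.approx([-np.log(2), 0.0, np.log(2)])


def test_clr_rows_sum_to_zero_and_scale_invariance(rng):
    counts = rng.integers(1, 200, size=(12, 30))
    table = make_table(counts)
    clr = clr_transform(table, pseudocount=1.0)
    assert np.allclose(clr.values.sum(axis=1), 0.0, atol=1e-9 * 12)
    # per-sample rescaling of positive counts leaves CLR unchanged at pc=0
    scaled = make_table(counts * 7)
    a = clr_transform(table, pseudocount=0.0).values
    b = clr_transform(scaled, pseudocount=0.0).values
    assert np.allclose(a, b)


def test_clr_zero_pseudocount_requires_positive_counts():
    with pytest.raises(ValueError):
        clr_transform(make_table([[0], [1]]), pseudocount=0.0)


# ---------------------------------------------------------------------------
# MB neighborhoods


def _clr_of(counts, pc=1.0):
    return clr_transform(make_table(counts), pseudocount=pc)


def test_full_shrinkage_above_max_correlation(rng):
    counts = rng.integers(1, 100, size=(6, 80))
    clr = _clr_of(counts)
    xs = _standardize(clr.values)
    corr = xs.T @ xs / xs.shape[0]
    np.fill_diagonal(corr, 0)
    lam = np.abs(corr).max() * 1.0001
    assert all(len(s) == 0 for s in mb_neighborhoods(clr, lam))


def test_coupled_pair_selected_independent_column_not(rng):
    n = 200
    z = rng.standard_normal(n)
    x = np.column_stack([z, z + 1e-3 * rng.standard_normal(n), rng.standard_normal(n)])
    from mdmnet.inference import CLRMatrix

    clr = CLRMatrix(x, ["a", "b", "c"], [f"s{i}" for i in range(n)], 0.0)
    neigh = mb_neighborhoods(clr, lam=0.2)
    assert neigh[0] == {1} and neigh[1] == {0}
    assert neigh[2] == set()


def test_supports_nested_on_orthogonal_design():
    # orthonormal predictors: lasso is coordinate-wise soft-thresholding,
    # so supports shrink monotonically as the penalty grows
    rng = np.random.default_rng(3)
    q, _ = np.linalg.qr(rng.standard_normal((40, 5)))
    x = q * np.sqrt(40)
    from mdmnet.inference import CLRMatrix

    clr = CLRMatrix(x @ np.diag([1, 1, 1, 1, 1.0]) + 0.3 * rng.standard_normal((40, 5)),
                    list("abcde"), [f"s{i}" for i in range(40)], 0.0)
    small = mb_neighborhoods(clr, lam=0.05)
    large = mb_neighborhoods(clr, lam=0.2)
    for s_small, s_large in zip(small, large):
        assert s_large <= s_small


def test_mb_rejects_nonfinite():
    from mdmnet.inference import CLRMatrix

    clr = CLRMatrix(np.array([[1.0, np.nan], [0.0, 1.0]]), ["a", "b"], ["s", "t"], 1.0)
    with pytest.raises(ValueError):
        mb_neighborhoods(clr, 0.1)


def test_symmetrize_rules(rng):
    assert symmetrize([{1}, set()], "or") == {(0, 1)}
    assert symmetrize([{1}, set()], "and") == set()
    sym_neigh = [{1}, {0}]
    assert symmetrize(sym_neigh, "or") == symmetrize(sym_neigh, "and")
    neigh = [set(rng.choice(8, size=rng.integers(0, 4), replace=False)) - {j}
             for j in range(8)]
    assert symmetrize(neigh, "and") <= symmetrize(neigh, "or")
    with pytest.raises(ValueError):
        symmetrize(sym_neigh, "xor")


# ---------------------------------------------------------------------------
# StARS


def test_stars_degenerate_variability_selects_densest_penalty():
    # identical samples: zero subsampling variability, D(lambda) = 0 everywhere,
    # so the smallest penalty in the path is selected
    counts = np.tile(np.array([[3], [9], [1], [27]]), (1, 40))
    table = make_table(counts)
    cfg = StARSConfig(lambda_path=np.array([0.5, 0.25, 0.1]), seed=0)
    net = stars_select(table, cfg)
    assert net.lambda_ == pytest.approx(0.1)
    assert net.instability == 0.0
    assert not net.stars_warning


def test_stars_independent_noise_yields_near_empty_graphs():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        counts = np.exp(rng.normal(3, 1, size=(10, 500))).astype(int) + 1
        net = stars_select(make_table(counts), StARSConfig(seed=seed))
        assert len(net.edges) <= 2


def test_stars_instability_bounds_and_monotone_path():
    spec = CommunitySpec(n_taxa=20, n_samples=120, depth=5000, seed=4)
    table, _ = generate_community(spec)
    net = stars_select(table, StARSConfig(seed=4))
    d = np.asarray(net.provenance["instability_path"])
    assert ((0 <= d) & (d <= 0.5)).all()
    assert (np.diff(d) >= -1e-12).all()  # monotonized, nondecreasing toward density
    assert net.instability <= 0.05


def test_mb_recovers_gaussian_hub_graph():
    """Graph recovery on Gaussian draws from a known sparse precision matrix."""
    f1s = []
    for seed in range(5):
        spec = CommunitySpec(seed=seed)
        rng = np.random.default_rng(seed)
        adj = _planted_adjacency(spec, rng)
        core = np.zeros(50, dtype=bool)
        core[: spec.n_hubs] = True
        omega = _precision_from_adjacency(adj, spec.edge_strength, core=core)
        chol = np.linalg.cholesky(_cov2cor(np.linalg.inv(omega)))
        z = rng.standard_normal((400, 50)) @ chol.T
        edges_idx, info = stars_select_matrix(z, StARSConfig(seed=seed))
        true = {(i, j) for i in range(50) for j in range(i + 1, 50) if adj[i, j]}
        tp = len(edges_idx & true)
        prec = tp / len(edges_idx) if edges_idx else 0.0
        rec = tp / len(true)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    assert np.mean(f1s) >= 0.7


# ---------------------------------------------------------------------------
# SparCC


def test_sparcc_symmetric_unit_diagonal(rng):
    counts = rng.integers(0, 300, size=(6, 40))
    corr = sparcc(make_table(counts), n_iterations=3, seed=0)
    r = corr.to_numpy()
    assert np.allclose(r, r.T)
    assert np.allclose(np.diag(r), 1.0)
    assert (np.abs(r) <= 1.0 + 1e-12).all()


def test_sparcc_requires_four_taxa(rng):
    with pytest.raises(ValueError):
        sparcc(make_table(rng.integers(1, 10, size=(3, 20))))


def test_sparcc_independent_components_near_zero():
    rng = np.random.default_rng(11)
    comp = np.exp(rng.normal(0, 1, size=(20, 500)))
    counts = np.floor(comp / comp.sum(axis=0) * 50_000).astype(int)
    corr = sparcc(make_table(counts), n_iterations=5, seed=1).to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert np.abs(corr).max() < 0.15


def test_sparcc_planted_covarying_pair_is_strongest():
    rng = np.random.default_rng(12)
    base = rng.normal(0, 1, size=(8, 400))
    base[1] = base[0]  # perfectly co-varying pair on the log scale
    comp = np.exp(base)
    counts = np.floor(comp / comp.sum(axis=0) * 100_000).astype(int)
    corr = sparcc(make_table(counts), n_iterations=5, seed=2).to_numpy()
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    assert {i, j} == {0, 1}


# ---------------------------------------------------------------------------
# Correlation networks


def _corr_df(matrix, ids):
    return pd.DataFrame(matrix, index=ids, columns=ids)


def test_threshold_edge_cases(rng):
    ids = list("abcde")
    r = rng.uniform(-0.9, 0.9, size=(5, 5))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    assert len(correlation_network(_corr_df(r, ids), 1.0).edges) == 0
    complete = correlation_network(_corr_df(r, ids), 0.0)
    assert len(complete.edges) == 10


def test_correlation_network_matches_elementwise_scan(rng):
    ids = list("abcde")
    r = rng.uniform(-1, 1, size=(5, 5))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    net = correlation_network(_corr_df(r, ids), 0.3)
    expected = {
        tuple(sorted((ids[i], ids[j])))
        for i in range(5)
        for j in range(i + 1, 5)
        if abs(r[i, j]) >= 0.3
    }
    assert net.edges == expected
    for (u, v), w in net.weights.items():
        assert w == pytest.approx(r[ids.index(u), ids.index(v)])


def test_correlation_network_rejects_asymmetry():
    r = np.eye(3)
    r[0, 1] = 0.5
    with pytest.raises(ValueError):
        correlation_network(_corr_df(r, list("abc")), 0.3)


def test_pearson_network_matches_bruteforce_thresholding(rng):
    counts = rng.integers(0, 50, size=(8, 60))
    table = make_table(counts)
    corr, pvals = pearson_correlation(table)
    net = build_network(table, "pearson", threshold=0.25, alpha=0.05)
    r, pv = corr.to_numpy(), pvals.to_numpy()
    ids = table.otu_ids
    expected = {
        tuple(sorted((ids[i], ids[j])))
        for i in range(8)
        for j in range(i + 1, 8)
        if abs(r[i, j]) >= 0.25 and pv[i, j] <= 0.05
    }
    assert net.edges == expected


# ---------------------------------------------------------------------------
# Dispatch and accounting


def test_build_network_dispatch_identity():
    spec = CommunitySpec(n_taxa=15, n_samples=60, depth=3000, seed=9)
    table, _ = generate_community(spec)
    direct = stars_select(table, StARSConfig(seed=5))
    wrapped = build_network(table, "mb", seed=5)
    assert wrapped.edges == direct.edges
    assert wrapped.lambda_ == direct.lambda_
    with pytest.raises(ValueError):
        build_network(table, "glasso")


def test_report_accounting(rng):
    spec = CommunitySpec(n_taxa=15, n_samples=60, depth=3000, seed=9)
    table, _ = generate_community(spec)
    net = build_network(table, "pearson", threshold=0.3)
    report = net.report()
    assert report["connected_nodes"] <= report["selected_nodes"]
    assert report["edge_node_ratio"] == pytest.approx(
        report["edges"] / report["connected_nodes"]
    )
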