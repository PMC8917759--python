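"""Signed-hybrid weighted co-expression network: bicor, soft threshold,
TOM, module detection, trait statistics and direct edges."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oysteriap import synth
from oysteriap.config import NetworkConfig
from oysteriap.network import (adjacency, bicor, bicor_matrix, build_network,
                               detect_modules, extract_direct_edges,
                               module_trait_significance, pick_soft_threshold,
                               tom_similarity)


def _bicor_reference(x, y):
    """Independent direct evaluation of the biweight midcorrelation."""
    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        a = (v - med) * w
        return a / np.sqrt((a ** 2).sum())
    return float(transform(x) @ transform(y))


# ---------------------------------------------------------------------------
# bicor

def test_bicor_self_and_antisymmetry():
    x = np.random.default_rng(0).standard_normal(20)
    assert bicor(x, x) == pytest.approx(1.0)
    assert bicor(x, -x) == pytest.approx(-1.0)


def test_bicor_matches_direct_formula_on_100_pairs():
    rng = np.random.default_rng(1)
    for _ in range(100):
        x = rng.standard_normal(20)
        y = 0.4 * x + rng.standard_normal(20)
        assert abs(bicor(x, y) - _bicor_reference(x, y)) <= 1e-10


def test_bicor_matrix_matches_pairwise():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((6, 25))
    C = bicor_matrix(X)
    for i in range(6):
        for j in range(6):
            expected = 1.0 if i == j else _bicor_reference(X[i], X[j])
            assert C[i, j] == pytest.approx(expected, abs=1e-10)


def test_bicor_constant_gene_reports_zero_with_warning():
    X = np.vstack([np.ones(10), np.random.default_rng(3).standard_normal(10)])
    with pytest.warns(RuntimeWarning, match="constant gene"):
        C = bicor_matrix(X)
    assert C[0, 1] == 0.0 and C[0, 0] == 1.0


def test_bicor_requires_four_samples():
    with pytest.raises(ValueError, match="4 samples"):
        bicor_matrix(np.ones((3, 3)))


def test_bicor_approaches_pearson_on_clean_gaussian_data():
    rng = np.random.default_rng(4)
    for _ in range(20):
        x = rng.standard_normal(500)
        y = 0.6 * x + 0.8 * rng.standard_normal(500)
        assert abs(bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05


# ---------------------------------------------------------------------------
# Adjacency

def test_adjacency_signed_hybrid_rules():
    cor = np.array([[1.0, -0.9], [-0.9, 1.0]])
    A = adjacency(cor, 9)
    assert A[0, 1] == 0.0 and A[0, 0] == 1.0
    cor1 = np.array([[1.0, 1.0], [1.0, 1.0]])
    assert adjacency(cor1, 9)[0, 1] == 1.0


def test_adjacency_matches_elementwise_oracle():
    rng = np.random.default_rng(5)
    cor = np.clip(rng.uniform(-1, 1, (15, 15)), -1, 1)
    cor = (cor + cor.T) / 2
    np.fill_diagonal(cor, 1.0)
    A = adjacency(cor, 6)
    for i in range(15):
        for j in range(15):
            want = 1.0 if i == j else \
                (cor[i, j] ** 6 if cor[i, j] > 0 else 0.0)
            assert A[i, j] == pytest.approx(want)


def test_adjacency_bounds_and_symmetry():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((30, 12))
    A = adjacency(np.asarray(bicor_matrix(X)), 9)
    assert np.allclose(A, A.T)
    assert (A >= 0).all() and (A <= 1).all()
    assert np.allclose(np.diag(A), 1.0)


# ---------------------------------------------------------------------------
# Soft threshold

def test_fallback_power_for_small_noisy_designs():
    expr, _trait, _labels = synth.gen_expression(100, 20, (), seed=1)
    beta, table = pick_soft_threshold(expr)
    assert beta == 9
    assert table.attrs.get("fallback") is True
    assert (table["signed_r2"] < 0.8).all()


def test_soft_threshold_matches_independent_fit_oracle():
    # rank-one correlation with heavy-tailed (Pareto) loadings: hubby
    # connectivity that reaches a scale-free fit at a moderate power
    rng = np.random.default_rng(7)
    v = np.clip(rng.pareto(2.0, 300) + 0.01, 0, None)
    v = v / v.max()
    cor = np.outer(v, v)
    np.fill_diagonal(cor, 1.0)
    cfg = NetworkConfig()
    beta, table = pick_soft_threshold(cor=cor, n_samples=25, cfg=cfg)

    def oracle_fit(k):
        k = k[k > 0]
        logk = np.log10(k)
        edges = np.linspace(logk.min(), logk.max() + 1e-12, 11)
        idx = np.clip(np.digitize(logk, edges) - 1, 0, 9)
        xs, ys = [], []
        for b in range(10):
            m = idx == b
            if m.any():
                xs.append(np.log10(k[m].mean()))
                ys.append(np.log10(m.mean()))
        res = stats.linregress(xs, ys)
        return -np.sign(res.slope) * res.rvalue ** 2

    expected = None
    for power in cfg.candidate_powers:
        A = adjacency(cor, power)
        r2 = oracle_fit(A.sum(axis=0) - 1)
        if r2 >= cfg.scale_free_r2_min:
            expected = power
            break
    assert expected is not None
    assert beta == expected


def test_smallest_passing_power_wins_at_power_one():
    # log-connectivities drawn with exponentially decaying density: the
    # histogram is already power-law at beta = 1, so 1 must be selected
    rng = np.random.default_rng(8)
    v = np.minimum(10 ** (rng.exponential(0.6, 300) - 3.0), 1.0)
    cor = np.outer(v, v)
    np.fill_diagonal(cor, 1.0)
    beta, table = pick_soft_threshold(cor=cor, n_samples=40)
    assert beta == 1
    assert table.loc[table.power == 1, "signed_r2"].iloc[0] >= 0.8


def test_all_zero_connectivity_errors():
    cor = -np.ones((5, 5))
    np.fill_diagonal(cor, 1.0)
    with pytest.raises(ValueError, match="zero"):
        pick_soft_threshold(cor=cor, n_samples=10)


# ---------------------------------------------------------------------------
# TOM and modules

def test_tom_bounds_and_diagonal():
    rng = np.random.default_rng(9)
    A = adjacency(np.asarray(bicor_matrix(rng.standard_normal((40, 15)))), 6)
    tom = tom_similarity(A)
    assert (tom >= 0).all() and (tom <= 1).all()
    assert np.allclose(np.diag(tom), 1.0)
    assert np.allclose(tom, tom.T)


def test_two_planted_blocks_recovered_exactly():
    expr, _t, labels = synth.gen_expression(
        100, 30, (50, 50), within_correlation=0.9, seed=10)
    A = adjacency(np.asarray(bicor_matrix(expr)), 9)
    got, eigengenes = detect_modules(A, expr)
    # same partition: each planted block maps to exactly one detected label
    for block in (1, 2):
        detected = set(got[labels == block])
        assert len(detected) == 1 and detected != {0}
    assert len(eigengenes) == 2


def test_white_noise_leaves_all_genes_unassigned():
    expr, _t, _l = synth.gen_expression(100, 20, (), seed=11)
    A = adjacency(np.asarray(bicor_matrix(expr)), 9)
    labels, eigengenes = detect_modules(A, expr)
    assert (labels == 0).all()
    assert eigengenes.empty


def test_fewer_genes_than_min_module_size_unassigned():
    expr, _t, _l = synth.gen_expression(10, 20, (), seed=12)
    A = adjacency(np.asarray(bicor_matrix(expr)), 9)
    labels, _ = detect_modules(A, expr)
    assert (labels == 0).all()


# ---------------------------------------------------------------------------
# Module-trait significance

def _eigengene_frame(vectors, samples):
    return pd.DataFrame(
        {i + 1: v for i, v in enumerate(vectors)}, index=samples).T


def test_trait_equal_eigengene_is_significant():
    samples = [f"s{i}" for i in range(20)]
    trait = np.r_[np.zeros(10), np.ones(10)]
    eig = _eigengene_frame([(trait - trait.mean()) / trait.std()], samples)
    out = module_trait_significance(eig, trait)
    assert out.loc[1, "r"] == pytest.approx(1.0)
    assert out.loc[1, "p"] == pytest.approx(0.0, abs=1e-12)
    assert bool(out.loc[1, "significant"])


def test_orthogonal_eigengene_not_significant():
    rng = np.random.default_rng(13)
    trait = np.r_[np.zeros(10), np.ones(10)]
    e = rng.standard_normal(20)
    e -= e.mean()
    t_std = (trait - trait.mean())
    e -= (e @ t_std) / (t_std @ t_std) * t_std  # project out the trait
    out = module_trait_significance(
        _eigengene_frame([e], [f"s{i}" for i in range(20)]), trait)
    assert out.loc[1, "p"] > 0.9
    assert not bool(out.loc[1, "significant"])


def test_p_value_matches_t_distribution_oracle():
    rng = np.random.default_rng(14)
    n = 30
    trait = rng.standard_normal(n)
    eig = 0.7 * (trait - trait.mean()) / trait.std() + \
        np.sqrt(1 - 0.49) * rng.standard_normal(n)
    out = module_trait_significance(
        _eigengene_frame([eig], [f"s{i}" for i in range(n)]), trait)
    r_oracle, p_oracle = stats.pearsonr(eig, trait)
    assert out.loc[1, "r"] == pytest.approx(r_oracle, abs=1e-12)
    assert out.loc[1, "p"] == pytest.approx(p_oracle, abs=1e-8)


def test_membership_condition_gates_significance():
    samples = [f"s{i}" for i in range(20)]
    trait = np.r_[np.zeros(10), np.ones(10)]
    eig = _eigengene_frame([(trait - trait.mean()) / trait.std()], samples)
    out = module_trait_significance(eig, trait, iap_count={1: 0},
                                    apoptosis_count={1: 5})
    assert not bool(out.loc[1, "significant"])
    out = module_trait_significance(eig, trait, iap_count={1: 2},
                                    apoptosis_count={1: 1})
    assert not bool(out.loc[1, "significant"])  # needs > 1 apoptosis


def test_constant_trait_errors():
    eig = _eigengene_frame([np.arange(5.0)], list("abcde"))
    with pytest.raises(ValueError, match="constant trait"):
        module_trait_significance(eig, np.ones(5))


# ---------------------------------------------------------------------------
# Direct edges

def _adjacency_frame(values, genes):
    return pd.DataFrame(values, index=genes, columns=genes)


def test_direct_edges_inside_significant_module():
    genes = ["iap1", "apo1", "apo2"]
    A = _adjacency_frame(np.full((3, 3), 0.5), genes)
    edges = extract_direct_edges(
        A, np.array([1, 1, 1]), {1}, {"iap1"}, {"apo1", "apo2"})
    assert len(edges) == 2
    assert set(edges["partner_id"]) == {"apo1", "apo2"}


def test_direct_edges_threshold_filters_all():
    genes = ["iap1", "apo1"]
    A = _adjacency_frame(np.full((2, 2), 0.01), genes)
    edges = extract_direct_edges(
        A, np.array([1, 1]), {1}, {"iap1"}, {"apo1"})
    assert edges.empty


def test_direct_edges_require_significant_shared_module():
    genes = ["iap1", "apo1"]
    A = _adjacency_frame(np.full((2, 2), 0.9), genes)
    assert extract_direct_edges(
        A, np.array([1, 2]), {1, 2}, {"iap1"}, {"apo1"}).empty
    assert extract_direct_edges(
        A, np.array([1, 1]), set(), {"iap1"}, {"apo1"}).empty


@pytest.mark.parametrize("seed", range(3))
def test_direct_edges_match_double_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 30
    genes = [f"g{i}" for i in range(n)]
    A = rng.uniform(0, 1, (n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    labels = rng.integers(0, 3, n)
    significant = {1, 2}
    iap = {g for g in genes[:10] if rng.random() < 0.6}
    apo = {g for g in genes[10:] if rng.random() < 0.6}
    A_df = _adjacency_frame(A, genes)
    got = extract_direct_edges(A_df, labels, significant, iap, apo)
    cfg = NetworkConfig()
    oracle = set()
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            if gi in iap and gj in apo and gi != gj \
                    and labels[i] == labels[j] and labels[i] in significant \
                    and A[i, j] >= cfg.edge_adjacency_min:
                oracle.add((gi, gj))
    assert set(zip(got["iap_id"], got["partner_id"])) == oracle
    # gene-order invariance
    perm = rng.permutation(n)
    got2 = extract_direct_edges(
        A_df.iloc[perm, perm], labels[perm], significant, iap, apo)
    assert got.to_dict("records") == got2.to_dict("records")


# ---------------------------------------------------------------------------
# Full flow

def test_build_network_strong_module_yields_edges():
    expr, trait, _labels = synth.gen_expression(
        120, 20, (40,), within_correlation=0.8, trait_r=0.8, seed=15)
    iap = set(expr.index[:3])
    apo = set(expr.index[4:12])
    net = build_network(expr, trait, iap, apo)
    assert net.beta == 9
    assert (net.trait_stats["significant"]).any()
    assert len(net.edges) > 0
    assert set(net.edges["iap_id"]) <= iap
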