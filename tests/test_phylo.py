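"""Distances, NJ, GTR pruning, marginal root reconstruction, indels, RF."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from skbio import TreeNode

from l1forge import phylo
from l1forge.align import Msa

# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------


def test_k2p_closed_forms():
    assert phylo.k2p_from_counts(100, 0, 0) == 0.0
    d1 = phylo.k2p_from_counts(100, 10, 5)
    assert d1 == pytest.approx(-0.5 * np.log(0.75) - 0.25 * np.log(0.9),
                               abs=1e-12)
    assert d1 == pytest.approx(0.17018, abs=5e-6)
    d2 = phylo.k2p_from_counts(100, 0, 5)
    assert d2 == pytest.approx(0.05199, abs=5e-6)


def test_k2p_saturation_raises():
    with pytest.raises(phylo.SaturationError):
        phylo.k2p_from_counts(100, 50, 10)


def test_k2p_matrix_counts_transitions_and_gaps():
    # 10 columns; row b differs by 1 transition (A->G) and 1 transversion
    # (C->A); one column is gapped in b and must be excluded pairwise.
    a = "ACGTACGTAC"
    b = "GCGTAAGTA-"
    msa = Msa(ids=["a", "b"], rows=[a, b])
    dm = phylo.k2p_distance_matrix(msa)
    expect = phylo.k2p_from_counts(9, 1, 1)
    assert dm["a", "b"] == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def random_additive_tree(n_taxa: int, rng) -> TreeNode:
    """Random binary topology with branch lengths U(0.01, 0.3)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.01, 0.3))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(0.01, 0.3))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return TreeNode(children=nodes)


def tree_distance_matrix(tree: TreeNode):
    dm = tree.tip_tip_distances()
    return np.asarray(dm.data), list(dm.ids)


def test_nj_four_taxon_example():
    ids = ["A", "B", "C", "D"]
    d = np.full((4, 4), 0.5)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.2
    d[2, 3] = d[3, 2] = 0.2
    tree = phylo.neighbor_joining(d, ids)
    # topology ((A,B),(C,D)) with cherry branches 0.1
    assert phylo.robinson_foulds(
        tree, TreeNode.read(["((A:0.1,B:0.1):0.15,(C:0.1,D:0.1):0.15);"])) == 0
    for tip in tree.tips():
        if tip.name in ("A", "B"):
            assert tip.length == pytest.approx(0.1, abs=1e-12)


def test_nj_three_taxa_three_point_formulas():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
    tree = phylo.neighbor_joining(d, ["x", "y", "z"])
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["x"] == pytest.approx((0.3 + 0.5 - 0.4) / 2, abs=1e-12)
    assert lengths["y"] == pytest.approx((0.3 + 0.4 - 0.5) / 2, abs=1e-12)
    assert lengths["z"] == pytest.approx((0.5 + 0.4 - 0.3) / 2, abs=1e-12)


def test_nj_rejects_asymmetry():
    d = np.array([[0.0, 0.1, 0.2], [0.3, 0.0, 0.1], [0.2, 0.1, 0.0]])
    with pytest.raises(ValueError):
        phylo.neighbor_joining(d, ["a", "b", "c"])


# ---------------------------------------------------------------------------
# Pruning likelihood: enumeration oracle
# ---------------------------------------------------------------------------


def random_tree_and_alignment(rng, max_leaves=6, max_sites=20):
    n = int(rng.integers(3, max_leaves + 1))
    tree = random_additive_tree(n, rng)
    sites = int(rng.integers(2, max_sites + 1))
    rows = ["".join("ACGT"[i] for i in rng.integers(0, 4, sites))
            for _ in range(n)]
    msa = Msa(ids=[f"t{i}" for i in range(n)], rows=rows)
    return tree, msa


def enumeration_loglik(msa, tree, model):
    """Sum the likelihood over every explicit ancestral state assignment."""
    internals = [n for n in tree.traverse() if not n.is_tip()]
    leaves = {t.name: i for i, t in enumerate(tree.tips())}
    codes = msa.codes()
    row_of = {name: i for i, name in enumerate(msa.ids)}
    total = 0.0
    for col in range(codes.shape[1]):
        site_lik = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assign)}
            lik = model.base_freqs[state[id(tree)]]
            for node in tree.traverse(include_self=False):
                s_parent = state[id(node.parent)]
                if node.is_tip():
                    s_child = codes[row_of[node.name], col]
                    if s_child >= 4:
                        continue  # missing data marginalizes out
                else:
                    s_child = state[id(node)]
                P = model.transition_matrix(node.length or 0.0)
                lik *= P[s_parent, s_child]
            site_lik += lik
        total += np.log(site_lik)
    del leaves
    return total


def test_pruning_zero_branch_limit():
    msa = Msa(ids=["a", "b"], rows=["A", "A"])
    tree = TreeNode.read(["(a:0.0,b:0.0);"])
    ll = phylo.pruning_loglik(msa, tree, phylo.GtrModel.jc())
    assert ll == pytest.approx(np.log(0.25), abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_pruning_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    tree, msa = random_tree_and_alignment(rng, max_leaves=5, max_sites=8)
    model = phylo.GtrModel(base_freqs=(0.3, 0.2, 0.3, 0.2),
                           exchangeabilities=(1, 4, 1, 1.5, 4, 1))
    got = phylo.pruning_loglik(msa, tree, model)
    want = enumeration_loglik(msa, tree, model)
    assert got == pytest.approx(want, rel=1e-9)


def test_pruning_invariant_under_rerooting():
    rng = np.random.default_rng(42)
    tree, msa = random_tree_and_alignment(rng, max_leaves=6, max_sites=15)
    model = phylo.GtrModel(base_freqs=(0.3, 0.2, 0.3, 0.2),
                           exchangeabilities=(1, 4, 1, 1.5, 4, 1))
    ll = phylo.pruning_loglik(msa, tree, model)
    ll_mid = phylo.pruning_loglik(msa, tree.root_at_midpoint(), model)
    assert ll == pytest.approx(ll_mid, rel=1e-9)


# ---------------------------------------------------------------------------
# Marginal root posteriors
# ---------------------------------------------------------------------------


def test_marginal_root_three_leaf_star():
    msa = Msa(ids=["a", "b", "c"], rows=["A", "A", "C"])
    tree = TreeNode.read(["(a:0.1,b:0.1,c:0.1);"])
    model = phylo.GtrModel.jc()
    post = phylo.marginal_root_posteriors(msa, tree, model)[0]
    P = model.transition_matrix(0.1)
    want = np.array([0.25 * P[s, 0] * P[s, 0] * P[s, 1] for s in range(4)])
    want /= want.sum()
    np.testing.assert_allclose(post, want, rtol=1e-9)
    assert post.argmax() == 0  # A


def test_posteriors_sum_to_one():
    rng = np.random.default_rng(9)
    tree, msa = random_tree_and_alignment(rng)
    post = phylo.marginal_root_posteriors(msa, tree.root_at_midpoint())
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# GTR fitting
# ---------------------------------------------------------------------------


def simulate_on_tree(tree, model, n_sites, rng):
    seqs = {}

    def visit(node, parent_seq):
        if parent_seq is None:
            seq = rng.choice(4, size=n_sites, p=model.base_freqs)
        else:
            P = model.transition_matrix(node.length or 0.0)
            seq = np.array([rng.choice(4, p=P[s]) for s in parent_seq])
        if node.is_tip():
            seqs[node.name] = "".join("ACGT"[i] for i in seq)
        for child in node.children:
            visit(child, seq)

    visit(tree, None)
    return Msa(ids=list(seqs), rows=list(seqs.values()))


def test_fitted_gtr_never_worse_than_jc():
    rng = np.random.default_rng(12)
    tree = random_additive_tree(6, rng)
    truth = phylo.GtrModel(exchangeabilities=(1, 6, 1, 1, 6, 1))
    msa = simulate_on_tree(tree, truth, 1500, rng)
    fitted = phylo.fit_gtr(msa, tree)
    ll_fit = phylo.pruning_loglik(msa, tree, fitted)
    ll_jc = phylo.pruning_loglik(
        msa, tree, phylo.GtrModel(base_freqs=fitted.base_freqs))
    assert ll_fit >= ll_jc - 1e-9


def test_gtr_recovers_transition_bias():
    rng = np.random.default_rng(5)
    tree = random_additive_tree(6, rng)
    truth = phylo.GtrModel(exchangeabilities=(1, 4, 1, 1, 4, 1))
    msa = simulate_on_tree(tree, truth, 4000, rng)
    fitted = phylo.fit_gtr(msa, tree)
    ex = fitted.exchangeabilities
    ag, ct = ex[1], ex[4]
    transversions = [ex[0], ex[2], ex[3], ex[5]]
    assert min(ag, ct) > max(transversions)


# ---------------------------------------------------------------------------
# Indel reconstruction
# ---------------------------------------------------------------------------


def _block_msa(patterns: list[str]):
    """Rows with one 4-column internal block (X = present, - = gap),
    flanked by all-present anchors so the block gaps are internal."""
    rows = []
    for p in patterns:
        block = "ACGT" if p == "X" else "----"
        rows.append("AAAA" + block + "TTTT")
    return Msa(ids=[f"t{i}" for i in range(len(rows))], rows=rows)


def test_block_present_in_all_leaves_is_present():
    msa = _block_msa(["X"] * 6)
    tree = phylo.neighbor_joining(
        np.abs(np.subtract.outer(np.arange(6), np.arange(6))) * 0.05,
        msa.ids, midpoint_root=True)
    for method in ("parsimony", "ml"):
        presence = phylo.reconstruct_indels(msa, tree, method)
        assert presence.all()


def test_block_in_single_leaf_absent_under_parsimony():
    msa = _block_msa(["X"] + ["-"] * 9)
    d = np.full((10, 10), 0.2)
    np.fill_diagonal(d, 0.0)
    tree = phylo.neighbor_joining(d, msa.ids, midpoint_root=True)
    presence = phylo.reconstruct_indels(msa, tree, "parsimony")
    assert not presence[4:8].any()
    assert presence[:4].all() and presence[8:].all()


def test_ml_and_parsimony_can_disagree():
    # block present only in the leaf on a near-zero branch; two absent
    # leaves sit on very long branches. Parsimony counts 2-vs-1 and drops
    # the block; ML trusts the short-branch evidence.
    msa = _block_msa(["X", "-", "-"])
    tree = TreeNode.read(["((t0:0.0001,t1:4.0):1.0,t2:4.0);"])
    pars = phylo.reconstruct_indels(msa, tree, "parsimony")
    ml = phylo.reconstruct_indels(msa, tree, "ml")
    assert not pars[4:8].any()
    assert ml[4:8].all()


def test_terminal_gap_runs_are_missing_data():
    # 5'-truncated rows should not vote 'absent' at the root
    rows = ["ACGTACGTACGT",
            "----ACGTACGT",
            "------GTACGT",
            "--------ACGT"]
    msa = Msa(ids=["a", "b", "c", "d"], rows=rows)
    d = np.full((4, 4), 0.1)
    np.fill_diagonal(d, 0.0)
    tree = phylo.neighbor_joining(d, msa.ids, midpoint_root=True)
    for method in ("parsimony", "ml"):
        presence = phylo.reconstruct_indels(msa, tree, method)
        assert presence.all()


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------


def bipartitions(tree: TreeNode) -> set[frozenset]:
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            out.add(min(side, tips - side, key=sorted))
    return out


def test_rf_identical_and_nni():
    t1 = TreeNode.read(["((a,b),c,(d,e));"])
    assert phylo.robinson_foulds(t1, t1.copy()) == 0
    t2 = TreeNode.read(["((a,c),b,(d,e));"])  # one NNI away
    assert phylo.robinson_foulds(t1, t2) == 2


@pytest.mark.parametrize("seed", range(6))
def test_rf_matches_bipartition_enumeration(seed):
    rng = np.random.default_rng(seed)
    t1 = random_additive_tree(7, rng)
    t2 = random_additive_tree(7, rng)
    want = len(bipartitions(t1) ^ bipartitions(t2))
    assert phylo.robinson_foulds(t1, t2) == want


def test_rf_leafset_mismatch():
    t1 = TreeNode.read(["((a,b),c);"])
    t2 = TreeNode.read(["((a,b),d);"])
    with pytest.raises(ValueError):
        phylo.robinson_foulds(t1, t2)
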