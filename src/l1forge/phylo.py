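"""Phylogenetics and ancestral sequence reconstruction.

Given a multiple sequence alignment of L1 copies, this module estimates
Kimura 2-parameter distances, builds a neighbor-joining tree, fits a GTR
substitution model, computes the Felsenstein-pruning likelihood, and
reconstructs the marginal maximum-likelihood root sequence with per-site
posterior probabilities. Alignment gaps are handled as binary gap-block
characters reconstructed at the root under either Fitch parsimony or a
two-state reversible likelihood model, so each alignment yields two
candidate root sequences (one per indel method).

Trees are scikit-bio ``TreeNode`` objects throughout (newick I/O comes for
free); neighbor joining delegates to scikit-bio and Robinson–Foulds
comparison to dendropy behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from . import seqio

BASES = "ACGT"
# exchangeability order: AC, AG, AT, CG, CT, GT (AG and CT are transitions)
RATE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
TRANSITION_RATE_IDX = (1, 4)


class SaturationError(ValueError):
    """Raised when a K2P log argument is non-positive (distance undefined)."""


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------


def k2p_from_counts(n_sites: int, n_transitions: float, n_transversions: float
                    ) -> float:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    if n_sites <= 0:
        raise ValueError("no shared ungapped sites")
    P = n_transitions / n_sites
    Q = n_transversions / n_sites
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(f"saturated pair (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * np.log(a) - 0.25 * np.log(b)


def k2p_distance_matrix(msa, on_saturation: str = "raise",
                        cap: float = 5.0) -> DistanceMatrix:
    """Pairwise K2P distances over shared ungapped columns of an MSA.

    ``on_saturation`` is ``"raise"`` (a saturated pair is an error) or
    ``"cap"`` (saturated pairs get the distance ``cap``; useful when the
    matrix only guides tree building over possibly-degraded inputs).
    """
    codes = msa.codes()
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    d = np.zeros((n, n))
    valid = codes < 4
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            ns = int(shared.sum())
            if ns == 0:
                if on_saturation == "cap":
                    d[i, j] = d[j, i] = cap
                    continue
                raise ValueError(f"rows {i},{j} share no ungapped columns")
            a = codes[i][shared]
            b = codes[j][shared]
            diff = a != b
            transition = diff & (np.abs(a - b) == 2)  # A<->G, C<->T
            ts = int(transition.sum())
            tv = int(diff.sum()) - ts
            try:
                d[i, j] = d[j, i] = k2p_from_counts(ns, ts, tv)
            except SaturationError:
                if on_saturation != "cap":
                    raise
                d[i, j] = d[j, i] = cap
    return DistanceMatrix(d, ids=list(msa.ids))


# ---------------------------------------------------------------------------
# Neighbor joining / Robinson-Foulds
# ---------------------------------------------------------------------------


def neighbor_joining(dist, ids: list[str] | None = None,
                     midpoint_root: bool = False) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Accepts a skbio ``DistanceMatrix`` or a square symmetric ndarray plus
    ids. Negative branch lengths are clamped to zero with a warning.
    """
    if not isinstance(dist, DistanceMatrix):
        arr = np.asarray(dist, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if ids is None:
            ids = [f"t{i}" for i in range(arr.shape[0])]
        dist = DistanceMatrix(arr, ids=list(ids))
    tree = _skbio_nj(dist)
    n_neg = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_neg += 1
    if n_neg:
        warnings.warn(f"clamped {n_neg} negative NJ branch lengths to 0")
    if midpoint_root:
        tree = tree.root_at_midpoint()
    return tree


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric bipartition (Robinson-Foulds) distance between two trees.

    Trees are compared unrooted; delegates to dendropy's bipartition
    machinery."""
    import dendropy
    from dendropy.calculate import treecompare

    s1 = {t.name for t in t1.tips()}
    s2 = {t.name for t in t2.tips()}
    if s1 != s2:
        raise ValueError("trees have different leaf sets")
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=str(t1), schema="newick",
                           taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=str(t2), schema="newick",
                           taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return int(treecompare.symmetric_difference(d1, d2))


# ---------------------------------------------------------------------------
# GTR model
# ---------------------------------------------------------------------------


@dataclass
class GtrModel:
    """General time-reversible substitution model.

    ``base_freqs``: stationary distribution pi; ``exchangeabilities``: the 6
    symmetric rates in the order AC, AG, AT, CG, CT, GT. The rate matrix is
    scaled to one expected substitution per site at stationarity.
    """

    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))

    def __post_init__(self):
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if abs(self.base_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base_freqs must sum to 1")
        if np.any(self.exchangeabilities <= 0) or np.any(self.base_freqs <= 0):
            raise ValueError("rates and frequencies must be positive")
        self._build()

    def _build(self):
        pi = self.base_freqs
        Q = np.zeros((4, 4))
        for k, (i, j) in enumerate(RATE_PAIRS):
            Q[i, j] = self.exchangeabilities[k] * pi[j]
            Q[j, i] = self.exchangeabilities[k] * pi[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        self.rate_matrix = Q
        # eigendecomposition of the symmetrized matrix for stable expm
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._eigvals = w
        self._left = U / sq[:, None]       # D^{-1/2} U
        self._right = (U * sq[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); row-stochastic for t >= 0."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._eigvals * t)) @ self._right
        return np.clip(P, 0.0, None)

    @classmethod
    def jc(cls) -> "GtrModel":
        return cls()


# ---------------------------------------------------------------------------
# Pruning likelihood and marginal root reconstruction
# ---------------------------------------------------------------------------


def _compress_patterns(codes: np.ndarray):
    """Unique alignment columns: (patterns (nrows, npat), counts, inverse)."""
    cols, inverse, counts = np.unique(
        codes, axis=1, return_inverse=True, return_counts=True)
    return cols, counts.astype(float), inverse


def _leaf_partials(states: np.ndarray) -> np.ndarray:
    """(npat, 4) conditional likelihoods at a leaf; gaps = missing (ones)."""
    npat = states.shape[0]
    L = np.zeros((npat, 4))
    known = states < 4
    L[known, states[known]] = 1.0
    L[~known, :] = 1.0
    return L


def _root_partials(patterns: np.ndarray, tree: TreeNode, model: GtrModel):
    """Post-order pruning; returns (L_root (npat,4), log_scale (npat,))."""
    logscale = np.zeros(patterns.shape[1])
    for node in tree.postorder():
        if node.is_tip():
            continue
        L = np.ones((patterns.shape[1], 4))
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            P = model.transition_matrix(t)
            if child.is_tip():
                Lc = _leaf_partials(patterns[child._row])
            else:
                Lc = child._partial
            L = L * (Lc @ P.T)
        mx = L.max(axis=1)
        mx[mx == 0.0] = 1.0
        L = L / mx[:, None]
        logscale += np.log(mx)
        node._partial = L
    return tree._partial, logscale


def _attach_rows(tree: TreeNode, ids: list[str]) -> None:
    index = {name: i for i, name in enumerate(ids)}
    for tip in tree.tips():
        if tip.name not in index:
            raise ValueError(f"tree leaf {tip.name!r} not in alignment")
        tip._row = index[tip.name]


def pruning_loglik(msa, tree: TreeNode, model: GtrModel | None = None) -> float:
    """Felsenstein-pruning log-likelihood of the alignment on the tree."""
    model = model or GtrModel.jc()
    codes = msa.codes()
    patterns, counts, _ = _compress_patterns(codes)
    _attach_rows(tree, msa.ids)
    if tree.is_tip():
        raise ValueError("tree has a single node")
    Lr, logscale = _root_partials(patterns, tree, model)
    site = Lr @ model.base_freqs
    return float((counts * (np.log(site) + logscale)).sum())


def marginal_root_posteriors(msa, tree: TreeNode,
                             model: GtrModel | None = None) -> np.ndarray:
    """(ncols, 4) marginal posterior over root states per alignment column.

    The tree's current root is the reconstruction target; posterior is
    proportional to pi_s * L_s(root).
    """
    model = model or GtrModel.jc()
    codes = msa.codes()
    patterns, _, inverse = _compress_patterns(codes)
    _attach_rows(tree, msa.ids)
    Lr, _ = _root_partials(patterns, tree, model)
    post = Lr * model.base_freqs[None, :]
    norm = post.sum(axis=1, keepdims=True)
    norm[norm == 0.0] = 1.0
    post = post / norm
    return post[inverse]


# ---------------------------------------------------------------------------
# GTR fitting
# ---------------------------------------------------------------------------


def empirical_base_freqs(codes: np.ndarray) -> np.ndarray:
    counts = np.array([(codes == b).sum() for b in range(4)], dtype=float)
    counts += 1.0  # pseudocount guards degenerate alignments
    return counts / counts.sum()


def fit_gtr(msa, tree: TreeNode, n_sweeps: int = 2,
            max_fit_sites: int = 2000) -> GtrModel:
    """Fit a GTR model on a fixed tree.

    Base frequencies are empirical column frequencies; exchangeabilities are
    optimized by coordinate ascent (GT fixed at 1 for identifiability) on
    the pruning log-likelihood, which never decreases across accepted steps.
    For long alignments the rate optimization runs on a deterministic
    subsample of ``max_fit_sites`` columns — exchangeabilities are global
    parameters and stabilize well below that many sites.
    """
    codes = msa.codes()
    if len(np.unique(codes[codes < 4])) < 2:
        warnings.warn("alignment has <2 distinct states; returning JC")
        return GtrModel.jc()
    pi = empirical_base_freqs(codes)
    if max_fit_sites and codes.shape[1] > max_fit_sites:
        sel = np.random.default_rng(0).choice(codes.shape[1], max_fit_sites,
                                              replace=False)
        codes = codes[:, np.sort(sel)]
    patterns, counts, _ = _compress_patterns(codes)
    _attach_rows(tree, msa.ids)

    def loglik(rates: np.ndarray) -> float:
        model = GtrModel(base_freqs=pi, exchangeabilities=rates)
        Lr, logscale = _root_partials(patterns, tree, model)
        site = Lr @ model.base_freqs
        return float((counts * (np.log(np.maximum(site, 1e-300)) + logscale)).sum())

    rates = np.ones(6)
    best = loglik(rates)
    for _ in range(n_sweeps):
        for k in range(5):  # GT (index 5) fixed at 1
            def neg(logr, k=k):
                r = rates.copy()
                r[k] = np.exp(logr)
                return -loglik(r)

            res = minimize_scalar(neg, bounds=(-4.0, 4.0), method="bounded",
                                  options={"maxiter": 20, "xatol": 1e-3})
            if -res.fun > best:
                best = -res.fun
                rates[k] = np.exp(res.x)
    return GtrModel(base_freqs=pi, exchangeabilities=rates)


# ---------------------------------------------------------------------------
# Indel (gap-block) reconstruction
# ---------------------------------------------------------------------------


def _gap_states(msa) -> np.ndarray:
    """(nrows, ncols) int8: 1 = residue present, 0 = internal gap
    (deletion evidence), 2 = terminal gap run (missing data).

    Leading and trailing gap runs of a row come from 5' truncation or
    alignment edges, not from deletion events, so they carry no signal
    about ancestral presence."""
    rows = msa.rows
    ncols = len(rows[0])
    out = np.ones((len(rows), ncols), dtype=np.int8)
    for i, row in enumerate(rows):
        arr = np.frombuffer(row.encode(), dtype=np.uint8) == ord("-")
        out[i, arr] = 0
        j = 0
        while j < ncols and arr[j]:
            out[i, j] = 2
            j += 1
        j = ncols - 1
        while j >= 0 and arr[j]:
            out[i, j] = 2
            j -= 1
    return out


def _gap_blocks(states: np.ndarray):
    """Collapse contiguous columns with identical 3-state row patterns into
    blocks. Returns list of (col_slice, leaf_states (nrows,) int8)."""
    ncols = states.shape[1]
    blocks = []
    start = 0
    for c in range(1, ncols + 1):
        if c == ncols or not np.array_equal(states[:, c], states[:, start]):
            blocks.append((slice(start, c), states[:, start]))
            start = c
    return blocks


def _fitch_root(tree: TreeNode, leaf_state: dict[str, int]) -> int:
    """Fitch parsimony root state for one binary character.

    Leaf state 2 means missing data (the leaf allows either state);
    ambiguous root sets resolve to 'present' (state 1)."""
    def visit(node) -> frozenset:
        if node.is_tip():
            st = leaf_state[node.name]
            return frozenset((0, 1)) if st == 2 else frozenset((st,))
        sets = [visit(c) for c in node.children]
        inter = frozenset.intersection(*sets)
        if inter:
            return inter
        return frozenset.union(*sets)

    root_set = visit(tree)
    return 1 if 1 in root_set else 0


def _binary_pruning(tree: TreeNode, leaf_states: np.ndarray,
                    ids: list[str], rate: float):
    """Two-state symmetric pruning over gap-block characters.

    leaf_states: (nrows, nchar) in {0,1}. Returns (loglik, root posterior
    of state 1 per character)."""
    index = {name: i for i, name in enumerate(ids)}
    nchar = leaf_states.shape[1]

    def P(t):
        e = np.exp(-2.0 * rate * t)
        p_same = 0.5 + 0.5 * e
        return np.array([[p_same, 1 - p_same], [1 - p_same, p_same]])

    def visit(node):
        if node.is_tip():
            L = np.ones((nchar, 2))
            st = leaf_states[index[node.name]]
            known = st < 2  # state 2 = missing data
            L[known, :] = 0.0
            L[np.arange(nchar)[known], st[known]] = 1.0
            return L, np.zeros(nchar)
        L = np.ones((nchar, 2))
        scale = np.zeros(nchar)
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            Lc, sc = visit(child)
            L = L * (Lc @ P(t).T)
            scale += sc
        mx = L.max(axis=1)
        mx[mx == 0.0] = 1.0
        L /= mx[:, None]
        return L, scale + np.log(mx)

    Lr, scale = visit(tree)
    site = Lr.sum(axis=1) * 0.5
    ll = float((np.log(np.maximum(site, 1e-300)) + scale).sum())
    post1 = (0.5 * Lr[:, 1]) / np.maximum(site, 1e-300)
    return ll, post1


def reconstruct_indels(msa, tree: TreeNode, method: str = "ml") -> np.ndarray:
    """Root presence/absence per alignment column.

    Contiguous gap columns with identical row patterns are collapsed to one
    binary character; ``method`` is ``"parsimony"`` (Fitch) or ``"ml"``
    (two-state reversible model, single gain/loss rate fitted by likelihood,
    root posterior >= 0.5 means present).
    """
    if method not in ("ml", "parsimony"):
        raise ValueError("method must be 'ml' or 'parsimony'")
    ncols = len(msa.rows[0])
    states = _gap_states(msa)
    presence = np.ones(ncols, dtype=bool)
    blocks = _gap_blocks(states)
    # characters: blocks where some row is gapped or missing; blocks with
    # no residue evidence at all resolve to absent
    var_blocks = []
    for sl, st in blocks:
        if (st == 1).all():
            continue
        if not (st == 1).any():
            presence[sl] = False
            continue
        var_blocks.append((sl, st))
    if not var_blocks:
        return presence

    if method == "parsimony":
        for sl, leaf_st in var_blocks:
            smap = {name: int(leaf_st[i]) for i, name in enumerate(msa.ids)}
            presence[sl] = bool(_fitch_root(tree, smap))
        return presence

    leaf_states = np.array([[int(st[i]) for sl, st in var_blocks]
                            for i in range(len(msa.ids))], dtype=np.int8)

    def neg(logr):
        ll, _ = _binary_pruning(tree, leaf_states, msa.ids, np.exp(logr))
        return -ll

    res = minimize_scalar(neg, bounds=(-7.0, 3.0), method="bounded",
                          options={"maxiter": 30, "xatol": 1e-3})
    _, post1 = _binary_pruning(tree, leaf_states, msa.ids, np.exp(res.x))
    for (sl, _), p in zip(var_blocks, post1):
        presence[sl] = p >= 0.5
    return presence


# ---------------------------------------------------------------------------
# Full root reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AncestralReconstruction:
    """Reconstructed root sequence with per-site posteriors.

    ``kept_columns`` indexes the alignment columns that survived the
    high-gap-fraction filter; ``presence`` marks which of those the indel
    reconstruction keeps at the root. ``posteriors`` rows correspond to kept
    columns and each sums to 1.
    """

    root_sequence: str
    kept_columns: np.ndarray
    presence: np.ndarray
    posteriors: np.ndarray
    indel_method: str
    mean_max_posterior: float

    def __post_init__(self):
        if self.posteriors.size:
            s = self.posteriors.sum(axis=1)
            if not np.allclose(s, 1.0, atol=1e-9):
                raise ValueError("posteriors must sum to 1")


def marginal_root_reconstruction(msa, tree: TreeNode | None = None,
                                 model: GtrModel | None = None,
                                 indel_method: str = "ml",
                                 max_gap_frac: float = 0.9,
                                 fit_model: bool = True
                                 ) -> AncestralReconstruction:
    """Reconstruct the marginal maximum-likelihood root of an alignment.

    Pipeline: drop columns gapped in more than ``max_gap_frac`` of rows
    (alignment-edge artifacts from 5' truncation), build a midpoint-rooted
    NJ tree from K2P distances unless one is supplied, fit GTR, compute
    per-column root posteriors, reconstruct gap blocks with the requested
    indel method, and emit the argmax base at every root-present column.
    """
    from .align import Msa

    codes = msa.codes()
    gap_frac = (codes == 4).mean(axis=0)
    kept = np.where(gap_frac <= max_gap_frac)[0]
    sub = Msa(ids=list(msa.ids),
              rows=["".join(row[c] for c in kept) for row in msa.rows])

    if tree is None:
        dm = k2p_distance_matrix(sub, on_saturation="cap")
        tree = neighbor_joining(dm, midpoint_root=True)
    if model is None:
        model = fit_gtr(sub, tree) if fit_model else GtrModel.jc()

    post = marginal_root_posteriors(sub, tree, model)
    presence = reconstruct_indels(sub, tree, method=indel_method)
    ml_bases = post.argmax(axis=1)
    root_seq = "".join(BASES[b] for b, keep in zip(ml_bases, presence) if keep)
    maxp = post.max(axis=1)
    mean_max = float(maxp[presence].mean()) if presence.any() else 0.0
    return AncestralReconstruction(
        root_sequence=root_seq,
        kept_columns=kept,
        presence=presence,
        posteriors=post,
        indel_method=indel_method,
        mean_max_posterior=mean_max,
    )


def posteriors_table(rec: AncestralReconstruction):
    """Per-column posterior TSV-ready DataFrame (column, A, C, G, T, maxprob)."""
    import pandas as pd

    df = pd.DataFrame(rec.posteriors, columns=list(BASES))
    df.insert(0, "column", rec.kept_columns)
    df["maxprob"] = rec.posteriors.max(axis=1)
    df["present"] = rec.presence
    return df
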