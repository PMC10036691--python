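"""Branch-wise mutation spectra from ancestral reconstruction on a fixed tree.

Given a rooted tree of fixed topology and a (pre-masked) alignment, marginal
maximum-likelihood ancestral states are reconstructed under GTR+G via the
standard two-pass pruning algorithm (post-order conditional likelihoods,
pre-order "outside" likelihoods), with model parameters estimated by ML on
the fixed topology.  Each branch's substitutions — parent state vs child
state, column-wise — are then collapsed into the six strand-symmetric types

    C:G>T:A, A:T>G:C, C:G>A:T, C:G>G:C, A:T>T:A, A:T>C:G

(e.g. G>A and C>T both count as C:G>T:A).  Columns with a gap or ambiguous
base at either endpoint, or whose reconstructed state has posterior below a
cutoff, are skipped on that branch.  Branches with at least a minimum number
of substitutions (default 20) enter enrichment rankings and the Tukey HSD
comparison of type proportions.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COLLAPSED_TYPES: tuple[str, ...] = (
    "C:G>T:A", "A:T>G:C", "C:G>A:T", "C:G>G:C", "A:T>T:A", "A:T>C:G")

# base-level moves realizing each collapsed, strand-symmetric type
TYPE_MOVES: dict[str, dict[str, str]] = {
    "C:G>T:A": {"C": "T", "G": "A"},
    "A:T>G:C": {"A": "G", "T": "C"},
    "C:G>A:T": {"C": "A", "G": "T"},
    "C:G>G:C": {"C": "G", "G": "C"},
    "A:T>T:A": {"A": "T", "T": "A"},
    "A:T>C:G": {"A": "C", "T": "G"},
}

_CLASSIFY: dict[tuple[str, str], str] = {
    (src, dst): t for t, moves in TYPE_MOVES.items() for src, dst in moves.items()
}


def classify_substitution(parent: str, child: str) -> str | None:
    """Collapsed type of a parent->child base change, or None if not a change."""
    return _CLASSIFY.get((parent, child))


def node_name(node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def label_internal_nodes(tree) -> None:
    """Give every unlabeled internal node a stable name N1, N2, ... (preorder)."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            i += 1
            node.label = f"N{i}"


def load_tree(source: str) -> dendropy.Tree:
    """Parse a rooted newick tree (string or path)."""
    try:
        tree = dendropy.Tree.get(data=source, schema="newick")
    except Exception:
        tree = dendropy.Tree.get(path=source, schema="newick")
    label_internal_nodes(tree)
    return tree


# ---------------------------------------------------------------------------
# GTR + discrete-gamma machinery

@dataclasses.dataclass
class SubstitutionModelParams:
    """GTR exchangeabilities (AC, AG, AT, CG, CT, GT; GT fixed to 1 during
    fitting), stationary base frequencies, gamma shape and category count."""

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float
    n_categories: int = 4
    log_likelihood: float | None = None

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities <= 0).any():
            raise ValueError("six positive exchangeabilities required")
        if self.frequencies.shape != (4,) or not np.isclose(self.frequencies.sum(), 1):
            raise ValueError("frequencies must be four values summing to 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT


def _rate_matrix(exch: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    q = np.zeros((4, 4))
    for rate, (i, j) in zip(exch, _PAIRS):
        q[i, j] = rate * freqs[j]
        q[j, i] = rate * freqs[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    return q / scale


def _gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    from scipy.stats import gamma as gamma_dist
    quantiles = (2 * np.arange(ncat) + 1) / (2 * ncat)
    rates = gamma_dist.ppf(quantiles, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def _transition_matrices(q: np.ndarray, freqs: np.ndarray,
                         lengths: Sequence[float],
                         rates: np.ndarray) -> np.ndarray:
    """P[c, e] = expm(Q * t_e * r_c) via symmetric eigendecomposition."""
    sqrt_f = np.sqrt(freqs)
    sym = q * sqrt_f[None, :] / sqrt_f[:, None]
    vals, vecs = np.linalg.eigh((sym + sym.T) / 2)
    left = vecs.T * sqrt_f[None, :]          # vecs^T diag(sqrt_f)
    right = vecs / sqrt_f[:, None]           # diag(1/sqrt_f) vecs
    out = np.empty((len(rates), len(lengths), 4, 4))
    for ci, r in enumerate(rates):
        for ei, t in enumerate(lengths):
            out[ci, ei] = (right * np.exp(vals * r * t)[None, :]) @ left
    return np.clip(out, 1e-300, None)


def _encode_alignment(tree, alignment: Mapping[str, str]):
    """Pattern-compress columns; returns (leaves, codes[nleaf, npat], weights)."""
    leaves = [node_name(l) for l in tree.leaf_node_iter()]
    missing = set(leaves) - set(alignment)
    if missing:
        raise ValueError(f"leaves missing from alignment: {sorted(missing)}")
    widths = {len(alignment[l]) for l in leaves}
    if len(widths) != 1:
        raise ValueError("alignment sequences differ in width")
    mat = np.array([[BASE_INDEX.get(c, -1) for c in alignment[l].upper()]
                    for l in leaves], dtype=np.int8)
    patterns, inverse, counts = np.unique(mat, axis=1, return_inverse=True,
                                          return_counts=True)
    return leaves, patterns, counts.astype(float), inverse


def _edge_lengths(tree) -> dict[str, float]:
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        out[node_name(edge.head_node)] = max(edge.length or 0.0, 1e-8)
    return out


class _Pruner:
    """Conditional-likelihood engine over pattern-compressed columns."""

    def __init__(self, tree, alignment: Mapping[str, str], ncat: int = 4):
        self.tree = tree
        label_internal_nodes(tree)
        self.leaves, self.patterns, self.weights, self.inverse = \
            _encode_alignment(tree, alignment)
        self.leaf_pos = {l: i for i, l in enumerate(self.leaves)}
        self.ncat = ncat
        self.postorder = list(tree.postorder_node_iter())
        self.edge_len = _edge_lengths(tree)
        self.edge_order = sorted(self.edge_len)
        self.edge_idx = {n: i for i, n in enumerate(self.edge_order)}

    def _leaf_partial(self, name: str) -> np.ndarray:
        codes = self.patterns[self.leaf_pos[name]]
        part = np.zeros((self.patterns.shape[1], 4))
        known = codes >= 0
        part[known, codes[known]] = 1.0
        part[~known, :] = 1.0                  # gap/N: missing data
        return part

    def _pmats(self, params: SubstitutionModelParams, scale: float = 1.0):
        q = _rate_matrix(params.exchangeabilities, params.frequencies)
        rates = _gamma_rates(params.alpha, self.ncat)
        lengths = [self.edge_len[n] * scale for n in self.edge_order]
        return _transition_matrices(q, params.frequencies, lengths, rates)

    def down_partials(self, params: SubstitutionModelParams, scale: float = 1.0):
        """Post-order conditionals L[node][cat, pattern, state]."""
        pmats = self._pmats(params, scale)
        npat = self.patterns.shape[1]
        down: dict[str, np.ndarray] = {}
        for node in self.postorder:
            name = node_name(node)
            if node.is_leaf():
                leaf = self._leaf_partial(name)
                down[name] = np.broadcast_to(leaf, (self.ncat, npat, 4)).copy()
            else:
                part = np.ones((self.ncat, npat, 4))
                for child in node.child_nodes():
                    cname = node_name(child)
                    pm = pmats[:, self.edge_idx[cname]]     # [cat, 4, 4]
                    part *= np.einsum("cij,cpj->cpi", pm, down[cname])
                down[name] = part
        return down, pmats

    def log_likelihood(self, params: SubstitutionModelParams,
                       scale: float = 1.0) -> float:
        down, _ = self.down_partials(params, scale)
        root = down[node_name(self.tree.seed_node)]
        site_l = np.einsum("cpi,i->p", root, params.frequencies) / self.ncat
        site_l = np.clip(site_l, 1e-300, None)
        return float((np.log(site_l) * self.weights).sum())


def fit_model(
    tree,
    alignment: Mapping[str, str],
    ncat: int = 4,
    optimize_scale: bool = True,
) -> tuple[SubstitutionModelParams, float]:
    """ML-estimate GTR+G parameters on the fixed topology.

    Base frequencies are empirical; exchangeabilities (GT fixed at 1), the
    gamma shape and an overall branch-length scale are optimized by
    L-BFGS-B.  Returns (params, branch_scale).
    """
    from scipy.optimize import minimize

    pruner = _Pruner(tree, alignment, ncat)
    counts = np.ones(4)
    for leaf in pruner.leaves:
        for c in alignment[leaf].upper():
            if c in BASE_INDEX:
                counts[BASE_INDEX[c]] += 1
    freqs = counts / counts.sum()

    nscale = 1 if optimize_scale else 0

    def unpack(x):
        exch = np.ones(6)
        exch[:5] = np.exp(x[:5])
        alpha = float(np.exp(x[5]))
        scale = float(np.exp(x[6])) if nscale else 1.0
        return exch, alpha, scale

    def neg_ll(x):
        exch, alpha, scale = unpack(x)
        params = SubstitutionModelParams(exch, freqs, alpha, ncat)
        return -pruner.log_likelihood(params, scale)

    x0 = np.zeros(6 + nscale)
    x0[5] = np.log(1.0)
    res = minimize(neg_ll, x0, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-8})
    exch, alpha, scale = unpack(res.x)
    params = SubstitutionModelParams(exch, freqs, alpha, ncat,
                                     log_likelihood=-float(res.fun))
    return params, scale


# ---------------------------------------------------------------------------
# marginal ancestral reconstruction

@dataclasses.dataclass
class AncestralReconstruction:
    tree: dendropy.Tree
    node_sequences: dict[str, str]          # every node, leaves verbatim
    posteriors: dict[str, np.ndarray]       # internal nodes: max posterior/column
    model: SubstitutionModelParams
    width: int


def reconstruct_ancestral(
    tree,
    alignment: Mapping[str, str],
    model: SubstitutionModelParams | None = None,
    ncat: int = 4,
) -> AncestralReconstruction:
    """Marginal ML states for every internal node of a fixed rooted topology.

    The alignment is expected to be pre-masked (RNA-editing columns already
    removed).  If ``model`` is None, GTR+G parameters are first estimated by
    ML on the fixed topology.
    """
    if isinstance(tree, str):
        tree = load_tree(tree)
    label_internal_nodes(tree)
    scale = 1.0
    if model is None:
        model, scale = fit_model(tree, alignment, ncat)
    pruner = _Pruner(tree, alignment, ncat)
    down, pmats = pruner.down_partials(model, scale)

    npat = pruner.patterns.shape[1]
    freqs = model.frequencies
    root_name = node_name(tree.seed_node)

    # pre-order outside pass: O[v][c,p,y] = likelihood of everything except
    # the subtree below v, as a function of the state y at v
    outside: dict[str, np.ndarray] = {
        root_name: np.broadcast_to(freqs, (pruner.ncat, npat, 4)).copy()}
    for node in tree.preorder_node_iter():
        uname = node_name(node)
        children = node.child_nodes()
        for child in children:
            cname = node_name(child)
            m = outside[uname].copy()
            for sib in children:
                if sib is child:
                    continue
                sname = node_name(sib)
                pm = pmats[:, pruner.edge_idx[sname]]
                m *= np.einsum("cij,cpj->cpi", pm, down[sname])
            pm = pmats[:, pruner.edge_idx[cname]]
            outside[cname] = np.einsum("cij,cpi->cpj", pm, m)

    node_sequences: dict[str, str] = {}
    posteriors: dict[str, np.ndarray] = {}
    width = len(pruner.inverse)
    for node in tree.preorder_node_iter():
        name = node_name(node)
        if node.is_leaf():
            node_sequences[name] = alignment[name].upper()
            continue
        joint = (outside[name] * down[name]).sum(axis=0)   # [pattern, 4]
        norm = joint.sum(axis=1, keepdims=True)
        post = joint / np.clip(norm, 1e-300, None)
        best = post.argmax(axis=1)
        best_p = post[np.arange(npat), best]
        seq = np.array(list(BASES))[best][pruner.inverse]
        node_sequences[name] = "".join(seq)
        posteriors[name] = best_p[pruner.inverse]
    return AncestralReconstruction(tree=tree, node_sequences=node_sequences,
                                   posteriors=posteriors, model=model,
                                   width=width)


# ---------------------------------------------------------------------------
# branch spectra

@dataclasses.dataclass
class SpectrumSurvey:
    counts: pd.DataFrame          # branches x six types, plus total
    proportions: pd.DataFrame     # branches x six types (total > 0 only)
    genome_wide: pd.Series        # per-type totals over all branches
    min_substitutions: int


def count_branch_substitutions(
    recon: AncestralReconstruction,
    min_posterior: float = 0.5,
    min_substitutions: int = 20,
) -> SpectrumSurvey:
    """Per-branch counts and proportions of the six collapsed types.

    A column contributes to a branch only when both endpoint states are
    unambiguous bases and any reconstructed endpoint has posterior at or
    above ``min_posterior``.
    """
    rows = {}
    for edge in recon.tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        parent = node_name(edge.tail_node)
        child = node_name(edge.head_node)
        pseq = recon.node_sequences[parent]
        cseq = recon.node_sequences[child]
        if len(pseq) != len(cseq):
            raise ValueError("node sequence width mismatch")
        ppost = recon.posteriors.get(parent)
        cpost = recon.posteriors.get(child)
        counts = dict.fromkeys(COLLAPSED_TYPES, 0)
        for i, (a, b) in enumerate(zip(pseq, cseq)):
            if a not in BASE_INDEX or b not in BASE_INDEX:
                continue
            if ppost is not None and ppost[i] < min_posterior:
                continue
            if cpost is not None and cpost[i] < min_posterior:
                continue
            if a != b:
                counts[_CLASSIFY[(a, b)]] += 1
        rows[child] = counts
    counts_df = pd.DataFrame(rows).T.reindex(columns=list(COLLAPSED_TYPES))
    counts_df.index.name = "branch"
    counts_df["total"] = counts_df.sum(axis=1)
    with_subs = counts_df[counts_df["total"] > 0]
    proportions = with_subs[list(COLLAPSED_TYPES)].div(with_subs["total"], axis=0)
    genome_wide = counts_df[list(COLLAPSED_TYPES)].sum()
    return SpectrumSurvey(counts=counts_df, proportions=proportions,
                          genome_wide=genome_wide,
                          min_substitutions=min_substitutions)


def spectrum_enrichment(
    survey: SpectrumSurvey,
    type_name: str,
    k: int = 10,
) -> pd.DataFrame:
    """Top-k branches by proportion of one type (branches above threshold).

    Ties are broken by total substitution count, then branch id.
    """
    if type_name not in COLLAPSED_TYPES:
        raise ValueError(f"unknown type {type_name!r}")
    eligible = survey.counts[survey.counts["total"] >= survey.min_substitutions]
    if eligible.empty:
        return pd.DataFrame(columns=["branch", "proportion", "total"])
    props = eligible[type_name] / eligible["total"]
    df = pd.DataFrame({"branch": eligible.index, "proportion": props.values,
                       "total": eligible["total"].values})
    df = df.sort_values(["proportion", "total", "branch"],
                        ascending=[False, False, True], kind="mergesort")
    return df.head(k).reset_index(drop=True)


def hsd_across_types(survey: SpectrumSurvey) -> pd.DataFrame:
    """Tukey HSD over per-branch type proportions (one-way layout, 6 groups).

    Observations are the per-branch proportions of each type, restricted to
    branches with at least the survey's minimum substitution count; all 15
    type pairs are compared via the studentized-range distribution.
    Degenerate input (zero within-group variance everywhere) yields p = 1
    for all pairs.
    """
    eligible = survey.counts[survey.counts["total"] >= survey.min_substitutions]
    if len(eligible) < 2:
        raise ValueError("need at least two branches above the threshold")
    props = eligible[list(COLLAPSED_TYPES)].div(eligible["total"], axis=0)
    values = np.concatenate([props[t].to_numpy() for t in COLLAPSED_TYPES])
    groups = np.concatenate([[t] * len(props) for t in COLLAPSED_TYPES])
    pairs = list(itertools.combinations(COLLAPSED_TYPES, 2))
    if np.allclose(values.var(), 0):
        return pd.DataFrame([{"type_a": a, "type_b": b, "meandiff": 0.0,
                              "p_adj": 1.0} for a, b in pairs])
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    res = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=[c.strip() for c in res.summary().data[0]])
    out = frame.rename(columns={"group1": "type_a", "group2": "type_b",
                                "p-adj": "p_adj"})
    return out[["type_a", "type_b", "meandiff", "p_adj"]]
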