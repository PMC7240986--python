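"""Network modules and the phylogenetically-corrected Covariance Ratio test.

Protein-interaction networks are clustered into modules with the Markov
Clustering algorithm (MCL): a random walk on the weighted graph is
alternately expanded (matrix squaring) and inflated (elementwise powering
with renormalization) until it converges to a hard attractor structure whose
basins are the modules.

The Covariance Ratio (CR) asks whether expression covaries more tightly
within modules than between them. For module pair (a, b),

    CR_ab = ||S_ab||_F / sqrt(||S_aa*||_F * ||S_bb*||_F)

where S is the trait covariance matrix, S_ab the between-module block and
the * marks within-module blocks with their diagonals zeroed; the overall CR
averages the pairwise values. CR = 1 means between-module covariance equals
within-module covariance; smaller is more modular. Significance comes from
permuting module labels across traits (one-sided toward modularity).
Phylogenetic correction first whitens the species dimension with the tree's
covariance, making rows exchangeable under Brownian Motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from coevo.phylo import SpeciesCovariance

__all__ = [
    "MarkovClustering",
    "mcl",
    "phylo_transform",
    "covariance_ratio",
    "CRResult",
    "read_edge_list",
]


def read_edge_list(path) -> nx.Graph:
    """Read a weighted, undirected edge list TSV (gene1, gene2, weight)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    g = nx.Graph()
    for a, b, w in df[cols].itertuples(index=False):
        if a == b:
            continue
        g.add_edge(a, b, weight=float(w))
    return g


class MarkovClustering:
    """Markov Clustering of a weighted graph.

    Parameters
    ----------
    inflation : float
        Inflation exponent; larger values give finer clusters.
    expansion : int
        Power of the expansion step (2 = matrix squaring).
    prune_threshold : float
        Entries below this are zeroed each iteration before renormalizing.
    max_iter, tol : int, float
        Iteration cap and convergence tolerance on the max entry change.
    rescale_weights : float or None
        Divide edge weights by this before clustering (1000 maps STRING
        confidence scores onto [0, 1]); None leaves weights as given.

    After ``fit(graph)``: ``labels_`` maps node -> module id (0-based, in
    order of each module's smallest node label). Deterministic.
    """

    def __init__(self, inflation: float = 2.0, expansion: int = 2,
                 prune_threshold: float = 1e-5, max_iter: int = 100,
                 tol: float = 1e-6, rescale_weights: float | None = 1000.0):
        self.inflation = inflation
        self.expansion = expansion
        self.prune_threshold = prune_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.rescale_weights = rescale_weights

    def get_params(self, deep=True):
        return {
            "inflation": self.inflation,
            "expansion": self.expansion,
            "prune_threshold": self.prune_threshold,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "rescale_weights": self.rescale_weights,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError("invalid parameter %r" % k)
            setattr(self, k, v)
        return self

    def fit(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ValueError("empty network")
        nodes = sorted(graph.nodes())
        n = len(nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        M = np.zeros((n, n))
        scale = self.rescale_weights or 1.0
        for a, b, data in graph.edges(data=True):
            w = float(data.get("weight", 1.0)) / scale
            if w < 0:
                raise ValueError("edge weights must be positive")
            M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
        np.fill_diagonal(M, 1.0)  # self-loops stabilize the walk
        M = M / M.sum(axis=0, keepdims=True)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            prev = M
            M = np.linalg.matrix_power(M, self.expansion)
            M = np.power(M, self.inflation)
            M[M < self.prune_threshold] = 0.0
            colsum = M.sum(axis=0, keepdims=True)
            colsum[colsum == 0] = 1.0
            M = M / colsum
            if np.abs(M - prev).max() < self.tol:
                break
        # attractor rows with support define (possibly overlapping) clusters;
        # overlaps are merged via connected components
        comp = nx.Graph()
        comp.add_nodes_from(range(n))
        for i in range(n):
            members = np.flatnonzero(M[i] > 1e-8)
            if M[i, i] > 1e-8 and members.size:
                for j in members:
                    comp.add_edge(i, int(j))
        labels = {}
        clusters = sorted(
            (sorted(c) for c in nx.connected_components(comp)),
            key=lambda c: (nodes[c[0]],),
        )
        for mid, members in enumerate(clusters):
            for i in members:
                labels[nodes[i]] = mid
        self.labels_ = labels
        self.matrix_ = M
        self.n_iter_ = n_iter
        return self

    def fit_predict(self, graph: nx.Graph) -> dict:
        return self.fit(graph).labels_


def mcl(graph: nx.Graph, inflation: float = 2.0, max_iter: int = 100,
        **kwargs) -> dict:
    """Module assignment (gene -> module id) by Markov clustering."""
    return MarkovClustering(inflation=inflation, max_iter=max_iter,
                            **kwargs).fit_predict(graph)


def phylo_transform(X, cov) -> np.ndarray:
    """Remove phylogenetic structure from a species-by-trait matrix.

    With C = U D U', returns D^{-1/2} U' (X - 1 theta'), where theta is the
    per-trait GLS root estimate. Under Brownian Motion the transformed rows
    are exchangeable (i.i.d. with covariance equal to the evolutionary rate
    matrix), so ordinary covariance statistics apply.
    """
    C = cov.matrix if isinstance(cov, SpeciesCovariance) else np.asarray(cov, float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = C.shape[0]
    if X.shape[0] != n:
        raise ValueError("X rows must match species covariance dimension")
    w, U = np.linalg.eigh(C)
    if w.min() <= 1e-12 * w.max():
        raise np.linalg.LinAlgError("singular species covariance")
    Cinv_one = U @ ((U.T @ np.ones(n)) / w)
    denom = np.ones(n) @ Cinv_one
    theta = (Cinv_one @ X) / denom
    centered = X - theta[None, :]
    return (U.T @ centered) / np.sqrt(w)[:, None]


@dataclass
class CRResult:
    cr: float
    p_value: float
    n_permutations: int
    pairwise: dict
    modules_used: list


def covariance_ratio(X, modules, n_perm: int = 999, seed: int = 0,
                     min_size: int = 15) -> CRResult:
    """Covariance Ratio modularity test on a (transformed) trait matrix.

    ``X`` is observations x traits (phylogenetically whitened when species
    are the observations); ``modules`` maps trait index or column label to a
    module id. Modules smaller than ``min_size`` traits are dropped; at
    least two must remain. The permutation p-value is the add-one proportion
    of trait-label shuffles with CR at or below the observed (one-sided
    toward modularity).
    """
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    if isinstance(modules, dict):
        labels = np.asarray([modules[i] for i in range(k)])
    else:
        labels = np.asarray(modules)
    if labels.size != k:
        raise ValueError("module labels must match trait count")
    keep_mods = [m for m in pd.unique(labels) if (labels == m).sum() >= min_size]
    if len(keep_mods) < 2:
        raise ValueError(
            "need at least 2 modules with >= %d traits (got %d)"
            % (min_size, len(keep_mods))
        )
    for m in keep_mods:
        if (labels == m).sum() < 2:
            raise ValueError("module %r has fewer than 2 traits" % m)
    keep = np.isin(labels, keep_mods)
    Xk = X[:, keep]
    lk = labels[keep]

    S = np.cov(Xk, rowvar=False)

    def overall_cr(lab):
        vals = {}
        for ai in range(len(keep_mods)):
            for bi in range(ai + 1, len(keep_mods)):
                a, b = keep_mods[ai], keep_mods[bi]
                ia, ib = lab == a, lab == b
                Sab = S[np.ix_(ia, ib)]
                Saa = S[np.ix_(ia, ia)].copy()
                Sbb = S[np.ix_(ib, ib)].copy()
                np.fill_diagonal(Saa, 0.0)
                np.fill_diagonal(Sbb, 0.0)
                denom = np.sqrt(
                    np.linalg.norm(Saa, "fro") * np.linalg.norm(Sbb, "fro")
                )
                vals[(a, b)] = float(np.linalg.norm(Sab, "fro") / denom)
        return float(np.mean(list(vals.values()))), vals

    obs, pairwise = overall_cr(lk)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(lk)
        cr_p, _unused = overall_cr(perm)
        if cr_p <= obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return CRResult(cr=obs, p_value=float(p), n_permutations=n_perm,
                    pairwise=pairwise, modules_used=list(keep_mods))
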