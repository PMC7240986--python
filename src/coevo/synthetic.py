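"""Synthetic inputs with the statistical structure the analysis assumes.

Generates every input the pipeline consumes: a time-calibrated Yule tree
(defaults mirror the study system — 18 fungal species with a root age of
723 million years), bivariate Brownian-Motion trait pairs with a specified
evolutionary correlation, replicate-level observation noise summarized to
per-species means and standard errors, labeled binding/control pair sets
(binding pairs drawn with correlation around 0.45, the fitted mean of the
empirical binding group; control pairs with correlation 0), and
stochastic-block-model interaction networks with STRING-like edge weights.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from coevo.normalize import ExpressionPanel, summarize_replicates
from coevo.phylo import Phylogeny, SpeciesCovariance, vcv
from coevo.mvbm import RateMatrix

__all__ = [
    "SimConfig",
    "PairRecord",
    "simulate_tree",
    "simulate_pair",
    "generate_pair_sets",
    "generate_network_fixture",
]


@dataclass
class PairRecord:
    """A gene pair: the unit of analysis.

    ``group`` is "binding" or "control"; ``rho_true`` records the simulated
    evolutionary correlation (None for empirical data); ``confidence`` and
    degrees are optional annotation columns consumed by the predictor
    analyses.
    """

    gene1: str
    gene2: str
    group: str = "binding"
    confidence: float | None = None
    degree1: int | None = None
    degree2: int | None = None
    rho_true: float | None = None

    @property
    def coevolving(self) -> bool:
        return self.group == "binding"


@dataclass
class SimConfig:
    """Simulation conditions for the labeled pair sets.

    Defaults reproduce the study conditions: an 18-tip tree with root age
    723 My; binding-pair evolutionary correlations from a truncated normal
    with mean 0.45 and sd 0.25 on (-1, 1); per-trait rates lognormal(0,
    0.5); 3 replicates per species with log-scale observation noise of sd
    0.1 (small relative to the Brownian tip variance, as in the study's
    well-replicated libraries).
    """

    n_tips: int = 18
    root_age: float = 723.0
    n_binding: int = 500
    n_control: int = 500
    rho_mean: float = 0.45
    rho_sd: float = 0.25
    sigma_log_mean: float = 0.0
    sigma_log_sd: float = 0.5
    n_replicates: int = 3
    obs_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be at least 3")
        for name in ("n_binding", "n_control", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError("%s must be nonnegative" % name)
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if not (-1 < self.rho_mean < 1):
            raise ValueError("rho_mean must lie in (-1, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_tree(n_tips: int = 18, root_age: float = 723.0,
                  seed: int = 0) -> Phylogeny:
    """Yule (pure-birth) tree rescaled to a fixed root age.

    Stands in for a fixed, dated species tree; seeded and deterministic.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be at least 3")
    taxa = dendropy.TaxonNamespace(["S%02d" % i for i in range(1, n_tips + 1)])
    pyrng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=pyrng,
    )
    tree.seed_node.edge.length = None
    # the generator stops at the n-th birth, leaving two zero-length tips;
    # run the process on for the exponential waiting time to the (n+1)-th
    # birth so pendant branches are positive and C is nonsingular
    extra = pyrng.expovariate(n_tips * 1.0)
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    phylo = Phylogeny(tree)
    scale = root_age / phylo.root_height
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= scale
    return Phylogeny(tree)


def _rate_matrix_cholesky(R) -> np.ndarray:
    R2 = R.as_array() if isinstance(R, RateMatrix) else np.asarray(R, float)
    return np.linalg.cholesky(R2)


def simulate_pair(cov, R, theta=(0.0, 0.0), se=None, rng=None) -> np.ndarray:
    """Simulate one trait pair under bivariate BM; returns a (2, n) matrix.

    Tip values are drawn from the 2n-variate normal with covariance
    R (x) C plus independent observation noise of standard deviation ``se``
    (scalar or (2, n)).
    """
    C = cov.matrix if isinstance(cov, SpeciesCovariance) else np.asarray(cov, float)
    n = C.shape[0]
    rng = np.random.default_rng(rng)
    Lc = np.linalg.cholesky(C)
    Lr = _rate_matrix_cholesky(R)
    Z = rng.standard_normal((n, 2))
    X = (Lc @ Z @ Lr.T).T + np.asarray(theta, float)[:, None]
    if se is not None:
        se = np.broadcast_to(np.asarray(se, float), (2, n))
        X = X + rng.standard_normal((2, n)) * se
    return X


def _draw_rho(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (-1.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_pair_sets(config: SimConfig, tree: Phylogeny = None):
    """Simulate labeled binding/control pair sets with replicate noise.

    Binding pairs evolve with a per-pair correlation drawn from the
    truncated normal of the config; control pairs evolve independently
    (correlation 0). Per-species replicates (Brownian tip value plus
    observation noise) are summarized to means and standard errors, so the
    returned panel has the same shape the normalization stage produces on
    real data.

    Returns ``(tree, panel, pairs)``.
    """
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = simulate_tree(config.n_tips, config.root_age,
                             seed=int(rng.integers(2 ** 31)))
    cov = vcv(tree)
    n = cov.n
    Lc = np.linalg.cholesky(cov.matrix)

    m = config.n_binding + config.n_control
    groups = ["binding"] * config.n_binding + ["control"] * config.n_control
    rho = np.concatenate([
        _draw_rho(rng, config.rho_mean, config.rho_sd, config.n_binding),
        np.zeros(config.n_control),
    ])
    r11 = rng.lognormal(config.sigma_log_mean, config.sigma_log_sd, size=m)
    r22 = rng.lognormal(config.sigma_log_mean, config.sigma_log_sd, size=m)

    # tip values for all pairs at once: X_k = L_C Z_k L_R(k)'
    Z = rng.standard_normal((m, n, 2))
    X = np.empty((m, 2, n))
    for k in range(m):
        Lr = np.linalg.cholesky(
            np.array([
                [r11[k], rho[k] * np.sqrt(r11[k] * r22[k])],
                [rho[k] * np.sqrt(r11[k] * r22[k]), r22[k]],
            ])
        )
        X[k] = (Lc @ Z[k] @ Lr.T).T

    reps = config.n_replicates
    noise = rng.standard_normal((m, 2, n, reps)) * config.obs_noise_sd
    obs = X[..., None] + noise  # (m, 2, n, reps)

    genes, pairs = [], []
    for k in range(m):
        tag = "B%04d" % k if groups[k] == "binding" else "C%04d" % (k - config.n_binding)
        genes += ["%s_x" % tag, "%s_y" % tag]
        pairs.append(PairRecord(
            gene1="%s_x" % tag, gene2="%s_y" % tag, group=groups[k],
            rho_true=float(rho[k]),
        ))

    # per species, summarize every gene's replicates through the normalize op
    flat = obs.reshape(m * 2, n, reps)  # genes x species x reps
    mean_rows, se_rows = [], []
    for i in range(n):
        mu, se = summarize_replicates(
            pd.DataFrame(flat[:, i, :], index=genes)
        )
        mean_rows.append(mu)
        se_rows.append(se)
    mean_df = pd.DataFrame(mean_rows, index=cov.species)
    se_df = pd.DataFrame(se_rows, index=cov.species)
    panel = ExpressionPanel(mean_df, se_df,
                            pd.Series(reps, index=cov.species))
    return tree, panel, pairs


def generate_network_fixture(n_modules: int = 3, module_size: int = 15,
                             p_within: float = 0.8, p_between: float = 0.05,
                             seed: int = 0):
    """Stochastic-block-model interaction network with STRING-like weights.

    Within-module edges get confidence weights ~ U(600, 999), between-module
    edges ~ U(150, 400). Returns ``(graph, true_modules)``.
    """
    import networkx as nx

    if n_modules < 1 or module_size < 2:
        raise ValueError("need n_modules >= 1 and module_size >= 2")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    truth = {}
    names = []
    for mmod in range(n_modules):
        for i in range(module_size):
            name = "M%02dG%03d" % (mmod, i)
            names.append(name)
            truth[name] = mmod
            g.add_node(name)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            same = truth[a] == truth[b]
            p = p_within if same else p_between
            if rng.random() < p:
                w = rng.uniform(600, 999) if same else rng.uniform(150, 400)
                g.add_edge(a, b, weight=float(w))
    return g, truth
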