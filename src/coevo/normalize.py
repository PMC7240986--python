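"""Cross-species expression normalization.

Raw TPM values are not comparable across species: library composition,
annotation completeness and lab protocols all shift the per-species
distributions. Each replicate is therefore mapped onto a standard lognormal
scale — ln(TPM) is z-scored across genes within the replicate — so that every
species contributes a trait on a common, boundary-free scale suitable for
Brownian-Motion modelling. Replicates are then summarized to a per-gene mean
and standard error (the measurement-error input of the model fits).

Missing data policy: a TPM of zero has no defined log value and is treated as
missing; genes missing in any species of the analysis set are excluded, and
the gene pairs containing them are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionPanel",
    "standardize_sample",
    "summarize_replicates",
    "apply_proxy_se",
    "filter_complete",
    "select_correlated_replicates",
    "LognormalStandardizer",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionPanel:
    """Species-by-gene normalized expression means with standard errors.

    ``mean`` and ``se`` are DataFrames indexed by species with gene columns
    (identical shape); missing values are explicit NaN. ``n_replicates`` maps
    each species to its replicate count.
    """

    mean: pd.DataFrame
    se: pd.DataFrame
    n_replicates: pd.Series = None

    def __post_init__(self):
        if list(self.mean.index) != list(self.se.index) or list(
            self.mean.columns
        ) != list(self.se.columns):
            raise ValueError("mean and se must share index (species) and columns (genes)")
        if (self.se.to_numpy() < 0).any():
            raise ValueError("standard errors must be nonnegative")
        if self.n_replicates is None:
            self.n_replicates = pd.Series(1, index=self.mean.index)

    @property
    def species(self) -> list:
        return list(self.mean.index)

    @property
    def genes(self) -> list:
        return list(self.mean.columns)

    def traits(self, gene1: str, gene2: str, species_order=None):
        """(2, n) mean and SE arrays for a gene pair, in ``species_order``."""
        order = list(species_order) if species_order is not None else self.species
        x = self.mean.loc[order, [gene1, gene2]].to_numpy().T
        s = self.se.loc[order, [gene1, gene2]].to_numpy().T
        return x, s


def standardize_sample(tpm) -> pd.Series:
    """Transform one replicate's TPM vector to the standard lognormal scale.

    Returns z = (ln(tpm) - mean) / sd over genes with tpm > 0, using the
    sample (n-1) standard deviation; zero-TPM genes map to NaN.
    """
    s = pd.Series(tpm, dtype=float)
    if (s < 0).any():
        raise ValueError("TPM values must be nonnegative")
    obs = s > 0
    if int(obs.sum()) == 0:
        raise ValueError("all-zero TPM vector cannot be standardized")
    if int(obs.sum()) < 3:
        raise ValueError("need at least 3 genes with TPM > 0")
    lx = np.log(s[obs])
    sd = lx.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance in log-TPM; cannot standardize")
    out = pd.Series(np.nan, index=s.index)
    out[obs] = (lx - lx.mean()) / sd
    return out


class LognormalStandardizer:
    """Transformer view of :func:`standardize_sample`.

    Stateless (``fit`` is a no-op); ``transform`` standardizes each column of
    a genes-by-replicates table independently.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return pd.DataFrame(
            {c: standardize_sample(X[c]) for c in X.columns}, index=X.index
        )

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError("LognormalStandardizer has no parameters")
        return self


def summarize_replicates(z):
    """Per-gene mean and standard error across replicates.

    Parameters
    ----------
    z : DataFrame (genes x replicates), 2-D array, or list of per-gene vectors
        Normalized values; NaN marks missing observations.

    Returns
    -------
    (mean, se)
        Per-gene mean and standard error (sample sd / sqrt(m)). A gene
        missing in any replicate is reported missing in both outputs
        (blanket missing-data exclusion); with a single replicate the mean
        passes through and the SE is missing.
    """
    if isinstance(z, list):
        if len(z) == 0:
            raise ValueError("need at least one replicate")
        z = pd.concat([pd.Series(v, dtype=float) for v in z], axis=1)
    arr = pd.DataFrame(z).astype(float)
    if arr.shape[1] == 0:
        raise ValueError("need at least one replicate")
    vals = arr.to_numpy()
    m = vals.shape[1]
    observed_all = ~np.isnan(vals).any(axis=1)
    mean = np.where(observed_all, vals.mean(axis=1), np.nan)
    if m >= 2:
        se = np.where(observed_all, vals.std(axis=1, ddof=1) / np.sqrt(m), np.nan)
    else:
        se = np.full(vals.shape[0], np.nan)
    idx = arr.index
    return pd.Series(mean, index=idx), pd.Series(se, index=idx)


def apply_proxy_se(panel: ExpressionPanel, proxy_map: dict) -> ExpressionPanel:
    """Fill missing standard errors from a closely-related proxy species.

    For each species in ``proxy_map`` whose SE row is missing, the proxy
    species' SEs are inherited gene-wise. Used when a species' expression
    data lack replicates, so no SE can be estimated directly.
    """
    se = panel.se.copy()
    for sp, proxy in proxy_map.items():
        if sp not in se.index:
            raise KeyError("species %r not in panel" % sp)
        if proxy not in se.index:
            raise KeyError("proxy species %r not in panel" % proxy)
        proxy_row = panel.se.loc[proxy]  # original values: proxies may not chain
        target = se.loc[sp]
        fill = target.isna()
        if fill.any() and proxy_row[fill].isna().any():
            raise ValueError(
                "proxy species %r is itself missing standard errors needed by %r"
                % (proxy, sp)
            )
        se.loc[sp, fill] = proxy_row[fill]
    return ExpressionPanel(panel.mean.copy(), se, panel.n_replicates)


def filter_complete(panel: ExpressionPanel, pairs=None):
    """Drop genes missing in any species, and the pairs containing them.

    Returns ``(panel, pairs, dropped_genes)``; ``pairs`` is None when no
    pair table is supplied. Idempotent.
    """
    complete = panel.mean.notna().all(axis=0)
    keep_genes = [g for g in panel.genes if complete[g]]
    dropped = sorted(set(panel.genes) - set(keep_genes))
    if dropped:
        log.info(
            "filter_complete: dropping %d/%d genes with missing data",
            len(dropped), len(panel.genes),
        )
    if not keep_genes:
        import warnings

        warnings.warn("all genes have missing data; empty panel", UserWarning)
    out = ExpressionPanel(
        panel.mean[keep_genes].copy(), panel.se[keep_genes].copy(), panel.n_replicates
    )
    if pairs is None:
        return out, None, dropped
    keep_set = set(keep_genes)
    kept_pairs = [p for p in pairs if p.gene1 in keep_set and p.gene2 in keep_set]
    if len(kept_pairs) < len(pairs):
        log.info(
            "filter_complete: dropping %d/%d pairs touching excluded genes",
            len(pairs) - len(kept_pairs), len(pairs),
        )
    return out, kept_pairs, dropped


def select_correlated_replicates(df: pd.DataFrame, k: int = 3, min_r: float = 0.98):
    """Pick the first ``k`` mutually correlated replicate columns.

    Curation helper for time-course experiments: returns the first ``k``
    columns whose pairwise Pearson correlations all exceed ``min_r``.
    Raises if no such subset exists among the leading candidates.
    """
    cols = list(df.columns)
    if len(cols) < k:
        raise ValueError("fewer than %d replicate columns" % k)
    corr = df.corr(method="pearson")
    from itertools import combinations

    for combo in combinations(cols, k):
        sub = corr.loc[list(combo), list(combo)].to_numpy()
        off = sub[~np.eye(k, dtype=bool)]
        if (off > min_r).all():
            return list(combo)
    raise ValueError("no %d mutually correlated replicates at r > %g" % (k, min_r))
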