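"""Group-level statistics on fitted correlations.

Pairs sharing a gene are not independent observations: a promiscuous hub
protein contributes to many pairs and can dominate a naive correlation. The
weighted Spearman correlation down-weights such pairs with

    weight = (1/2) * (1/N1 + 1/N2)

where N_i counts how often gene i appears in the analyzed set. Confidence
intervals and p-values come from a nonparametric bootstrap over pairs.
Membership-controlled resampling (each gene in at most one pair per subset)
provides a stronger check that shared membership does not drive group
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pair_weights",
    "weighted_spearman",
    "WeightedSpearmanResult",
    "group_tests",
    "bh_adjust",
    "membership_subsets",
]


def _gene_columns(pairs):
    """Extract (gene1, gene2) sequences from records or a DataFrame."""
    if isinstance(pairs, pd.DataFrame):
        return pairs["gene1"].tolist(), pairs["gene2"].tolist()
    g1 = [p.gene1 for p in pairs]
    g2 = [p.gene2 for p in pairs]
    return g1, g2


def pair_weights(pairs) -> np.ndarray:
    """Per-pair weights from gene appearance counts within the given set."""
    g1, g2 = _gene_columns(pairs)
    counts = {}
    for g in g1 + g2:
        counts[g] = counts.get(g, 0) + 1
    return np.array(
        [0.5 * (1.0 / counts[a] + 1.0 / counts[b]) for a, b in zip(g1, g2)]
    )


def _weighted_pearson(x, y, w):
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance")
    return cov / np.sqrt(vx * vy)


@dataclass
class WeightedSpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int


def weighted_spearman(x, y, pairs=None, weights=None, n_boot: int = 2000,
                      seed: int = 0) -> WeightedSpearmanResult:
    """Weighted Spearman rank correlation with bootstrap CI and p-value.

    Ranks (average ranks for ties) are computed unweighted; the weights
    enter only the Pearson correlation of the ranks. When ``weights`` is
    omitted they are derived from the gene appearance counts of ``pairs``.
    The percentile bootstrap resamples pairs with replacement, recomputing
    appearance-count weights within each resample when pairs are given; the
    p-value is twice the smaller tail proportion of bootstrap estimates on
    either side of zero, floored at 1/n_boot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = x.size
    if m < 4:
        raise ValueError("need at least 4 pairs")
    if weights is None:
        if pairs is None:
            weights = np.ones(m)
        else:
            weights = pair_weights(pairs)
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant ranks: correlation undefined")
    rho = _weighted_pearson(rx, ry, weights)

    if pairs is not None:
        g1, g2 = _gene_columns(pairs)
        g1, g2 = np.asarray(g1), np.asarray(g2)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        if pairs is not None:
            sub = pd.DataFrame({"gene1": g1[idx], "gene2": g2[idx]})
            w = pair_weights(sub)
        else:
            w = weights[idx]
        bx, by = stats.rankdata(x[idx]), stats.rankdata(y[idx])
        if np.ptp(bx) == 0 or np.ptp(by) == 0:
            boot[b] = np.nan
            continue
        boot[b] = _weighted_pearson(bx, by, w)
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    frac_le = np.mean(boot <= 0)
    frac_ge = np.mean(boot >= 0)
    p = max(2.0 * min(frac_le, frac_ge), 1.0 / n_boot)
    return WeightedSpearmanResult(float(rho), float(lo), float(hi),
                                  float(min(p, 1.0)), n_boot)


def group_tests(rho_binding, rho_control, popmean: float = 0.0) -> dict:
    """One-sample t-tests per group against ``popmean`` and a Welch t-test.

    Under no coevolution the expected correlation is 0; the one-sample test
    asks whether a group's mean correlation departs from that, the Welch
    test whether the two groups differ. Raises on zero-variance groups
    (t statistics undefined), except that two degenerate groups with equal
    means give a Welch t of 0 and p of 1.
    """
    out = {}
    groups = {"binding": np.asarray(rho_binding, float),
              "control": np.asarray(rho_control, float)}
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError("group %r needs at least 2 values" % name)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("group %r has zero variance; t-test undefined" % name)
        t = stats.ttest_1samp(v, popmean)
        ci = t.confidence_interval(0.95)
        out[name] = {
            "n": int(v.size),
            "mean": float(v.mean()),
            "t": float(t.statistic),
            "p": float(t.pvalue),
            "ci95": (float(ci.low), float(ci.high)),
        }
    b, c = groups["binding"], groups["control"]
    if b.std(ddof=1) == 0 and c.std(ddof=1) == 0:
        if b.mean() == c.mean():
            out["welch"] = {"t": 0.0, "p": 1.0}
        else:
            raise ValueError("both groups degenerate; Welch t undefined")
    else:
        w = stats.ttest_ind(b, c, equal_var=False)
        out["welch"] = {"t": float(w.statistic), "p": float(w.pvalue)}
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def membership_subsets(pairs, values: pd.DataFrame = None, n_subsets: int = 200,
                       max_size: int = 200, seed: int = 0):
    """Resample pair subsets in which each gene appears at most once.

    Pairs are shuffled (seeded) and accepted greedily while neither gene has
    been used, stopping at ``max_size`` pairs per subset. Returns
    ``(subsets, means)``: index lists into ``pairs``, and — when ``values``
    (a DataFrame with columns such as rho_c / rho_u aligned to pairs) is
    given — a DataFrame of per-subset column means.
    """
    g1, g2 = _gene_columns(pairs)
    m = len(g1)
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        order = rng.permutation(m)
        used = set()
        chosen = []
        for i in order:
            if g1[i] in used or g2[i] in used or g1[i] == g2[i]:
                continue
            chosen.append(int(i))
            used.add(g1[i])
            used.add(g2[i])
            if len(chosen) >= max_size:
                break
        subsets.append(sorted(chosen))
    if values is None:
        return subsets, None
    values = pd.DataFrame(values).reset_index(drop=True)
    means = pd.DataFrame(
        [values.iloc[s].mean(numeric_only=True) for s in subsets]
    )
    return subsets, means
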