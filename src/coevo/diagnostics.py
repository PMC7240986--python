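"""Independent contrasts and the Brownian-Motion assumption screen.

Phylogenetic independent contrasts (Felsenstein's pruning construction) turn
n tip values into n-1 standardized differences that are i.i.d. standard
normal scaled by the BM rate when the trait truly evolves by Brownian
Motion. Departures from BM show up as a dependence between the magnitude of
a contrast and its standard deviation (the square root of its expected
variance): under early bursts, rate heterogeneity or bounded evolution, deep
contrasts are systematically too large or too small. The screen correlates
|contrast| with contrast SD (Garland-style diagnostic) and flags genes whose
correlation is significant; pairs containing a flagged gene are excluded
from model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from coevo.phylo import Phylogeny

__all__ = ["ContrastSet", "pic", "bm_violation_test", "filter_bm"]

log = logging.getLogger(__name__)


@dataclass
class ContrastSet:
    """Standardized contrasts and their standard deviations (n-1 each)."""

    contrasts: np.ndarray
    sds: np.ndarray


def _resolved_topology(phylo: Phylogeny):
    """Bifurcating nested-tuple copy of the tree.

    Multifurcations are resolved deterministically in child order with
    zero-length branches; a unifurcating root is collapsed into its child's
    branch. Nodes are ``("leaf", label, blen)`` or
    ``("node", left, right, blen)``.
    """

    def build(node, edge_len):
        if node.is_leaf():
            return ("leaf", node.taxon.label, edge_len)
        sub = [build(ch, ch.edge.length or 0.0) for ch in node.child_nodes()]
        if len(sub) == 1:
            kind, *rest = sub[0]
            child_len = rest[-1]
            return tuple([kind, *rest[:-1], child_len + edge_len])
        while len(sub) > 2:  # ladderize extra children with zero-length edges
            merged = ("node", sub[0], sub[1], 0.0)
            sub = [merged] + sub[2:]
        return ("node", sub[0], sub[1], edge_len)

    topo = build(phylo.tree.seed_node, 0.0)
    if topo[0] == "leaf":
        raise ValueError("tree must have at least 2 tips")
    return topo


def pic(phylo: Phylogeny, x) -> ContrastSet:
    """Phylogenetic independent contrasts of one trait.

    ``x`` maps tip labels to values, or is an array in the tree's preorder
    tip order. At each internal node the contrast is
    (x_L - x_R) / sqrt(b_L + b_R) with branch lengths adjusted upward by
    b_L b_R / (b_L + b_R) as ancestral values are estimated; contrasts are
    emitted in postorder.
    """
    if isinstance(x, dict):
        vals = dict(x)
    else:
        arr = np.asarray(x, dtype=float)
        if arr.size != phylo.n_tips:
            raise ValueError("x length must equal number of tips")
        vals = dict(zip(phylo.tip_labels, arr))
    missing = set(phylo.tip_labels) - set(vals)
    if missing:
        raise ValueError("missing trait values for tips: %s" % sorted(missing))
    if any(not np.isfinite(vals[k]) for k in phylo.tip_labels):
        raise ValueError("trait values must be finite (no missing data)")

    contrasts, sds = [], []

    def visit(node):
        """Return (estimated value, adjusted pendant branch) below node."""
        if node[0] == "leaf":
            return vals[node[1]], node[2]
        _, left, right, blen = node
        vl, bl = visit(left)
        vr, br = visit(right)
        var = bl + br
        if var > 0:
            contrasts.append((vl - vr) / np.sqrt(var))
            sds.append(np.sqrt(var))
            node_val = (vl / bl + vr / br) / (1.0 / bl + 1.0 / br) if bl > 0 and br > 0 \
                else (vl if bl == 0 else vr)
            adj = bl * br / var
        else:
            # zero-length cherry from a resolved multifurcation: emit a
            # zero-variance contrast only if the values actually differ
            if vl != vr:
                raise ValueError("zero-length cherry with differing values")
            node_val, adj = vl, 0.0
        return node_val, blen + adj

    topo = _resolved_topology(phylo)
    visit(topo)
    return ContrastSet(np.asarray(contrasts), np.asarray(sds))


def bm_violation_test(phylo: Phylogeny, x, diagnostic: str = "abs",
                      alpha: float = 0.05):
    """Test a trait for departure from Brownian Motion.

    Correlates the contrasts (absolute values by default, raw with
    ``diagnostic='raw'``) against their standard deviations; a significant
    Pearson correlation (p < ``alpha``) flags the trait as violating the BM
    assumption. Returns ``(r, p, violated)``; degenerate inputs (zero
    variance in either vector) are untestable and reported not violated with
    ``r`` and ``p`` NaN.
    """
    if phylo.n_tips < 4:
        raise ValueError("need at least 4 tips to test the BM assumption")
    if diagnostic not in ("abs", "raw"):
        raise ValueError("diagnostic must be 'abs' or 'raw'")
    cs = pic(phylo, x)
    c = np.abs(cs.contrasts) if diagnostic == "abs" else cs.contrasts
    if np.ptp(c) == 0 or np.ptp(cs.sds) == 0:
        return np.nan, np.nan, False
    res = stats.pearsonr(c, cs.sds)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def filter_bm(panel, phylo: Phylogeny, pairs, enabled: bool = True,
              diagnostic: str = "abs", alpha: float = 0.05):
    """Drop pairs containing a gene that violates the BM assumption.

    Each gene is tested once on the full species set; any pair containing a
    violating gene is removed. With ``enabled=False`` the input pairs are
    returned unchanged (mirrors running the analysis without the screen).
    Returns ``(kept_pairs, report)`` where report maps gene -> (r, p,
    violated).
    """
    if not enabled:
        return list(pairs), {}
    report = {}
    genes = {g for p in pairs for g in (p.gene1, p.gene2)}
    order = phylo.tip_labels
    for g in sorted(genes):
        xvals = panel.mean.loc[order, g].to_numpy()
        report[g] = bm_violation_test(phylo, xvals, diagnostic=diagnostic, alpha=alpha)
    bad = {g for g, (_, _, v) in report.items() if v}
    kept = [p for p in pairs if p.gene1 not in bad and p.gene2 not in bad]
    if bad:
        log.info(
            "filter_bm: %d/%d genes violate BM; dropping %d/%d pairs",
            len(bad), len(genes), len(pairs) - len(kept), len(pairs),
        )
    return kept, report
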