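"""Non-phylogenetic significance procedures for correlation screens.

Two empirical-null procedures widely used for expression coevolution are
implemented as detectors for benchmarking against the phylogenetic model:

* Histogram crossover: overlay the relative histograms of the candidate
  (binding) and null (control) correlation distributions and call
  significant every pair above the first bin from which the candidate's
  relative frequency stays strictly above the null's.
* Per-pair randomization: compare each pair's correlation against draws
  from the null pool, convert the exceedance count to an add-one p-value
  (k+1)/(n+1), and choose the p cutoff whose empirical false discovery rate
  on the labeled set is at most a target (5% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CrossoverCutoff",
    "RandomizationResult",
    "crossover_cutoff",
    "crossover_classify",
    "randomization_p",
    "calibrate_cutoff_fdr",
    "CrossoverDetector",
    "RandomizationDetector",
]


@dataclass
class CrossoverCutoff:
    """Crossover point of binding vs control correlation histograms.

    ``cutoff`` is the left edge of the crossover bin, or None when the
    histograms never cross (a valid outcome, not an error).
    """

    cutoff: float | None
    bin_width: float
    bin_edges: np.ndarray

    @property
    def found(self) -> bool:
        return self.cutoff is not None


@dataclass
class RandomizationResult:
    k_greater: int
    p_value: float
    n_rand: int


def _edges(bin_width: float) -> np.ndarray:
    nbins = int(round(2.0 / bin_width))
    if abs(nbins * bin_width - 2.0) > 1e-9:
        raise ValueError("bin width must divide the [-1, 1] range evenly")
    return np.linspace(-1.0, 1.0, nbins + 1)


def crossover_cutoff(binding_r, control_r, bin_width: float = 0.05) -> CrossoverCutoff:
    """Histogram-crossover significance cutoff.

    Both groups are binned on common edges spanning [-1, 1]. The cutoff is
    the left edge of the smallest nonempty bin from which, in every nonempty
    bin onward, the binding group's relative frequency strictly exceeds the
    control's; empty bins are skipped when checking the condition.
    """
    binding_r = np.asarray(binding_r, dtype=float)
    control_r = np.asarray(control_r, dtype=float)
    if binding_r.size == 0 or control_r.size == 0:
        raise ValueError("both groups must be nonempty")
    edges = _edges(bin_width)
    hb, _ = np.histogram(np.clip(binding_r, -1, 1), bins=edges)
    hc, _ = np.histogram(np.clip(control_r, -1, 1), bins=edges)
    rb = hb / binding_r.size
    rc = hc / control_r.size
    nonempty = (hb + hc) > 0
    exceeds = rb > rc
    # suffix scan: condition holds from bin i iff every nonempty bin >= i exceeds
    ok_from_here = True
    cutoff = None
    for i in range(len(rb) - 1, -1, -1):
        if not nonempty[i]:
            continue
        ok_from_here = ok_from_here and exceeds[i]
        if ok_from_here:
            cutoff = float(edges[i])
    return CrossoverCutoff(cutoff=cutoff, bin_width=bin_width, bin_edges=edges)


def crossover_classify(test_r, cutoff) -> np.ndarray:
    """Call pairs with correlation at or above the crossover cutoff.

    A missing (never-crossing) cutoff yields no calls, with a warning.
    """
    test_r = np.asarray(test_r, dtype=float)
    if isinstance(cutoff, CrossoverCutoff):
        cutoff = cutoff.cutoff
    if cutoff is None:
        warnings.warn("no crossover cutoff found; calling nothing", UserWarning)
        return np.zeros(test_r.shape, dtype=bool)
    return test_r >= cutoff


def randomization_p(r_target: float, null_pool_r, n_rand: int = 1000,
                    rng=None) -> RandomizationResult:
    """Add-one randomization p-value of one correlation against a null pool.

    Draws ``n_rand`` correlations from the pool with replacement and counts
    those strictly greater than the target; p = (k + 1) / (n_rand + 1),
    which can never reach 0.
    """
    pool = np.asarray(null_pool_r, dtype=float)
    if pool.size == 0:
        raise ValueError("empty null pool")
    rng = np.random.default_rng(rng)
    draws = pool[rng.integers(0, pool.size, size=n_rand)]
    k = int((draws > r_target).sum())
    return RandomizationResult(k_greater=k, p_value=(k + 1) / (n_rand + 1),
                               n_rand=n_rand)


def calibrate_cutoff_fdr(p_binding, p_control, target_fdr: float = 0.05) -> float:
    """Largest p cutoff keeping the empirical FDR at or below the target.

    Control calls (p <= cutoff) count as false positives; candidate cutoffs
    are the observed p-values. When no candidate qualifies, a value just
    below the smallest observed p (calling nothing) is returned.
    """
    pb = np.asarray(p_binding, dtype=float)
    pc = np.asarray(p_control, dtype=float)
    if pb.size == 0 or pc.size == 0:
        raise ValueError("both p-value vectors must be nonempty")
    candidates = np.unique(np.concatenate([pb, pc]))[::-1]  # descending
    for tau in candidates:
        calls_b = int((pb <= tau).sum())
        calls_c = int((pc <= tau).sum())
        total = calls_b + calls_c
        fdr = calls_c / total if total else 0.0
        if fdr <= target_fdr:
            return float(tau)
    return float(candidates[-1] - 1e-12)


class CrossoverDetector:
    """Crossover-cutoff classifier over labeled correlations.

    ``fit(r, y)`` learns the cutoff from correlations ``r`` with boolean
    labels ``y`` (True = binding); ``predict(r)`` calls pairs at or above
    it. Fitted attributes: ``cutoff_`` (CrossoverCutoff).
    """

    def __init__(self, bin_width: float = 0.05):
        self.bin_width = bin_width

    def get_params(self, deep=True):
        return {"bin_width": self.bin_width}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError("invalid parameter %r" % k)
            setattr(self, k, v)
        return self

    def fit(self, r, y):
        r = np.asarray(r, dtype=float)
        y = np.asarray(y, dtype=bool)
        self.cutoff_ = crossover_cutoff(r[y], r[~y], bin_width=self.bin_width)
        return self

    def predict(self, r) -> np.ndarray:
        return crossover_classify(r, self.cutoff_)


class RandomizationDetector:
    """Randomization-null classifier with FDR-calibrated p cutoff.

    ``fit(r, y)`` computes per-pair randomization p-values against the
    control pool (optionally excluding, per target pair, null pairs sharing
    a gene) and calibrates the p cutoff to the target FDR on the labels.
    Fitted attributes: ``p_values_``, ``cutoff_``, ``calls_``.
    """

    def __init__(self, n_rand: int = 1000, target_fdr: float = 0.05,
                 allow_shared_genes: bool = False, random_state: int = 0):
        self.n_rand = n_rand
        self.target_fdr = target_fdr
        self.allow_shared_genes = allow_shared_genes
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "n_rand": self.n_rand,
            "target_fdr": self.target_fdr,
            "allow_shared_genes": self.allow_shared_genes,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError("invalid parameter %r" % k)
            setattr(self, k, v)
        return self

    def fit(self, r, y, genes=None):
        """Learn p-values and cutoff from labeled correlations.

        ``genes`` is an optional (m, 2) array of gene labels used for the
        shared-gene leakage guard.
        """
        r = np.asarray(r, dtype=float)
        y = np.asarray(y, dtype=bool)
        rng = np.random.default_rng(self.random_state)
        ctrl_idx = np.flatnonzero(~y)
        pool = r[ctrl_idx]
        if pool.size == 0:
            raise ValueError("empty null pool")
        p = np.empty(r.size)
        if genes is not None:
            genes = np.asarray(genes, dtype=object)
        self_pos = {int(ci): j for j, ci in enumerate(ctrl_idx)}
        gene_to_ctrl = {}
        if genes is not None and not self.allow_shared_genes:
            for j, cj in enumerate(ctrl_idx):
                for g in genes[cj]:
                    gene_to_ctrl.setdefault(g, []).append(j)
        for i in range(r.size):
            exclude = set()
            if i in self_pos:
                exclude.add(self_pos[i])
            if genes is not None and not self.allow_shared_genes:
                for g in genes[i]:
                    exclude.update(gene_to_ctrl.get(g, ()))
            this_pool = np.delete(pool, sorted(exclude)) if exclude else pool
            if this_pool.size == 0:
                raise ValueError("empty null pool after shared-gene exclusion")
            p[i] = randomization_p(r[i], this_pool, n_rand=self.n_rand,
                                   rng=rng).p_value
        self.p_values_ = p
        self.cutoff_ = calibrate_cutoff_fdr(p[y], p[~y], self.target_fdr)
        self.calls_ = p <= self.cutoff_
        return self

    def predict(self, r=None) -> np.ndarray:
        if r is not None:
            raise ValueError(
                "randomization p-values are defined only for fitted pairs; "
                "call fit on the full labeled set"
            )
        return self.calls_
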