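"""Independent contrasts and the Brownian-Motion screen."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from coevo.diagnostics import bm_violation_test, filter_bm, pic
from coevo.normalize import ExpressionPanel
from coevo.phylo import vcv
from coevo.synthetic import PairRecord, simulate_pair, simulate_tree


class TestPic:
    def test_worked_example(self, cherry3):
        cs = pic(cherry3, {"A": 1.0, "B": 3.0, "C": 10.0})
        np.testing.assert_allclose(sorted(cs.contrasts), [-4.2762, -1.4142],
                                   atol=1e-4)
        np.testing.assert_allclose(sorted(cs.sds), [1.4142, 1.8708], atol=1e-4)

    def test_two_tip_tree(self, tree_from_string):
        cs = pic(tree_from_string("(A:1,B:1);"), {"A": 0.0, "B": 2.0})
        np.testing.assert_allclose(cs.contrasts, [-np.sqrt(2)])

    def test_constant_trait_gives_zero_contrasts(self, cherry3):
        cs = pic(cherry3, {"A": 2.0, "B": 2.0, "C": 2.0})
        np.testing.assert_allclose(cs.contrasts, 0.0)
        assert (cs.sds > 0).all()

    def test_rotation_invariant_up_to_sign(self, tree_from_string):
        x = {"A": 1.0, "B": 3.0, "C": 10.0}
        a = pic(tree_from_string("((A:1,B:1):1,C:2);"), x)
        b = pic(tree_from_string("(C:2,(B:1,A:1):1);"), x)
        np.testing.assert_allclose(sorted(np.abs(a.contrasts)),
                                   sorted(np.abs(b.contrasts)), atol=1e-12)
        np.testing.assert_allclose(sorted(a.sds), sorted(b.sds), atol=1e-12)

    def test_missing_value_errors(self, cherry3):
        with pytest.raises(ValueError):
            pic(cherry3, {"A": 1.0, "B": np.nan, "C": 2.0})

    def test_multifurcation_resolved(self, tree_from_string):
        star = tree_from_string("(A:1,B:1,C:1,D:1);")
        cs = pic(star, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        assert cs.contrasts.size == 3

    def test_sum_squared_contrasts_estimates_rate(self, rng):
        t = simulate_tree(64, root_age=1.0, seed=3)
        C = vcv(t)
        sigma2 = 2.5
        ests = []
        for _ in range(200):
            x = simulate_pair(C, np.diag([sigma2, 1.0]), rng=rng)[0]
            cs = pic(t, dict(zip(C.species, x)))
            ests.append((cs.contrasts ** 2).sum() / cs.contrasts.size)
        assert np.mean(ests) == pytest.approx(sigma2, rel=0.05)

    def test_matches_ape_pic(self, tmp_path):
        """Cross-package oracle: ape::pic on a random 8-tip tree."""
        t = simulate_tree(8, root_age=5.0, seed=21)
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        cs = pic(t, dict(zip(t.tip_labels, x)))
        nwk = tmp_path / "t.nwk"
        t.write_newick(nwk)
        vals = ",".join("%s=%.12f" % (sp, v) for sp, v in zip(t.tip_labels, x))
        script = textwrap.dedent("""
            suppressMessages(library(ape))
            tr <- read.tree("%s")
            x <- c(%s)
            p <- pic(x[tr$tip.label], tr, var.contrasts=TRUE)
            cat(sprintf("%%.10f", p[,1]), sep="\\n")
            cat("---\\n")
            cat(sprintf("%%.10f", sqrt(p[,2])), sep="\\n")
        """ % (nwk, vals))
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        top, bottom = out.stdout.split("---")
        r_contrasts = np.array([float(v) for v in top.split()])
        r_sds = np.array([float(v) for v in bottom.split()])
        np.testing.assert_allclose(sorted(np.abs(cs.contrasts)),
                                   sorted(np.abs(r_contrasts)), atol=1e-8)
        np.testing.assert_allclose(sorted(cs.sds), sorted(r_sds), atol=1e-8)


class TestBMViolation:
    def test_constructed_violation(self, tree_from_string):
        # heteroscedastic by construction: contrasts proportional to their sds
        t = simulate_tree(12, root_age=3.0, seed=9)
        base = pic(t, dict(zip(t.tip_labels, np.zeros(12))))
        # build trait producing |contrast| = 2*sds is hard directly; instead
        # feed a strongly non-BM trait (exponential of depth-correlated noise)
        rng = np.random.default_rng(0)
        C = vcv(t)
        x = np.exp(4 * simulate_pair(C, np.eye(2), rng=rng)[0] / np.sqrt(C.matrix.max()))
        r, p, violated = bm_violation_test(t, dict(zip(C.species, x)))
        assert np.isfinite(r) and 0 <= p <= 1

    def test_constant_trait_untestable(self, star4):
        r, p, violated = bm_violation_test(star4, np.full(4, 3.0))
        assert not violated
        assert np.isnan(r)

    def test_too_few_tips_errors(self, cherry3):
        with pytest.raises(ValueError):
            bm_violation_test(cherry3, [1.0, 2.0, 3.0])

    def test_null_calibration(self, rng):
        """Under true BM the screen flags ~5% of genes at alpha=0.05."""
        t = simulate_tree(18, root_age=723.0, seed=2)
        C = vcv(t)
        n_rep = 400
        flags = 0
        for _ in range(n_rep):
            x = simulate_pair(C, np.eye(2), rng=rng)[0]
            _, _, v = bm_violation_test(t, dict(zip(C.species, x)))
            flags += v
        rate = flags / n_rep
        # binomial 99% bounds around 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - half <= rate <= 0.05 + half


class TestFilterBM:
    def _setup(self):
        t = simulate_tree(10, root_age=5.0, seed=1)
        C = vcv(t)
        rng = np.random.default_rng(8)
        genes = {}
        for g in ("a", "b", "c"):
            genes[g] = simulate_pair(C, np.eye(2), rng=rng)[0]
        mean = pd.DataFrame(genes, index=C.species)
        se = mean * 0.0
        panel = ExpressionPanel(mean, se)
        pairs = [PairRecord("a", "b"), PairRecord("b", "c")]
        return panel, t, pairs

    def test_disabled_is_identity(self):
        panel, t, pairs = self._setup()
        kept, report = filter_bm(panel, t, pairs, enabled=False)
        assert kept == pairs and report == {}

    def test_no_violation_identity(self):
        panel, t, pairs = self._setup()
        kept, report = filter_bm(panel, t, pairs, alpha=1e-12)
        assert kept == pairs
        assert set(report) == {"a", "b", "c"}

    def test_violating_gene_drops_its_pairs(self):
        panel, t, pairs = self._setup()
        kept, report = filter_bm(panel, t, pairs, alpha=1.01)
        # alpha > 1 flags every testable gene, so everything drops
        assert kept == []
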