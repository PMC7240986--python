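"""Bivariate Brownian-Motion likelihood, fitting and the coevolution LRT."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from coevo import mvbm
from coevo.phylo import vcv
from coevo.synthetic import simulate_pair, simulate_tree

STAR4_X = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]])


def dense_mvn_loglik(C, x, se, theta, R):
    """Independent oracle: explicit 2n-dimensional multivariate normal."""
    S = np.kron(np.asarray(R, float), C) + np.diag(np.asarray(se, float).ravel() ** 2)
    mu = np.repeat(np.asarray(theta, float), C.shape[0])
    return multivariate_normal.logpdf(np.asarray(x, float).ravel(), mean=mu, cov=S)


class TestLoglik:
    def test_univariate_star_closed_form(self, tree_from_string):
        # one effective trait on a 3-tip star: matches the scalar normal density
        C = vcv(tree_from_string("(A:1,B:1,C:1);")).matrix
        x = np.array([[1.0, 0.0, -1.0], [0.5, 0.0, -0.5]])
        sigma2 = 2.0 / 3.0
        R = np.array([[sigma2, 0.0], [0.0, 1.0]])
        ll = mvbm.bm_loglik(C, x, None, [0.0, 0.0], R)
        expected_trait1 = -(3 / 2) * np.log(2 * np.pi * sigma2) - 2.0 / (2 * sigma2)
        expected_trait2 = -(3 / 2) * np.log(2 * np.pi) - 0.5 / 2
        assert ll == pytest.approx(expected_trait1 + expected_trait2, abs=1e-6)
        assert expected_trait1 == pytest.approx(-3.6486, abs=1e-4)

    def test_matches_dense_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            t = simulate_tree(n, root_age=10.0, seed=int(rng.integers(2 ** 31)))
            C = vcv(t).matrix
            R = mvbm._pack_R(*rng.normal(0, 1, 2), float(np.clip(rng.normal(), -2, 2)))
            x = rng.normal(size=(2, n))
            se = np.abs(rng.normal(0.3, 0.1, size=(2, n)))
            theta = rng.normal(size=2)
            ll = mvbm.bm_loglik(C, x, se, theta, R)
            assert ll == pytest.approx(dense_mvn_loglik(C, x, se, theta, R),
                                       abs=1e-8)

    def test_huge_se_removes_information(self, cherry3, rng):
        # with one observation's SE blown up, loglik differences across
        # parameter values equal those of the model without that species
        C = vcv(cherry3).matrix
        x = rng.normal(size=(2, 3))
        se = np.zeros((2, 3))
        se[0, 2] = 1e6
        R1 = np.array([[1.0, 0.3], [0.3, 1.0]])
        R2 = np.array([[2.0, -0.5], [-0.5, 1.5]])
        d_full = (mvbm.bm_loglik(C, x, se, [0, 0], R1)
                  - mvbm.bm_loglik(C, x, se, [0, 0], R2))
        # reduced model: drop species C's trait-1 observation via the dense oracle
        keep = [0, 1, 3, 4, 5]
        S1 = np.kron(R1, C)[np.ix_(keep, keep)]
        S2 = np.kron(R2, C)[np.ix_(keep, keep)]
        xv = x.ravel()[keep]
        d_red = (multivariate_normal.logpdf(xv, mean=np.zeros(5), cov=S1)
                 - multivariate_normal.logpdf(xv, mean=np.zeros(5), cov=S2))
        assert d_full == pytest.approx(d_red, abs=1e-4)


class TestFitPair:
    def test_star_tree_reduces_to_pearson(self, star4):
        res = mvbm.fit_pair(vcv(star4), STAR4_X)
        assert res.rho_c == pytest.approx(0.8, abs=1e-6)
        assert res.converged

    def test_constrained_fit_zeroes_covariance(self, star4):
        res = mvbm.fit_pair(vcv(star4), STAR4_X, constrain_zero_cov=True)
        assert res.R.r12 == 0.0
        assert res.rho_c == 0.0

    def test_collinear_traits_clamp_to_boundary(self, star4):
        x = np.vstack([STAR4_X[0], STAR4_X[0]])
        res = mvbm.fit_pair(vcv(star4), x)
        assert res.rho_c == pytest.approx(1.0, abs=1e-5)
        assert res.boundary

    def test_too_few_species_errors(self, tree_from_string):
        t = tree_from_string("(A:1,B:1);")
        with pytest.raises(ValueError, match="at least 3"):
            mvbm.fit_pair(vcv(t), np.ones((2, 2)))

    def test_constant_trait_errors(self, star4):
        x = np.vstack([np.ones(4), STAR4_X[1]])
        with pytest.raises(ValueError, match="non-constant"):
            mvbm.fit_pair(vcv(star4), x)


class TestLRT:
    def test_star_tree_closed_form(self, star4):
        C = vcv(star4)
        full = mvbm.fit_pair(C, STAR4_X)
        null = mvbm.fit_pair(C, STAR4_X, constrain_zero_cov=True)
        out = mvbm.lrt(full, null)
        assert out.lrt_stat == pytest.approx(-4 * np.log(1 - 0.8 ** 2), abs=1e-6)

    def test_identical_fits_give_p_one(self, star4):
        null = mvbm.fit_pair(vcv(star4), STAR4_X, constrain_zero_cov=True)
        out = mvbm.lrt(null, null)
        assert out.lrt_stat == 0.0
        assert out.p_value == 1.0

    def test_chi2_critical_value(self, star4):
        from scipy.stats import chi2

        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_invariant_to_affine_rescaling(self, rng):
        t = simulate_tree(8, root_age=10.0, seed=5)
        C = vcv(t)
        x = simulate_pair(C, np.array([[1.0, 0.5], [0.5, 1.0]]), rng=rng)
        se = np.full((2, 8), 0.05)

        def stat(xx, ss):
            full = mvbm.fit_pair(C, xx, ss)
            null = mvbm.fit_pair(C, xx, ss, constrain_zero_cov=True)
            return mvbm.lrt(full, null).lrt_stat

        base = stat(x, se)
        x2 = x.copy()
        x2[0] = 3.0 * x2[0] - 7.0
        se2 = se.copy()
        se2[0] *= 3.0
        assert stat(x2, se2) == pytest.approx(base, abs=1e-4)


class TestRhoU:
    def test_worked_example(self):
        r, p = mvbm.rho_u(STAR4_X[0], STAR4_X[1])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert 0 < p < 1

    def test_antithetic(self):
        r, _ = mvbm.rho_u([1.0, 2, 3, 4], [-1.0, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            mvbm.rho_u([1.0, 2, 3], [5.0, 5, 5])


class TestEstimatorAPI:
    def test_fit_attributes_and_test(self, star4):
        est = mvbm.PhyloPairBM(vcv(star4)).fit(STAR4_X.T)
        assert est.rho_c_ == pytest.approx(0.8, abs=1e-6)
        assert est.converged_
        out = est.test()
        assert est.lrt_stat_ == pytest.approx(out.lrt_stat)
        assert 0 <= est.p_value_ <= 1

    def test_get_set_params(self):
        est = mvbm.PhyloPairBM()
        est.set_params(constrain_zero_cov=True)
        assert est.get_params()["constrain_zero_cov"] is True
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)


def test_fit_matches_independent_r_implementation(tmp_path):
    """Cross-package oracle: ML rate matrix from phytools::evol.vcv."""
    t = simulate_tree(10, root_age=5.0, seed=11)
    C = vcv(t)
    x = simulate_pair(C, np.array([[1.0, 0.6], [0.6, 1.0]]),
                      rng=np.random.default_rng(7))
    res = mvbm.fit_pair(C, x)
    nwk = tmp_path / "t.nwk"
    t.write_newick(nwk)
    dat = tmp_path / "x.tsv"
    with open(dat, "w") as fh:
        fh.write("species\tx\ty\n")
        for i, sp in enumerate(C.species):
            fh.write("%s\t%.12f\t%.12f\n" % (sp, x[0, i], x[1, i]))
    script = textwrap.dedent("""
        suppressMessages(library(phytools))
        tr <- read.tree("%s")
        d <- read.table("%s", header=TRUE, row.names=1)
        fit <- evol.vcv(tr, as.matrix(d))
        R <- fit$R.single
        cat(R[1,1], R[2,2], R[1,2], fit$logL1, sep="\\n")
    """ % (nwk, dat))
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    r11, r22, r12, logl = map(float, out.stdout.strip().split("\n"))
    rho_r = r12 / np.sqrt(r11 * r22)
    assert res.rho_c == pytest.approx(rho_r, abs=1e-4)
    assert res.loglik == pytest.approx(logl, abs=1e-4)
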