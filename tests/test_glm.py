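"""NB GLM fitting and likelihood-ratio tests."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from mirgba.glm import contrast_design, fit_nbglm, lrt, nb_loglik
from mirgba.simulate import SimulationConfig, design_matrix, simulate_counts

GBA_CONTRAST = np.array([0.0, 0.0, -1.0, 1.0])


def _small_instance(seed, n=8, p=2, phi=0.2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    if np.linalg.matrix_rank(X) < p:  # force both groups present
        X[0, 1], X[1, 1] = 0.0, 1.0
    offsets = rng.uniform(8, 9, n)
    beta = rng.normal(-6, 0.5, p)
    mu = np.exp(X @ beta + offsets)
    y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu), size=n).astype(float)
    return y[None, :], X, offsets, phi


class TestFit:
    def test_poisson_closed_form_single_group(self):
        fit = fit_nbglm(np.array([[3.0, 5.0]]), np.ones((2, 1)), np.zeros(2), 0.0)
        assert np.allclose(fit.fitted, 4.0)
        assert fit.coef[0, 0] == pytest.approx(np.log(4.0), abs=1e-8)

    @pytest.mark.parametrize("phi", [0.0, 0.2, 1.0])
    def test_saturated_design_reproduces_cell_means(self, rng, phi):
        """Any dispersion: the saturated 2x2 fit hits observed cell means."""
        from mirgba.simulate import make_design

        design = make_design(4)
        X = design_matrix(design).to_numpy()
        y = rng.poisson(40, size=(6, len(design))).astype(float)
        fit = fit_nbglm(y, X, np.zeros(len(design)), phi)
        cells = list(zip(design["genotype"], design["age"]))
        for cell in set(cells):
            cols = [i for i, c in enumerate(cells) if c == cell]
            assert np.allclose(
                fit.fitted[:, cols].mean(axis=1), y[:, cols].mean(axis=1), rtol=1e-5
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_generic_optimizer(self, seed):
        """IRLS deviance agrees with direct likelihood maximization."""
        y, X, offsets, phi = _small_instance(seed)
        fit = fit_nbglm(y, X, offsets, phi)

        def negll(beta):
            mu = np.exp(X @ beta + offsets)
            return -nb_loglik(y, mu[None, :], phi)[0]

        opt = optimize.minimize(negll, np.zeros(X.shape[1]), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        ll_irls = nb_loglik(y, fit.fitted, phi)[0]
        assert ll_irls == pytest.approx(-opt.fun, abs=1e-6)

    def test_all_zero_feature_no_crash(self):
        y = np.vstack([np.zeros(4), [5.0, 6, 7, 8]])
        fit = fit_nbglm(y, np.ones((4, 1)), np.zeros(4), 0.1)
        assert np.all(fit.fitted > 0)
        assert np.isfinite(fit.deviance).all()

    def test_rank_deficient_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_nbglm(np.ones((1, 4)), X, np.zeros(4), 0.1)


@pytest.fixture(scope="module")
def small_fit():
    cfg = SimulationConfig(n_features=40, n_per_cell=3, seed=5, frac_pattern_c=0.2)
    counts, design, _ = simulate_counts(cfg)
    y = counts.to_numpy(float)
    X = design_matrix(design).to_numpy()
    offsets = np.log(y.sum(0))
    return y, X, offsets


class TestLRT:

    def test_contrast_equals_reparameterized_coefficient(self, small_fit):
        """Testing a single coefficient via a contrast changes nothing."""
        y, X, offsets = small_fit
        s1, p1, l1 = lrt(y, X, offsets, 0.1, coef=3)
        c = np.zeros(4)
        c[3] = 1.0
        s2, p2, l2 = lrt(y, X, offsets, 0.1, contrast=c)
        assert np.allclose(s1, s2, atol=1e-8)
        assert np.allclose(l1, l2, atol=1e-6)

    def test_contrast_scale_invariance(self, small_fit):
        y, X, offsets = small_fit
        s1, _, l1 = lrt(y, X, offsets, 0.1, contrast=GBA_CONTRAST)
        s2, _, l2 = lrt(y, X, offsets, 0.1, contrast=3.0 * GBA_CONTRAST)
        assert np.allclose(s1, s2, atol=1e-7)
        assert np.allclose(3.0 * l1, l2, atol=1e-5)

    def test_flat_feature_null_statistic(self):
        y = np.full((1, 20), 7.0)
        from mirgba.simulate import make_design

        design = make_design(5)
        X = design_matrix(design).to_numpy()
        s, p, _ = lrt(y, X, np.zeros(20), 0.1, contrast=GBA_CONTRAST)
        assert s[0] == pytest.approx(0.0, abs=1e-6)
        assert p[0] == pytest.approx(1.0, abs=1e-4)

    def test_null_interaction_pvalues_uniform(self):
        """With the true dispersion, null LRT p-values are uniform."""
        cfg = SimulationConfig(
            n_features=2000, n_per_cell=5, dispersion=0.16,
            frac_pattern_a=0, frac_pattern_b=0, frac_pattern_c=0,
            frac_pattern_d=0, seed=2024,
        )
        counts, design, _ = simulate_counts(cfg)
        y = counts.to_numpy(float)
        X = design_matrix(design).to_numpy()
        _, p, _ = lrt(y, X, np.log(y.sum(0)), 0.16, contrast=GBA_CONTRAST)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_contrast_outside_design_rejected(self, small_fit):
        y, X, offsets = small_fit
        with pytest.raises(ValueError):
            lrt(y, X, offsets, 0.1, contrast=np.zeros(4))
        with pytest.raises(ValueError):
            lrt(y, X, offsets, 0.1)  # neither coef nor contrast

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_matches_edger_glmfit(self, tmp_path):
        """Coefficients and LRT statistics agree with edgeR at fixed phi."""
        cfg = SimulationConfig(n_features=30, n_per_cell=3, seed=12, frac_pattern_c=0.2)
        counts, design, _ = simulate_counts(cfg)
        y = counts.to_numpy(float)
        X = design_matrix(design).to_numpy()
        offsets = np.log(y.sum(0))
        fit = fit_nbglm(y, X, offsets, 0.1)
        s_n, _, l_n = lrt(y, X, offsets, 0.1, coef=2, fit=fit)
        s_g, _, l_g = lrt(y, X, offsets, 0.1, contrast=GBA_CONTRAST, fit=fit)

        cpath, dpath, opath = (
            tmp_path / "c.tsv", tmp_path / "d.tsv", tmp_path / "o.tsv",
        )
        counts.to_csv(cpath, sep="\t")
        design.to_csv(dpath, sep="\t", index=False)
        script = f"""
suppressMessages(library(edgeR))
x <- as.matrix(read.delim('{cpath}', row.names=1))
targets <- read.delim('{dpath}')
targets$genotype <- relevel(factor(targets$genotype), 'Normal')
targets$age <- relevel(factor(targets$age), 'Young')
design <- model.matrix(~genotype + genotype:age, data=targets)
fit <- glmFit(x, design, dispersion=0.1, lib.size=colSums(x), prior.count=0)
a <- glmLRT(fit, coef=3)$table; b <- glmLRT(fit, contrast=c(0,0,-1,1))$table
write.table(cbind(a$logFC, a$LR, b$logFC, b$LR), '{opath}',
            sep='\t', quote=FALSE, row.names=FALSE, col.names=FALSE)
"""
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(opath, sep="\t", header=None).to_numpy()
        assert np.allclose(ref[:, 0], l_n, atol=1e-4)
        assert np.allclose(ref[:, 1], s_n, atol=1e-5)
        assert np.allclose(ref[:, 2], l_g, atol=1e-4)
        assert np.allclose(ref[:, 3], s_g, atol=1e-5)


def test_contrast_design_spans_same_space():
    X = design_matrix(
        __import__("mirgba.simulate", fromlist=["make_design"]).make_design(3)
    ).to_numpy()
    X_new, X_red = contrast_design(X, GBA_CONTRAST)
    # same column space: projections agree
    P = X @ np.linalg.pinv(X)
    P_new = X_new @ np.linalg.pinv(X_new)
    assert np.allclose(P, P_new, atol=1e-10)
    assert X_red.shape[1] == X.shape[1] - 1
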