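"""REML machinery: oracle equivalence, parameter recovery, SNP models,
epistasis and diagnostics."""

import numpy as np
import pytest

from expherit.reml_core import (EigenRotation, MixedModelSpec,
                                VarianceComponents, make_spec, reml_fit,
                                heritability, fit_snp_model,
                                eqtl_heritability, fit_epistasis,
                                model_diagnostics, _restricted_ll)
from tests.conftest import make_expression


def _random_instance(rng, n_ind=None, n_rep=None, p=None):
    """A small random mixed-model instance with a genotype-derived K."""
    n_ind = n_ind or int(rng.integers(8, 30))
    n_rep = n_rep or int(rng.integers(1, 3))
    p = p or int(rng.integers(1, 3))
    m = 80
    freqs = rng.uniform(0.1, 0.5, m)
    g = rng.binomial(2, freqs, size=(n_ind, m)).astype(float)
    x = (g - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))
    K = x @ x.T / m
    K = K + 1e-6 * np.eye(n_ind)
    idx = np.repeat(np.arange(n_ind), n_rep)
    X = np.column_stack([np.ones(idx.size)]
                        + [rng.normal(size=idx.size) for _ in range(p - 1)])
    lam_true = 10 ** rng.uniform(-1, 1)
    L = np.linalg.cholesky(K + 1e-9 * np.eye(n_ind))
    y = X @ rng.normal(size=p) \
        + np.sqrt(lam_true) * (L @ rng.normal(size=n_ind))[idx] \
        + rng.normal(size=idx.size)
    return MixedModelSpec(y, X, idx, K)


def grid_oracle(spec, n_grid=2000):
    """Independent dense-grid maximiser of the restricted likelihood."""
    rot = EigenRotation(spec.K, spec.indiv_index)
    ystar, Xstar = rot.rotate(spec.y), rot.rotate(spec.X)
    grid = np.concatenate([[0.0], np.logspace(-5, 5, n_grid)])
    vals = [_restricted_ll(l, rot.d, ystar, Xstar)[0] for l in grid]
    return float(np.max(vals))


def test_profiled_optimum_matches_dense_grid():
    rng = np.random.default_rng(12345)
    for _ in range(8):
        spec = _random_instance(rng)
        vc = reml_fit(spec)
        assert vc.loglik_reml >= grid_oracle(spec) - 1e-6


def test_recovery_of_equal_components(study400):
    """sigma_g2 = sigma_e2 = 1 truth at n=400, 4 replicates."""
    panel, _, cfg, K = study400
    rng = np.random.default_rng(99)
    n = panel.n_individuals
    idx = np.repeat(np.arange(n), 4)
    w, q = np.linalg.eigh(K)
    L = q * np.sqrt(np.clip(w, 0, None))
    y = (L @ rng.standard_normal(n))[idx] + rng.standard_normal(idx.size)
    spec = MixedModelSpec(y, np.ones((idx.size, 1)), idx, K)
    vc = reml_fit(spec)
    assert abs(vc.sigma_g2 - 1.0) < 0.15
    assert abs(vc.sigma_e2 - 1.0) < 0.15


def test_null_truth_rarely_shows_heritability(study400):
    panel, _, cfg, K = study400
    rng = np.random.default_rng(7)
    idx = np.repeat(np.arange(panel.n_individuals), 4)
    rot = EigenRotation(K, idx)
    X = np.ones((idx.size, 1))
    low = 0
    n_rep = 40
    for _ in range(n_rep):
        y = rng.standard_normal(idx.size)
        vc = reml_fit(MixedModelSpec(y, X, idx, K), rotation=rot)
        low += vc.h2 < 0.05
    assert low >= 0.9 * n_rep


@pytest.mark.parametrize("sg,se,expected", [
    (1.0, 1.0, 0.5), (0.0, 2.0, 0.0), (3.0, 1.0, 0.75)])
def test_heritability_ratio(sg, se, expected):
    vc = VarianceComponents(sg, se, 0., 0., np.zeros(1), 0., 10, 1)
    assert heritability(vc) == pytest.approx(expected)


def test_heritability_undefined_flagged():
    vc = VarianceComponents(0.0, 0.0, 0., 0., np.zeros(1), 0., 10, 1)
    assert heritability(vc) == 0.0
    assert "undefined_h2" in vc.flags


def test_non_psd_kinship_rejected():
    K = np.array([[1.0, 2.0], [2.0, 1.0]])   # eigenvalues 3, -1
    with pytest.raises(ValueError, match="positive semi-definite"):
        EigenRotation(K, np.array([0, 0, 1, 1]))


class TestSnpModel:
    def test_irrelevant_snp_changes_little(self, study400_expression):
        panel, expr, truth, cfg, K = study400_expression
        idx = np.repeat(np.arange(panel.n_individuals), cfg.n_replicates)
        rot = EigenRotation(K, idx)
        spec = make_spec(expr.values[2], panel.populations, K)
        vc_free = reml_fit(spec, rotation=rot)
        x = panel.dosages[:, 500].copy()
        x[np.isnan(x)] = np.nanmean(x)
        vc_snp = fit_snp_model(spec, x[idx][:, None], rotation=rot)
        eh = eqtl_heritability(vc_free, vc_snp)
        assert eh.h2_qtl < 0.02

    def test_collinear_snp_dropped_with_warning(self, study400_expression):
        panel, expr, truth, cfg, K = study400_expression
        spec = make_spec(expr.values[1], panel.populations, K)
        const = np.ones((spec.y.size, 1))
        with pytest.warns(UserWarning, match="collinear"):
            aug = spec.with_columns(const)
        assert aug.X.shape[1] == spec.X.shape[1]

    def test_planted_snp_variance_recovered(self, study400):
        panel, _, cfg, K = study400
        expr, truth, ecfg = make_expression(
            panel, cfg, seed=314, n_genes=2, h2_list=[0.3, 0.3],
            qtl_specs=[(0, "trans", 0.2), (1, "trans", 0.1)])
        idx = np.repeat(np.arange(panel.n_individuals), 4)
        rot = EigenRotation(K, idx)
        snp_ids = list(panel.snps["snp_id"])
        spec0 = make_spec(expr.values[0], panel.populations, K)
        vc_free = reml_fit(spec0, rotation=rot)
        j = snp_ids.index(truth.qtl_truth[0][1])
        x = panel.dosages[:, j].copy()
        x[np.isnan(x)] = np.nanmean(x)
        vc_snp = fit_snp_model(spec0, x[idx][:, None], rotation=rot)
        eh = eqtl_heritability(vc_free, vc_snp)
        assert abs(eh.h2_qtl - 0.2) < 0.07
        # the drop must be genetic, not residual
        assert eh.delta_sigma_g2 > 3 * abs(eh.delta_sigma_e2)


class TestEqtlHeritabilityArithmetic:
    def _vc(self, sg, se):
        return VarianceComponents(sg, se, 0., 0., np.zeros(1), 0., 10, 1)

    def test_fraction_of_sum_drop(self):
        eh = eqtl_heritability(self._vc(0.5, 0.5), self._vc(0.4, 0.4))
        assert eh.h2_qtl == pytest.approx(0.2)

    def test_equal_sums_give_zero(self):
        eh = eqtl_heritability(self._vc(0.5, 0.5), self._vc(0.6, 0.4))
        assert eh.h2_qtl == 0.0

    def test_increase_floored_with_flag(self):
        eh = eqtl_heritability(self._vc(0.5, 0.5), self._vc(0.6, 0.5))
        assert eh.h2_qtl == 0.0
        assert "negative_h2_qtl_floored" in eh.flags

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            eqtl_heritability(self._vc(0.0, 0.0), self._vc(0.1, 0.1))


class TestEpistasis:
    def test_interaction_never_explains_less(self, study400):
        panel, _, cfg, K = study400
        expr, truth, _ = make_expression(
            panel, cfg, seed=55, n_genes=1, h2_list=[0.3],
            epistasis_specs=[(0, 0.15)])
        idx = np.repeat(np.arange(panel.n_individuals), 4)
        rot = EigenRotation(K, idx)
        snp_ids = list(panel.snps["snp_id"])
        _, s1, s2, _ = truth.epistasis_truth[0]
        x1 = panel.dosages[:, snp_ids.index(s1)].copy()
        x2 = panel.dosages[:, snp_ids.index(s2)].copy()
        x1[np.isnan(x1)] = np.nanmean(x1)
        x2[np.isnan(x2)] = np.nanmean(x2)
        spec = make_spec(expr.values[0], panel.populations, K)
        res = fit_epistasis(spec, x1[idx], x2[idx], rotation=rot)
        assert res.h2_qtl_interaction >= res.h2_qtl_additive - 1e-6
        assert res.preferred == "interaction"
        assert res.delta_explained > 0.05

    def test_constant_product_reports_additive(self, study400):
        panel, _, cfg, K = study400
        expr, truth, _ = make_expression(panel, cfg, seed=56, n_genes=1,
                                         h2_list=[0.3])
        spec = make_spec(expr.values[0], panel.populations, K)
        idx = np.repeat(np.arange(panel.n_individuals), 4)
        x1 = np.tile([0.0, 1.0], idx.size // 2)
        x2 = np.zeros(idx.size)
        with pytest.raises(ValueError, match="polymorphic"):
            fit_epistasis(spec, x1, x2)


class TestDiagnostics:
    def test_well_specified_model_not_flagged(self, study400_expression):
        panel, expr, truth, cfg, K = study400_expression
        idx = np.repeat(np.arange(panel.n_individuals), cfg.n_replicates)
        rot = EigenRotation(K, idx)
        flagged = 0
        for g in range(4):
            spec = make_spec(expr.values[g], panel.populations, K)
            vc = reml_fit(spec, rotation=rot)
            flagged += model_diagnostics(vc, spec).significant
        assert flagged <= 1

    def test_omitted_population_effect_fires_flag(self, study400):
        """Population expression shifts left out of the fixed design leak
        into the residual and correlate with the (population-structured)
        fitted SNP effect; the flag fires in most seeded replicates."""
        panel, _, cfg, K = study400
        n = panel.n_individuals
        pops = panel.populations
        levels = list(dict.fromkeys(pops))
        # the most population-differentiated SNP proxies the omitted shift
        freqs = np.vstack(
            [np.nanmean(panel.dosages[panel.population_index(p)], axis=0)
             / 2 for p in levels])
        j = int(np.argmax(freqs.max(axis=0) - freqs.min(axis=0)))
        x = panel.dosages[:, j].copy()
        x[np.isnan(x)] = np.nanmean(x)
        w, q = np.linalg.eigh(K)
        L = q * np.sqrt(np.clip(w, 0, None))
        idx = np.repeat(np.arange(n), 2)
        X = np.column_stack([np.ones(idx.size), x[idx]])
        rot = EigenRotation(K, idx)
        fired = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            shift = dict(zip(levels, rng.normal(0, 0.6, len(levels))))
            u = L @ rng.standard_normal(n)
            y_ind = np.asarray([shift[p] for p in pops]) + 0.4 * x + u
            y = y_ind[idx] + rng.normal(0, 0.5, idx.size)
            spec = MixedModelSpec(y, X, idx, K)
            vc = reml_fit(spec, rotation=rot)
            fired += model_diagnostics(vc, spec).significant
        assert fired >= 5

    def test_constant_response_reported_undefined(self, study400):
        panel, _, cfg, K = study400
        idx = np.repeat(np.arange(panel.n_individuals), 2)
        spec = MixedModelSpec(np.zeros(idx.size) + 5.0,
                              np.ones((idx.size, 1)), idx, K)
        vc = reml_fit(spec)
        diag = model_diagnostics(vc, spec)
        assert np.isnan(diag.correlation)
        assert "undefined" in diag.note
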