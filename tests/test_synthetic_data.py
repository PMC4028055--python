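"""Generator checks: divergence, missingness, planted structure, determinism."""

import numpy as np
import pytest

from expherit.synthetic_data import (SimConfig, simulate_genotypes,
                                     simulate_expression, simulate_trios,
                                     plant_relatives, simulate_study)


def weir_cockerham_fst(panel):
    """Independent Weir-Cockerham theta estimator over populations."""
    pops = panel.population_names()
    r = len(pops)
    n_i, p_i, h_i = [], [], []
    for pop in pops:
        g = panel.dosages[panel.population_index(pop)]
        n = (~np.isnan(g)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nansum(g, axis=0) / (2 * n)
            h = np.nansum(g == 1, axis=0) / n
        n_i.append(n), p_i.append(p), h_i.append(h)
    n_i, p_i, h_i = map(np.asarray, (n_i, p_i, h_i))
    nbar = n_i.mean(axis=0)
    nc = (r * nbar - (n_i ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                           - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a[ok].sum() / (a + b + c)[ok].sum()


def test_fst_of_simulated_panel_matches_divergence_parameter():
    cfg = SimConfig(n_populations=2, n_per_pop=100, n_snps=5000, fst=0.2,
                    n_genes=1, seed=1)
    panel, _ = simulate_genotypes(cfg)
    assert abs(weir_cockerham_fst(panel) - 0.2) < 0.03


def test_vanishing_divergence_gives_similar_population_frequencies():
    cfg = SimConfig(n_populations=2, n_per_pop=200, n_snps=3000, fst=0.01,
                    n_genes=1, seed=2)
    panel, _ = simulate_genotypes(cfg)
    assert weir_cockerham_fst(panel) < 0.03


def test_missingness_mask_and_positions():
    cfg = SimConfig(n_populations=2, n_per_pop=20, n_snps=200,
                    missing_rate=0.0, n_genes=1, seed=3)
    panel, _ = simulate_genotypes(cfg)
    assert not panel.missing_mask.any()
    for chrom, sub in panel.snps.groupby("chrom"):
        assert (np.diff(sub["pos"]) > 0).all()


def test_invalid_fst_rejected():
    with pytest.raises(ValueError, match="fst"):
        SimConfig(fst=1.5)


def test_seed_reproduces_outputs_bitwise():
    cfg = SimConfig(n_populations=2, n_per_pop=15, n_snps=150, n_genes=3,
                    missing_rate=0.05, n_families=4, seed=42)
    a = simulate_study(cfg)
    b = simulate_study(SimConfig(**{**cfg.__dict__}))
    np.testing.assert_array_equal(a[0].dosages, b[0].dosages)
    np.testing.assert_array_equal(a[1].values, b[1].values)
    ta, _, _ = simulate_trios(cfg)
    tb, _, _ = simulate_trios(cfg)
    np.testing.assert_array_equal(ta.dosages, tb.dosages)


class TestPlantRelatives:
    def test_duplicate_pair_identical(self, small_panel):
        panel, truth, cfg = small_panel
        a, b = panel.individuals[0], panel.individuals[1]
        out = plant_relatives(panel, [(a, b, "duplicate")], cfg)
        ga, gb = out.dosages[0], out.dosages[1]
        shared = ~np.isnan(ga) & ~np.isnan(gb)
        np.testing.assert_array_equal(ga[shared], gb[shared])

    def test_parent_offspring_share_an_allele_everywhere(self, small_panel):
        panel, truth, cfg = small_panel
        a, b = panel.individuals[2], panel.individuals[3]
        out = plant_relatives(panel, [(a, b, "parent_offspring")], cfg)
        ga, gb = out.dosages[2], out.dosages[3]
        shared = ~np.isnan(ga) & ~np.isnan(gb)
        # opposite homozygotes share no allele
        assert not np.any((ga[shared] == 0) & (gb[shared] == 2))
        assert not np.any((ga[shared] == 2) & (gb[shared] == 0))

    def test_cross_population_pair_rejected(self, small_panel):
        panel, truth, cfg = small_panel
        a = panel.individuals[0]
        b = panel.individuals[-1]
        with pytest.raises(ValueError, match="population"):
            plant_relatives(panel, [(a, b, "duplicate")], cfg)


def test_variance_decomposition_matches_configured_fractions():
    """Per-array variance of a simulated gene splits into the configured
    polygenic / QTL / residual fractions within Monte-Carlo error."""
    cfg = SimConfig(n_populations=1, n_per_pop=1000, n_snps=500, fst=0.1,
                    n_genes=2, h2_list=[0.4, 0.0],
                    qtl_specs=[(0, "trans", 0.2)], pop_effect_sd=0.0,
                    seed=8)
    panel, expr, truth = simulate_study(cfg)
    y = expr.values[0]
    total = y.var()
    assert abs(total - 1.0) < 0.1
    # replicate-shared (between-individual) variance = polygenic + QTL
    between = y.mean(axis=1).var() - y.var(axis=1).mean() / (y.shape[1] - 1)
    assert abs(between - 0.6) < 0.08
    null = expr.values[1]
    assert abs(null.var() - 1.0) < 0.1
    assert abs(null.mean(axis=1).var()
               - null.var(axis=1).mean() / (null.shape[1] - 1)) < 0.05


def test_null_gene_has_no_genetic_signal(study400):
    panel, truth, cfg, K = study400
    from expherit.reml_core import EigenRotation, make_spec, reml_fit
    expr, truth2 = simulate_expression(panel, cfg, truth)
    idx = np.repeat(np.arange(panel.n_individuals), cfg.n_replicates)
    rot = EigenRotation(K, idx)
    vc = reml_fit(make_spec(expr.values[0], panel.populations, K),
                  rotation=rot)
    assert vc.h2 < 0.05


class TestTrios:
    def test_offspring_equals_midparent_when_fully_heritable(self):
        cfg = SimConfig(n_populations=1, n_per_pop=2, n_snps=100, n_genes=2,
                        h2_list=[1.0], n_families=10,
                        replicate_noise_sd=0.0, seed=4)
        _, expr, fam = simulate_trios(cfg)
        means = expr.replicate_means()
        mid = (means[fam["father_id"]].to_numpy()
               + means[fam["mother_id"]].to_numpy()) / 2
        np.testing.assert_allclose(means[fam["child_id"]].to_numpy(), mid,
                                   atol=1e-10)

    def test_offspring_genotypes_are_mendelian(self):
        cfg = SimConfig(n_populations=1, n_per_pop=2, n_snps=300, n_genes=1,
                        n_families=5, seed=5)
        panel, _, fam = simulate_trios(cfg)
        d = {s: panel.dosages[i] for i, s in enumerate(panel.individuals)}
        for _, row in fam.iterrows():
            f, m, c = (d[row["father_id"]], d[row["mother_id"]],
                       d[row["child_id"]])
            # child dosage must be writable as tf + tm with tf in the
            # father's transmissible set and tm in the mother's
            lo = np.where(f == 2, 1, 0) + np.where(m == 2, 1, 0)
            hi = np.where(f >= 1, 1, 0) + np.where(m >= 1, 1, 0)
            assert np.all(c >= lo) and np.all(c <= hi)

    def test_too_few_families_rejected(self):
        cfg = SimConfig(n_families=1)
        with pytest.raises(ValueError, match="families"):
            simulate_trios(cfg)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimConfig(n_genes=3, h2_list=[0.1, 0.5, 0.9],
                    qtl_specs=[(0, "cis", 0.2)],
                    epistasis_specs=[(1, 0.1)], seed=9)
    cfg.to_yaml(tmp_path / "c.yaml")
    back = SimConfig.from_yaml(tmp_path / "c.yaml")
    assert back == cfg
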