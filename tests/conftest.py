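import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from expherit.synthetic_data import (SimConfig, simulate_genotypes,
                                     simulate_expression, realized_kinship)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """2 populations x 30 individuals, 400 SNPs, a little missingness."""
    cfg = SimConfig(n_populations=2, n_per_pop=30, n_snps=400, fst=0.15,
                    missing_rate=0.02, n_genes=2, seed=101)
    panel, truth = simulate_genotypes(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def study400():
    """The main study-scale fixture: 4 populations x 100, 2,000 SNPs.

    Returns (panel, truth, config, K) with K the realized within-population
    GRM used both to draw and to fit polygenic effects.
    """
    cfg = SimConfig(n_populations=4, n_per_pop=100, n_snps=2000, fst=0.1,
                    n_genes=4, h2_list=[0.0, 0.3, 0.6, 0.9], seed=202)
    panel, truth = simulate_genotypes(cfg)
    K = realized_kinship(panel)
    return panel, truth, cfg, K


@pytest.fixture(scope="session")
def study400_expression(study400):
    panel, truth, cfg, K = study400
    expr, truth = simulate_expression(panel, cfg, truth)
    return panel, expr, truth, cfg, K


def make_expression(panel, base_cfg, seed, **overrides):
    """Simulate a fresh expression layer on an existing genotype panel."""
    from expherit.synthetic_data import TruthRecord
    fields = dict(n_populations=base_cfg.n_populations,
                  n_per_pop=base_cfg.n_per_pop, n_snps=base_cfg.n_snps,
                  fst=base_cfg.fst, maf_range=base_cfg.maf_range,
                  n_replicates=base_cfg.n_replicates, seed=seed)
    fields.update(overrides)
    cfg = SimConfig(**fields)
    truth = TruthRecord(gene_h2=np.asarray(cfg.h2_list, dtype=float),
                        populations=panel.populations)
    expr, truth = simulate_expression(panel, cfg, truth)
    return expr, truth, cfg
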