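"""IBD estimation, kinship merging, relative exclusion and MDS checks."""

import numpy as np
import pandas as pd
import pytest

from expherit.panels import GenotypePanel, KinshipMatrix
from expherit.relatedness import (estimate_ibd, merge_kinship,
                                  exclude_related, mds)
from expherit.synthetic_data import (SimConfig, simulate_genotypes,
                                     plant_relatives)


@pytest.fixture(scope="module")
def planted_fixture():
    """One population of 102 with a planted duplicate and parent-offspring
    pair; many independent SNPs so pi-hat noise is small."""
    cfg = SimConfig(n_populations=1, n_per_pop=102, n_snps=40000, fst=0.1,
                    n_genes=1, seed=21)
    panel, truth = simulate_genotypes(cfg)
    ids = panel.individuals
    pairs = [(ids[0], ids[1], "duplicate"),
             (ids[2], ids[3], "parent_offspring")]
    panel = plant_relatives(panel, pairs, cfg, truth)
    table = estimate_ibd(panel, "POP1", list(panel.snps["snp_id"]))
    return panel, truth, table


def _pihat(table, a, b):
    m = ((table["id1"] == a) & (table["id2"] == b)) \
        | ((table["id1"] == b) & (table["id2"] == a))
    return float(table.loc[m, "pihat"].iloc[0])


class TestEstimateIbd:
    def test_duplicate_pair_near_one(self, planted_fixture):
        panel, truth, table = planted_fixture
        ids = panel.individuals
        assert _pihat(table, ids[0], ids[1]) >= 0.95

    def test_parent_offspring_near_half(self, planted_fixture):
        panel, truth, table = planted_fixture
        ids = panel.individuals
        assert abs(_pihat(table, ids[2], ids[3]) - 0.5) < 0.1

    def test_unrelated_pairs_low(self, planted_fixture):
        panel, truth, table = planted_fixture
        planted = set(panel.individuals[:4])
        others = table[~(table["id1"].isin(planted)
                         | table["id2"].isin(planted))]
        assert others["pihat"].mean() < 0.02
        assert others["pihat"].max() < 0.05

    def test_truth_kinship_recovered(self, planted_fixture):
        panel, truth, table = planted_fixture
        for a, b, rel, k_true in truth.relative_pairs:
            assert abs(_pihat(table, a, b) - k_true) < 0.1

    def test_snp_order_invariance(self, small_panel):
        panel, _, _ = small_panel
        snps = list(panel.snps["snp_id"])
        t1 = estimate_ibd(panel, "POP1", snps)
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(snps))
        t2 = estimate_ibd(panel, "POP1", perm)
        np.testing.assert_allclose(t1["pihat"], t2["pihat"], atol=1e-12)

    def test_sparse_pairs_flagged_unreliable(self, small_panel):
        panel, _, _ = small_panel
        few = list(panel.snps["snp_id"][:50])
        t = estimate_ibd(panel, "POP1", few)
        assert t["unreliable"].all()

    def test_single_individual_population_rejected(self, small_panel):
        panel, _, _ = small_panel
        solo = panel.subset_individuals(np.array([0, 1]))
        solo.populations[1] = "LONE"
        with pytest.raises(ValueError):
            estimate_ibd(solo, "LONE", list(panel.snps["snp_id"]))


class TestMergeKinship:
    @staticmethod
    def _table(ids, pihat=0.01):
        recs = [{"id1": a, "id2": b, "pihat": pihat}
                for i, a in enumerate(ids) for b in ids[i + 1:]]
        return pd.DataFrame(recs)

    def test_block_diagonal_structure(self):
        k = merge_kinship({"A": self._table(["a1", "a2", "a3"], 0.02),
                           "B": self._table(["b1", "b2"], 0.03)})
        assert k.values.shape == (5, 5)
        k.validate()
        cross = k.values[:3, 3:]
        assert np.all(cross == 0.0)
        assert np.all(np.diag(k.values) == 1.0)
        assert k.values[0, 1] == 0.02 and k.values[3, 4] == 0.03

    def test_single_population_identity_plus_table(self):
        k = merge_kinship({"A": self._table(["x", "y"], 0.4)})
        np.testing.assert_array_equal(k.values,
                                      [[1.0, 0.4], [0.4, 1.0]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            merge_kinship({"A": self._table(["x", "y"]),
                           "B": self._table(["y", "z"])})

    def test_psd_clip_leaves_no_negative_eigenvalues(self, planted_fixture):
        panel, truth, table = planted_fixture
        k = merge_kinship({"POP1": table}).psd_clipped()
        assert np.linalg.eigvalsh(k.values).min() >= -1e-8


class TestExcludeRelated:
    def _kin(self, values, ids):
        return KinshipMatrix(np.asarray(values, dtype=float), ids,
                             np.asarray(["P"] * len(ids), dtype=object))

    def _panel(self, ids, missing_counts):
        m = max(missing_counts) + 1
        g = np.zeros((len(ids), m + 4))
        g[:, :4] = [0, 1, 2, 1]
        for i, c in enumerate(missing_counts):
            g[i, 4:4 + c] = np.nan
        snps = pd.DataFrame({"snp_id": [f"s{j}" for j in range(m + 4)],
                             "chrom": "chr1",
                             "pos": np.arange(1, m + 5),
                             "ref": "A", "alt": "G"})
        return GenotypePanel(g, ids, np.asarray(["P"] * len(ids),
                                                dtype=object), snps)

    def test_member_with_more_missing_dropped(self):
        ids = ["u", "v"]
        kin = self._kin([[1, 0.5], [0.5, 1]], ids)
        panel = self._panel(ids, [1, 3])
        assert exclude_related(kin, panel) == ["v"]

    def test_no_pair_above_threshold_drops_nothing(self):
        ids = ["u", "v"]
        kin = self._kin([[1, 0.04], [0.04, 1]], ids)
        assert exclude_related(kin, self._panel(ids, [0, 0])) == []

    def test_related_triangle_resolved(self):
        ids = ["a", "b", "c"]
        kin = self._kin([[1, 0.5, 0.3], [0.5, 1, 0.4], [0.3, 0.4, 1]], ids)
        drop = exclude_related(kin, self._panel(ids, [2, 1, 0]))
        keep = [i for i in ids if i not in drop]
        sub = kin.values[np.ix_([ids.index(i) for i in keep],
                                [ids.index(i) for i in keep])]
        off = sub - np.diag(np.diag(sub))
        assert off.max() <= 0.05


class TestMds:
    def test_identical_individuals_coincide(self):
        cfg = SimConfig(n_populations=2, n_per_pop=20, n_snps=500, fst=0.15,
                        missing_rate=0.0, n_genes=1, seed=31)
        panel, _ = simulate_genotypes(cfg)
        dup = plant_relatives(
            panel, [(panel.individuals[0], panel.individuals[1],
                     "duplicate")], cfg)
        coords = mds(dup, k=2)
        # identical genotype vectors -> zero distance -> same embedding
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_two_populations_separate_on_first_coordinate(self, small_panel):
        panel, _, _ = small_panel
        coords = mds(panel, k=2)
        a = coords[panel.populations == "POP1", 0]
        b = coords[panel.populations == "POP2", 0]
        assert a.max() < b.min() or b.max() < a.min()

    def test_nested_divergence_needs_third_coordinate(self):
        # two deeply diverged groups, each split into two shallow subgroups
        rng = np.random.default_rng(7)
        m = 4000
        p_anc = rng.uniform(0.2, 0.5, m)

        def drift(p, f):
            return np.clip(rng.beta(p * (1 - f) / f,
                                    (1 - p) * (1 - f) / f), 1e-3, 1 - 1e-3)

        pa, pb = drift(p_anc, 0.25), drift(p_anc, 0.25)
        freqs = [drift(pa, 0.02), drift(pa, 0.02),
                 drift(pb, 0.02), drift(pb, 0.02)]
        g = np.vstack([rng.binomial(2, f, size=(25, m)).astype(float)
                       for f in freqs])
        snps = pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)],
                             "chrom": "chr1", "pos": np.arange(1, m + 1),
                             "ref": "A", "alt": "G"})
        pops = np.repeat(["P1", "P2", "P3", "P4"], 25)
        panel = GenotypePanel(g, [f"i{i}" for i in range(100)],
                              pops.astype(object), snps)
        coords = mds(panel, k=3)

        def separated(c, x, y):
            cx, cy = c[pops == x], c[pops == y]
            return cx.max() < cy.min() or cy.max() < cx.min()

        # the deep split dominates the first coordinate
        assert separated(coords[:, 0], "P1", "P3")
        # the shallow pairs need a later coordinate
        assert not separated(coords[:, 0], "P1", "P2") \
            or not separated(coords[:, 0], "P3", "P4")
        assert any(separated(coords[:, c], "P1", "P2") for c in (1, 2))

    def test_k_not_smaller_than_n_rejected(self, small_panel):
        panel, _, _ = small_panel
        sub = panel.subset_individuals(np.arange(3))
        with pytest.raises(ValueError):
            mds(sub, k=3)
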