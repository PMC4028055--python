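"""Trio-family heritability: midparent regression and enrichment testing.

Narrow-sense heritability of an expression trait can be estimated in trio
families as the least-squares slope of offspring value on the midparent
value (the mean of the two parents); under an additive model the slope's
expectation is h^2.  Estimates from small family counts are noisy and may
be negative; negative slopes are reported as-is.  Fisher's exact test
checks whether genes carrying eQTLs are enriched for non-negative trio
estimates (slope >= 0).

Note: the estimator regresses *offspring on midparent* by default — the
direction with expectation h^2; a switch reproduces the reverse
(midparent-on-offspring) regression for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TrioHeritability", "midparent_regression", "fisher_enrichment",
           "trio_heritability_table"]


@dataclass
class TrioHeritability:
    gene: str
    slope: float
    stderr: float
    n_families: int
    flags: list


def midparent_regression(offspring, parent1, parent2, gene: str = "gene",
                         regress_on: str = "midparent") -> TrioHeritability:
    """Heritability as the regression slope over trio families.

    ``offspring``, ``parent1`` and ``parent2`` hold one replicate-averaged
    expression value per family.  With ``regress_on="midparent"`` (default)
    the slope of offspring on midparent is returned; ``"offspring"``
    reverses the axes.  Requires at least 3 complete families; zero
    midparent variance is flagged with an undefined slope.
    """
    offspring = np.asarray(offspring, dtype=float)
    midparent = (np.asarray(parent1, dtype=float)
                 + np.asarray(parent2, dtype=float)) / 2.0
    ok = ~np.isnan(offspring) & ~np.isnan(midparent)
    offspring, midparent = offspring[ok], midparent[ok]
    n = offspring.size
    if n < 3:
        return TrioHeritability(gene, np.nan, np.nan, n, ["too_few_families"])
    x, y = ((midparent, offspring) if regress_on == "midparent"
            else (offspring, midparent))
    if np.var(x) == 0:
        return TrioHeritability(gene, np.nan, np.nan, n,
                                ["zero_predictor_variance"])
    res = stats.linregress(x, y)
    return TrioHeritability(gene, float(res.slope), float(res.stderr), n, [])


def fisher_enrichment(table) -> tuple:
    """Two-sided Fisher exact test on a 2x2 count table.

    Rows: {eQTL gene, non-eQTL gene}; columns: {h^2 >= 0, h^2 < 0}.
    Returns ``(odds_ratio, p_value)``; a zero margin yields P = 1 with an
    undefined (NaN) odds ratio.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return (np.nan, 1.0)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return (float(odds), float(p))


def trio_heritability_table(expression_means: pd.DataFrame,
                            family_map: pd.DataFrame,
                            regress_on: str = "midparent") -> pd.DataFrame:
    """Per-gene midparent-regression estimates for a whole panel.

    ``expression_means`` is gene x individual (replicate-averaged);
    ``family_map`` has columns family_id, father_id, mother_id, child_id.
    """
    fathers = list(family_map["father_id"])
    mothers = list(family_map["mother_id"])
    children = list(family_map["child_id"])
    rows = []
    for gene in expression_means.index:
        v = expression_means.loc[gene]
        th = midparent_regression(v[children].to_numpy(),
                                  v[fathers].to_numpy(),
                                  v[mothers].to_numpy(),
                                  gene=str(gene), regress_on=regress_on)
        rows.append({"gene": th.gene, "slope": th.slope,
                     "stderr": th.stderr, "n_families": th.n_families,
                     "flags": ";".join(th.flags)})
    return pd.DataFrame(rows)
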