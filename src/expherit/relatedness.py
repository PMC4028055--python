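"""Pairwise IBD estimation, kinship merging, relative exclusion, and MDS.

Relationship coefficients are genome-wide probabilities of allelic identity
by descent (pi-hat), estimated within each population by the method of
moments from identity-by-state (IBS) sharing at LD-pruned SNPs.  The
expected IBS probabilities given IBD state use allele frequencies estimated
from the same sample, with the small-sample bias correction obtained by
treating the four (or three) alleles of a pair as draws *without
replacement* from the observed allele pool — the standard correction of
moment-based relatedness estimators.

Per-population matrices are merged into one block-diagonal kinship matrix
by fixing cross-population coefficients at zero (separated populations are
assumed unrelated), with unit diagonal.  Close relatives (pi-hat above a
cutoff, default 0.05) are excluded greedily, dropping the member of each
pair with more missing genotypes.  Classical multidimensional scaling of
allele-sharing distances provides the structure diagnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panels import GenotypePanel, KinshipMatrix

__all__ = ["estimate_ibd", "merge_kinship", "exclude_related", "mds",
           "ibs_distance"]

MIN_INFORMATIVE_SNPS = 100


def _falling(x, k):
    """x (x-1) ... (x-k+1), elementwise."""
    out = np.ones_like(np.asarray(x, dtype=float))
    for i in range(k):
        out = out * (x - i)
    return out


def _expected_ibs_given_ibd(alt_count, total_alleles):
    """Per-SNP P(IBS=s | IBD=z) under without-replacement allele draws.

    Returns (e00, e10, e20, e11, e21): P(IBS=0|IBD=0), P(IBS=1|IBD=0),
    P(IBS=2|IBD=0), P(IBS=1|IBD=1), P(IBS=2|IBD=1).
    """
    X = np.asarray(alt_count, dtype=float)
    T = np.asarray(total_alleles, dtype=float)
    Y = T - X
    with np.errstate(invalid="ignore", divide="ignore"):
        T4 = _falling(T, 4)
        T3 = _falling(T, 3)
        e00 = 2 * _falling(X, 2) * _falling(Y, 2) / T4
        e10 = (4 * _falling(X, 3) * Y + 4 * X * _falling(Y, 3)) / T4
        e20 = (_falling(X, 4) + _falling(Y, 4)
               + 4 * _falling(X, 2) * _falling(Y, 2)) / T4
        e11 = (2 * _falling(X, 2) * Y + 2 * X * _falling(Y, 2)) / T3
        e21 = (_falling(X, 3) + _falling(Y, 3)
               + _falling(X, 2) * Y + X * _falling(Y, 2)) / T3
    bad = ~np.isfinite(e00) | (T < 4)
    for e in (e00, e10, e20, e11, e21):
        e[bad] = 0.0
    return e00, e10, e20, e11, e21, bad


def _ibs_counts(dosages):
    """Pairwise IBS 0/1/2 counts and shared-call masks via one-hot products."""
    H = [(dosages == v).astype(float) for v in (0.0, 1.0, 2.0)]
    ibs0 = H[0] @ H[2].T
    ibs0 = ibs0 + ibs0.T
    ibs1 = H[0] @ H[1].T + H[1] @ H[2].T
    ibs1 = ibs1 + ibs1.T
    ibs2 = H[0] @ H[0].T + H[1] @ H[1].T + H[2] @ H[2].T
    mf = (~np.isnan(dosages)).astype(float)
    return ibs0, ibs1, ibs2, mf


def estimate_ibd(panel: GenotypePanel, population, pruned_snps) -> pd.DataFrame:
    """Method-of-moments pairwise IBD within one population.

    For every pair, observed IBS 0/1/2 counts over jointly non-missing
    pruned SNPs are matched against bias-corrected expectations to solve
    for P(IBD=0/1/2); the three probabilities are truncated to [0,1] and
    renormalised, and pi-hat = P(IBD=2) + P(IBD=1)/2.  Pairs sharing fewer
    than 100 informative SNPs are flagged ``unreliable``.

    Returns a table with columns id1, id2, z0, z1, z2, pihat, n_snps,
    unreliable.
    """
    rows_idx = panel.population_index(population)
    if len(rows_idx) < 2:
        raise ValueError(f"population {population!r} has fewer than 2 "
                         "individuals")
    sub = panel.subset_individuals(rows_idx).select_snp_ids(pruned_snps)
    g = sub.dosages
    mask = ~np.isnan(g)
    alt = np.nansum(g, axis=0)
    total = 2.0 * mask.sum(axis=0)
    e00, e10, e20, e11, e21, bad = _expected_ibs_given_ibd(alt, total)
    g = g.copy()
    g[:, bad] = np.nan          # uninformative SNPs excluded entirely

    ibs0, ibs1, ibs2, mf = _ibs_counts(g)
    n_shared = mf @ mf.T
    E00 = (mf * e00) @ mf.T
    E10 = (mf * e10) @ mf.T
    E20 = (mf * e20) @ mf.T
    E11 = (mf * e11) @ mf.T
    E21 = (mf * e21) @ mf.T

    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = np.where(E00 > 0, ibs0 / E00, 0.0)
        z1 = np.where(E11 > 0, (ibs1 - z0 * E10) / E11, 0.0)
        z2 = np.where(n_shared > 0,
                      (ibs2 - z0 * E20 - z1 * E21) / n_shared, 0.0)
    z = np.stack([z0, z1, z2])
    z = np.clip(z, 0.0, 1.0)
    tot = z.sum(axis=0)
    tot[tot == 0] = 1.0
    z /= tot
    pihat = z[2] + 0.5 * z[1]

    ids = sub.individuals
    recs = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            recs.append({
                "id1": ids[i], "id2": ids[j],
                "z0": z[0, i, j], "z1": z[1, i, j], "z2": z[2, i, j],
                "pihat": pihat[i, j], "n_snps": int(n_shared[i, j]),
                "unreliable": bool(n_shared[i, j] < MIN_INFORMATIVE_SNPS),
            })
    return pd.DataFrame(recs)


def merge_kinship(tables: dict) -> KinshipMatrix:
    """Merge per-population pi-hat tables into one block-diagonal kinship.

    ``tables`` maps population label to the table from :func:`estimate_ibd`.
    Cross-population coefficients are exactly zero and the diagonal is 1.
    Duplicate individual ids across populations raise.
    """
    individuals, populations = [], []
    for pop, tab in tables.items():
        ids = list(dict.fromkeys(list(tab["id1"]) + list(tab["id2"])))
        individuals += ids
        populations += [pop] * len(ids)
    if len(set(individuals)) != len(individuals):
        raise ValueError("duplicate individual ids across populations")
    pos = {s: i for i, s in enumerate(individuals)}
    K = np.zeros((len(individuals), len(individuals)))
    for tab in tables.values():
        for id1, id2, pihat in zip(tab["id1"], tab["id2"], tab["pihat"]):
            i, j = pos[id1], pos[id2]
            K[i, j] = K[j, i] = pihat
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(K, individuals,
                         np.asarray(populations, dtype=object),
                         snp_provenance="merged per-population IBD")


def exclude_related(kinship: KinshipMatrix, panel: GenotypePanel,
                    threshold: float = 0.05) -> list:
    """Ids to drop so that no remaining pair exceeds the pi-hat threshold.

    Iterates greedily from the highest pi-hat pair; within a pair the member
    with more missing genotypes is dropped (ties: the id later in sort
    order).
    """
    miss = dict(zip(panel.individuals, panel.individual_missing_counts()))
    K = kinship.values.copy()
    np.fill_diagonal(K, 0.0)
    ids = kinship.individuals
    dropped = []
    while True:
        i, j = np.unravel_index(np.argmax(K), K.shape)
        if K[i, j] <= threshold:
            break
        a, b = ids[i], ids[j]
        ma, mb = miss.get(a, 0), miss.get(b, 0)
        if ma > mb:
            drop = i
        elif mb > ma:
            drop = j
        else:
            drop = i if str(a) > str(b) else j
        dropped.append(ids[drop])
        K[drop, :] = 0.0
        K[:, drop] = 0.0
    return dropped


def ibs_distance(panel: GenotypePanel) -> np.ndarray:
    """1 - (mean IBS sharing)/2 over jointly non-missing SNPs, pairwise."""
    ibs0, ibs1, ibs2, mf = _ibs_counts(panel.dosages)
    n_shared = mf @ mf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ibs = (ibs1 + 2.0 * ibs2) / n_shared
    mean_ibs[~np.isfinite(mean_ibs)] = 0.0
    d = 1.0 - mean_ibs / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def mds(panel: GenotypePanel, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of the allele-sharing distance matrix.

    Returns the ``k`` leading principal coordinates (n x k).  Signs are
    fixed so each coordinate's largest-magnitude loading is positive.
    """
    n = panel.n_individuals
    if k >= n:
        raise ValueError("k must be smaller than the number of individuals")
    D = ibs_distance(panel)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1][:k]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    for c in range(k):
        imax = np.argmax(np.abs(coords[:, c]))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    return coords
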