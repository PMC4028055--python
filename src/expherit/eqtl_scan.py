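"""Genome-wide gene-SNP association scan, peak merging, cis/trans labels.

The scan regresses each gene's replicate-averaged expression on intercept +
population indicators + SNP dosage (ordinary least squares) and t-tests the
SNP coefficient; population indicators absorb mean expression differences
between populations so that allele-frequency divergence does not masquerade
as association.  Significance is Bonferroni over the number of SNPs (genes
deliberately not counted).  Significant SNPs of a gene are merged into
peaks by single-linkage positional clustering with a 5 Mb gap, and each
peak is labelled cis when its lead SNP falls within the gene span extended
by 500 kb on both sides (the strand-resolved "500 kb upstream of the
transcript start to 500 kb downstream of the 3' end" window), else trans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panels import GenotypePanel

__all__ = ["bonferroni_threshold", "expected_false_positive_fraction",
           "scan_gene", "merge_peaks", "classify_cis_trans", "EqtlPeak",
           "CIS_WINDOW", "MERGE_WINDOW"]

CIS_WINDOW = 500_000
MERGE_WINDOW = 5_000_000


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise P-value threshold alpha / m over m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


def expected_false_positive_fraction(alpha: float, n_genes: int,
                                     n_discoveries: int) -> float:
    """Expected chance discoveries (alpha per gene at the Bonferroni
    threshold) as a fraction of the discoveries actually made."""
    if n_discoveries <= 0:
        raise ValueError("n_discoveries must be positive")
    return alpha * n_genes / n_discoveries


@dataclass
class EqtlPeak:
    gene: str
    chrom: str
    lead_snp: str
    lead_pos: int
    lead_p: float
    member_snps: list = field(default_factory=list)
    start: int = 0
    end: int = 0
    label: str | None = None
    h2_qtl: float | None = None
    pi_ratio: float | None = None


def scan_gene(y_means: np.ndarray, populations, panel: GenotypePanel,
              threshold: float, gene: str = "gene",
              return_all: bool = False) -> pd.DataFrame:
    """OLS association of one gene against every SNP, with population
    covariates.

    ``y_means`` holds replicate-averaged expression per individual of
    ``panel``.  Per SNP the model y ~ 1 + population + dosage is fitted on
    pairwise-complete observations and the dosage coefficient t-tested
    (two-sided, df = n - p).  Monomorphic SNPs are skipped.  Returns
    records with P below ``threshold`` (or all records when
    ``return_all``), columns gene, snp_id, chrom, pos, beta, t, p, n.
    """
    y = np.asarray(y_means, dtype=float)
    populations = np.asarray(populations)
    if y.size != panel.n_individuals:
        raise ValueError("one expression value per panel individual required")
    levels = list(dict.fromkeys(populations))
    C = np.column_stack(
        [np.ones(y.size)] + [(populations == lev).astype(float)
                             for lev in levels[1:]])
    p_cov = C.shape[1]
    ok_y = ~np.isnan(y)
    G = panel.dosages

    # fast path: project covariates out of y and of complete SNP columns
    beta = np.full(panel.n_snps, np.nan)
    tval = np.full(panel.n_snps, np.nan)
    pval = np.full(panel.n_snps, np.nan)
    nobs = np.zeros(panel.n_snps, dtype=int)

    complete = ~np.isnan(G).any(axis=0)
    idx_fast = np.flatnonzero(complete)
    if idx_fast.size:
        Cy = C[ok_y]
        yy = y[ok_y]
        Q, _ = np.linalg.qr(Cy)
        y_res = yy - Q @ (Q.T @ yy)
        Xf = G[ok_y][:, idx_fast]
        X_res = Xf - Q @ (Q.T @ Xf)
        sxx = np.einsum("ij,ij->j", X_res, X_res)
        poly = sxx > 1e-12
        sxy = X_res.T @ y_res
        n = yy.size
        df = n - p_cov - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(poly, sxy / sxx, np.nan)
            rss = np.maximum(np.sum(y_res ** 2) - b ** 2 * sxx, 0.0)
            se = np.sqrt(rss / df / sxx)
            t = b / se
        beta[idx_fast] = b
        tval[idx_fast] = t
        # an exact fit underflows; keep P in (0, 1]
        pv = np.maximum(2.0 * stats.t.sf(np.abs(t), df),
                        np.nextafter(0.0, 1.0))
        pv[~np.isfinite(b)] = np.nan
        pval[idx_fast] = pv
        nobs[idx_fast] = n

    # slow path: SNPs with missing calls, pairwise-complete per SNP
    for j in np.flatnonzero(~complete):
        x = G[:, j]
        ok = ok_y & ~np.isnan(x)
        n = int(ok.sum())
        if n <= p_cov + 2 or np.nanstd(x[ok]) == 0:
            continue
        D = np.column_stack([C[ok], x[ok]])
        coef, res_ss, rank, _ = np.linalg.lstsq(D, y[ok], rcond=None)
        if rank < D.shape[1]:
            continue
        df = n - D.shape[1]
        resid = y[ok] - D @ coef
        s2 = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(D.T @ D)
        se = np.sqrt(s2 * xtx_inv[-1, -1])
        beta[j] = coef[-1]
        tval[j] = coef[-1] / se
        pval[j] = 2.0 * stats.t.sf(abs(tval[j]), df)
        nobs[j] = n

    out = pd.DataFrame({
        "gene": gene,
        "snp_id": panel.snps["snp_id"],
        "chrom": panel.snps["chrom"],
        "pos": panel.snps["pos"],
        "beta": beta, "t": tval, "p": pval, "n": nobs,
    })
    out = out[np.isfinite(out["p"])]
    if not return_all:
        out = out[out["p"] < threshold]
    return out.reset_index(drop=True)


def merge_peaks(records: pd.DataFrame,
                window: int = MERGE_WINDOW) -> list:
    """Merge one gene's significant SNPs into eQTL peaks.

    Per chromosome, consecutive significant SNPs at most ``window`` apart
    (single-linkage on position) form one peak; the lead SNP is the
    smallest P (ties: smaller position).  The peaks partition the input
    records exactly.
    """
    peaks = []
    if len(records) == 0:
        return peaks
    for chrom, sub in records.groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "snp_id"], kind="stable")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window)
        bounds = [0] + (breaks + 1).tolist() + [len(sub)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            clust = sub.iloc[a:b]
            lead = clust.sort_values(["p", "pos"], kind="stable").iloc[0]
            peaks.append(EqtlPeak(
                gene=str(clust["gene"].iloc[0]), chrom=str(chrom),
                lead_snp=str(lead["snp_id"]), lead_pos=int(lead["pos"]),
                lead_p=float(lead["p"]),
                member_snps=list(clust["snp_id"]),
                start=int(pos[a]), end=int(pos[b - 1])))
    return peaks


def classify_cis_trans(peak: EqtlPeak, gene_annotation) -> str:
    """Label a peak cis/trans from its lead SNP and the gene's location.

    Cis iff the lead SNP is on the gene's chromosome with position inside
    [gene 5' end - 500 kb, gene 3' end + 500 kb] inclusive; the window is
    symmetric in genomic coordinates for both strands.  Returns
    ``"unknown"`` for unannotated genes.
    """
    if gene_annotation is None:
        peak.label = "unknown"
        return "unknown"
    ann = gene_annotation
    lo = min(int(ann["start"]), int(ann["end"])) - CIS_WINDOW
    hi = max(int(ann["start"]), int(ann["end"])) + CIS_WINDOW
    if str(peak.chrom) == str(ann["chrom"]) and lo <= peak.lead_pos <= hi:
        peak.label = "cis"
    else:
        peak.label = "trans"
    return peak.label


PEAK_COLUMNS = ["gene", "chrom", "lead_snp", "lead_pos", "lead_p",
                "n_member_snps", "start", "end", "label", "h2_qtl",
                "pi_ratio"]


def peaks_to_frame(peaks: list) -> pd.DataFrame:
    """Peak list as a table (one row per eQTL)."""
    if not peaks:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    return pd.DataFrame([{
        "gene": p.gene, "chrom": p.chrom, "lead_snp": p.lead_snp,
        "lead_pos": p.lead_pos, "lead_p": p.lead_p,
        "n_member_snps": len(p.member_snps), "start": p.start, "end": p.end,
        "label": p.label, "h2_qtl": p.h2_qtl, "pi_ratio": p.pi_ratio,
    } for p in peaks])
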