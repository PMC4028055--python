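"""SNP quality control: call-rate / MAF / HWE / autosome filters, LD pruning.

Filters follow the standard population-genetics QC chain: drop SNPs on sex
chromosomes, genotyped in under 90% of individuals, with minor-allele
frequency below 0.05, or departing from Hardy-Weinberg equilibrium at
P < 0.001 — applied independently within each population, a SNP surviving
only if it passes in every population (the consensus set).  LD pruning
greedily removes one member of any SNP pair whose genotypic correlation
r^2 reaches 0.05 within a sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panels import GenotypePanel

__all__ = ["QcThresholds", "QcReport", "hwe_test", "filter_snps", "ld_prune"]

SEX_CHROMS = {"X", "Y", "chrX", "chrY", "23", "24", "MT", "chrM"}


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    autosomes_only: bool = True
    prune_r2: float = 0.05
    prune_window: int = 50
    prune_step: int = 5

    def __post_init__(self):
        if not 0 < self.min_call_rate <= 1:
            raise ValueError("min_call_rate must lie in (0, 1]")
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must lie in [0, 0.5)")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must lie in (0, 1)")
        if not 0 < self.prune_r2 <= 1:
            raise ValueError("prune_r2 must lie in (0, 1]")
        if self.prune_window < 2:
            raise ValueError("prune_window must be at least 2 SNPs")
        if self.prune_step < 1:
            raise ValueError("prune_step must be at least 1")


@dataclass
class QcReport:
    n_input: int
    n_removed: dict = field(default_factory=dict)  # criterion -> SNP count
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": "input", "n_snps": self.n_input}]
        rows += [{"criterion": f"removed_{k}", "n_snps": v}
                 for k, v in self.n_removed.items()]
        rows.append({"criterion": "output", "n_snps": self.n_output})
        return pd.DataFrame(rows)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square goodness-of-fit P-value against Hardy-Weinberg
    proportions.  Monomorphic SNPs return 1."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorised HWE chi-square over SNP columns (NaN = missing)."""
    nAA = np.nansum(dosages == 0, axis=0).astype(float)
    nAa = np.nansum(dosages == 1, axis=0).astype(float)
    naa = np.nansum(dosages == 2, axis=0).astype(float)
    n = nAA + nAa + naa
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * nAA + nAa) / (2 * n)
        eAA, eAa, eaa = n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2
        chi2 = ((nAA - eAA) ** 2 / eAA + (nAa - eAa) ** 2 / eAa
                + (naa - eaa) ** 2 / eaa)
    out = stats.chi2.sf(chi2, df=1)
    out[np.isnan(chi2)] = 1.0       # monomorphic or empty
    out[(p == 0) | (p == 1)] = 1.0
    return out


def filter_snps(panel: GenotypePanel, thresholds: QcThresholds = QcThresholds(),
                per_population: bool = True):
    """Apply the four SNP filters; returns ``(filtered_panel, QcReport)``.

    With ``per_population`` a SNP must pass call rate, MAF and HWE in every
    population to survive (consensus SNPs); otherwise the pooled sample is
    used.  Raises if nothing survives.
    """
    m = panel.n_snps
    report = QcReport(n_input=m)
    keep = np.ones(m, dtype=bool)

    if thresholds.autosomes_only:
        sex = panel.snps["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()
        report.n_removed["sex_chromosome"] = int(sex.sum())
        keep &= ~sex

    if per_population:
        if panel.populations is None or len(panel.populations) == 0:
            raise ValueError("per-population QC requires population labels")
        groups = [panel.subset_individuals(panel.population_index(p))
                  for p in panel.population_names()]
    else:
        groups = [panel]

    fail_call = np.zeros(m, dtype=bool)
    fail_maf = np.zeros(m, dtype=bool)
    fail_hwe = np.zeros(m, dtype=bool)
    for sub in groups:
        fail_call |= sub.call_rate() < thresholds.min_call_rate
        with np.errstate(invalid="ignore"):
            fail_maf |= ~(sub.maf() >= thresholds.min_maf)  # NaN fails
        fail_hwe |= _hwe_pvalues(sub.dosages) < thresholds.hwe_alpha
    report.n_removed["call_rate"] = int((keep & fail_call).sum())
    keep &= ~fail_call
    report.n_removed["maf"] = int((keep & fail_maf).sum())
    keep &= ~fail_maf
    report.n_removed["hwe"] = int((keep & fail_hwe).sum())
    keep &= ~fail_hwe

    report.n_output = int(keep.sum())
    if report.n_output == 0:
        raise ValueError("no SNPs survive QC; thresholds remove everything")
    return panel.subset_snps(keep), report


def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    mask = ~np.isnan(g)
    gz = np.nan_to_num(g, nan=0.0)
    n = mask.T @ mask.astype(float)
    sx = gz.T @ mask.astype(float)         # sx[j,k] = sum of g_j over shared
    sxy = gz.T @ gz
    sxx = (gz ** 2).T @ mask.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_x = sxx - sx ** 2 / n
        r2 = cov ** 2 / (var_x * var_x.T)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(panel: GenotypePanel,
             thresholds: QcThresholds = QcThresholds()) -> list:
    """Greedy sliding-window LD pruning; returns the retained SNP id list.

    Within each window of ``prune_window`` SNPs (per chromosome, position
    order), while any retained pair has genotypic r^2 >= ``prune_r2``, the
    member with the lower call rate is dropped (ties: the higher-position
    member); the window then advances by ``prune_step`` SNPs.
    """
    win, step, thr = (thresholds.prune_window, thresholds.prune_step,
                      thresholds.prune_r2)
    call = panel.call_rate()
    pos = panel.snps["pos"].to_numpy()
    keep = np.ones(panel.n_snps, dtype=bool)

    def one_pass(cidx):
        """Slide windows over the currently retained SNPs of one
        chromosome; returns True if anything was dropped."""
        dropped = False
        start = 0
        while True:
            live = [j for j in cidx[start:start + win] if keep[j]]
            if len(live) > 1:
                live = np.asarray(live)
                r2 = _pairwise_r2(panel.dosages[:, live])
                while True:
                    jmax, kmax = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[jmax, kmax] < thr:
                        break
                    a, b = live[jmax], live[kmax]
                    if call[a] < call[b]:
                        drop_local = jmax
                    elif call[b] < call[a]:
                        drop_local = kmax
                    else:
                        drop_local = jmax if pos[a] > pos[b] else kmax
                    keep[live[drop_local]] = False
                    dropped = True
                    r2[drop_local, :] = 0.0
                    r2[:, drop_local] = 0.0
            if start + win >= len(cidx):
                return dropped
            start += step

    for chrom in panel.snps["chrom"].unique():
        cidx_all = np.flatnonzero((panel.snps["chrom"] == chrom).to_numpy())
        cidx_all = cidx_all[np.argsort(pos[cidx_all], kind="stable")]
        # repeat over the retained subset until stable, so that windows of
        # the pruned panel (which re-pack after removals) are clean too and
        # pruning is idempotent
        while one_pass([j for j in cidx_all if keep[j]]):
            pass
    return [panel.snps["snp_id"].iloc[j]
            for j in np.flatnonzero(keep)]
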