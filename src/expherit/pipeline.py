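"""End-to-end pipeline: simulate -> QC -> relatedness -> normalise ->
heritability -> eQTL scan -> eQTL heritability -> epistasis -> trio ->
report.

Every stage writes its outputs as TSV under the run directory, and a JSON
manifest records the seed, the SNP/individual counts at each filter and the
stages completed, so a rerun with the same configuration and seed
reproduces all outputs byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic_data import SimConfig, simulate_study, simulate_trios
from .genotype_qc import QcThresholds, filter_snps, ld_prune
from .relatedness import estimate_ibd, merge_kinship, exclude_related, mds
from .expression_prep import normalize_panel, collapse_and_average
from .reml_core import (EigenRotation, make_spec, reml_fit, fit_snp_model,
                        eqtl_heritability, fit_epistasis, model_diagnostics)
from .eqtl_scan import (bonferroni_threshold, scan_gene, merge_peaks,
                        classify_cis_trans, peaks_to_frame,
                        MERGE_WINDOW)
from .trio_analysis import trio_heritability_table, fisher_enrichment

log = logging.getLogger("expherit")

__all__ = ["PipelineConfig", "run_pipeline", "summarize",
           "heritability_stage", "scan_stage", "eqtl_stage",
           "epistasis_stage"]


@dataclass
class PipelineConfig:
    """All knobs of the analysis; defaults are the study's thresholds
    (call rate 0.90, MAF 0.05, HWE 0.001, prune r^2 0.05, relatedness
    cutoff 0.05, Bonferroni alpha 0.05, 5 Mb merge, 500 kb cis window)."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    relatedness_cutoff: float = 0.05
    bonferroni_alpha: float = 0.05
    merge_window: int = MERGE_WINDOW
    outdir: str = "expherit_run"
    hist_bins: int = 20
    gene_groups: dict = field(default_factory=dict)
    per_population_h2: bool = True
    mds_dims: int = 3

    @property
    def seed(self) -> int:
        return self.sim.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimConfig(**{**d.get("sim", {}),
                           **({"maf_range": tuple(d["sim"]["maf_range"])}
                              if "maf_range" in d.get("sim", {}) else {})})
        qc = QcThresholds(**d.get("qc", {}))
        rest = {k: v for k, v in d.items() if k not in ("sim", "qc")}
        return cls(sim=sim, qc=qc, **rest)


def _flags(fl):
    return ";".join(fl)


def _expand_snp(dosage_ind, indiv_index):
    x = np.asarray(dosage_ind, dtype=float).copy()
    x[np.isnan(x)] = np.nanmean(x)
    return x[indiv_index]


def heritability_stage(gene_panel, populations, K):
    """Per-gene REML heritability with shared eigen-rotation.

    Returns ``(table, fits, rotation, indiv_index)`` where ``fits`` maps
    gene to (spec, VarianceComponents) for reuse by downstream stages.
    """
    n_rep = gene_panel.n_replicates
    indiv_index = np.repeat(np.arange(len(gene_panel.individuals)), n_rep)
    rotation = EigenRotation(K, indiv_index)
    rows, fits = [], {}
    for gi, gene in enumerate(gene_panel.features):
        spec = make_spec(gene_panel.values[gi], populations, K)
        vc = reml_fit(spec, rotation=rotation)
        diag = model_diagnostics(vc, spec)
        fits[gene] = (spec, vc)
        rows.append({
            "gene": gene, "sigma_g2": vc.sigma_g2, "sigma_e2": vc.sigma_e2,
            "h2": vc.h2, "loglik_reml": vc.loglik_reml,
            "loglik_ml": vc.loglik_ml, "converged": vc.converged,
            "flags": _flags(vc.flags), "diag_corr": diag.correlation,
            "diag_p": diag.p_value})
    return pd.DataFrame(rows), fits, rotation, indiv_index


def scan_stage(gene_means, populations, panel, threshold):
    """Genome-wide association scan over all genes; significant records."""
    assoc = []
    for gene in gene_means.index:
        hits = scan_gene(gene_means.loc[gene].to_numpy(), populations,
                         panel, threshold, gene=gene)
        if len(hits):
            assoc.append(hits)
    if not assoc:
        return pd.DataFrame(columns=["gene", "snp_id", "chrom", "pos",
                                     "beta", "t", "p", "n"])
    return pd.concat(assoc, ignore_index=True)


def eqtl_stage(assoc, annotation, panel, fits, rotation, indiv_index,
               merge_window=MERGE_WINDOW):
    """Peak merging, cis/trans labels and multi-SNP eQTL heritability.

    ``annotation`` is indexed by gene id with chrom/start/end columns.
    Returns the peak list; each gene's aggregated h2_qtl/pi is attached to
    its peaks.
    """
    snp_pos = {s: i for i, s in enumerate(panel.snps["snp_id"])}
    all_peaks = []
    for gene, sub in assoc.groupby("gene", sort=True):
        peaks = merge_peaks(sub, window=merge_window)
        for p in peaks:
            classify_cis_trans(
                p, annotation.loc[gene] if gene in annotation.index else None)
        if gene in fits:
            spec, vc_free = fits[gene]
            lead_cols = np.column_stack(
                [_expand_snp(panel.dosages[:, snp_pos[p.lead_snp]],
                             indiv_index) for p in peaks])
            vc_snp = fit_snp_model(spec, lead_cols, rotation=rotation)
            eh = eqtl_heritability(vc_free, vc_snp)
            for p in peaks:
                p.h2_qtl, p.pi_ratio = eh.h2_qtl, eh.pi_ratio
        all_peaks += peaks
    return all_peaks


def epistasis_stage(peaks_df, fits, panel, rotation, indiv_index):
    """Additive-vs-interaction comparison for genes with >= 2 peaks."""
    snp_pos = {s: i for i, s in enumerate(panel.snps["snp_id"])}
    rows = []
    if len(peaks_df) == 0:
        return pd.DataFrame(columns=["gene", "snp1", "snp2", "aic_additive",
                                     "aic_interaction", "preferred",
                                     "h2_qtl_additive", "h2_qtl_interaction",
                                     "delta_explained"])
    for gene, sub in peaks_df.groupby("gene", sort=True):
        if len(sub) < 2 or gene not in fits:
            continue
        leads = list(sub.sort_values("lead_p")["lead_snp"][:2])
        spec, _ = fits[gene]
        x1 = _expand_snp(panel.dosages[:, snp_pos[leads[0]]], indiv_index)
        x2 = _expand_snp(panel.dosages[:, snp_pos[leads[1]]], indiv_index)
        res = fit_epistasis(spec, x1, x2, rotation=rotation)
        rows.append({
            "gene": gene, "snp1": leads[0], "snp2": leads[1],
            "aic_additive": res.aic_additive,
            "aic_interaction": res.aic_interaction,
            "preferred": res.preferred,
            "h2_qtl_additive": res.h2_qtl_additive,
            "h2_qtl_interaction": res.h2_qtl_interaction,
            "delta_explained": res.delta_explained})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest.

    A stage failure is recorded in the manifest (written with
    ``completed=False``) and re-raised, so callers exit non-zero rather
    than producing silently empty downstream files.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest = {"version": __version__, "seed": config.seed,
                "stages": [], "counts": {}, "completed": False}

    def _save_manifest():
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)

    try:
        # ---- simulate ---------------------------------------------------
        log.info("simulating study (seed=%d)", config.seed)
        panel, expr_raw, truth = simulate_study(config.sim)
        panel.to_dosage_tsv(out / "genotypes.tsv")
        expr_raw.to_tsv(out / "expression_raw.tsv")
        truth.to_tsv(out / "truth.tsv")
        truth.gene_annotation.to_csv(out / "gene_annotation.tsv", sep="\t",
                                     index=False)
        config.sim.to_yaml(out / "sim_config.yaml")
        manifest["counts"]["n_individuals"] = panel.n_individuals
        manifest["counts"]["n_snps_input"] = panel.n_snps
        manifest["stages"].append("simulate")

        # ---- genotype QC ------------------------------------------------
        qc_panel, report = filter_snps(panel, config.qc, per_population=True)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["counts"]["n_snps_qc"] = qc_panel.n_snps
        pruned = {}
        for pop in qc_panel.population_names():
            sub = qc_panel.subset_individuals(qc_panel.population_index(pop))
            pruned[pop] = ld_prune(sub, config.qc)
            manifest["counts"][f"n_pruned_{pop}"] = len(pruned[pop])
        with open(out / "pruned_snps.tsv", "w") as f:
            for pop, ids in pruned.items():
                for s in ids:
                    f.write(f"{pop}\t{s}\n")
        manifest["stages"].append("qc")

        # ---- relatedness ------------------------------------------------
        tables = {pop: estimate_ibd(qc_panel, pop, pruned[pop])
                  for pop in qc_panel.population_names()}
        kin = merge_kinship(tables)
        kin.to_tsv(out / "kinship.tsv")
        drop = exclude_related(kin, qc_panel, config.relatedness_cutoff)
        manifest["counts"]["n_related_dropped"] = len(drop)
        pd.Series(drop, dtype=object).to_csv(out / "excluded_individuals.tsv",
                                             sep="\t", index=False,
                                             header=["individual"])
        keep_ids = [s for s in kin.individuals if s not in set(drop)]
        keep_idx = [kin.individuals.index(s) for s in keep_ids]
        K = kin.values[np.ix_(keep_idx, keep_idx)]
        qc_panel = qc_panel.drop_individuals(drop)
        # align panel order to kinship order
        order = [qc_panel.individuals.index(s) for s in keep_ids]
        qc_panel = qc_panel.subset_individuals(np.asarray(order))
        coords = mds(qc_panel, k=min(config.mds_dims,
                                     qc_panel.n_individuals - 1))
        pd.DataFrame(coords, index=qc_panel.individuals,
                     columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
                     ).to_csv(out / "mds.tsv", sep="\t")
        manifest["stages"].append("relatedness")

        # ---- expression normalisation ----------------------------------
        expr = expr_raw.drop_individuals(drop)
        expr = expr.subset_individuals(np.asarray(
            [expr.individuals.index(s) for s in keep_ids]))
        expr = normalize_panel(expr)
        gene_panel, gene_means = collapse_and_average(expr)
        gene_panel.to_tsv(out / "expression_normalized.tsv")
        gene_means.to_csv(out / "expression_means.tsv", sep="\t")
        manifest["stages"].append("normalize")

        # ---- heritability ----------------------------------------------
        pops = qc_panel.populations
        n_rep = gene_panel.n_replicates
        h2_table, fits, rotation, indiv_index = heritability_stage(
            gene_panel, pops, K)
        h2_table.to_csv(out / "heritability.tsv", sep="\t", index=False)
        manifest["stages"].append("h2")

        if config.per_population_h2 and len(set(pops)) > 1:
            prows = []
            for pop in qc_panel.population_names():
                pidx = np.flatnonzero(pops == pop)
                Kp = K[np.ix_(pidx, pidx)]
                rot_p = EigenRotation(
                    Kp, np.repeat(np.arange(len(pidx)), n_rep))
                for gi, gene in enumerate(gene_panel.features):
                    vals = gene_panel.values[gi][pidx]
                    spec = make_spec(vals, ["ALL"] * len(pidx), Kp)
                    vc = reml_fit(spec, rotation=rot_p)
                    prows.append({"population": pop, "gene": gene,
                                  "h2": vc.h2})
            per_pop = pd.DataFrame(prows)
            per_pop.to_csv(out / "heritability_by_population.tsv", sep="\t",
                           index=False)
            wide = per_pop.pivot(index="gene", columns="population",
                                 values="h2")
            wide.corr().to_csv(out / "h2_population_correlation.tsv",
                               sep="\t")
            manifest["stages"].append("h2_by_population")

        # ---- eQTL scan --------------------------------------------------
        thr = bonferroni_threshold(config.bonferroni_alpha, qc_panel.n_snps)
        manifest["counts"]["bonferroni_threshold"] = thr
        assoc = scan_stage(gene_means, pops, qc_panel, thr)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest["counts"]["n_significant_associations"] = len(assoc)
        manifest["stages"].append("scan")

        # ---- peaks, cis/trans, eQTL heritability ------------------------
        ann = truth.gene_annotation.set_index("gene_id")
        all_peaks = eqtl_stage(assoc, ann, qc_panel, fits, rotation,
                               indiv_index, merge_window=config.merge_window)
        peaks_df = peaks_to_frame(all_peaks)
        peaks_df.to_csv(out / "eqtl_peaks.tsv", sep="\t", index=False)
        manifest["counts"]["n_eqtl_peaks"] = len(all_peaks)
        manifest["counts"]["n_cis"] = sum(p.label == "cis" for p in all_peaks)
        manifest["counts"]["n_trans"] = sum(p.label == "trans"
                                            for p in all_peaks)
        manifest["stages"].append("eqtl_h2")

        # ---- epistasis for genes with two or more peaks ------------------
        epi = epistasis_stage(peaks_df, fits, qc_panel, rotation,
                              indiv_index)
        epi.to_csv(out / "epistasis.tsv", sep="\t", index=False)
        manifest["counts"]["n_epistasis_tested"] = len(epi)
        manifest["stages"].append("epistasis")

        # ---- trio families ----------------------------------------------
        if config.sim.n_families >= 2:
            tpanel, texpr, fam = simulate_trios(config.sim)
            fam.to_csv(out / "trio_families.tsv", sep="\t", index=False)
            tmeans = texpr.replicate_means()
            trio_tab = trio_heritability_table(tmeans, fam)
            trio_tab.to_csv(out / "trio_heritability.tsv", sep="\t",
                            index=False)
            eqtl_genes = set(peaks_df["gene"]) if len(peaks_df) else set()
            nonneg = trio_tab["slope"] >= 0
            is_eqtl = trio_tab["gene"].isin(eqtl_genes)
            table = [[int((is_eqtl & nonneg).sum()),
                      int((is_eqtl & ~nonneg).sum())],
                     [int((~is_eqtl & nonneg).sum()),
                      int((~is_eqtl & ~nonneg).sum())]]
            odds, pval = fisher_enrichment(table)
            manifest["counts"]["trio_enrichment_odds"] = odds
            manifest["counts"]["trio_enrichment_p"] = pval
            manifest["stages"].append("trio")

        # ---- report ------------------------------------------------------
        summarize(out, config.gene_groups, bins=config.hist_bins)
        manifest["stages"].append("report")
        manifest["completed"] = True
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _save_manifest()
        log.removeHandler(fh)
        fh.close()
        raise
    _save_manifest()
    log.removeHandler(fh)
    fh.close()
    return manifest


def _hist_table(values, bins, lo=0.0, hi=1.0):
    counts, edges = np.histogram(np.asarray(values, dtype=float),
                                 bins=bins, range=(lo, hi))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def summarize(results_dir, gene_groups=None, bins: int = 20) -> dict:
    """Emit summary tables (and plots) from a finished run directory.

    Histograms of h^2 overall, per gene group (e.g. housekeeping lists),
    and by eQTL class; the stacked cis/trans h2_qtl histogram; the pi-ratio
    distribution.  Tables are written first; plots are a convenience.
    """
    out = Path(results_dir)
    h2 = pd.read_csv(out / "heritability.tsv", sep="\t")
    peaks_path = out / "eqtl_peaks.tsv"
    peaks = (pd.read_csv(peaks_path, sep="\t") if peaks_path.exists()
             and peaks_path.stat().st_size > 0 else pd.DataFrame())

    _hist_table(h2["h2"], bins).to_csv(out / "report_h2_hist.tsv", sep="\t",
                                       index=False)
    report = {"n_genes": len(h2), "mean_h2": float(h2["h2"].mean())}

    for name, genes in (gene_groups or {}).items():
        genes = set(genes)
        sub = h2[h2["gene"].isin(genes)]
        absent = genes - set(h2["gene"])
        if absent:
            log.warning("gene group %s: %d listed genes absent (%s...)",
                        name, len(absent), sorted(absent)[:3])
        if len(sub) == 0:
            log.warning("gene group %s empty; skipped", name)
            continue
        _hist_table(sub["h2"], bins).to_csv(
            out / f"report_h2_hist_{name}.tsv", sep="\t", index=False)

    if len(peaks):
        cis_genes = set(peaks.loc[peaks["label"] == "cis", "gene"])
        trans_only = set(peaks["gene"]) - cis_genes
        for cls, genes in (("cis", cis_genes), ("trans_only", trans_only),
                           ("no_eqtl", set(h2["gene"]) - set(peaks["gene"]))):
            sub = h2[h2["gene"].isin(genes)]
            if len(sub):
                _hist_table(sub["h2"], bins).to_csv(
                    out / f"report_h2_hist_{cls}.tsv", sep="\t", index=False)
        stacked = []
        for label in ("cis", "trans"):
            sub = peaks[peaks["label"] == label]
            ht = _hist_table(sub["h2_qtl"].dropna(), bins)
            ht["label"] = label
            stacked.append(ht)
        pd.concat(stacked, ignore_index=True).to_csv(
            out / "report_h2qtl_hist.tsv", sep="\t", index=False)
        _hist_table(peaks["pi_ratio"].dropna(), bins).to_csv(
            out / "report_pi_hist.tsv", sep="\t", index=False)
        report["mean_h2_qtl_cis"] = float(
            peaks.loc[peaks["label"] == "cis", "h2_qtl"].mean())
        report["mean_h2_qtl_trans"] = float(
            peaks.loc[peaks["label"] == "trans", "h2_qtl"].mean())

    _plot_histograms(out, h2, peaks, bins)
    with open(out / "report_summary.json", "w") as f:
        json.dump(report, f, indent=2, default=str)
    return report


def _plot_histograms(out, h2, peaks, bins):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(h2["h2"], bins=bins, range=(0, 1), color="grey")
    ax.set_xlabel("heritability $h^2$")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(out / "report_h2_hist.png", dpi=120)
    plt.close(fig)
    if len(peaks):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        data = [peaks.loc[peaks["label"] == lab, "h2_qtl"].dropna()
                for lab in ("cis", "trans")]
        ax.hist(data, bins=bins, range=(0, 1), stacked=True,
                label=["cis", "trans"], color=["tab:blue", "black"])
        ax.set_xlabel("variance fraction explained by eQTL")
        ax.set_ylabel("eQTLs")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "report_h2qtl_hist.png", dpi=120)
        plt.close(fig)
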