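"""Synthetic study generator: structured genotypes, replicated expression, trios.

Emulates the statistical structure of a multi-population expression-genetics
study: several geographically separated populations whose allele frequencies
diverge under a Balding-Nichols model, essentially unrelated individuals
(with optional planted relative pairs), per-individual polygenic expression
values with configurable narrow-sense heritability, planted cis/trans QTLs
and optional multiplicative SNP x SNP epistasis, replicated arrays per
individual with independent array-level noise, and trio families produced by
Mendelian transmission.

All randomness flows from ``SimConfig.seed`` through fixed named substreams,
so a given configuration reproduces every output bit-for-bit.

Expression is simulated directly on a log-like (normalised) scale.  Variance
fractions are defined on the per-array scale: for each gene the polygenic
fraction (``h2_list``), the planted QTL fractions and the epistatic fraction
must sum to at most 1, the remainder being the iid per-array residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panels import ExpressionPanel, GenotypePanel, SNP_COLUMNS

__all__ = [
    "SimConfig", "QtlSpec", "EpistasisSpec", "TruthRecord",
    "simulate_genotypes", "plant_relatives", "simulate_expression",
    "simulate_trios", "simulate_raw_probes", "simulate_study",
    "realized_kinship",
]

# named substreams off the master seed, one per generator stage
_STREAMS = {"genotypes": 0, "relatives": 1, "annotation": 2,
            "expression": 3, "trios": 4, "raw": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: ``gene`` index, ``role`` ('cis' or 'trans'), variance
    fraction of the per-array phenotypic variance."""
    gene: int
    role: str
    frac: float

    def __post_init__(self):
        if self.role not in ("cis", "trans"):
            raise ValueError("QTL role must be 'cis' or 'trans'")
        if not 0 < self.frac < 1:
            raise ValueError("QTL variance fraction must be in (0,1)")


@dataclass(frozen=True)
class EpistasisSpec:
    """A planted multiplicative SNP x SNP interaction on one gene."""
    gene: int
    frac: float


@dataclass
class SimConfig:
    n_populations: int = 4
    n_per_pop: int = 50
    n_snps: int = 2000
    fst: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.0
    n_genes: int = 20
    n_replicates: int = 4
    h2_list: list = field(default_factory=list)  # broadcast if length 1
    qtl_specs: list = field(default_factory=list)
    epistasis_specs: list = field(default_factory=list)
    pop_effect_sd: float = 0.5
    mu: float = 8.0
    n_chromosomes: int = 4
    snp_spacing: int = 5000
    n_families: int = 0
    replicate_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_populations", "n_per_pop", "n_snps", "n_genes",
                     "n_replicates", "n_chromosomes", "snp_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must be an interval in (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be a probability below 1")
        if not self.h2_list:
            self.h2_list = [0.5]
        if len(self.h2_list) == 1:
            self.h2_list = list(self.h2_list) * self.n_genes
        if len(self.h2_list) != self.n_genes:
            raise ValueError("h2_list must have one entry per gene")
        if any(not 0 <= h <= 1 for h in self.h2_list):
            raise ValueError("target heritabilities must lie in [0, 1]")
        self.qtl_specs = [q if isinstance(q, QtlSpec) else QtlSpec(*q)
                          for q in self.qtl_specs]
        self.epistasis_specs = [e if isinstance(e, EpistasisSpec)
                                else EpistasisSpec(*e)
                                for e in self.epistasis_specs]
        for g in range(self.n_genes):
            tot = self.h2_list[g] \
                + sum(q.frac for q in self.qtl_specs if q.gene == g) \
                + sum(e.frac for e in self.epistasis_specs if e.gene == g)
            if tot > 1 + 1e-12:
                raise ValueError(
                    f"variance fractions for gene {g} sum to {tot:.3f} > 1")

    @property
    def n_individuals(self) -> int:
        return self.n_populations * self.n_per_pop

    # flat-key YAML round trip (QTL specs as lists)
    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        d["maf_range"] = list(self.maf_range)
        d["qtl_specs"] = [[q.gene, q.role, q.frac] for q in self.qtl_specs]
        d["epistasis_specs"] = [[e.gene, e.frac]
                                for e in self.epistasis_specs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["maf_range"] = tuple(d.get("maf_range", (0.05, 0.5)))
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth planted by the generator, for parameter-recovery tests."""
    gene_h2: np.ndarray                    # polygenic fraction per gene
    qtl_truth: list = field(default_factory=list)       # (gene, snp_id, role, frac)
    epistasis_truth: list = field(default_factory=list)  # (gene, snp1, snp2, frac)
    relative_pairs: list = field(default_factory=list)   # (id_a, id_b, rel, pihat)
    populations: np.ndarray | None = None
    pop_freqs: np.ndarray | None = None    # (n_populations, n_snps)
    gene_annotation: pd.DataFrame | None = None

    def total_h2(self, gene: int) -> float:
        """Narrow-sense truth: polygenic plus additive QTL fractions."""
        return float(self.gene_h2[gene]) + sum(
            f for g, _, _, f in self.qtl_truth if g == gene)

    def to_tsv(self, path) -> None:
        rows = [{"record": "gene_h2", "key": f"G{g:04d}", "value": h}
                for g, h in enumerate(self.gene_h2)]
        rows += [{"record": f"qtl_{role}", "key": f"G{g:04d}:{snp}",
                  "value": f} for g, snp, role, f in self.qtl_truth]
        rows += [{"record": "epistasis", "key": f"G{g:04d}:{s1}x{s2}",
                  "value": f} for g, s1, s2, f in self.epistasis_truth]
        rows += [{"record": f"relative_{rel}", "key": f"{a}:{b}",
                  "value": k} for a, b, rel, k in self.relative_pairs]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig):
    """Draw a structured genotype panel under the Balding-Nichols model.

    Per SNP an ancestral frequency ``p`` is uniform on ``maf_range``; each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around it, and
    genotypes are Binomial(2, p_pop).  SNPs are laid in ascending position
    order on ``n_chromosomes`` synthetic chromosomes.

    Returns
    -------
    (GenotypePanel, TruthRecord)
    """
    rng = _rng(config.seed, "genotypes")
    npop, nper, m = config.n_populations, config.n_per_pop, config.n_snps
    p_anc = rng.uniform(*config.maf_range, size=m)
    F = config.fst
    a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
    pop_freqs = rng.beta(a, b, size=(npop, m))
    pop_freqs = np.clip(pop_freqs, 1e-6, 1 - 1e-6)

    dosages = np.empty((npop * nper, m))
    pops = np.empty(npop * nper, dtype=object)
    individuals = []
    for k in range(npop):
        sl = slice(k * nper, (k + 1) * nper)
        dosages[sl] = rng.binomial(2, pop_freqs[k], size=(nper, m))
        pops[sl] = f"POP{k + 1}"
        individuals += [f"POP{k + 1}_I{i:04d}" for i in range(nper)]
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chroms, positions = [], []
    for j in range(m):
        c = j // per_chrom
        chroms.append(f"chr{c + 1}")
        positions.append((j - c * per_chrom + 1) * config.snp_spacing)
    snps = pd.DataFrame({
        "snp_id": [f"snp{j:06d}" for j in range(m)],
        "chrom": chroms, "pos": positions,
        "ref": "A", "alt": "G"})[SNP_COLUMNS]

    panel = GenotypePanel(dosages, individuals, pops, snps)
    truth = TruthRecord(gene_h2=np.asarray(config.h2_list, dtype=float),
                        populations=pops.copy(), pop_freqs=pop_freqs)
    return panel, truth


def plant_relatives(panel: GenotypePanel, pairs, config: SimConfig,
                    truth: TruthRecord | None = None) -> GenotypePanel:
    """Overwrite genotypes so that given pairs become close relatives.

    ``pairs`` is a list of ``(id_a, id_b, relationship)`` with relationship
    ``"duplicate"`` or ``"parent_offspring"``; the second individual's
    genotypes are rewritten.  Pairs must lie within one population (the
    model treats populations as unrelated).  The second individual's
    original missingness pattern is preserved.
    """
    rng = _rng(config.seed, "relatives")
    dosages = panel.dosages.copy()
    idx = {s: i for i, s in enumerate(panel.individuals)}
    pop_names = panel.population_names()
    for id_a, id_b, rel in pairs:
        ia, ib = idx[id_a], idx[id_b]
        if panel.populations[ia] != panel.populations[ib]:
            raise ValueError(
                f"pair ({id_a}, {id_b}) spans populations; cross-population "
                "individuals are unrelated by assumption")
        missing_b = np.isnan(dosages[ib])
        parent = dosages[ia].copy()
        # parent's own missing calls are imputed from population frequency
        if truth is not None and truth.pop_freqs is not None:
            p = truth.pop_freqs[pop_names.index(panel.populations[ia])]
        else:
            within = panel.populations == panel.populations[ia]
            with np.errstate(invalid="ignore"):
                p = np.nanmean(dosages[within], axis=0) / 2.0
            p = np.nan_to_num(p, nan=0.5)
        pm = np.isnan(parent)
        parent[pm] = rng.binomial(2, p[pm])
        if rel == "duplicate":
            new = parent
            pihat = 1.0
        elif rel == "parent_offspring":
            transmitted = np.where(parent == 1, rng.integers(0, 2, parent.size),
                                   parent / 2)
            new = transmitted + rng.binomial(1, p)
            pihat = 0.5
        else:
            raise ValueError(f"unknown relationship {rel!r}")
        new = new.astype(float)
        new[missing_b] = np.nan
        dosages[ib] = new
        if truth is not None:
            truth.relative_pairs.append((id_a, id_b, rel, pihat))
    return GenotypePanel(dosages, list(panel.individuals),
                         panel.populations.copy(), panel.snps.copy())


def realized_kinship(panel: GenotypePanel) -> np.ndarray:
    """Realized standardized-genotype relationship, zero across populations.

    Within each population, genotypes are centred and scaled by the
    within-population allele frequency (2p, sqrt(2p(1-p))) and the GRM is
    X X'/m; cross-population entries are exactly zero, mirroring the
    analysis assumption that separated populations are unrelated.
    Monomorphic-in-population SNPs contribute nothing.  Missing calls are
    mean-imputed (zero after centring).
    """
    n = panel.n_individuals
    K = np.zeros((n, n))
    for pop in panel.population_names():
        rows = panel.population_index(pop)
        g = panel.dosages[rows]
        with np.errstate(invalid="ignore"):
            p = np.nanmean(g, axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        p = p[poly]
        x = g[:, poly] - 2 * p
        x = np.nan_to_num(x, nan=0.0)
        x /= np.sqrt(2 * p * (1 - p))
        K[np.ix_(rows, rows)] = (x @ x.T) / x.shape[1]
    return K


# ---------------------------------------------------------------------------
# expression


def _annotate_genes(panel: GenotypePanel, config: SimConfig):
    """Place genes at SNP-anchored positions across the panel's chromosomes."""
    rng = _rng(config.seed, "annotation")
    anchors = rng.choice(panel.n_snps, size=config.n_genes, replace=False)
    rows = []
    for g, j in enumerate(sorted(anchors)):
        start = int(panel.snps["pos"].iloc[j])
        rows.append({"gene_id": f"G{g:04d}",
                     "chrom": panel.snps["chrom"].iloc[j],
                     "start": start, "end": start + 10_000,
                     "strand": "+" if rng.random() < 0.5 else "-",
                     "anchor_snp": panel.snps["snp_id"].iloc[j]})
    return pd.DataFrame(rows)


def _choose_qtl_snp(panel, annotation, gene, role, rng, maf, taken):
    ann = annotation.iloc[gene]
    pos = panel.snps["pos"].to_numpy()
    same_chrom = (panel.snps["chrom"] == ann["chrom"]).to_numpy()
    in_window = same_chrom & (pos >= ann["start"] - 500_000) \
        & (pos <= ann["end"] + 500_000)
    ok = (maf >= 0.05) & ~np.isin(np.arange(panel.n_snps), list(taken))
    cand = np.flatnonzero((in_window if role == "cis" else ~same_chrom) & ok)
    if cand.size == 0:
        raise ValueError(f"no eligible {role} QTL SNP for gene {gene}")
    return int(rng.choice(cand))


def simulate_expression(panel: GenotypePanel, config: SimConfig,
                        truth: TruthRecord):
    """Simulate replicated expression with polygenic, QTL and epistatic parts.

    For gene g and individual i on array j:

        y_ij = mu + pop_effect + sum_k alpha_k x_ik (+ gamma w_i) + u_i + e_ij

    with ``u ~ MVN(0, sigma_g^2 K_true)`` (K_true the realized within-
    population GRM), ``e_ij`` iid, and all coefficients scaled so the
    empirical per-array variance fractions match the configured ones.  The
    epistatic covariate ``w`` is the product x1*x2 residualised on
    (1, x1, x2), so the planted interaction variance is orthogonal to the
    additive terms.  Replicates share ``u_i`` and the fixed part but carry
    independent ``e_ij``.

    Returns ``(ExpressionPanel, TruthRecord)``; the truth record is updated
    in place with QTL/epistasis assignments and the gene annotation.
    """
    rng = _rng(config.seed, "expression")
    n, n_genes, n_rep = panel.n_individuals, config.n_genes, config.n_replicates
    annotation = _annotate_genes(panel, config)
    truth.gene_annotation = annotation

    K = realized_kinship(panel)
    w, q = np.linalg.eigh(K)
    L = q * np.sqrt(np.clip(w, 0.0, None))

    maf = panel.maf()
    dos = panel.dosages.copy()
    # mean-impute missing dosages for phenotype construction only
    col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
    nanpos = np.isnan(dos)
    dos[nanpos] = np.take(col_mean, np.nonzero(nanpos)[1])

    pop_names = panel.population_names()
    pop_idx = np.asarray([pop_names.index(p) for p in panel.populations])

    taken: set = set()
    gene_qtls = {g: [] for g in range(n_genes)}
    for qspec in config.qtl_specs:
        j = _choose_qtl_snp(panel, annotation, qspec.gene, qspec.role, rng,
                            maf, taken)
        taken.add(j)
        gene_qtls[qspec.gene].append((j, qspec.role, qspec.frac))
        truth.qtl_truth.append((qspec.gene, panel.snps["snp_id"].iloc[j],
                                qspec.role, qspec.frac))
    gene_epi = {g: [] for g in range(n_genes)}
    for espec in config.epistasis_specs:
        pair = gene_qtls[espec.gene]
        if len(pair) >= 2:
            j1, j2 = pair[0][0], pair[1][0]
        else:  # plant two dedicated trans-acting loci for the interaction
            j1 = _choose_qtl_snp(panel, annotation, espec.gene, "trans", rng,
                                 maf, taken)
            taken.add(j1)
            j2 = _choose_qtl_snp(panel, annotation, espec.gene, "trans", rng,
                                 maf, taken)
            taken.add(j2)
        gene_epi[espec.gene].append((j1, j2, espec.frac))
        truth.epistasis_truth.append(
            (espec.gene, panel.snps["snp_id"].iloc[j1],
             panel.snps["snp_id"].iloc[j2], espec.frac))

    values = np.empty((n_genes, n, n_rep))
    for g in range(n_genes):
        h2 = config.h2_list[g]
        resid = 1.0 - h2 - sum(f for _, _, f in gene_qtls[g]) \
            - sum(f for _, _, f in gene_epi[g])
        fixed = np.full(n, config.mu)
        fixed += rng.normal(0.0, config.pop_effect_sd,
                            size=len(pop_names))[pop_idx]
        for j, _, frac in gene_qtls[g]:
            x = dos[:, j]
            sd = x.std()
            fixed += np.sqrt(frac) / sd * (x - x.mean())
        for j1, j2, frac in gene_epi[g]:
            x1, x2 = dos[:, j1], dos[:, j2]
            A = np.column_stack([np.ones(n), x1, x2])
            prod = x1 * x2
            wres = prod - A @ np.linalg.lstsq(A, prod, rcond=None)[0]
            sd = wres.std()
            if sd > 0:
                fixed += np.sqrt(frac) / sd * wres
        u = L @ rng.standard_normal(n) * np.sqrt(h2)
        e = rng.normal(0.0, np.sqrt(max(resid, 0.0)), size=(n, n_rep))
        values[g] = (fixed + u)[:, None] + e

    expr = ExpressionPanel(values, [f"G{g:04d}" for g in range(n_genes)],
                           list(panel.individuals), layer="normalized",
                           probe_to_gene={f"G{g:04d}": f"G{g:04d}"
                                          for g in range(n_genes)})
    return expr, truth


def simulate_raw_probes(n_probes: int, n_individuals: int, n_replicates: int,
                        seed: int, frac_low: float = 0.2,
                        background: float = 100.0):
    """Raw-intensity probe panel with per-array background, for testing the
    lowly-expressed-probe filter.  A ``frac_low`` fraction of probes sit
    below background on every array for most individuals."""
    rng = _rng(seed, "raw")
    n_low = int(round(frac_low * n_probes))
    vals = rng.lognormal(mean=6.5, sigma=0.4,
                         size=(n_probes, n_individuals, n_replicates))
    vals[:n_low] = rng.uniform(10.0, 0.9 * background,
                               size=(n_low, n_individuals, n_replicates))
    bg = np.full((n_individuals, n_replicates), background)
    probes = [f"P{k:05d}" for k in range(n_probes)]
    return ExpressionPanel(vals, probes,
                           [f"I{i:04d}" for i in range(n_individuals)],
                           layer="raw",
                           probe_to_gene={p: f"G{k // 2:04d}"
                                          for k, p in enumerate(probes)},
                           background=bg)


# ---------------------------------------------------------------------------
# trios


def simulate_trios(config: SimConfig):
    """Trio families: parents unrelated, offspring by Mendelian transmission.

    Expression is built on the additive model so that the expected
    offspring-on-midparent regression slope equals the configured h^2 for
    each gene: parent values are mu + g + e with Var(g) = h2, the offspring
    genetic value is the parental mean (no segregation term, which leaves
    the slope's expectation exactly h2 and makes the h2=1 noise-free case an
    identity).  Replicate noise is budgeted inside the environmental
    variance so replicate-averaged values keep the configured h2.

    Returns
    -------
    (GenotypePanel, ExpressionPanel, DataFrame)
        Genotypes and expression for all members (fathers, mothers,
        children) and the family map (family_id, father_id, mother_id,
        child_id).
    """
    if config.n_families < 2:
        raise ValueError("need at least 2 trio families")
    rng = _rng(config.seed, "trios")
    nf, m = config.n_families, config.n_snps
    p = rng.uniform(*config.maf_range, size=m)

    def mendel(parent):
        return np.where(parent == 1,
                        rng.integers(0, 2, parent.shape),
                        parent / 2)

    fathers = rng.binomial(2, p, size=(nf, m)).astype(float)
    mothers = rng.binomial(2, p, size=(nf, m)).astype(float)
    children = mendel(fathers) + mendel(mothers)

    ids, rows = [], []
    for f in range(nf):
        ids += [f"FAM{f:03d}_F", f"FAM{f:03d}_M", f"FAM{f:03d}_C"]
        rows.append({"family_id": f"FAM{f:03d}",
                     "father_id": f"FAM{f:03d}_F",
                     "mother_id": f"FAM{f:03d}_M",
                     "child_id": f"FAM{f:03d}_C"})
    dosages = np.empty((3 * nf, m))
    dosages[0::3], dosages[1::3], dosages[2::3] = fathers, mothers, children
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    snps = pd.DataFrame({
        "snp_id": [f"snp{j:06d}" for j in range(m)],
        "chrom": [f"chr{j // per_chrom + 1}" for j in range(m)],
        "pos": [(j % per_chrom + 1) * config.snp_spacing for j in range(m)],
        "ref": "A", "alt": "G"})[SNP_COLUMNS]
    panel = GenotypePanel(dosages, ids,
                          np.asarray(["TRIO"] * (3 * nf), dtype=object), snps)

    n_rep = config.n_replicates
    values = np.empty((config.n_genes, 3 * nf, n_rep))
    for g in range(config.n_genes):
        h2 = config.h2_list[g]
        env = 1.0 - h2
        rep_var = min(config.replicate_noise_sd ** 2, 0.5 * env * n_rep)
        shared_env = env - rep_var / n_rep
        gf = rng.normal(0.0, np.sqrt(h2), nf)
        gm = rng.normal(0.0, np.sqrt(h2), nf)
        gc = (gf + gm) / 2.0
        base = np.empty(3 * nf)
        for garr, off in ((gf, 0), (gm, 1), (gc, 2)):
            base[off::3] = config.mu + garr \
                + rng.normal(0.0, np.sqrt(max(shared_env, 0.0)), nf)
        values[g] = base[:, None] + rng.normal(
            0.0, np.sqrt(rep_var), size=(3 * nf, n_rep))
    expr = ExpressionPanel(values,
                           [f"G{g:04d}" for g in range(config.n_genes)],
                           ids, layer="normalized")
    return panel, expr, pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig, relative_pairs=None):
    """Convenience wrapper: genotypes (+ optional planted relatives) and
    expression in one call.  Returns (panel, expression, truth)."""
    panel, truth = simulate_genotypes(config)
    if relative_pairs:
        panel = plant_relatives(panel, relative_pairs, config, truth)
    expr, truth = simulate_expression(panel, config, truth)
    return panel, expr, truth
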