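# expherit

Variance-component heritability and eQTL mapping for replicated gene
expression traits measured in structured populations.

## The problem

How much of the person-to-person variation in a gene's expression level is
genetic?  Given genome-wide SNP genotypes and replicated microarray
intensities for individuals drawn from several geographically separated
populations, `expherit` estimates, for every gene:

* the narrow-sense heritability *h²* of its expression level, by REML on a
  variance-component mixed model with a genotype-derived kinship matrix;
* its expression QTLs (eQTLs), by a genome-wide association scan corrected
  for population structure, with peak merging and cis/trans classification;
* the fraction of phenotypic variance each eQTL explains, and the share π
  of the total heritability the detected eQTLs account for ("missing
  heritability");
* whether a multiplicative SNP×SNP interaction (epistasis) between two
  eQTLs explains additional variance, judged by AIC;
* trio-family heritability by midparent-offspring regression, as an
  independent cross-check on the population-based estimates.

It is written for statistical geneticists and computational biologists who
want these estimators as a library (each analysis step is an importable,
tested function) or as a pipeline (`expherit all`).  A synthetic-data
generator reproduces the statistical structure such a study assumes —
allele-frequency divergence between populations, polygenic expression
values with configurable *h²*, planted cis/trans QTLs and epistasis,
replicate arrays, trio families — so the whole chain is testable without
any external data.

## The model

For expression value $y_{ij}$ of individual $i$ on array $j$:

$$y_{ij} = \mu + \mathbf{S}_i\beta + \sum_k \alpha_k x_{ik} + u_i + e_{ij}$$

where $\mathbf{S}_i$ are population indicators (one level omitted),
$x_{ik} \in \{0,1,2\}$ are optional SNP dosages, $u \sim N(0,\sigma_g^2
\mathbf{K})$ is the polygenic effect with $\mathbf{K}$ the kinship matrix,
and $e \sim N(0,\sigma_e^2\mathbf{I})$.  The phenotypic covariance is
$\mathbf{V} = \sigma_g^2\mathbf{Z}\mathbf{K}\mathbf{Z}' +
\sigma_e^2\mathbf{I}$ with $\mathbf{Z}$ mapping arrays to individuals, and

$$h^2 = \frac{\sigma_g^2}{\sigma_g^2 + \sigma_e^2}.$$

$\mathbf{K}$ is built by method-of-moments IBD estimation (pi-hat) within
each population from LD-pruned SNPs, merged block-diagonally with
cross-population coefficients fixed at zero.  REML is profiled over the
variance ratio $\lambda = \sigma_g^2/\sigma_e^2$ in the eigenbasis of
$\mathbf{Z}\mathbf{K}\mathbf{Z}'$, which guarantees non-negative
components and hence $\hat h^2 \in [0,1]$.  The variance explained by a
SNP is the drop in $\hat\sigma_g^2 + \hat\sigma_e^2$ between the SNP-free
and SNP-inclusive fits, relative to the SNP-free sum; π is that quantity
over $\hat h^2$.  The association scan itself is OLS of replicate-averaged
expression on dosage plus population indicators, with Bonferroni
correction over SNPs, 5 Mb single-linkage peak merging and a ±500 kb cis
window around the gene.

## Worked example

```python
import numpy as np
from expherit.synthetic_data import SimConfig, simulate_study, realized_kinship
from expherit.reml_core import (EigenRotation, make_spec, reml_fit,
                                fit_snp_model, eqtl_heritability)

cfg = SimConfig(n_populations=4, n_per_pop=100, n_snps=2000, fst=0.1,
                n_genes=3, h2_list=[0.2, 0.5, 0.8],
                qtl_specs=[(1, "cis", 0.2)], seed=11)
panel, expr, truth = simulate_study(cfg)
K = realized_kinship(panel)
idx = np.repeat(np.arange(panel.n_individuals), cfg.n_replicates)
rot = EigenRotation(K, idx)
for g, gene in enumerate(expr.features):
    spec = make_spec(expr.values[g], panel.populations, K)
    vc = reml_fit(spec, rotation=rot)
    print(f"{gene}: sigma_g2={vc.sigma_g2:.3f} sigma_e2={vc.sigma_e2:.3f} "
          f"h2={vc.h2:.3f}")

gene, snp, role, frac = truth.qtl_truth[0]
j = list(panel.snps["snp_id"]).index(snp)
x = panel.dosages[:, j]
x = np.where(np.isnan(x), np.nanmean(x), x)
spec = make_spec(expr.values[gene], panel.populations, K)
vc_free = reml_fit(spec, rotation=rot)
vc_snp = fit_snp_model(spec, x[idx][:, None], rotation=rot)
eh = eqtl_heritability(vc_free, vc_snp)
print(f"{snp} ({role}, planted {frac:.0%}): h2_qtl={eh.h2_qtl:.3f} "
      f"pi={eh.pi_ratio:.3f}")
```

prints

```
G0000: sigma_g2=0.213 sigma_e2=0.792 h2=0.212
G0001: sigma_g2=0.731 sigma_e2=0.285 h2=0.719
G0002: sigma_g2=0.795 sigma_e2=0.199 h2=0.800
snp001284 (cis, planted 20%): h2_qtl=0.215 pi=0.299
```

Four hundred individuals from four populations, 2,000 SNPs, four replicate
arrays per individual.  The three genes were simulated with polygenic
fractions 0.2 / 0.5 / 0.8; gene `G0001` additionally carries a cis QTL at
20% of phenotypic variance, so its SNP-free heritability is ≈0.7 (the QTL
variance is genetic and loads onto $\hat\sigma_g^2$).  The
variance-component differencing attributes h²_qtl = 0.215 to the planted
SNP — recovering the 20% truth — which is π ≈ 0.30 of the gene's total
heritability.

The same analysis runs end-to-end from a shell:

```sh
expherit all --config config.yaml        # simulate → QC → kinship → h² →
                                         # scan → eQTL-h² → epistasis →
                                         # trio → report
```

with per-stage subcommands (`simulate`, `qc`, `relatedness`, `normalize`,
`h2`, `scan`, `eqtl-h2`, `epistasis`, `trio`, `report`) operating on the
run directory.

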