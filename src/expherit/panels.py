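"""Core data containers: genotype panels, expression panels, kinship matrices.

Genotypes are held as an individuals x SNPs dosage matrix (count of the
alternate allele, 0/1/2) with ``NaN`` marking missing calls, alongside SNP
metadata (chromosome, 1-based position, alleles) and per-individual
population labels.  Expression is a feature x individual x replicate array
with a layer tag.  Kinship is a symmetric individual x individual matrix of
genome-wide IBD sharing probabilities (pi-hat), block-diagonal across
populations under the assumption that geographically separated populations
are unrelated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "ExpressionPanel", "KinshipMatrix"]

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypePanel:
    """Dosage matrix plus SNP metadata and population labels.

    Parameters
    ----------
    dosages : ndarray, shape (n_individuals, n_snps)
        Alternate-allele counts as floats; ``NaN`` encodes a missing call.
    individuals : list of str
        Sample identifiers, aligned to the rows of ``dosages``.
    populations : ndarray of str
        Population label per individual.
    snps : DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``
        (position 1-based); rows aligned to the columns of ``dosages``.
    """

    dosages: np.ndarray
    individuals: list
    populations: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.dosages.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label required per individual")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table lacks columns {missing_cols}")

    # -- basic shape ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    # -- per-SNP / per-individual statistics ------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of individuals with a non-missing call, per SNP."""
        return 1.0 - np.mean(self.missing_mask, axis=0)

    def individual_missing_counts(self) -> np.ndarray:
        """Number of missing genotype calls per individual."""
        return self.missing_mask.sum(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing calls."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting -------------------------------------------------------
    def subset_snps(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            dosages=self.dosages[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
        )

    def select_snp_ids(self, snp_ids) -> "GenotypePanel":
        pos = pd.Index(self.snps["snp_id"]).get_indexer(list(snp_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(snp_ids, pos) if p < 0]
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return self.subset_snps(pos)

    def subset_individuals(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            dosages=self.dosages[index],
            individuals=[self.individuals[i] for i in index],
            populations=self.populations[index],
        )

    def drop_individuals(self, ids) -> "GenotypePanel":
        drop = set(ids)
        keep = [i for i, s in enumerate(self.individuals) if s not in drop]
        return self.subset_individuals(np.asarray(keep, dtype=int))

    def population_index(self, population) -> np.ndarray:
        return np.flatnonzero(self.populations == population)

    def population_names(self) -> list:
        seen = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    # -- I/O --------------------------------------------------------------
    def to_dosage_tsv(self, path) -> None:
        """Write SNPs x individuals dosage TSV with SNP metadata columns."""
        df = self.snps.copy()
        mat = pd.DataFrame(
            self.dosages.T, columns=self.individuals, index=df.index
        )
        pd.concat([df, mat], axis=1).to_csv(path, sep="\t", index=False,
                                            na_rep="NA")

    @classmethod
    def from_dosage_tsv(cls, path, populations) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        snps = df[SNP_COLUMNS].copy()
        sample_cols = [c for c in df.columns if c not in SNP_COLUMNS]
        dosages = df[sample_cols].to_numpy(dtype=float).T
        pops = np.asarray([populations[s] for s in sample_cols], dtype=object)
        return cls(dosages, sample_cols, pops, snps.reset_index(drop=True))

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with GT genotypes (1-based positions)."""
        buf = io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        buf.write("\t".join(str(s) for s in self.individuals) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in enumerate(self.snps.itertuples(index=False)):
            calls = []
            for d in self.dosages[:, j]:
                calls.append("./." if np.isnan(d) else gt_map[int(round(d))])
            buf.write(
                f"{row.chrom}\t{int(row.pos)}\t{row.snp_id}\t{row.ref}\t"
                f"{row.alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_vcf(cls, path, populations) -> "GenotypePanel":
        """Read genotypes from a VCF via cyvcf2 (GT field only)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, dosage_cols = [], []
        for var in vcf:
            rows.append(
                (var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                 int(var.POS), var.REF, var.ALT[0] if var.ALT else "."))
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(var.gt_types, dtype=float)
            col = np.where(gt == 3, 2.0, gt)
            col[gt == 2] = np.nan
            dosage_cols.append(col)
        snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
        dosages = np.column_stack(dosage_cols) if dosage_cols else \
            np.empty((len(samples), 0))
        pops = np.asarray([populations[s] for s in samples], dtype=object)
        return cls(dosages, samples, pops, snps)


@dataclass
class ExpressionPanel:
    """Feature x individual x replicate intensity array with a layer tag.

    ``layer`` is one of ``"raw"``, ``"normalized"`` or ``"averaged"``; the
    averaged layer has one replicate axis entry.  ``background`` (raw layer
    only) holds one background-noise estimate per array, i.e. per
    (individual, replicate) pair.
    """

    values: np.ndarray
    features: list
    individuals: list
    layer: str = "raw"
    probe_to_gene: dict = field(default_factory=dict)
    background: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (features, individuals, replicates)")
        nf, ni, _ = self.values.shape
        if nf != len(self.features) or ni != len(self.individuals):
            raise ValueError("values shape does not match feature/sample lists")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != self.values.shape[1:]:
                raise ValueError("background must be (individuals, replicates)")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def replicate_means(self) -> pd.DataFrame:
        """Feature x individual means over replicates."""
        return pd.DataFrame(self.values.mean(axis=2), index=self.features,
                            columns=self.individuals)

    def subset_features(self, index) -> "ExpressionPanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        feats = [self.features[i] for i in index]
        return replace(self, values=self.values[index], features=feats)

    def subset_individuals(self, index) -> "ExpressionPanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            values=self.values[:, index, :],
            individuals=[self.individuals[i] for i in index],
            background=None if self.background is None
            else self.background[index],
        )

    def drop_individuals(self, ids) -> "ExpressionPanel":
        drop = set(ids)
        keep = [i for i, s in enumerate(self.individuals) if s not in drop]
        return self.subset_individuals(np.asarray(keep, dtype=int))

    # -- I/O: rows are (sample, replicate), one column per feature ---------
    def to_tsv(self, path) -> None:
        nf, ni, nr = self.values.shape
        recs = {
            "sample_id": np.repeat(self.individuals, nr),
            "replicate": np.tile(np.arange(1, nr + 1), ni),
        }
        flat = self.values.reshape(nf, ni * nr)
        for k, f in enumerate(self.features):
            recs[str(f)] = flat[k]
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, layer="normalized", probe_to_gene=None):
        df = pd.read_csv(path, sep="\t")
        feats = [c for c in df.columns if c not in ("sample_id", "replicate")]
        individuals = list(dict.fromkeys(df["sample_id"]))
        reps = sorted(df["replicate"].unique())
        vals = np.full((len(feats), len(individuals), len(reps)), np.nan)
        ind_pos = {s: i for i, s in enumerate(individuals)}
        rep_pos = {r: i for i, r in enumerate(reps)}
        fmat = df[feats].to_numpy(dtype=float)
        for r, (sid, rep) in enumerate(zip(df["sample_id"], df["replicate"])):
            vals[:, ind_pos[sid], rep_pos[rep]] = fmat[r]
        return cls(vals, feats, individuals, layer=layer,
                   probe_to_gene=probe_to_gene or {})


@dataclass
class KinshipMatrix:
    """Symmetric pi-hat matrix, block-diagonal across populations."""

    values: np.ndarray
    individuals: list
    populations: np.ndarray
    snp_provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.populations = np.asarray(self.populations, dtype=object)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square over individuals")

    def validate(self, atol=1e-8) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("kinship matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("kinship diagonal must be 1")
        off = v - np.diag(np.diag(v))
        if off.min() < -atol or off.max() > 1 + atol:
            raise ValueError("off-diagonal kinship outside [0, 1]")
        cross = ~np.equal.outer(self.populations, self.populations)
        if np.any(np.abs(v[cross]) > atol):
            raise ValueError("cross-population kinship must be exactly 0")

    def psd_clipped(self) -> "KinshipMatrix":
        """Clip negative eigenvalues at zero (V must stay PSD in REML)."""
        w, q = np.linalg.eigh(self.values)
        if w.min() >= 0:
            return self
        v = (q * np.clip(w, 0.0, None)) @ q.T
        v = (v + v.T) / 2.0
        return replace(self, values=v)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.individuals,
                     columns=self.individuals).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, populations) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        inds = list(df.columns)
        pops = np.asarray([populations[s] for s in inds], dtype=object)
        return cls(df.to_numpy(dtype=float), inds, pops)
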