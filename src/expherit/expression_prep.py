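"""Expression pre-processing: probe filter, normalisation, collapsing.

The chain mirrors a replicated-microarray design: probes expressed above
array background are kept (a probe is removed when its raw intensity falls
below the array background on *all* replicates for more than half of the
individuals); each individual's replicates are quantile-normalised against
each other; individuals are then median-normalised by an additive shift on
the log-like scale; probes are collapsed to genes by unweighted averaging
and replicates averaged to one value per individual.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .panels import ExpressionPanel

__all__ = ["filter_probes", "quantile_normalize_replicates",
           "median_normalize_individuals", "collapse_and_average",
           "normalize_panel"]


def filter_probes(raw: ExpressionPanel, whitelist=None) -> ExpressionPanel:
    """Drop probes not in the whitelist or below background in all
    replicates for more than 50% of individuals.

    The whitelist encodes upstream probe-to-transcript mapping screens and
    is consumed as given; ``None`` admits every probe.  Backgrounds are one
    value per array (individual, replicate); missing backgrounds fall back
    to the 5th percentile of each array's intensities.
    """
    if raw.layer != "raw":
        raise ValueError("probe filtering applies to the raw layer")
    bg = raw.background
    if bg is None:
        bg = np.percentile(raw.values, 5.0, axis=0)
    below_all = np.all(raw.values < bg[None, :, :], axis=2)  # probe x indiv
    frac_low = below_all.mean(axis=1)
    keep = frac_low <= 0.5
    if whitelist is not None:
        wl = set(whitelist)
        keep &= np.asarray([p in wl for p in raw.features])
    return raw.subset_features(keep)


def quantile_normalize_replicates(values: np.ndarray) -> np.ndarray:
    """Quantile-normalise one individual's replicate vectors.

    ``values`` is (n_features, n_replicates).  Each replicate's sorted
    values are replaced by the mean of sorted values across replicates,
    written back in rank order; tied entries receive the mean of the
    reference values at their tied positions.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a (features, >=2 replicates) matrix")
    nf, nr = values.shape
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(nr):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(nf)
        assigned[order] = ref
        s = col[order]
        start = 0
        for i in range(1, nf + 1):
            if i == nf or s[i] != s[start]:
                if i - start > 1:       # tie block: share the mean reference
                    assigned[order[start:i]] = ref[start:i].mean()
                start = i
        out[:, j] = assigned
    return out


def median_normalize_individuals(panel: ExpressionPanel) -> ExpressionPanel:
    """Shift each individual's values so every individual median equals the
    global median (additive shift, appropriate on a log-like scale)."""
    med_ind = np.median(panel.values, axis=(0, 2))
    global_med = np.median(panel.values)
    shifted = panel.values + (global_med - med_ind)[None, :, None]
    return replace(panel, values=shifted, layer="normalized")


def collapse_and_average(panel: ExpressionPanel):
    """Collapse probes to genes (unweighted probe mean) and average
    replicates.

    Returns ``(gene_panel, gene_means)`` where ``gene_panel`` is the
    gene x (individual, replicate) panel and ``gene_means`` a
    gene x individual DataFrame of replicate means.  Genes left with no
    surviving probe simply do not appear.
    """
    if not panel.probe_to_gene:
        raise ValueError("probe-to-gene map required to collapse")
    unmapped = [p for p in panel.features if p not in panel.probe_to_gene]
    if unmapped:
        raise ValueError(f"probes without gene mapping: {unmapped[:5]}")
    genes = list(dict.fromkeys(panel.probe_to_gene[p]
                               for p in panel.features))
    gvals = np.empty((len(genes), panel.values.shape[1],
                      panel.values.shape[2]))
    probes_of = {g: [] for g in genes}
    for i, p in enumerate(panel.features):
        probes_of[panel.probe_to_gene[p]].append(i)
    for k, g in enumerate(genes):
        gvals[k] = panel.values[probes_of[g]].mean(axis=0)
    gene_panel = ExpressionPanel(gvals, genes, list(panel.individuals),
                                 layer=panel.layer,
                                 probe_to_gene={g: g for g in genes})
    return gene_panel, gene_panel.replicate_means()


def normalize_panel(raw_or_norm: ExpressionPanel) -> ExpressionPanel:
    """Within-individual quantile normalisation followed by across-individual
    median normalisation."""
    vals = raw_or_norm.values.copy()
    for i in range(vals.shape[1]):
        vals[:, i, :] = quantile_normalize_replicates(vals[:, i, :])
    qn = replace(raw_or_norm, values=vals, layer="normalized",
                 background=None)
    return median_normalize_individuals(qn)
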