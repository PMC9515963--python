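"""Functional profiling: KO projection, pathway aggregation, and
genus-pathway contribution z-scores.

Sample-level KO abundances are the abundance-weighted sums of predicted
per-feature gene copy numbers; pathway abundances sum the member-KO
abundances.  The genus-by-pathway contribution matrix averages copy
numbers over a pathway's KOs and over a genus's features, and each
pathway column is standardized to z-scores across genera to highlight
which genus carries which pathway.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bundle_io import FeatureTable, KoCopyTable, GeneSetCatalog, TaxonomyMap


def project_ko(table: FeatureTable, copies: KoCopyTable) -> FeatureTable:
    """Project feature abundances to KO relative abundances.

    ``u[s, k] = sum_j a[s, j] * c[j, k]`` with each sample row then closed
    to unit sum.  Exact zeros are preserved: a KO carried by no present
    feature stays exactly zero.
    """
    rel = table.relabund()
    present = np.array(rel.feature_ids)[(rel.values > 0).any(axis=0)]
    missing = set(present) - set(copies.data.index)
    if missing:
        raise ValueError(f"features missing from copy table: {sorted(missing)[:5]}")
    c = copies.data.reindex(rel.feature_ids).fillna(0.0)
    raw = rel.data.to_numpy() @ c.to_numpy()
    sums = raw.sum(axis=1)
    if (sums <= 0).any():
        bad = rel.sample_ids[int(np.argmax(sums <= 0))]
        raise ValueError(f"sample {bad!r} projects to all-zero KO abundance")
    out = pd.DataFrame(raw / sums[:, None], index=rel.sample_ids,
                       columns=copies.ko_ids)
    return FeatureTable(out, kind="relabund")


def aggregate_pathways(ko_abund: FeatureTable, catalog: GeneSetCatalog):
    """Sum member-KO relative abundances per pathway.

    Returns ``(relabund FeatureTable, raw DataFrame)``: the raw per-sample
    pathway sums (overlapping pathways may sum past 1) and the row-closed
    version used for diversity computations.  Catalog KOs absent from the
    KO table are dropped with a warning.
    """
    if not catalog.sets:
        raise ValueError("empty pathway catalog")
    kos = set(ko_abund.feature_ids)
    raw = {}
    for pid in catalog.pathway_ids:
        members = catalog.sets[pid] & kos
        orphans = catalog.sets[pid] - kos
        if orphans:
            warnings.warn(f"pathway {pid}: {len(orphans)} member KO(s) absent "
                          "from the KO table; dropped")
        raw[pid] = ko_abund.data.loc[:, sorted(members)].sum(axis=1) if members \
            else pd.Series(0.0, index=ko_abund.data.index)
    raw = pd.DataFrame(raw)
    sums = raw.sum(axis=1)
    if (sums <= 0).any():
        bad = raw.index[int(np.argmax((sums <= 0).to_numpy()))]
        raise ValueError(f"sample {bad!r} has zero total pathway abundance")
    rel = FeatureTable(raw.div(sums, axis=0), kind="relabund")
    return rel, raw


def genus_pathway_zscores(copies: KoCopyTable, catalog: GeneSetCatalog,
                          taxonomy: TaxonomyMap):
    """Genus-by-pathway contribution z-scores.

    Contribution ``C[g, p]`` is the mean over the genus's features of the
    mean copy number over the pathway's KOs; each pathway column is
    standardized across genera.  Columns with zero variance get all-zero
    z-scores and are flagged.
    """
    genus = taxonomy.data["genus"].reindex(copies.data.index).fillna("")
    genus = genus.where(genus != "", "unassigned")
    if genus.nunique() < 2:
        raise ValueError("need at least 2 genera")
    kos = set(copies.ko_ids)
    per_pathway = {}
    for pid in catalog.pathway_ids:
        members = sorted(catalog.sets[pid] & kos)
        per_pathway[pid] = copies.data.loc[:, members].mean(axis=1) if members \
            else pd.Series(0.0, index=copies.data.index)
    contrib = pd.DataFrame(per_pathway).groupby(genus).mean()
    mean = contrib.mean(axis=0)
    sd = contrib.std(axis=0, ddof=1)
    flat = sd == 0
    z = (contrib - mean).div(sd.where(~flat, 1.0), axis=1)
    z.loc[:, flat] = 0.0
    return z, list(z.columns[flat])
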