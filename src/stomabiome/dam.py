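"""Compositional differential abundance via Dirichlet Monte-Carlo clr
instances (ALDEx2-style).

Counts are aggregated to the requested taxonomic rank, Monte-Carlo
instances of the underlying composition are drawn per sample from
Dirichlet(counts + prior) and clr-transformed, a Wilcoxon rank-sum test
with Benjamini-Hochberg correction is run per instance, and a
standardized effect size is computed per feature.  Features are called
differential at the expected-BH and effect thresholds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bundle_io import FeatureTable, TaxonomyMap, RANKS
from . import stats

P_THRESH = 0.3
EFFECT_THRESH = 0.17


@dataclasses.dataclass
class MCInstances:
    """clr values per (sample, feature, Monte-Carlo instance)."""

    clr: np.ndarray  # (n_samples, n_features, n_mc)
    sample_ids: list
    feature_ids: list
    seed: int

    def __post_init__(self):
        if self.clr.shape[2] < 2:
            raise ValueError("need n_mc >= 2")
        sums = self.clr.sum(axis=1)
        if np.abs(sums).max() > 1e-6:
            raise ValueError("clr instances do not sum to zero")


def aggregate_rank(table: FeatureTable, taxonomy: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum counts over features sharing the lineage prefix through ``rank``.

    Features unassigned at the rank are pooled into ``unassigned at <rank>``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    prefix_ranks = RANKS[: RANKS.index(rank) + 1]
    tax = taxonomy.data.reindex(table.feature_ids).fillna("")
    labels = []
    for _, row in tax.iterrows():
        if row[rank] == "":
            labels.append(f"unassigned at {rank}")
        else:
            labels.append("; ".join(row[r] for r in prefix_ranks))
    grouped = table.data.T.groupby(np.array(labels)).sum().T
    return FeatureTable(grouped, kind=table.kind)


def dirichlet_clr_instances(table: FeatureTable, n_mc=128, prior=0.5,
                            seed=0) -> MCInstances:
    """Draw clr-transformed Dirichlet Monte-Carlo instances per sample."""
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    if prior <= 0:
        raise ValueError("prior must be > 0")
    counts = table.values
    if (counts.sum(axis=1) <= 0).any():
        bad = table.sample_ids[int(np.argmax(counts.sum(axis=1) <= 0))]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    rng = np.random.default_rng(seed)
    n_s, n_f = counts.shape
    out = np.empty((n_s, n_f, n_mc))
    for i in range(n_s):
        draws = rng.dirichlet(counts[i] + prior, size=n_mc)  # (n_mc, n_f)
        logd = np.log(draws)
        out[i] = (logd - logd.mean(axis=1, keepdims=True)).T
    return MCInstances(out, table.sample_ids, table.feature_ids, seed)


def aldex_like_test(mc: MCInstances, groups, stoma_level="stoma",
                    other_level="non_stoma") -> pd.DataFrame:
    """Per-feature expected BH-adjusted p (eBH) and standardized effect.

    Per Monte-Carlo instance a two-sided Wilcoxon rank-sum test is run per
    feature and BH-adjusted across features; eBH is the mean adjusted p
    over instances.  The effect is the median over instances of
    ``(median clr stoma - median clr non-stoma) / max(MAD_s, MAD_n)`` with
    the denominator floored at 1e-8.
    """
    groups = pd.Series(groups).reindex(mc.sample_ids)
    a_idx = np.flatnonzero((groups == stoma_level).to_numpy())
    b_idx = np.flatnonzero((groups == other_level).to_numpy())
    if a_idx.size < 2 or b_idx.size < 2:
        raise ValueError("each group needs at least 2 samples")
    a = mc.clr[a_idx]  # (n_a, F, M)
    b = mc.clr[b_idx]
    res = sps.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    pvals = res.pvalue  # (F, M)
    n_f, n_mc = pvals.shape
    adj = np.empty_like(pvals)
    for m in range(n_mc):
        adj[:, m] = stats.benjamini_hochberg(pvals[:, m])
    ebh = adj.mean(axis=1)

    med_a = np.median(a, axis=0)  # (F, M)
    med_b = np.median(b, axis=0)
    mad_a = np.median(np.abs(a - med_a[None]), axis=0)
    mad_b = np.median(np.abs(b - med_b[None]), axis=0)
    sigma = np.maximum(np.maximum(mad_a, mad_b), 1e-8)
    effect = np.median((med_a - med_b) / sigma, axis=1)
    return pd.DataFrame({"feature": mc.feature_ids, "effect": effect,
                         "eBH": ebh}).set_index("feature")


def call_differential(precursor: pd.DataFrame, p_thresh=P_THRESH,
                      effect_thresh=EFFECT_THRESH) -> pd.DataFrame:
    """Attach up/down/none calls at the eBH and effect thresholds."""
    if p_thresh <= 0 or effect_thresh <= 0:
        raise ValueError("thresholds must be positive")
    out = precursor.copy()
    sig = out["eBH"] < p_thresh
    out["call"] = np.where(sig & (out["effect"] > effect_thresh), "up",
                           np.where(sig & (out["effect"] < -effect_thresh),
                                    "down", "none"))
    return out


def differential_abundance(table: FeatureTable, groups, taxonomy=None,
                           rank=None, n_mc=128, prior=0.5, seed=0,
                           p_thresh=P_THRESH, effect_thresh=EFFECT_THRESH) -> pd.DataFrame:
    """One-call pipeline: optional rank aggregation, MC clr, test, calls."""
    if rank is not None:
        if taxonomy is None:
            raise ValueError("rank aggregation needs a taxonomy")
        table = aggregate_rank(table, taxonomy, rank)
    mc = dirichlet_clr_instances(table, n_mc=n_mc, prior=prior, seed=seed)
    pre = aldex_like_test(mc, groups)
    return call_differential(pre, p_thresh=p_thresh, effect_thresh=effect_thresh)
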