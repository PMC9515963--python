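"""Preranked gene-set enrichment over KO effect sizes.

KOs are ranked by effect size in descending order; for each pathway a
weighted Kolmogorov-Smirnov-like running sum gives the enrichment score
(ES), a gene-label permutation null gives a one-sided p-value, and NES
normalizes the ES by the mean magnitude of same-sign null scores.
Pathways are significant at BH-adjusted p < 0.05.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .bundle_io import GeneSetCatalog
from . import stats

BH_ALPHA = 0.05


@dataclasses.dataclass
class RankedList:
    """Ordered (id, score) pairs, scores descending; ties broken by id."""

    ids: list
    scores: np.ndarray

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked list ids must be unique")
        self.scores = np.asarray(self.scores, dtype=float)
        order = sorted(range(len(self.ids)),
                       key=lambda i: (-self.scores[i], self.ids[i]))
        self.ids = [self.ids[i] for i in order]
        self.scores = self.scores[order]

    @classmethod
    def from_effects(cls, effects: pd.Series) -> "RankedList":
        return cls(list(effects.index), effects.to_numpy(dtype=float))


def gsea_es(ranked: RankedList, members, weight=1.0) -> float:
    """Enrichment score: signed maximum deviation of the running sum.

    Hits advance by ``|score|^weight`` (normalized over hits), misses
    retreat by ``1/(N - N_hits)``.
    """
    member_mask = np.array([i in members for i in ranked.ids])
    n_hit = int(member_mask.sum())
    n = member_mask.size
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    return _es_from_mask(ranked.scores, member_mask, weight)


def _es_from_mask(scores: np.ndarray, member_mask: np.ndarray, weight: float) -> float:
    w = np.abs(scores) ** weight
    hit_w = np.where(member_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member scores exactly zero: fall back to equal steps
        hit_w = member_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~member_mask) / (member_mask.size - member_mask.sum())
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_prerank(ranked: RankedList, catalog: GeneSetCatalog, n_perm=1000,
                 seed=0, min_size=3, weight=1.0) -> pd.DataFrame:
    """Preranked GSEA over a pathway catalog with a gene-label permutation null.

    For each retained pathway (``min_size <= |set ∩ list| <= N-1``) the null
    is the ES of random same-size KO sets; p is the one-sided tail on the
    observed ES's sign with +1 smoothing; NES divides by the mean |null ES|
    of that sign; BH is applied across retained pathways.
    """
    id_index = {ko: i for i, ko in enumerate(ranked.ids)}
    n = len(ranked.ids)
    retained = []
    for pid in catalog.pathway_ids:
        k = len(catalog.sets[pid] & id_index.keys())
        if min_size <= k <= n - 1:
            retained.append((pid, k))
    if not retained:
        raise ValueError("no pathway passes the size filter")

    rng = np.random.default_rng(seed)
    sizes = sorted({k for _, k in retained})
    null_by_size = {}
    for k in sizes:
        null = np.empty(n_perm)
        for j in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            null[j] = _es_from_mask(ranked.scores, mask, weight)
        null_by_size[k] = null

    rows = []
    for pid, k in retained:
        mask = np.zeros(n, dtype=bool)
        mask[[id_index[ko] for ko in catalog.sets[pid] if ko in id_index]] = True
        es = _es_from_mask(ranked.scores, mask, weight)
        null = null_by_size[k]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if es >= 0:
            p = (1 + (same_sign >= es).sum()) / (1 + same_sign.size)
        else:
            p = (1 + (same_sign <= es).sum()) / (1 + same_sign.size)
        mean_mag = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / mean_mag if same_sign.size and mean_mag > 0 else np.nan
        rows.append({"pathway": pid, "size": k, "ES": es, "NES": nes, "p": p})
    out = pd.DataFrame(rows).set_index("pathway")
    out["fdr"] = stats.benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["fdr"] < BH_ALPHA
    return out
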