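"""Alpha and beta diversity.

Alpha: observed richness, Shannon entropy (log base 2) and Faith's
phylogenetic diversity, computable at ASV, KO or pathway level (Faith's
PD only where a tree exists, i.e. ASVs).  Beta: unweighted and weighted
(non-normalized) UniFrac, principal-coordinate analysis, and PERMANOVA
with a permutation p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
from skbio import DistanceMatrix

from .bundle_io import FeatureTable, PhyloTree
from . import stats

ALPHA_METRICS = ("observed", "shannon", "faiths_pd")


def _observed(row: np.ndarray) -> int:
    return int((row > 0).sum())


def _shannon(row: np.ndarray) -> float:
    p = row[row > 0]
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


def faiths_pd(present_features, tree: PhyloTree) -> float:
    """Total branch length of the union of root-to-tip paths of the
    observed features."""
    present = set(present_features)
    tip_missing = present - set(tree.tip_names)
    if tip_missing:
        raise ValueError(f"features absent from tree: {sorted(tip_missing)[:5]}")
    total = 0.0
    observed = {}
    for node in tree.tree.postorder():
        if node.is_tip():
            obs = node.name in present
        else:
            obs = any(observed[id(c)] for c in node.children)
        observed[id(node)] = obs
        if obs and not node.is_root():
            total += node.length
    return total


def alpha_diversity(table: FeatureTable, metric: str, tree: PhyloTree = None,
                    level="ASV") -> pd.DataFrame:
    """Per-sample alpha diversity as a tidy frame (sample, level, metric, value)."""
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "faiths_pd":
        if tree is None:
            raise ValueError("faiths_pd requires a tree")
        if level != "ASV":
            raise ValueError("faiths_pd is defined only at the ASV level")
    vals = table.values
    if (vals.sum(axis=1) <= 0).any():
        bad = table.sample_ids[int(np.argmax(vals.sum(axis=1) <= 0))]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    feats = np.array(table.feature_ids)
    out = []
    for i, sid in enumerate(table.sample_ids):
        row = vals[i]
        if metric == "observed":
            v = _observed(row)
        elif metric == "shannon":
            v = _shannon(row)
        else:
            v = faiths_pd(feats[row > 0], tree)
        out.append((sid, level, metric, v))
    return pd.DataFrame(out, columns=["sample", "level", "metric", "value"])


def _branch_incidence(tree: PhyloTree, feature_ids):
    """(tips x branches) 0/1 incidence matrix and branch lengths.

    One column per non-root node; entry 1 when the tip descends through
    that node's branch.
    """
    tip_index = {f: i for i, f in enumerate(feature_ids)}
    nodes = [n for n in tree.tree.postorder() if not n.is_root()]
    lengths = np.array([n.length for n in nodes])
    inc = np.zeros((len(feature_ids), len(nodes)), dtype=float)
    below = {}
    for j, node in enumerate(nodes):
        if node.is_tip():
            tips = [tip_index[node.name]] if node.name in tip_index else []
        else:
            tips = [i for c in node.children for i in below[id(c)]]
        below[id(node)] = tips
        inc[tips, j] = 1.0
    return inc, lengths


def unifrac(table: FeatureTable, tree: PhyloTree, weighted=False,
            normalized=False) -> DistanceMatrix:
    """UniFrac distance matrix between all sample pairs.

    Unweighted: fraction of observed branch length unique to one sample of
    the pair.  Weighted: sum over branches of branch length times the
    absolute difference in descendant abundance proportions (classic
    non-normalized form unless ``normalized=True``, which divides by the
    branch-length-weighted sum of the two proportions).

    Computed by a single post-order accumulation of per-branch descendant
    abundance per sample.
    """
    rel = table.relabund()
    missing = set(np.array(rel.feature_ids)[(rel.values > 0).any(axis=0)]) \
        - set(tree.tip_names)
    if missing:
        raise ValueError(f"features absent from tree: {sorted(missing)[:5]}")
    inc, lengths = _branch_incidence(tree, rel.feature_ids)
    p = rel.values @ inc  # (samples x branches) descendant proportions
    if weighted:
        diff = np.abs(p[:, None, :] - p[None, :, :])
        d = (diff * lengths).sum(axis=2)
        if normalized:
            tot = ((p[:, None, :] + p[None, :, :]) * lengths).sum(axis=2)
            with np.errstate(invalid="ignore"):
                d = np.where(tot > 0, d / np.where(tot > 0, tot, 1.0), 0.0)
    else:
        a = (p > 0).astype(float)
        shared = (a * lengths) @ a.T           # sum of lengths observed in both
        observed = np.diag(shared)
        union = observed[:, None] + observed[None, :] - shared
        with np.errstate(invalid="ignore"):
            d = np.where(union > 0, 1.0 - shared / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float jitter
    return DistanceMatrix(d, ids=rel.sample_ids)


def pcoa(dist: DistanceMatrix):
    """Principal-coordinate analysis of a distance matrix.

    Eigendecomposition of the double-centered ``-d^2/2`` matrix; axes with
    positive eigenvalues are kept, ordered by eigenvalue, and the summed
    magnitude of any negative eigenvalues is reported.
    """
    d = dist.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("pcoa requires at least 3 samples")
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = scipy.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    coords = pd.DataFrame(
        coords, index=list(dist.ids),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    negative_magnitude = float(-eigvals[eigvals < 0].sum())
    return coords, prop, negative_magnitude


def _permanova_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(dist: DistanceMatrix, groups, n_perm=999, seed=0) -> stats.TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from within/between sums of squared distances;
    p = (number of permuted F >= observed + 1) / (n_perm + 1).
    """
    groups = pd.Series(groups)
    if not groups.index.equals(pd.RangeIndex(len(groups))):
        groups = groups.reindex(list(dist.ids))
    codes, uniques = pd.factorize(np.asarray(groups))
    k = len(uniques)
    if k < 2 or (np.bincount(codes) < 2).any():
        raise ValueError("permanova needs >= 2 groups with >= 2 samples each")
    d2 = dist.data ** 2
    f_obs = _permanova_f(d2, codes, k)
    if not np.isfinite(f_obs):
        return stats.TestResult(np.inf, 1.0 / (n_perm + 1), "permanova", degenerate=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _permanova_f(d2, rng.permutation(codes), k) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return stats.TestResult(float(f_obs), p, "permanova")


def compare_alpha(records: pd.DataFrame, groups: pd.Series,
                  stoma_level="stoma", other_level="non_stoma") -> pd.DataFrame:
    """Group comparison of alpha indices (one row per level/metric pair).

    Mann-Whitney U plus Cohen's d per index; BH correction across all the
    indices compared together (the seven-index family).
    """
    rows = []
    for (level, metric), sub in records.groupby(["level", "metric"]):
        sub = sub.set_index("sample")
        g = groups.reindex(sub.index)
        a = sub.loc[g == stoma_level, "value"].to_numpy(dtype=float)
        b = sub.loc[g == other_level, "value"].to_numpy(dtype=float)
        d = stats.cohens_d(a, b)
        res = stats.mann_whitney_u(a, b) if np.isfinite(d) else \
            stats.TestResult(np.nan, 1.0, "mann_whitney", degenerate=True)
        rows.append({"level": level, "metric": metric, "d": d, "p": res.p_value})
    out = pd.DataFrame(rows)
    out["fdr"] = stats.benjamini_hochberg(out["p"].to_numpy())
    return out
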