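"""Trait annotation and compositional comparison of trait categories.

Each feature is annotated with Gram stainability (GramPos / GramNeg /
Various / Unknown) and oxygen requirement (Anaerobe / NonAnaerobe /
Various / Unknown) by walking its lineage through a trait database in a
fixed rank order and adopting the first hit.  Per-sample category
proportions are then clr-transformed and compared between groups with
Mann-Whitney U, Cohen's d and Benjamini-Hochberg correction within each
trait axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .bundle_io import FeatureTable, TaxonomyMap, TraitDB, GRAM_LEVELS, OXYGEN_LEVELS
from . import stats

# rank walk order: species first, then genus, order, class, phylum
# ("family" deliberately absent from the default; insert_family adds it)
DEFAULT_RANK_ORDER = ("species", "genus", "order", "class", "phylum")

AXES = {"gram": GRAM_LEVELS, "oxygen": OXYGEN_LEVELS}


@dataclasses.dataclass
class TraitAssignment:
    """Per-feature gram/oxygen categories plus the rank that decided each."""

    data: pd.DataFrame  # index: feature id; columns: gram, oxygen, gram_rank, oxygen_rank

    def category(self, axis: str) -> pd.Series:
        return self.data[axis]


def annotate_traits(taxonomy: TaxonomyMap, db: TraitDB,
                    rank_order=DEFAULT_RANK_ORDER,
                    insert_family=False) -> TraitAssignment:
    """Propagate trait-database annotations down the taxonomy.

    For each feature the ranks in ``rank_order`` are tried in turn; the
    first rank whose taxon name has a database record decides the
    annotation (a database value of ``Various`` is adopted as ``Various``).
    Features with no hit at any rank are ``Unknown``.
    """
    order = list(rank_order)
    if insert_family and "family" not in order:
        order.insert(order.index("genus") + 1, "family")
    rows = {}
    for fid, lineage in taxonomy.data.iterrows():
        gram, oxygen = "Unknown", "Unknown"
        gram_rank, oxygen_rank = "none", "none"
        for rank in order:
            hit = db.get(rank, lineage[rank])
            if hit is not None:
                gram, oxygen = hit
                gram_rank = oxygen_rank = rank
                break
        rows[fid] = (gram, oxygen, gram_rank, oxygen_rank)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["gram", "oxygen", "gram_rank", "oxygen_rank"]
    )
    return TraitAssignment(df)


def category_composition(table: FeatureTable, traits: TraitAssignment,
                         axis: str) -> pd.DataFrame:
    """Per-sample proportions of the four categories of one trait axis.

    Rows sum to one because the categories (including Various and Unknown)
    partition the features.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {sorted(AXES)}")
    rel = table.relabund()
    cats = traits.category(axis).reindex(rel.feature_ids)
    if cats.isna().any():
        missing = cats.index[cats.isna()][0]
        raise ValueError(f"feature {missing!r} lacks a trait assignment")
    out = pd.DataFrame(0.0, index=rel.sample_ids, columns=list(AXES[axis]))
    grouped = rel.data.T.groupby(cats).sum().T  # samples x present categories
    for c in grouped.columns:
        out[c] = grouped[c]
    return out


def clr_transform(composition: pd.DataFrame, delta=None) -> pd.DataFrame:
    """Centered log-ratio transform with multiplicative zero replacement.

    Zeros are replaced by ``delta`` (default: 65% of the smallest nonzero
    proportion in the matrix) and rows are renormalized before taking
    logs.  Each output row sums to zero.
    """
    x = composition.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("proportions must be non-negative")
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("all-zero composition row")
    if (x == 0).any():
        if delta is None:
            delta = 0.65 * x[x > 0].min()
        x = np.where(x == 0, delta, x)
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=composition.index, columns=composition.columns)


def compare_categories(clr_values: pd.DataFrame, groups: pd.Series,
                       stoma_level="stoma", other_level="non_stoma") -> pd.DataFrame:
    """Between-group comparison of clr-transformed category abundances.

    For each category: Cohen's d (stoma minus non-stoma), Mann-Whitney U
    p-value, and BH-adjusted p across the categories of the axis.
    """
    groups = groups.reindex(clr_values.index)
    a_idx = groups == stoma_level
    b_idx = groups == other_level
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for cat in clr_values.columns:
        a = clr_values.loc[a_idx, cat].to_numpy()
        b = clr_values.loc[b_idx, cat].to_numpy()
        d = stats.cohens_d(a, b)
        degenerate = not np.isfinite(d)
        if degenerate:
            res = stats.TestResult(np.nan, 1.0, "mann_whitney", degenerate=True)
        else:
            res = stats.mann_whitney_u(a, b)
        rows.append({"category": cat, "d": d, "p": res.p_value,
                     "degenerate": degenerate or res.degenerate})
    out = pd.DataFrame(rows).set_index("category")
    out["fdr"] = stats.benjamini_hochberg(out["p"].to_numpy())
    return out
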