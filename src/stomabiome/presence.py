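"""Presence-class attribution: Common/Uncommon/Rare features, per-feature
presence/absence Fisher tests, and the diversity-attribution summary.

A feature present in more than 99% of samples (both groups pooled) is
"Common", in fewer than 1% "Rare", otherwise "Uncommon"; fractions of
exactly 0.01 or 0.99 fall in "Uncommon".  Uncommon features are the
candidates driving group differences in diversity, and the attribution
summary checks whether the sign of their median differential-abundance
effect agrees with the sign of the group difference in the corresponding
diversity index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bundle_io import FeatureTable
from . import stats

CLASSES = ("Common", "Uncommon", "Rare")


def classify_presence(table: FeatureTable) -> pd.DataFrame:
    """Per-feature presence fraction (over all samples) and class."""
    present = table.values > 0
    frac = present.mean(axis=0)
    cls = np.where(frac > 0.99, "Common", np.where(frac < 0.01, "Rare", "Uncommon"))
    return pd.DataFrame({"fraction": frac, "class": cls},
                        index=table.feature_ids)


def fisher_presence(table: FeatureTable, groups, stoma_level="stoma",
                    other_level="non_stoma") -> pd.DataFrame:
    """Per-feature 2x2 Fisher test of presence/absence by group."""
    groups = pd.Series(groups).reindex(table.sample_ids)
    a_idx = (groups == stoma_level).to_numpy()
    b_idx = (groups == other_level).to_numpy()
    present = table.values > 0
    rows = {}
    for j, fid in enumerate(table.feature_ids):
        t = [[int(present[a_idx, j].sum()), int((~present[a_idx, j]).sum())],
             [int(present[b_idx, j].sum()), int((~present[b_idx, j]).sum())]]
        rows[fid] = stats.fisher_exact_2x2(t).p_value
    return pd.DataFrame({"fisher_p": rows})


def attribution_summary(classes: pd.DataFrame, effects: pd.DataFrame,
                        fisher: pd.DataFrame, alpha_direction: float,
                        level="genus") -> pd.DataFrame:
    """Per-class summary linking presence classes to the diversity contrast.

    For each class: feature count, count with Fisher p < 0.05, median
    differential-abundance effect, and (for Uncommon) whether the sign of
    the median effect agrees with the sign of the group difference in the
    matching diversity index (``alpha_direction``).
    """
    merged = classes.join(effects, how="inner").join(fisher, how="left")
    rows = []
    for cls in CLASSES:
        sub = merged[merged["class"] == cls]
        med = float(np.median(sub["effect"])) if len(sub) else np.nan
        if cls == "Uncommon" and len(sub) and med != 0 and alpha_direction != 0:
            agree = bool(np.sign(med) == np.sign(alpha_direction))
        else:
            agree = None  # indeterminate
        rows.append({
            "level": level, "class": cls, "n": len(sub),
            "n_fisher_sig": int((sub["fisher_p"] < 0.05).sum()) if len(sub) else 0,
            "median_effect": med,
            "agrees_with_diversity": agree,
        })
    return pd.DataFrame(rows)
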