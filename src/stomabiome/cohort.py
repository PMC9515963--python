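"""Consort-style sample exclusion, rarefaction and baseline-metadata summary.

The study design removes antibiotic users and samples with missing stoma
status before analysis, rarefies every remaining sample to a common read
depth, and summarises the clinical variables per group.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd

from .bundle_io import FeatureTable, SampleMetadata
from . import stats


@dataclasses.dataclass
class ConsortReport:
    enrolled: int
    steps: list  # (label, n_excluded) in application order
    analyzed: int
    group_sizes: dict
    empty_result: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [("enrolled", self.enrolled)]
        rows += [(f"excluded: {lab}", n) for lab, n in self.steps]
        rows.append(("analyzed", self.analyzed))
        rows += [(f"group: {g}", n) for g, n in self.group_sizes.items()]
        return pd.DataFrame(rows, columns=["step", "n"])


def apply_exclusions(metadata: SampleMetadata, criteria, group_column="stoma_status"):
    """Apply ordered exclusion filters and tally a consort report.

    ``criteria`` is a sequence of ``(column, value)`` pairs; a sample whose
    column equals the value is excluded.  A sample matched by an earlier
    filter is not recounted by a later one.
    """
    df = metadata.data
    kept = list(df.index)
    steps = []
    for col, value in criteria:
        if col not in df.columns:
            raise KeyError(f"exclusion column {col!r} not in metadata")
        hit = [s for s in kept if str(df.loc[s, col]) == str(value)]
        kept = [s for s in kept if s not in set(hit)]
        steps.append((f"{col}={value}", len(hit)))
    groups = {}
    if group_column in df.columns:
        counts = df.loc[kept, group_column].value_counts()
        groups = {k: int(v) for k, v in counts.items()}
    report = ConsortReport(
        enrolled=len(df), steps=steps, analyzed=len(kept),
        group_sizes=groups, empty_result=len(kept) == 0,
    )
    return kept, report


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # seed derived from (master seed, stable hash of sample id): rarefaction
    # of a sample does not depend on the order samples appear in the table
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(sample_id).encode())])
    )


def rarefy(table: FeatureTable, depth=None, seed=0):
    """Subsample each sample without replacement to a common read depth.

    ``depth=None`` uses the minimum sample total (so no sample is dropped),
    mirroring the usual rarefy-to-minimum rule.  Samples with fewer reads
    than ``depth`` are dropped and returned in the second element.
    """
    if table.kind != "counts":
        raise ValueError("rarefy operates on count tables")
    counts = np.round(table.values).astype(np.int64)
    totals = counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    kept_rows, dropped = [], []
    out = []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sid)
            continue
        if totals[i] == depth:
            out.append(counts[i])
        else:
            rng = _sample_rng(seed, sid)
            out.append(rng.multivariate_hypergeometric(counts[i], depth))
        kept_rows.append(sid)
    rarefied = FeatureTable(
        pd.DataFrame(np.array(out, dtype=np.int64), index=kept_rows,
                     columns=table.feature_ids),
        kind="counts",
    )
    return rarefied, dropped


def format_count_percent(count: int, denominator: int) -> str:
    """"9 (43%)"-style cell: percent over the non-missing denominator,
    rounded to the nearest integer."""
    pct = 0 if denominator == 0 else round(100.0 * count / denominator)
    return f"{count} ({pct:.0f}%)"


def compare_metadata(metadata: SampleMetadata, group_column: str,
                     missing_token="missing") -> pd.DataFrame:
    """Baseline table: per-variable summaries and between-group tests.

    Numeric variables get mean (SD) and Welch's t; two-level categorical
    variables get n (%) and Fisher's exact test; other categorical
    variables get Pearson's chi-squared.  Percentages use non-missing
    denominators; missing counts are reported separately.
    """
    df = metadata.data
    if group_column not in df.columns:
        raise KeyError(f"grouping column {group_column!r} not in metadata")
    gvals = df[group_column].astype(str)
    levels = sorted(set(gvals) - {missing_token})
    if len(levels) != 2:
        raise ValueError(f"grouping column must have exactly 2 non-missing levels, got {levels}")
    in_g = {g: gvals == g for g in levels}

    rows = []
    for col in df.columns:
        if col == group_column:
            continue
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        str_vals = series.astype(str)
        is_missing = str_vals.isin([missing_token, "nan", ""]) | series.isna()
        if numeric.notna()[~is_missing].all() and numeric.nunique() > 2:
            cells, vecs = {}, {}
            for g in levels:
                x = numeric[in_g[g] & ~is_missing].to_numpy(dtype=float)
                vecs[g] = x
                cells[g] = f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})" if x.size else "-"
            res = stats.welch_t(vecs[levels[0]], vecs[levels[1]]) \
                if all(v.size >= 2 for v in vecs.values()) \
                else stats.TestResult(np.nan, 1.0, "welch_t", degenerate=True)
            rows.append({"variable": col, "level": "", **cells,
                         "missing": int(is_missing.sum()),
                         "test": res.method, "p": res.p_value,
                         "degenerate": res.degenerate})
        else:
            cats = sorted(set(str_vals[~is_missing]))
            contingency = np.array(
                [[int(((str_vals == c) & in_g[g] & ~is_missing).sum()) for g in levels]
                 for c in cats]
            )
            if len(cats) == 2:
                res = stats.fisher_exact_2x2(contingency)
            elif len(cats) < 2:
                res = stats.TestResult(np.nan, 1.0, "chi_square", degenerate=True)
            else:
                res = stats.chi_square(contingency)
            denom = contingency.sum(axis=0)
            for ci, c in enumerate(cats):
                cells = {g: format_count_percent(int(contingency[ci, gi]), int(denom[gi]))
                         for gi, g in enumerate(levels)}
                rows.append({"variable": col, "level": c, **cells,
                             "missing": int(is_missing.sum()),
                             "test": res.method,
                             "p": res.p_value if ci == 0 else np.nan,
                             "degenerate": res.degenerate})
    return pd.DataFrame(rows)
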