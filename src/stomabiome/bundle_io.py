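"""Domain types, readers/writers and cross-validation for the input bundle.

The pipeline consumes a bundle of seven artifacts: a sample-by-feature
count (or relative-abundance) table, a seven-rank taxonomy, a rooted
phylogeny, sample metadata, a trait database (Gram stain and oxygen
requirement by rank and taxon name), a per-feature KO gene-copy table and
a pathway-to-KO catalog.  Everything on disk is plain text: TSV for
tables, Newick for the tree, GMT for the catalog.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

GRAM_LEVELS = ("GramPos", "GramNeg", "Various", "Unknown")
OXYGEN_LEVELS = ("Anaerobe", "NonAnaerobe", "Various", "Unknown")


class BundleError(ValueError):
    """Raised when an input file violates a structural invariant."""


def _check_unique(ids, what, source=""):
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for x in ids:
            if x in seen:
                dup = x
                break
            seen.add(x)
        raise BundleError(f"duplicate {what} {dup!r}{' in ' + source if source else ''}")


@dataclasses.dataclass
class FeatureTable:
    """Sample-by-feature matrix of counts or relative abundances.

    ``data`` is a pandas DataFrame with samples as rows and features as
    columns; ``kind`` is ``"counts"`` or ``"relabund"``.  Relative-abundance
    tables must have rows summing to one.
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self):
        if self.kind not in ("counts", "relabund"):
            raise BundleError(f"unknown table kind {self.kind!r}")
        _check_unique(self.data.index, "sample id")
        _check_unique(self.data.columns, "feature id")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise BundleError(
                f"non-finite value at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise BundleError(
                f"negative value {vals[r, c]} at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.kind == "relabund":
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                i = int(np.argmax(bad))
                raise BundleError(
                    f"relative-abundance row for sample {self.data.index[i]!r} "
                    f"sums to {sums[i]}, expected 1"
                )

    @property
    def sample_ids(self):
        return list(self.data.index)

    @property
    def feature_ids(self):
        return list(self.data.columns)

    @property
    def values(self):
        return self.data.to_numpy(dtype=float)

    def relabund(self) -> "FeatureTable":
        """Close each sample row to unit sum (no-op on relabund tables)."""
        if self.kind == "relabund":
            return self
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0][0]
            raise BundleError(f"sample {bad!r} has zero total; cannot normalize")
        return FeatureTable(self.data.div(sums, axis=0), kind="relabund")


@dataclasses.dataclass
class TaxonomyMap:
    """feature id -> seven-rank lineage (empty strings for unassigned ranks)."""

    data: pd.DataFrame  # index: feature id; columns: RANKS

    def __post_init__(self):
        _check_unique(self.data.index, "feature id", "taxonomy")
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise BundleError(f"taxonomy missing rank columns {missing}")
        self.data = self.data.loc[:, list(RANKS)].fillna("").astype(str)

    def lineage(self, feature_id: str) -> dict:
        return self.data.loc[feature_id].to_dict()


@dataclasses.dataclass
class PhyloTree:
    """Rooted phylogeny whose tips are feature ids; wraps ``skbio.TreeNode``."""

    tree: TreeNode

    def __post_init__(self):
        tips = [t.name for t in self.tree.tips()]
        _check_unique(tips, "tip label", "tree")
        for node in self.tree.traverse(include_self=True):
            if node.is_root():
                if node.length is None:
                    node.length = 0.0
                continue
            if node.length is None or not np.isfinite(node.length) or node.length < 0:
                raise BundleError(
                    f"branch above {node.name or '<internal>'} has invalid "
                    f"length {node.length!r}"
                )

    @property
    def tip_names(self):
        return [t.name for t in self.tree.tips()]

    def total_length(self) -> float:
        return sum(n.length for n in self.tree.traverse(include_self=True) if not n.is_root())


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample clinical/technical variables; ``stoma_status`` and
    ``antibiotic_user`` are constrained enumerations, other columns free."""

    data: pd.DataFrame  # index: sample id

    STATUS = ("stoma", "non_stoma", "missing")
    YESNO = ("yes", "no", "missing")

    def __post_init__(self):
        _check_unique(self.data.index, "sample id", "metadata")
        for col, levels in (("stoma_status", self.STATUS), ("antibiotic_user", self.YESNO)):
            if col in self.data.columns:
                vals = self.data[col].fillna("missing").astype(str)
                bad = set(vals) - set(levels)
                if bad:
                    raise BundleError(f"metadata column {col!r} has invalid values {sorted(bad)}")
                self.data[col] = vals

    @property
    def sample_ids(self):
        return list(self.data.index)


@dataclasses.dataclass
class TraitDB:
    """(rank, taxon name) -> Gram stainability and oxygen requirement."""

    data: pd.DataFrame  # columns: rank, name, gram, oxygen

    def __post_init__(self):
        need = {"rank", "name", "gram", "oxygen"}
        if not need <= set(self.data.columns):
            raise BundleError(f"trait DB needs columns {sorted(need)}")
        bad_rank = set(self.data["rank"]) - set(RANKS)
        if bad_rank:
            raise BundleError(f"trait DB has unknown ranks {sorted(bad_rank)}")
        keys = list(zip(self.data["rank"], self.data["name"]))
        _check_unique(keys, "(rank, name) key", "trait DB")
        for col, levels in (("gram", GRAM_LEVELS[:3]), ("oxygen", OXYGEN_LEVELS[:3])):
            bad = set(self.data[col]) - set(levels)
            if bad:
                raise BundleError(f"trait DB column {col!r} has invalid values {sorted(bad)}")
        self._lookup = {
            (r, n): (g, o)
            for r, n, g, o in zip(
                self.data["rank"], self.data["name"], self.data["gram"], self.data["oxygen"]
            )
        }

    def get(self, rank: str, name: str):
        """Return (gram, oxygen) or None when the taxon is absent."""
        if not name:
            return None
        return self._lookup.get((rank, name))


@dataclasses.dataclass
class KoCopyTable:
    """Predicted gene (KO) copy numbers per feature: features x KOs."""

    data: pd.DataFrame  # index: feature id; columns: KO ids

    def __post_init__(self):
        _check_unique(self.data.index, "feature id", "KO copy table")
        _check_unique(self.data.columns, "KO id", "KO copy table")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            bad = np.argwhere(~(np.isfinite(vals) & (vals >= 0)))[0]
            raise BundleError(
                f"invalid copy number at feature {self.data.index[bad[0]]!r}, "
                f"KO {self.data.columns[bad[1]]!r}"
            )

    @property
    def ko_ids(self):
        return list(self.data.columns)


@dataclasses.dataclass
class GeneSetCatalog:
    """pathway id -> non-empty set of member KO ids, plus display names."""

    sets: dict
    names: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        for pid, members in self.sets.items():
            if not members:
                raise BundleError(f"pathway {pid!r} has an empty KO set")
            self.sets[pid] = set(members)

    @property
    def pathway_ids(self):
        return list(self.sets)


@dataclasses.dataclass
class Bundle:
    table: FeatureTable
    taxonomy: TaxonomyMap
    tree: PhyloTree
    metadata: SampleMetadata
    traits: TraitDB
    ko_copies: KoCopyTable
    catalog: GeneSetCatalog


# ---------------------------------------------------------------------------
# taxonomy string handling (SILVA-style "d__X; p__Y; ...")

_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


def parse_lineage(s: str) -> dict:
    """Parse a SILVA-style lineage string into a rank->name dict.

    Prefixes (``d__`` etc.) are stripped; empty or bare ``__`` entries
    become empty strings; missing trailing ranks are empty.
    """
    out = dict.fromkeys(RANKS, "")
    if not s or not s.strip():
        return out
    parts = [p.strip() for p in s.split(";")]
    for rank, part in zip(RANKS, parts):
        for pref in _PREFIXES:
            if part.startswith(pref):
                part = part[len(pref):]
                break
        out[rank] = "" if part == "__" else part
    return out


def format_lineage(lineage: dict) -> str:
    return "; ".join(f"{p}{lineage.get(r, '')}" for p, r in zip(_PREFIXES, RANKS))


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)


def read_feature_table(path, kind="counts", orientation="samples_as_rows") -> FeatureTable:
    df = _read_tsv(path).astype(float)
    if orientation == "features_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise BundleError(f"unknown orientation {orientation!r}")
    try:
        return FeatureTable(df, kind=kind)
    except BundleError as e:
        raise BundleError(f"{path}: {e}") from None


def write_feature_table(table: FeatureTable, path):
    df = table.data
    vals = df.to_numpy(dtype=float)
    if np.allclose(vals, np.round(vals)):  # canonical integer formatting
        df = df.astype(np.int64)
    df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyMap:
    df = _read_tsv(path)
    if "lineage" in df.columns:
        parsed = pd.DataFrame([parse_lineage(s) for s in df["lineage"]], index=df.index)
        return TaxonomyMap(parsed)
    return TaxonomyMap(df)


def write_taxonomy(tax: TaxonomyMap, path):
    out = pd.DataFrame(
        {"lineage": [format_lineage(dict(row)) for _, row in tax.data.iterrows()]},
        index=tax.data.index,
    )
    out.rename_axis("feature_id").to_csv(path, sep="\t")


def read_tree(path) -> PhyloTree:
    try:
        tree = TreeNode.read(str(path))
    except Exception as e:  # skbio raises several parser error types
        raise BundleError(f"{path}: malformed Newick ({e})") from None
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path):
    buf = _io.StringIO()
    tree.tree.write(buf)
    Path(path).write_text(buf.getvalue())


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path))


def write_metadata(md: SampleMetadata, path):
    md.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_trait_db(path) -> TraitDB:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return TraitDB(df)


def write_trait_db(db: TraitDB, path):
    db.data.loc[:, ["rank", "name", "gram", "oxygen"]].to_csv(path, sep="\t", index=False)


def read_ko_copies(path) -> KoCopyTable:
    return KoCopyTable(_read_tsv(path).astype(float))


def write_ko_copies(copies: KoCopyTable, path):
    copies.data.rename_axis("feature_id").to_csv(path, sep="\t")


def read_gmt(path) -> GeneSetCatalog:
    sets, names = {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BundleError(f"{path}: GMT line with fewer than 3 fields: {line[:60]!r}")
        pid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if pid in sets:
            raise BundleError(f"{path}: duplicate pathway id {pid!r}")
        sets[pid] = set(members)
        names[pid] = desc
    return GeneSetCatalog(sets, names)


def write_gmt(catalog: GeneSetCatalog, path):
    lines = []
    for pid in catalog.pathway_ids:
        desc = catalog.names.get(pid, pid)
        lines.append("\t".join([pid, desc] + sorted(catalog.sets[pid])))
    Path(path).write_text("\n".join(lines) + "\n")


BUNDLE_FILES = {
    "table": "feature_table.tsv",
    "taxonomy": "taxonomy.tsv",
    "tree": "tree.nwk",
    "metadata": "metadata.tsv",
    "traits": "trait_db.tsv",
    "ko_copies": "ko_copies.tsv",
    "catalog": "pathways.gmt",
}


def read_bundle(directory, table_kind="counts", orientation="samples_as_rows") -> Bundle:
    """Read a full input bundle from a directory of canonical file names."""
    d = Path(directory)
    for name in BUNDLE_FILES.values():
        if not (d / name).exists():
            raise BundleError(f"missing bundle file {d / name}")
    return Bundle(
        table=read_feature_table(d / BUNDLE_FILES["table"], kind=table_kind,
                                 orientation=orientation),
        taxonomy=read_taxonomy(d / BUNDLE_FILES["taxonomy"]),
        tree=read_tree(d / BUNDLE_FILES["tree"]),
        metadata=read_metadata(d / BUNDLE_FILES["metadata"]),
        traits=read_trait_db(d / BUNDLE_FILES["traits"]),
        ko_copies=read_ko_copies(d / BUNDLE_FILES["ko_copies"]),
        catalog=read_gmt(d / BUNDLE_FILES["catalog"]),
    )


def write_bundle(bundle: Bundle, directory):
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_feature_table(bundle.table, d / BUNDLE_FILES["table"])
    write_taxonomy(bundle.taxonomy, d / BUNDLE_FILES["taxonomy"])
    write_tree(bundle.tree, d / BUNDLE_FILES["tree"])
    write_metadata(bundle.metadata, d / BUNDLE_FILES["metadata"])
    write_trait_db(bundle.traits, d / BUNDLE_FILES["traits"])
    write_ko_copies(bundle.ko_copies, d / BUNDLE_FILES["ko_copies"])
    write_gmt(bundle.catalog, d / BUNDLE_FILES["catalog"])


# ---------------------------------------------------------------------------
# cross-validation


def validate_bundle(bundle: Bundle) -> list:
    """Cross-check the bundle's components; returns findings, not exceptions.

    An empty list means the bundle is fully consistent.
    """
    findings = []
    features = set(bundle.table.feature_ids)
    tax_features = set(bundle.taxonomy.data.index)
    tips = set(bundle.tree.tip_names)
    copy_features = set(bundle.ko_copies.data.index)
    meta_samples = set(bundle.metadata.sample_ids)
    copy_kos = set(bundle.ko_copies.ko_ids)

    for f in sorted(features - tax_features):
        findings.append(("missing taxonomy", f))
    for f in sorted(features - tips):
        findings.append(("missing from tree", f))
    for f in sorted(features - copy_features):
        findings.append(("missing KO copies", f))
    for s in sorted(set(bundle.table.sample_ids) - meta_samples):
        findings.append(("missing metadata", s))
    for pid in bundle.catalog.pathway_ids:
        for ko in sorted(bundle.catalog.sets[pid] - copy_kos):
            findings.append(("orphan KO", f"{pid}:{ko}"))
    return findings
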