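"""Synthetic fecal-community generator.

Builds complete input bundles — phylogeny, taxonomy, trait database,
per-feature KO copy numbers, pathway catalog, count table and sample
metadata — with the statistical structure the downstream analysis
assumes: an anaerobe-enriched bacterial clade, an archaeal methanogen
clade confined to the non-stoma group, and an aerobe "invader" clade
carrying exclusive degradation genes that expands in the stoma group.
Counts are Dirichlet-multinomial draws at variable sequencing depth, and
the metadata plants antibiotic-user and missing-status samples so the
consort filtering is exercised end to end.

The default configuration mirrors the study's shape: 21 stoma and 98
non-stoma patients analyzed out of 220 enrolled (79 antibiotic users and
22 samples without stoma information excluded), read depths on the order
of 42,000, and roughly 150 bacterial genera.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skbio import TreeNode

from .bundle_io import (
    Bundle, FeatureTable, GeneSetCatalog, KoCopyTable, PhyloTree, RANKS,
    SampleMetadata, TaxonomyMap, TraitDB,
)
from .traits import TraitAssignment


@dataclasses.dataclass
class SimConfig:
    """Generative parameters; the defaults are the study-shaped preset."""

    n_taxa: int = 150              # bacterial ASVs in the main clade
    anaerobe_fraction: float = 0.6  # fraction of main-clade taxa that are anaerobes
    n_stoma: int = 21
    n_non_stoma: int = 98
    depletion: float = 0.25        # multiplier on anaerobe abundance in the stoma group
    richness_reduction: int = 30   # main-clade taxa zeroed in the stoma group
    n_invaders: int = 8            # stoma-exclusive aerobes with degradation KOs
    n_archaea: int = 4             # non-stoma-exclusive methanogens
    depth_low: int = 42292         # sequencing depth ~ Uniform{depth_low..depth_high}
    depth_high: int = 84584
    concentration: float = 200.0   # Dirichlet precision (technical noise; biology is explicit)
    sigma_log_abundance: float = 1.2
    sigma_biological: float = 0.7  # per-sample log-normal taxon variability
    depletion_jitter: float = 0.4  # sd of the per-sample log-log depletion scatter
    invader_log_shift: float = -0.75
    archaea_log_shift: float = -0.5
    n_antibiotic_excluded: int = 79
    n_missing_stoma: int = 22
    n_housekeeping_kos: int = 400
    n_degradation_kos: int = 10
    n_methane_kos: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.depletion <= 1.0):
            raise ValueError("depletion must be in (0, 1]")
        if not (0.0 <= self.anaerobe_fraction <= 1.0):
            raise ValueError("anaerobe_fraction must be in [0, 1]")
        if self.richness_reduction > self.n_taxa:
            raise ValueError("cannot zero more taxa than exist")
        if min(self.n_taxa, self.n_stoma, self.n_non_stoma, self.n_invaders,
               self.n_archaea, self.richness_reduction) < 0:
            raise ValueError("counts must be non-negative")
        if self.depth_low < 1:
            raise ValueError("depth must be >= 1")


def paper_like() -> SimConfig:
    """The study-shaped preset (identical to the defaults)."""
    return SimConfig()


def null_config(n_per_group=15, n_taxa=40, seed=0) -> SimConfig:
    """Exchangeable groups: no depletion, no richness loss, no exclusive taxa."""
    return SimConfig(n_taxa=n_taxa, n_stoma=n_per_group, n_non_stoma=n_per_group,
                     depletion=1.0, richness_reduction=0, n_invaders=0,
                     n_archaea=0, n_antibiotic_excluded=0, n_missing_stoma=0,
                     depth_low=5000, depth_high=10000, seed=seed)


@dataclasses.dataclass
class Community:
    tree: PhyloTree
    taxonomy: TaxonomyMap
    traits_db: TraitDB
    truth: TraitAssignment
    ko_copies: KoCopyTable
    catalog: GeneSetCatalog
    anaerobes: list          # feature ids of anaerobic main-clade taxa
    invaders: list
    archaea: list
    main_taxa: list


def _coalescent(tips, rng, stem=0.2, branch_scale=0.1):
    """Random pair-merge subtree over the tip names.

    Topology follows random coalescence; every branch gets an independent
    exponential length so pendant branches carry real weight (losing a tip
    loses measurable phylogenetic diversity).
    """
    if not tips:
        return None
    nodes = [TreeNode(name=t) for t in tips]
    while len(nodes) > 1:
        k = len(nodes)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        a.length = rng.exponential(branch_scale)
        b.length = rng.exponential(branch_scale)
        parent = TreeNode(children=[a, b])
        nodes = [nodes[x] for x in range(k) if x not in (i, j)] + [parent]
    nodes[0].length = stem
    return nodes[0]


def simulate_community(config: SimConfig) -> Community:
    """Generate the static part of a bundle: tree, taxonomy, traits, KO
    copies and pathway catalog (no counts)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))

    n_ana = int(round(config.anaerobe_fraction * config.n_taxa))
    main = [f"ASV_{i:04d}" for i in range(config.n_taxa)]
    anaerobes = main[:n_ana]
    invaders = [f"INV_{i:04d}" for i in range(config.n_invaders)]
    archaea = [f"ARC_{i:04d}" for i in range(config.n_archaea)]

    clades = [c for c in (
        _coalescent(anaerobes, rng),
        _coalescent(main[n_ana:], rng),
        _coalescent(invaders, rng),
        _coalescent(archaea, rng),
    ) if c is not None]
    # join clades pairwise so the root is strictly bifurcating
    root = clades[0]
    for other in clades[1:]:
        root = TreeNode(children=[root, other], length=0.2)
    root.length = 0.0
    tree = PhyloTree(root)

    # taxonomy: one synthetic genus per 1-2 ASVs, phyla follow the clades
    phylum_of = {}
    for f in anaerobes:
        phylum_of[f] = "Obanaerobia"
    for f in main[n_ana:]:
        phylum_of[f] = "Facultativia"
    for f in invaders:
        phylum_of[f] = "Degradobia"
    for f in archaea:
        phylum_of[f] = "Methanarchia"

    all_ids = main + invaders + archaea
    tax_rows, genus_of = {}, {}
    prev_genus = None
    for idx, f in enumerate(all_ids):
        domain = "Archaea" if f in set(archaea) else "Bacteria"
        # ~15% of main-clade ASVs share the previous ASV's genus
        if (f in set(main) and prev_genus is not None
                and phylum_of.get(all_ids[idx - 1]) == phylum_of[f]
                and rng.random() < 0.15):
            genus = prev_genus
        else:
            genus = f"g_{f}"
        genus_of[f] = genus
        prev_genus = genus
        species = f"s_{f}" if rng.random() < 0.4 else ""
        tax_rows[f] = {
            "domain": domain, "phylum": phylum_of[f],
            "class": f"c_{phylum_of[f]}", "order": f"o_{genus}",
            "family": f"f_{genus}", "genus": genus, "species": species,
        }
    taxonomy = TaxonomyMap(pd.DataFrame.from_dict(tax_rows, orient="index")
                           .loc[:, list(RANKS)])

    # trait database and ground-truth assignment
    db_rows, truth_rows = [], {}
    db_keys = set()

    def add_record(rank, name, gram, oxy):
        if (rank, name) not in db_keys:
            db_keys.add((rank, name))
            db_rows.append({"rank": rank, "name": name, "gram": gram, "oxygen": oxy})

    genus_first = {}
    for f in all_ids:
        genus = genus_of[f]
        if genus in genus_first:
            # shared genus: reuse the first ASV's annotation for consistency
            truth_rows[f] = truth_rows[genus_first[genus]]
            continue
        genus_first[genus] = f
        if f in set(invaders):
            intended = ("GramNeg", "NonAnaerobe")
            add_record("genus", genus, *intended)
            rank = "genus"
        elif f in set(archaea):
            intended = ("Various", "Anaerobe")
            add_record("genus", genus, *intended)
            rank = "genus"
        else:
            oxy = "Anaerobe" if f in set(anaerobes) else "NonAnaerobe"
            gram = "GramPos" if rng.random() < 0.7 else "GramNeg"
            u = rng.random()
            if u < 0.80:  # genus-level record
                intended, rank = (gram, oxy), "genus"
                add_record("genus", genus, *intended)
            elif u < 0.87:  # only an order-level record
                intended, rank = (gram, oxy), "order"
                add_record("order", f"o_{genus}", *intended)
            elif u < 0.93:  # database could not settle on one annotation
                intended, rank = ("Various", oxy), "genus"
                add_record("genus", genus, *intended)
            else:  # absent from the database entirely
                intended, rank = ("Unknown", "Unknown"), "none"
        truth_rows[f] = (*intended, rank, rank)

    # species-level overrides on a few annotated main-clade taxa
    candidates = [f for f in main if taxonomy.data.loc[f, "species"]
                  and truth_rows[f][2] == "genus"]
    for f in candidates[:3]:
        g, o = truth_rows[f][0], truth_rows[f][1]
        flipped = "GramNeg" if g == "GramPos" else "GramPos"
        add_record("species", taxonomy.data.loc[f, "species"], flipped, o)
        truth_rows[f] = (flipped, o, "species", "species")

    traits_db = TraitDB(pd.DataFrame(db_rows))
    truth = TraitAssignment(pd.DataFrame.from_dict(
        truth_rows, orient="index",
        columns=["gram", "oxygen", "gram_rank", "oxygen_rank"]).loc[all_ids])

    # KO copy numbers: housekeeping on everyone, degradation exclusive to
    # invaders, methane exclusive to archaea
    hk = [f"K{10000 + i:05d}" for i in range(config.n_housekeeping_kos)]
    deg = [f"K{20000 + i:05d}" for i in range(config.n_degradation_kos)]
    met = [f"K{30000 + i:05d}" for i in range(config.n_methane_kos)]
    copies = pd.DataFrame(0.0, index=all_ids, columns=hk + deg + met)
    # housekeeping genes are carried by every taxon with mild copy-number
    # variation, so their community profile wobbles with composition but no
    # KO tracks the group contrast systematically
    copies.loc[:, hk] = rng.poisson(1.0, size=(len(all_ids), len(hk))) + 1.0
    if invaders:
        copies.loc[invaders, deg] = rng.poisson(1.0, size=(len(invaders), len(deg))) + 1.0
    if archaea:
        copies.loc[archaea, met] = rng.poisson(1.0, size=(len(archaea), len(met))) + 1.0
    ko_copies = KoCopyTable(copies)

    sets, names = {}, {}
    n_hk_path = 5
    for i in range(n_hk_path):
        members = hk[i::n_hk_path]
        sets[f"path_hk{i + 1}"] = set(members)
        names[f"path_hk{i + 1}"] = f"housekeeping metabolism {i + 1}"
    for i in range(3):
        sets[f"path_deg{i + 1}"] = set(deg[i::3])
        names[f"path_deg{i + 1}"] = f"xenobiotic degradation {i + 1}"
    sets["path_methane"] = set(met)
    names["path_methane"] = "methane metabolism"
    catalog = GeneSetCatalog(sets, names)

    return Community(tree=tree, taxonomy=taxonomy, traits_db=traits_db,
                     truth=truth, ko_copies=ko_copies, catalog=catalog,
                     anaerobes=anaerobes, invaders=invaders, archaea=archaea,
                     main_taxa=main)


def dirichlet_multinomial(p, concentration, depths, rng) -> np.ndarray:
    """Draw count vectors from a Dirichlet-multinomial with mean ``p``.

    Zero entries of ``p`` stay exactly zero.  ``depths`` is one depth per
    sample.
    """
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    alpha = concentration * p
    out = np.zeros((len(depths), p.size), dtype=np.int64)
    pos = alpha > 0
    for i, depth in enumerate(depths):
        g = rng.gamma(alpha[pos])
        if g.sum() == 0:  # pathological underflow; fall back to the mean
            g = p[pos]
        probs = g / g.sum()
        out[i, pos] = rng.multinomial(int(depth), probs)
    return out


def _base_profile(community: Community, config: SimConfig, rng):
    """Base taxon abundances plus the masks the group effects act on."""
    ids = community.main_taxa + community.invaders + community.archaea
    base = np.exp(rng.normal(0.0, config.sigma_log_abundance, size=len(ids)))
    n_main = len(community.main_taxa)
    n_inv = len(community.invaders)
    inv = slice(n_main, n_main + n_inv)
    arc = slice(n_main + n_inv, len(ids))
    base[inv] *= np.exp(config.invader_log_shift)
    base[arc] *= np.exp(config.archaea_log_shift)
    is_ana = np.isin(ids, community.anaerobes)
    # the taxa lost to the stoma are drawn from the rare tail: low-abundance
    # organisms are the ones that drop below detection when conditions shift
    if config.richness_reduction:
        pool = np.argsort(base[:n_main])[:min(2 * config.richness_reduction, n_main)]
        zero_idx = rng.choice(pool, size=config.richness_reduction, replace=False)
    else:
        zero_idx = np.array([], dtype=int)
    return ids, base, is_ana, zero_idx, inv, arc


def _draw_sample(base, stoma, config, is_ana, zero_idx, inv, arc, depth, rng):
    """One sample: per-person taxon variability, stoma effects with
    per-person strength, then a Dirichlet-multinomial draw."""
    p = base * np.exp(rng.normal(0.0, config.sigma_biological, size=base.size))
    # per-sample depletion strength: log-delta scattered multiplicatively,
    # so delta = 1 (the null) stays exactly 1 for every sample
    log_delta = np.log(config.depletion) * np.exp(
        rng.normal(0.0, config.depletion_jitter))
    if stoma:
        delta_s = np.exp(log_delta)
        p[is_ana] *= delta_s
        p[zero_idx] = 0.0
        p[inv] *= 1.0 / delta_s
        p[arc] = 0.0
    else:
        p[inv] = 0.0
    if p.sum() == 0:
        raise ValueError("degenerate configuration: empty sample profile")
    return dirichlet_multinomial(p, config.concentration, [depth], rng)[0]


def simulate_counts(community: Community, config: SimConfig):
    """Draw the count table and metadata for the full enrolled cohort.

    Analyzed samples come first (stoma then non-stoma), followed by the
    planted antibiotic users and the samples with missing stoma status;
    those extras are drawn from the non-stoma profile.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    ids, base, is_ana, zero_idx, inv, arc = _base_profile(community, config, rng)

    n_extra = config.n_antibiotic_excluded + config.n_missing_stoma
    n_total = config.n_stoma + config.n_non_stoma + n_extra
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    depths = rng.integers(config.depth_low, config.depth_high + 1, size=n_total)

    counts = np.array([
        _draw_sample(base, i < config.n_stoma, config, is_ana, zero_idx,
                     inv, arc, depths[i], rng)
        for i in range(n_total)
    ])
    table = FeatureTable(pd.DataFrame(counts, index=sample_ids, columns=ids),
                         kind="counts")

    n_analyzed = config.n_stoma + config.n_non_stoma
    status = (["stoma"] * config.n_stoma + ["non_stoma"] * config.n_non_stoma
              + list(rng.choice(["stoma", "non_stoma"],
                                size=config.n_antibiotic_excluded))
              + ["missing"] * config.n_missing_stoma)
    antibiotic = (["no"] * n_analyzed
                  + ["yes"] * config.n_antibiotic_excluded
                  + ["no"] * config.n_missing_stoma)
    stoma_mask = np.array(status) == "stoma"
    age = np.round(rng.normal(62, 12, size=n_total)).clip(24, 85)
    bmi = np.round(rng.normal(22.0, 3.5, size=n_total) - 0.8 * stoma_mask, 1)
    sex = rng.choice(["female", "male"], size=n_total)
    ppi = rng.choice(["user", "non_user"], size=n_total, p=[0.8, 0.2])
    bristol = np.minimum(7, np.maximum(
        1, np.round(rng.normal(4.0, 1.2, size=n_total) + 1.5 * stoma_mask))).astype(int)
    metadata = SampleMetadata(pd.DataFrame({
        "stoma_status": status, "antibiotic_user": antibiotic,
        "age": age, "bmi": bmi, "sex": sex, "ppi": ppi, "bristol": bristol,
    }, index=sample_ids))
    return table, metadata


def simulate_bundle(config: SimConfig) -> Bundle:
    """Full bundle: community plus counts and metadata, ready for the pipeline."""
    community = simulate_community(config)
    table, metadata = simulate_counts(community, config)
    return Bundle(table=table, taxonomy=community.taxonomy, tree=community.tree,
                  metadata=metadata, traits=community.traits_db,
                  ko_copies=community.ko_copies, catalog=community.catalog)
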