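"""End-to-end pipeline: cohort filtering through presence attribution.

Each stage is a pure function of (inputs, config, seed) and writes tidy
TSVs into a run directory; a JSON manifest records the seed, parameters
and SHA-256 hashes of every input and output so a run can be audited and
reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import bundle_io, cohort, dam, diversity, enrichment, functional, presence, traits
from .bundle_io import Bundle, FeatureTable

DEFAULT_EXCLUSIONS = (("antibiotic_user", "yes"), ("stoma_status", "missing"))
DAM_RANKS = ("phylum", "family", "genus")


@dataclasses.dataclass
class PipelineResult:
    consort: cohort.ConsortReport
    baseline: pd.DataFrame
    trait_tables: dict          # axis -> Table-2-shaped frame
    alpha: pd.DataFrame         # tidy per-sample records
    alpha_comparison: pd.DataFrame
    permanova: dict             # metric -> TestResult
    dam_results: dict           # level -> DAResult frame
    gsea: pd.DataFrame
    presence_tables: dict       # level -> classes+fisher frame
    attribution: pd.DataFrame


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scaled_counts(rel: FeatureTable, depth: float) -> FeatureTable:
    """Pseudo-count table for the Dirichlet machinery from a relabund table."""
    return FeatureTable(rel.data * depth, kind="counts")


def run_pipeline(bundle: Bundle, seed=0, exclusions=DEFAULT_EXCLUSIONS,
                 rarefy_depth=None, n_mc=128, n_perm=999, gsea_perm=1000,
                 out_dir=None) -> PipelineResult:
    """Run every stage on a bundle; optionally write TSVs + manifest to
    ``out_dir``."""
    rng_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                 for name, s in zip(
                     ("rarefy", "dam", "permanova", "gsea"),
                     np.random.SeedSequence(seed).spawn(4))}

    # ---- cohort -----------------------------------------------------------
    kept, consort = cohort.apply_exclusions(bundle.metadata, exclusions)
    table = FeatureTable(bundle.table.data.loc[kept], kind="counts")
    rarefied, dropped = cohort.rarefy(table, depth=rarefy_depth,
                                      seed=rng_seeds["rarefy"])
    depth = int(rarefied.values.sum(axis=1)[0]) if rarefied.data.shape[0] else 0
    groups = bundle.metadata.data.loc[rarefied.sample_ids, "stoma_status"]
    meta_kept = bundle_io.SampleMetadata(bundle.metadata.data.loc[rarefied.sample_ids])
    baseline = cohort.compare_metadata(meta_kept, "stoma_status")

    # ---- traits -----------------------------------------------------------
    assignment = traits.annotate_traits(bundle.taxonomy, bundle.traits)
    rel = rarefied.relabund()
    trait_tables = {}
    for axis in ("gram", "oxygen"):
        comp = traits.category_composition(rel, assignment, axis)
        clr = traits.clr_transform(comp)
        trait_tables[axis] = traits.compare_categories(clr, groups)

    # ---- functional projection (shared by diversity, DA, GSEA) ------------
    ko_rel = functional.project_ko(rel, bundle.ko_copies)
    path_rel, _path_raw = functional.aggregate_pathways(ko_rel, bundle.catalog)

    # ---- alpha diversity ---------------------------------------------------
    alpha_parts = [
        diversity.alpha_diversity(rel, "observed", level="ASV"),
        diversity.alpha_diversity(rel, "shannon", level="ASV"),
        diversity.alpha_diversity(rel, "faiths_pd", tree=bundle.tree, level="ASV"),
        diversity.alpha_diversity(ko_rel, "observed", level="KO"),
        diversity.alpha_diversity(ko_rel, "shannon", level="KO"),
        diversity.alpha_diversity(path_rel, "observed", level="pathway"),
        diversity.alpha_diversity(path_rel, "shannon", level="pathway"),
    ]
    alpha = pd.concat(alpha_parts, ignore_index=True)
    alpha_cmp = diversity.compare_alpha(alpha, groups)

    # ---- beta diversity ----------------------------------------------------
    permanova_res = {}
    for name, weighted in (("unweighted_unifrac", False), ("weighted_unifrac", True)):
        dm = diversity.unifrac(rel, bundle.tree, weighted=weighted)
        permanova_res[name] = diversity.permanova(
            dm, groups, n_perm=n_perm, seed=rng_seeds["permanova"])

    # ---- differential abundance -------------------------------------------
    dam_results = {}
    for rank in DAM_RANKS:
        dam_results[rank] = dam.differential_abundance(
            rarefied, groups, taxonomy=bundle.taxonomy, rank=rank,
            n_mc=n_mc, seed=rng_seeds["dam"])
    dam_results["KO"] = dam.differential_abundance(
        _scaled_counts(ko_rel, depth), groups, n_mc=n_mc, seed=rng_seeds["dam"])
    dam_results["pathway"] = dam.differential_abundance(
        _scaled_counts(path_rel, depth), groups, n_mc=n_mc, seed=rng_seeds["dam"])

    # ---- enrichment over KO effects ---------------------------------------
    ranked = enrichment.RankedList.from_effects(dam_results["KO"]["effect"])
    gsea = enrichment.gsea_prerank(ranked, bundle.catalog, n_perm=gsea_perm,
                                   seed=rng_seeds["gsea"])

    # ---- presence attribution ---------------------------------------------
    genus_table = dam.aggregate_rank(rarefied, bundle.taxonomy, "genus")
    presence_tables, attribution_parts = {}, []
    shannon = alpha[alpha["metric"] == "shannon"].set_index("sample")
    for level, tbl in (("genus", genus_table),
                       ("pathway", _scaled_counts(path_rel, depth))):
        classes = presence.classify_presence(tbl)
        fisher = presence.fisher_presence(tbl, groups)
        key = "genus" if level == "genus" else "pathway"
        effects = dam_results[key][["effect"]]
        sh = shannon[shannon["level"] == ("ASV" if level == "genus" else "pathway")]
        g = groups.reindex(sh.index)
        direction = float(np.median(sh.loc[g == "stoma", "value"])
                          - np.median(sh.loc[g == "non_stoma", "value"]))
        presence_tables[level] = classes.join(fisher).join(effects)
        attribution_parts.append(
            presence.attribution_summary(classes, effects, fisher, direction,
                                         level=level))
    attribution = pd.concat(attribution_parts, ignore_index=True)

    result = PipelineResult(
        consort=consort, baseline=baseline, trait_tables=trait_tables,
        alpha=alpha, alpha_comparison=alpha_cmp, permanova=permanova_res,
        dam_results=dam_results, gsea=gsea, presence_tables=presence_tables,
        attribution=attribution,
    )
    if out_dir is not None:
        write_run(result, bundle, out_dir, seed=seed, params={
            "exclusions": [list(e) for e in exclusions],
            "rarefy_depth": rarefy_depth or "auto", "n_mc": n_mc,
            "n_perm": n_perm, "gsea_perm": gsea_perm,
            "dropped_samples": dropped,
        })
    return result


def write_run(result: PipelineResult, bundle: Bundle, out_dir, seed, params):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs_dir = out / "inputs"
    bundle_io.write_bundle(bundle, inputs_dir)

    result.consort.to_frame().to_csv(out / "consort.tsv", sep="\t", index=False)
    result.baseline.to_csv(out / "baseline.tsv", sep="\t", index=False)
    for axis, tbl in result.trait_tables.items():
        tbl.to_csv(out / f"traits_{axis}.tsv", sep="\t")
    result.alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
    result.alpha_comparison.to_csv(out / "alpha_comparison.tsv", sep="\t", index=False)
    perma = pd.DataFrame(
        [{"metric": m, "F": r.statistic, "p": r.p_value}
         for m, r in result.permanova.items()])
    perma.to_csv(out / "permanova.tsv", sep="\t", index=False)
    for level, tbl in result.dam_results.items():
        tbl.to_csv(out / f"dam_{level}.tsv", sep="\t")
    result.gsea.to_csv(out / "gsea.tsv", sep="\t")
    for level, tbl in result.presence_tables.items():
        tbl.to_csv(out / f"presence_{level}.tsv", sep="\t")
    result.attribution.to_csv(out / "attribution.tsv", sep="\t", index=False)

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.suffix != ".json")
    manifest = {
        "seed": seed,
        "params": params,
        "stages": ["cohort", "traits", "diversity_alpha", "diversity_beta",
                   "dam", "function", "enrichment", "presence", "attribution"],
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
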