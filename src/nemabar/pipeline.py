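"""End-to-end orchestration: simulation or provided inputs through QC,
SV resolution, rOTU clustering, per-region-set phylogenies and tree
evaluation, emitting a deterministic report bundle."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import alleles, io, phylo, qc, rotu as rotu_mod, treetax
from .config import PipelineConfig, region_set_name
from .pcr import extract_all_regions
from .synthetic import ReferenceSpecies, SimulationConfig, simulate_all

logger = logging.getLogger(__name__)



def build_region_sequences(
    references: list[ReferenceSpecies],
) -> tuple[dict[str, dict[int, "object"]], pd.DataFrame]:
    """In-silico PCR over every reference; returns per-species RegionSeq maps
    and a coordinate report (species, region, start, end, complete)."""
    per_species = {}
    rows = []
    for ref in references:
        regions = extract_all_regions(ref.sequence, ref.species_id)
        per_species[ref.species_id] = regions
        for rid, reg in sorted(regions.items()):
            rows.append((ref.species_id, rid, reg.start, reg.end, reg.complete))
    report = pd.DataFrame(
        rows, columns=["species_id", "region", "start", "end", "complete"])
    return per_species, report


def trees_for_region_sets(
    references: list[ReferenceSpecies],
    rotu_seqs: dict[str, dict[int, str]],
    config: PipelineConfig,
) -> dict[str, dict]:
    """Build one bootstrapped, outgroup-rooted tree per configured region set.

    ``rotu_seqs``: rOTU id -> {region -> regional SV sequence}.  A taxon
    (reference or rOTU) lacking any region of a set is excluded from that
    set's tree and listed in the exclusion report.
    """
    per_species, _ = build_region_sequences(references)
    ref_orders = {r.species_id: r.order for r in references}
    outgroup = next(r.species_id for r in references if r.is_outgroup)

    results: dict[str, dict] = {}
    for rs in config.region_sets:
        name = region_set_name(rs)
        seqs: dict[str, str] = {}
        excluded: list[str] = []
        for sp, regions in sorted(per_species.items()):
            if all(r in regions and regions[r].complete for r in rs):
                seqs[sp] = "".join(regions[r].sequence for r in rs)
            else:
                excluded.append(sp)
        for rid_, rmap in sorted(rotu_seqs.items()):
            if all(r in rmap for r in rs):
                seqs[rid_] = "".join(rmap[r] for r in rs)
            else:
                excluded.append(rid_)
        if len(seqs) < 3 or outgroup not in seqs:
            logger.warning("region set %s: too few taxa, skipped", name)
            continue
        t0 = time.time()
        tree = phylo.bootstrap_support(
            seqs, n_replicates=config.bootstrap, seed=config.seed,
            model=config.distance_model,
        )
        rooted = phylo.root_at_outgroup(tree, outgroup)
        labels = {}
        for leaf in seqs:
            if leaf == outgroup:
                labels[leaf] = "outgroup"
            elif leaf in ref_orders:
                labels[leaf] = ref_orders[leaf]
            else:
                labels[leaf] = "rOTU"
        results[name] = {
            "tree": rooted,
            "labels": labels,
            "excluded": sorted(excluded),
            "regions": rs,
        }
        logger.info("region set %s: %d taxa, %.1fs",
                    name, len(seqs), time.time() - t0)
    return results


def assign_taxonomy(
    rotus: list[rotu_mod.ROTU],
    trees: dict[str, dict],
    references: list[ReferenceSpecies],
    preferred_order: list[str] | None = None,
) -> pd.DataFrame:
    """Assign each rOTU an order and feeding code from the largest-region-set
    tree containing it, falling back to smaller sets when the rOTU lacks a
    region."""
    annotation = {r.species_id: r.feeding_code for r in references
                  if not r.is_outgroup}
    names = preferred_order or sorted(
        trees, key=lambda n: -len(trees[n]["regions"]))
    rows = []
    for r in rotus:
        assigned = None
        for name in names:
            info = trees.get(name)
            if info is None or r.rotu_id not in info["labels"]:
                continue
            order, clade_size = treetax.assign_rotu_order(
                info["tree"], r.rotu_id, info["labels"])
            code, nearest, dist = treetax.assign_feeding_type(
                info["tree"], r.rotu_id, annotation)
            assigned = (r.rotu_id, order, code, nearest, dist,
                        clade_size, name)
            break
        if assigned is None:
            assigned = (r.rotu_id, "NA", "NA", "NA", float("nan"), 0, "NA")
        r.order, r.feeding_code = assigned[1], assigned[2]
        rows.append(assigned)
    return pd.DataFrame(rows, columns=[
        "rotu", "order", "feeding_code", "nearest_reference",
        "patristic_distance", "clade_size", "region_set",
    ])


def run_pipeline(
    sim_config: SimulationConfig,
    config: PipelineConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Full synthetic run: simulate -> QC -> resolve -> cluster -> trees ->
    evaluate.  Returns the report bundle; when ``outdir`` is given every
    artifact is also written there, stamped with the config hash and seed."""
    references, tables, truth = simulate_all(sim_config)

    qc_reports, retained = {}, {}
    for rid, table in sorted(tables.items()):
        kept, report = qc.select_nematode_samples(
            table, config.min_reads, config.min_nem_frac, config.minor_floor)
        retained[rid] = kept
        report.insert(1, "region", rid)
        qc_reports[rid] = report
        logger.info("region %d: %d/%d samples retained",
                    rid, len(kept), report.shape[0])
    qc_report = pd.concat(qc_reports.values(), ignore_index=True)

    compositions = []
    for rid, table in sorted(tables.items()):
        props, _zero = qc.relative_abundance(table)
        comp = qc.aggregate_phylum(props, config.phylum_min_frac)
        comp.insert(1, "region", rid)
        compositions.append(comp)
    composition = pd.concat(compositions, ignore_index=True)

    profiles = alleles.build_isolate_profiles(
        tables, retained, config.minor_floor, config.max_allele_edits)
    excluded = alleles.flag_ambiguous_isolates(profiles,
                                               config.max_allele_edits)
    calls = alleles.allele_calls_table(profiles)
    rotus = rotu_mod.cluster_isolates(profiles, config.experiment_code)
    logger.info("%d isolates -> %d rOTUs (%d excluded as ambiguous)",
                sum(r.n_isolates for r in rotus), len(rotus), len(excluded))

    seq_maps = {
        rid: dict(zip(t["sv_id"], t["sequence"]))
        for rid, t in tables.items()
    }
    rotu_seqs = {
        r.rotu_id: {rid: seq_maps[rid][sv] for rid, sv in r.regional.items()}
        for r in rotus
    }
    trees = trees_for_region_sets(references, rotu_seqs, config)
    assignments = assign_taxonomy(rotus, trees, references)
    order_summary = rotu_mod.summarize_orders(rotus)
    feeding_summary = rotu_mod.summarize_feeding(rotus)
    n_mat, m_mat = treetax.compare_concatenations(
        {name: (info["tree"], info["labels"])
         for name, info in trees.items()})

    bundle = {
        "references": references,
        "tables": tables,
        "truth": truth,
        "qc_report": qc_report,
        "composition": composition,
        "profiles": profiles,
        "excluded_samples": excluded,
        "allele_calls": calls,
        "rotus": rotus,
        "rotu_table": rotu_mod.rotu_table(rotus),
        "assignments": assignments,
        "order_summary": order_summary,
        "feeding_summary": feeding_summary,
        "trees": trees,
        "cluster_counts": n_mat,
        "max_cluster_sizes": m_mat,
    }
    if outdir is not None:
        write_bundle(bundle, sim_config, config, outdir)
    return bundle


def write_bundle(bundle: dict, sim_config: SimulationConfig,
                 config: PipelineConfig, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_references(bundle["references"],
                        out / "references.fasta",
                        out / "reference_annotations.tsv")
    for rid, table in bundle["tables"].items():
        io.write_table(table, out / f"sv_table_r{rid}.tsv")
    io.write_table(bundle["qc_report"], out / "qc_report.tsv")
    io.write_table(bundle["composition"], out / "phylum_composition.tsv")
    io.write_table(bundle["allele_calls"], out / "allele_calls.tsv")
    io.write_table(bundle["rotu_table"], out / "rotu_table.tsv")
    io.write_table(bundle["assignments"], out / "rotu_assignments.tsv")
    io.write_table(bundle["order_summary"], out / "order_summary.tsv")
    io.write_table(bundle["feeding_summary"], out / "feeding_summary.tsv")
    bundle["cluster_counts"].to_csv(out / "cluster_counts.tsv", sep="\t")
    bundle["max_cluster_sizes"].to_csv(out / "max_cluster_sizes.tsv", sep="\t")
    pd.DataFrame({"excluded_sample": bundle["excluded_samples"]}).to_csv(
        out / "excluded_samples.tsv", sep="\t", index=False)
    for name, info in bundle["trees"].items():
        io.write_newick(info["tree"], out / f"tree_{name}.nwk")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "pipeline_config": asdict(config),
        "simulation_config": asdict(sim_config),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n")
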