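"""End-to-end orchestration: simulate -> cluster -> partition -> phylogeny ->
recombination, with the independent CRISPR, PTS and synteny stages, a
parameter manifest and summary tables.

Configuration is a single flat INI-style file with sections; every parameter
a stage consumes is recorded in the manifest together with sha256 checksums
of the written artifacts, so a rerun with the same config is verifiably
identical.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import crispr as crispr_mod
from . import pangenome as pan_mod
from . import phylo as phylo_mod
from . import pts as pts_mod
from . import recombination as recomb_mod
from . import synteny as synteny_mod
from .io_formats import write_clusters, write_fasta, write_gene_table, write_newick_file
from .orthology import ClusteringParams, build_graph, mcl_cluster, score_pairs
from .sim import (
    CrisprSimConfig,
    PangenomeSimConfig,
    PtsSimConfig,
    SimulatedPangenome,
    pts_input_tables,
    simulate_pangenome,
    true_clusters,
)


def load_config(path) -> PangenomeSimConfig:
    """Read the flat key=value config file into a simulation config."""
    parser = configparser.ConfigParser()
    parser.read(str(path))
    sim = parser["simulate"] if "simulate" in parser else {}
    groups = []
    for tok in sim.get("groups", "A:3,B:3").split(","):
        gid, n = tok.strip().split(":")
        groups.append((gid, int(n)))
    cfg = PangenomeSimConfig(
        seed=int(sim.get("seed", 0)),
        groups=groups,
        core_families=int(sim.get("core_families", 200)),
        accessory_families=int(sim.get("accessory_families", 150)),
        gene_length=int(sim.get("gene_length", 900)),
        recomb_fraction=float(sim.get("recomb_fraction", 0.1)),
        tract_length=int(sim.get("tract_length", 300)),
        crispr=CrisprSimConfig(),
        pts=PtsSimConfig(),
    )
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def adjusted_rand_index(labels_a: dict[str, str], labels_b: dict[str, str]) -> float:
    """ARI between two partitions given as item -> cluster-label maps."""
    items = sorted(labels_a)
    if sorted(labels_b) != items:
        raise ValueError("partitions cover different item sets")
    a_ids = {l: i for i, l in enumerate(sorted({labels_a[x] for x in items}))}
    b_ids = {l: i for i, l in enumerate(sorted({labels_b[x] for x in items}))}
    table = np.zeros((len(a_ids), len(b_ids)), dtype=np.int64)
    for x in items:
        table[a_ids[labels_a[x]], b_ids[labels_b[x]]] += 1
    n = table.sum()
    sum_comb = (table * (table - 1) // 2).sum()
    a_comb = (table.sum(1) * (table.sum(1) - 1) // 2).sum()
    b_comb = (table.sum(0) * (table.sum(0) - 1) // 2).sum()
    total = n * (n - 1) // 2
    expected = a_comb * b_comb / total if total else 0.0
    max_index = (a_comb + b_comb) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def family_alignment(
    sim: SimulatedPangenome, members: list[tuple[str, str]], taxa_by_genome: bool = True
) -> phylo_mod.Alignment:
    """Column-identity alignment of a single-copy family's CDS sequences
    (simulated homologs carry no indels)."""
    seqs = {}
    for genome, gene in members:
        key = genome if taxa_by_genome else gene
        seqs[key] = sim.cds[gene]
    return phylo_mod.Alignment.from_dict(seqs)


def run_pipeline(config: PangenomeSimConfig, outdir, stages: set[str] | None = None) -> dict:
    """Execute the stages in dependency order and write the report directory.

    Returns a results dict with the key quantities of every stage; stage
    tables and a manifest land under `outdir`.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or {
        "simulate",
        "cluster",
        "pangenome",
        "phylo",
        "recomb",
        "crispr",
        "pts",
        "stats",
    }
    manifest: dict = {"stages": {}, "outputs": {}}
    results: dict = {}
    t0 = time.time()

    # --- simulate -----------------------------------------------------------
    sim = simulate_pangenome(config)
    truth = sim.truth
    data = out / "data"
    data.mkdir(exist_ok=True)
    for g in sim.genomes:
        write_fasta(
            [(f"{g.genome_id}.{cid}", seq) for cid, seq in g.contigs],
            data / f"{g.genome_id}.fna",
        )
    write_fasta(sorted(sim.proteins.items()), data / "proteins.faa")
    write_fasta(sorted(sim.cds.items()), data / "cds.fna")
    write_gene_table(sim.annotations, data / "genes.tsv")
    (data / "true_tree.nwk").write_text(truth.tree_newick + "\n")
    manifest["stages"]["simulate"] = {
        "seed": config.seed,
        "groups": config.groups,
        "core_families": config.core_families,
        "accessory_families": config.accessory_families,
        "gene_length": config.gene_length,
        "recomb_fraction": config.recomb_fraction,
        "tract_length": config.tract_length,
    }
    results["n_genes"] = len(sim.annotations)
    results["n_genomes"] = len(sim.genomes)

    groups = {gid: {f"{gid}{i + 1}" for i in range(n)} for gid, n in config.groups}
    all_genomes = {g.genome_id for g in sim.genomes}

    # --- cluster ------------------------------------------------------------
    clusters = None
    if "cluster" in stages:
        params = ClusteringParams()
        hits = score_pairs(sim.proteins)
        gene_genome = {gene: truth.gene_genome[gene] for gene in sim.proteins}
        graph = build_graph(hits, gene_genome, params)
        clusters = mcl_cluster(graph, params)
        write_clusters(clusters, out / "groups.txt")
        inferred = {
            gene: fam for fam, members in clusters.families.items() for _, gene in members
        }
        ari = adjusted_rand_index(inferred, truth.membership)
        results["n_families"] = len(clusters)
        results["clustering_ari"] = ari
        manifest["stages"]["cluster"] = {
            "inflation": params.inflation,
            "prune_threshold": params.prune_threshold,
            "convergence_tol": params.convergence_tol,
        }

    # --- pangenome ----------------------------------------------------------
    if clusters is not None and "pangenome" in stages:
        pan = pan_mod.extract_pan_orthologs(clusters, all_genomes)
        partition_rows = []
        venn_tables = {}
        for gid, members in groups.items():
            core = pan_mod.group_core(clusters, members)
            acc = pan_mod.group_accessory(clusters, members)
            spec_core = pan_mod.group_specific_core(
                clusters, members, all_genomes - members
            )
            venn = pan_mod.venn_partition(clusters, acc, members)
            venn_tables[gid] = venn
            results[f"group_core_{gid}"] = len(core)
            results[f"group_accessory_{gid}"] = len(acc)
            results[f"group_specific_core_{gid}"] = len(spec_core)
            for fam in core:
                partition_rows.append({"family": fam, "group": gid, "label": "group-core"})
            for fam in acc:
                partition_rows.append(
                    {"family": fam, "group": gid, "label": "group-accessory"}
                )
        results["pan_orthologs"] = len(pan)
        pd.DataFrame(partition_rows).to_csv(out / "partition.tsv", sep="\t", index=False)
        venn_rows = []
        for gid, venn in venn_tables.items():
            for region, count in sorted(venn.items(), key=lambda kv: sorted(kv[0])):
                venn_rows.append(
                    {"group": gid, "region": "+".join(sorted(region)), "families": count}
                )
        pd.DataFrame(venn_rows).to_csv(out / "venn.tsv", sep="\t", index=False)
        manifest["stages"]["pangenome"] = {"groups": {g: sorted(m) for g, m in groups.items()}}

    # --- phylogeny ----------------------------------------------------------
    if clusters is not None and "phylo" in stages:
        pan = pan_mod.extract_pan_orthologs(clusters, all_genomes)
        alignments = {
            fam: family_alignment(sim, clusters.families[fam]) for fam in pan
        }
        taxa = sorted(all_genomes)
        concat, spans = phylo_mod.concatenate(alignments, taxa)
        tree = phylo_mod.bootstrap_support(concat, n=100, seed=config.seed)
        write_newick_file(tree, out / "core_tree.nwk")
        # per-gene trees + monophyly of each group (others as outgroup)
        gene_trees = {
            fam: phylo_mod.nj_tree(phylo_mod.jc_distance(aln))
            for fam, aln in alignments.items()
        }
        first_group = sorted(groups)[0]
        outgroup = all_genomes - groups[first_group]
        report = phylo_mod.monophyly_report(gene_trees, groups, outgroup)
        report.to_csv(out / "monophyly.tsv", sep="\t", index=False)
        results["core_alignment_columns"] = concat.width
        results["monophyly_incongruent"] = int(report["incongruent"].sum())
        results["monophyly_tested"] = int((report["status"] == "tested").sum())
        manifest["stages"]["phylo"] = {"bootstrap": 100, "seed": config.seed}

    # --- recombination ------------------------------------------------------
    if clusters is not None and "recomb" in stages:
        rparams = recomb_mod.RecombinationParams(seed=config.seed)
        for gid, members in groups.items():
            core = pan_mod.group_core(clusters, members)
            alns = {}
            for fam in core:
                mem = [(g, x) for g, x in clusters.families[fam] if g in members]
                alns[fam] = family_alignment(sim, mem)
            table, summary = recomb_mod.scan_genes(alns, rparams)
            table.to_csv(out / f"recombination_{gid}.tsv", sep="\t", index=False)
            results[f"recombinant_{gid}"] = summary["recombinant"]
            results[f"recombinant_fraction_{gid}"] = summary["fraction"]
            results[f"recomb_evaluable_{gid}"] = summary["evaluable"]
        manifest["stages"]["recomb"] = {
            "permutations": rparams.permutations,
            "alpha": rparams.alpha,
            "phi_window": rparams.phi_window,
            "seed": rparams.seed,
        }

    # --- CRISPR -------------------------------------------------------------
    if "crispr" in stages:
        cparams = crispr_mod.CrisprParams()
        arrays = []
        for g in sim.genomes:
            arrays.extend(crispr_mod.detect_arrays(g, cparams))
        spacers, regions = crispr_mod.extract_spacers(arrays)
        write_fasta(spacers, out / "spacers.fna")
        regions.to_csv(out / "crispr_regions.tsv", sep="\t", index=False)
        masked = crispr_mod.mask_spacers(sim.genomes, arrays)
        hits = crispr_mod.find_protospacers(spacers, masked, cparams.max_mismatches)
        counts, hit_table = crispr_mod.spacer_network(hits, truth.group_of_genome)
        hit_table.to_csv(out / "spacer_hits.tsv", sep="\t", index=False)
        results["crispr_arrays"] = len(arrays)
        results["crispr_spacers"] = len(spacers)
        results["spacer_hits_within_group"] = counts["within_group"]
        results["spacer_hits_between_group"] = counts["between_group"]
        manifest["stages"]["crispr"] = {
            "max_mismatches": cparams.max_mismatches,
            "min_repeats": cparams.min_repeats,
        }

    # --- PTS ----------------------------------------------------------------
    if "pts" in stages:
        tc_hits, domain_calls = pts_input_tables(truth)
        filtered = pts_mod.filter_tc_hits(tc_hits)
        operons = pts_mod.infer_operons(sim.annotations, max_gap=200)
        calls = pts_mod.call_pts(filtered, domain_calls, operons)
        complete = pts_mod.count_complete_man_operons(calls)
        pd.DataFrame(
            [
                {
                    "gene": c.gene_id,
                    "genome": c.genome,
                    "family": c.family,
                    "operon": c.operon_id,
                    "role": c.role,
                }
                for c in calls
            ]
        ).to_csv(out / "pts_calls.tsv", sep="\t", index=False)
        results["pts_called_genes"] = len(calls)
        results["pts_complete_man_operons"] = sum(complete.values())
        results["pts_complete_by_genome"] = dict(sorted(complete.items()))
        manifest["stages"]["pts"] = {"max_gap": 200, "evalue": 0.01}

    # --- genome statistics --------------------------------------------------
    if "stats" in stages:
        rows = [
            synteny_mod.genome_summary(g, sim.annotations) for g in sim.genomes
        ]
        pd.DataFrame(rows).to_csv(out / "genome_stats.tsv", sep="\t", index=False)
        results["mean_genome_size"] = float(np.mean([r["size"] for r in rows]))
        manifest["stages"]["stats"] = {"min_contig": 500}

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "results.json").write_text(
        json.dumps(_json_safe(results), indent=2, default=str)
    )
    return results


def _json_safe(obj):
    """Replace NaN with None recursively so the JSON stays strict."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def summarize(outdir) -> dict[str, pd.DataFrame]:
    """Collect the stage tables of a finished run into summary tables.

    Missing stage outputs are skipped with a notice in the returned mapping.
    """
    out = Path(outdir)
    tables: dict[str, pd.DataFrame] = {}
    notices: list[str] = []
    for name, fname in [
        ("genome_stats", "genome_stats.tsv"),
        ("partition", "partition.tsv"),
        ("venn", "venn.tsv"),
        ("monophyly", "monophyly.tsv"),
        ("crispr_regions", "crispr_regions.tsv"),
        ("spacer_hits", "spacer_hits.tsv"),
        ("pts_calls", "pts_calls.tsv"),
    ]:
        path = out / fname
        if path.exists():
            tables[name] = pd.read_csv(path, sep="\t")
        else:
            notices.append(f"{fname} missing; table omitted")
    tables["_notices"] = pd.DataFrame({"notice": notices})
    return tables
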