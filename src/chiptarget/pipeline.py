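"""End-to-end orchestration: simulate -> peaks -> annotate -> motif -> DE -> report.

Each stage writes plain-text artifacts under the output directory; a
``#`` header with the seed and configuration digest makes runs
reproducible and diffable.  The same stages are runnable individually
through the CLI.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import annotate, expression, io, motifs, peaks, simulate
from .config import PipelineConfig, SimulationParams, config_digest
from .integrate import build_report, build_targets, integrate as integrate_sets, write_report
from .types import BindingRegion, ReadSet

logger = logging.getLogger(__name__)

MAX_GIBBS_SEQUENCES = 50
GIBBS_HALF_WINDOW = 100


def run_simulate(params: SimulationParams, outdir: Path, header: str):
    """Generate and write the synthetic dataset; returns in-memory objects."""
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate.simulate_genome(params)
    io.write_fasta(genome, outdir / "genome.fa")
    io.write_gff3(genes, outdir / "genes.gff3", header)
    io.write_bed12(genes, outdir / "genes.bed12", header)
    io.write_ground_truth(truth, outdir / "truth_sites.tsv", outdir / "truth_genes.tsv",
                          params.conditions, header)
    reads: dict[tuple[str, str, int], ReadSet] = {}
    for condition in params.conditions:
        for rep in range(1, params.n_replicates + 1):
            chip = simulate.simulate_chip_reads(genome, truth, params, condition, rep)
            inp = simulate.simulate_input_reads(genome, params, rep)
            io.write_bed6(chip, outdir / f"chip_{condition}_rep{rep}.bed", header)
            io.write_bed6(inp, outdir / f"input_rep{rep}.bed", header)
            reads[("chip", condition, rep)] = chip
            reads[("input", condition, rep)] = inp
    expr = simulate.simulate_expression(genes, truth, params)
    io.write_expression(expr, outdir / "expression.tsv", header)
    return genome, genes, truth, reads, expr


def run_all(params: SimulationParams, config: PipelineConfig, outdir: str | Path,
            seed: int) -> dict:
    """Run the whole pipeline on freshly simulated data; returns the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = SimulationParams(**{**params.__dict__, "seed": seed})
    digest = config_digest(params, config, seed)
    header = f"seed={seed} config={digest}"
    logger.info("pipeline run: %s", header)

    genome, genes, truth, reads, expr = run_simulate(params, outdir, header)
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    # --- binding regions per condition (replicate-intersected) ---------
    regions_by_condition: dict[str, list[BindingRegion]] = {}
    for ci, condition in enumerate(params.conditions):
        chip_by_rep = [reads[("chip", condition, r)] for r in range(1, params.n_replicates + 1)]
        input_by_rep = [reads[("input", condition, r)] for r in range(1, params.n_replicates + 1)]
        regions = peaks.detect_binding_regions(
            chip_by_rep, input_by_rep, chrom_lengths, config,
            condition=condition, seed=seed * 1000 + ci)
        regions_by_condition[condition] = regions
        io.write_regions(regions, outdir / f"regions_{condition}.tsv", header)

    # --- annotation ----------------------------------------------------
    compartments = {}
    for condition, regions in regions_by_condition.items():
        assignments = annotate.assign_regions(regions, genes, config)
        compartments[condition] = annotate.compartment_summary(assignments)
        profile = annotate.tss_distance_profile(assignments, config)
        annotate.positional_binomial_test(profile, config.positional_alpha)
        _write_profile(profile, outdir / f"tss_profile_{condition}.tsv", header)
    candidates = annotate.candidate_targets(regions_by_condition, genes, config)
    (outdir / "candidate_genes.tsv").write_text(
        "\n".join([f"# {header}", "gene_id"] + sorted(candidates)) + "\n")

    # --- motif analysis ------------------------------------------------
    all_regions = [r for rs in regions_by_condition.values() for r in rs]
    hits = motifs.scan_word(genome, config.motif_word)
    genome_length = sum(chrom_lengths.values())
    fold = (motifs.word_fold_enrichment(hits, all_regions, genome_length)
            if all_regions else float("nan"))
    edges, profile_counts = motifs.word_positional_profile(
        hits, all_regions, config.motif_flank, config.bin_size)
    with open(outdir / "word_profile.tsv", "w") as fh:
        fh.write(f"# {header}\nbin_start\tbin_end\tcount\n")
        for i, c in enumerate(profile_counts):
            fh.write(f"{edges[i]}\t{edges[i + 1]}\t{c}\n")
    motif_model = None
    region_seqs = [
        genome[r.chrom][max(0, r.midpoint - GIBBS_HALF_WINDOW): r.midpoint + GIBBS_HALF_WINDOW]
        for r in all_regions[:MAX_GIBBS_SEQUENCES]
    ]
    region_seqs = [s for s in region_seqs if len(s) >= len(config.motif_word)]
    if len(region_seqs) >= 2:
        motif_model = motifs.gibbs_motif_search(
            region_seqs, width=len(config.motif_word), seed=seed)
        with open(outdir / "motif.tsv", "w") as fh:
            fh.write(f"# {header}\nconsensus\t{motif_model.consensus}\n"
                     f"information_content\t{motif_model.information_content:.4f}\n")
            for row in motif_model.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")

    # --- differential expression ---------------------------------------
    matrix = expression.ExpressionMatrix.from_frame(expr)
    de = expression.per_gene_de(matrix, config)
    _write_de(de, sorted(matrix.times), outdir / "de_results.tsv", header)

    # --- integration & report ------------------------------------------
    up_ids, down_ids = integrate_sets(candidates, de)
    up_targets = build_targets(up_ids, "up", genes, regions_by_condition, de, config)
    down_targets = build_targets(down_ids, "down", genes, regions_by_condition, de, config)
    _write_targets(up_targets + down_targets, outdir / "target_genes.tsv", header)

    rel = expression.relative_expression(matrix)
    cluster_groups = {}
    for direction, ids, k in (("up", up_ids, 2), ("down", down_ids, 3)):
        if len(ids) >= max(2, k):
            _, labels = expression.hierarchical_cluster(rel.loc[ids], n_groups=k)
            table: dict[int, int] = {}
            for v in labels:
                table[int(v)] = table.get(int(v), 0) + 1
            cluster_groups[direction] = table

    report = build_report(
        regions_by_condition, compartments, candidates, de,
        up_targets, down_targets, config, times=sorted(matrix.times),
        cluster_groups=cluster_groups or None)
    report["run"] = {"seed": seed, "config_digest": digest}
    report["motif"] = {
        "word": config.motif_word,
        "fold_enrichment": fold,
        "n_hits": len(hits),
        "discovered_consensus": motif_model.consensus if motif_model else None,
    }
    write_report(report, outdir / "report.json")
    return report


def _write_profile(profile, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\nbin_start\tbin_end\tobserved\texpected\tp\tsignificant\n")
        for i in range(profile.n_bins):
            p = profile.p_values[i] if profile.p_values is not None else float("nan")
            sig = bool(profile.significant[i]) if profile.significant is not None else False
            fh.write(f"{profile.bin_edges[i]}\t{profile.bin_edges[i + 1]}\t"
                     f"{profile.observed[i]}\t{profile.expected:.4f}\t{p:.6g}\t{int(sig)}\n")


def _write_de(de, times, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        cols = ["gene_id"] + [f"log2fc_{t}h" for t in times] + ["p_anova", "q", "call", "times_passing"]
        fh.write(f"# {header}\n" + "\t".join(cols) + "\n")
        for r in de:
            fh.write("\t".join(
                [r.gene_id] + [f"{r.log2fc[t]:.6f}" for t in times]
                + [f"{r.p_anova:.6g}", f"{r.q:.6g}", r.call,
                   ",".join(map(str, r.times_passing))]
            ) + "\n")


def _write_targets(targets, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\ngene_id\tdirection\ttss_distance\tn_regions\tcategory\n")
        for t in targets:
            dist = "" if t.tss_distance is None else f"{t.tss_distance:.0f}"
            fh.write(f"{t.gene_id}\t{t.direction}\t{dist}\t{len(t.regions)}\t{t.category}\n")
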