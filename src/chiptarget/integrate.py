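"""Binding x expression integration and report assembly.

A target gene is a candidate bound gene (binding region within the
400-bp upstream window in either condition) that is also called
up- or down-regulated in the overexpressor.  The report tabulates
region counts, compartment percentages, Venn overlaps, functional
categories and cluster groups, with all percentages computed half-up
the way printed report tables round them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .annotate import nearest_upstream_region
from .config import PipelineConfig
from .stats import percentage
from .types import BindingRegion, DEResult, GeneModel, TargetGene

logger = logging.getLogger(__name__)

FUNCTION_CATEGORIES = (
    "biosynthetic enzyme",
    "defence response",
    "transcription factor",
    "protein kinase",
    "transporter",
    "other function",
    "unknown function",
)


def integrate(candidates: set[str], de: list[DEResult]) -> tuple[list[str], list[str]]:
    """Intersect bound candidates with up/down DE calls.

    Returns (up-target ids, down-target ids), disjoint by construction;
    candidates absent from the DE table are logged and excluded.
    """
    de_by_gene = {r.gene_id: r for r in de}
    missing = sorted(g for g in candidates if g not in de_by_gene)
    if missing:
        logger.warning("%d candidate genes absent from the DE table: %s",
                       len(missing), ", ".join(missing[:10]))
    up = sorted(g for g in candidates if g in de_by_gene and de_by_gene[g].call == "up")
    down = sorted(g for g in candidates if g in de_by_gene and de_by_gene[g].call == "down")
    return up, down


def build_targets(gene_ids: list[str], direction: str, genes: list[GeneModel],
                  regions_by_condition: dict[str, list[BindingRegion]],
                  de: list[DEResult], config: PipelineConfig,
                  category_map: dict[str, str] | None = None) -> list[TargetGene]:
    """Assemble full TargetGene records for one direction."""
    gene_by_id = {g.gene_id: g for g in genes}
    de_by_gene = {r.gene_id: r for r in de}
    all_regions = [r for regions in regions_by_condition.values() for r in regions]
    out = []
    for gid in gene_ids:
        gene = gene_by_id[gid]
        support, dist = nearest_upstream_region(gene, all_regions, config)
        category = (category_map or {}).get(gid, "unknown function")
        out.append(TargetGene(
            gene_id=gid, direction=direction, regions=support,
            tss_distance=dist, log2fc=de_by_gene[gid].log2fc, category=category,
        ))
    return out


def classify_function(targets: list[TargetGene],
                      category_map: dict[str, str]) -> dict[str, dict[str, float]]:
    """Counts and percentages over the fixed functional categories.

    Unmapped genes fall in "unknown function"; an unrecognised category
    label in the map is an error naming the valid labels.
    """
    bad = sorted(set(category_map.values()) - set(FUNCTION_CATEGORIES))
    if bad:
        raise ValueError(
            f"unrecognised categories {bad}; valid labels: {list(FUNCTION_CATEGORIES)}")
    counts = {c: 0 for c in FUNCTION_CATEGORIES}
    for t in targets:
        counts[category_map.get(t.gene_id, "unknown function")] += 1
    total = len(targets)
    return {
        "counts": counts,
        "percentages": {c: (percentage(counts[c], total, 1) if total else 0.0)
                        for c in FUNCTION_CATEGORIES},
    }


def region_condition_overlap(regions_by_condition: dict[str, list[BindingRegion]]
                             ) -> dict[str, int]:
    """Venn counts of region overlap between the two conditions (by >= 1 bp)."""
    conds = list(regions_by_condition)
    if len(conds) != 2:
        return {c: len(regions_by_condition[c]) for c in conds}
    a, b = conds
    ra, rb = regions_by_condition[a], regions_by_condition[b]

    def overlaps_any(r: BindingRegion, others: list[BindingRegion]) -> bool:
        return any(o.chrom == r.chrom and o.start < r.end and o.end > r.start
                   for o in others)

    shared_a = sum(overlaps_any(r, rb) for r in ra)
    shared_b = sum(overlaps_any(r, ra) for r in rb)
    return {
        a: len(ra),
        b: len(rb),
        f"{a}_shared": shared_a,
        f"{b}_shared": shared_b,
        f"{a}_only": len(ra) - shared_a,
        f"{b}_only": len(rb) - shared_b,
    }


def build_report(regions_by_condition: dict[str, list[BindingRegion]],
                 compartments_by_condition: dict[str, dict],
                 candidates: set[str], de: list[DEResult],
                 up_targets: list[TargetGene], down_targets: list[TargetGene],
                 config: PipelineConfig, times: list[int] | None = None,
                 cluster_groups: dict[str, dict[int, int]] | None = None) -> dict:
    """Machine-readable summary of the whole run.

    Percentage conventions follow the printed-report style: the up/down
    target percentages are quoted against the per-condition
    binding-region counts (the convention of the source tables), with a
    corrected companion ratio against the DE gene counts, clearly
    labelled.
    """
    conds = list(regions_by_condition)
    de_up = [r for r in de if r.call == "up"]
    de_down = [r for r in de if r.call == "down"]
    times = times or sorted({t for r in de for t in r.log2fc})
    thr = config.fc_threshold
    import math
    log_thr = math.log2(thr)

    per_time = {}
    for t in times:
        n_up = sum(1 for r in de_up if r.log2fc.get(t, 0) >= log_thr)
        n_down = sum(1 for r in de_down if r.log2fc.get(t, 0) <= -log_thr)
        per_time[str(t)] = {"up": n_up, "down": n_down}

    n_regions = {c: len(regions_by_condition[c]) for c in conds}
    report = {
        "regions": {
            "counts": n_regions,
            "condition_overlap": region_condition_overlap(regions_by_condition),
        },
        "compartments": compartments_by_condition,
        "candidates": {"count": len(candidates)},
        "differential_expression": {
            "up_union": len(de_up),
            "down_union": len(de_down),
            "per_time": per_time,
        },
        "targets": {
            "up": len(up_targets),
            "down": len(down_targets),
            "total": len(up_targets) + len(down_targets),
        },
        "functional_classification": {
            "up": classify_function(up_targets, {t.gene_id: t.category for t in up_targets}),
            "down": classify_function(down_targets, {t.gene_id: t.category for t in down_targets}),
        },
    }
    # percentage of regions whose 400-bp window yields an up/down target:
    # printed-report convention uses the region count as denominator
    if len(conds) >= 2:
        denom_up, denom_down = n_regions[conds[0]], n_regions[conds[1]]
    elif conds:
        denom_up = denom_down = n_regions[conds[0]]
    else:
        denom_up = denom_down = 0
    pct = {}
    if denom_up:
        pct["up_vs_region_count"] = percentage(len(up_targets), denom_up, 1)
    if denom_down:
        pct["down_vs_region_count"] = percentage(len(down_targets), denom_down, 1)
    if de_up:
        pct["up_vs_de_gene_count"] = percentage(len(up_targets), len(de_up), 1)
    if de_down:
        pct["down_vs_de_gene_count"] = percentage(len(down_targets), len(de_down), 1)
    report["targets"]["percentages"] = pct
    if cluster_groups:
        groups = {}
        for direction, table in cluster_groups.items():
            total = sum(table.values())
            groups[direction] = {
                "counts": {str(k): v for k, v in sorted(table.items())},
                "percentages": {str(k): percentage(v, total, 0) for k, v in sorted(table.items())}
                if total else {},
            }
        report["cluster_groups"] = groups
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
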