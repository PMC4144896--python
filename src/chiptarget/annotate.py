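"""Compartment assignment of binding regions and target-gene nomination.

Regions are assigned to one of four mutually exclusive compartments
relative to the nearest gene, strand-aware:

* ``upstream``  — region midpoint within ``upstream_window`` bp 5' of a TSS,
* ``gene``      — midpoint between TSS and TTS,
* ``downstream``— midpoint within ``downstream_window`` bp 3' of a TTS,
* ``intergenic``— none of the above.

Precedence is upstream > gene > downstream; within a compartment the
gene minimising the absolute distance to its anchor (TSS for
upstream/gene, TTS for downstream) wins, ties broken by lexicographic
gene identifier.  Candidate target genes are those with a binding
region overlapping the 400-bp window immediately upstream of their TSS
in either condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import PipelineConfig
from .types import BindingRegion, GeneModel, RegionAssignment

logger = logging.getLogger(__name__)

CATEGORIES = ("upstream", "gene", "downstream", "intergenic")


def _signed_tss_distance(mid: int, gene: GeneModel) -> int:
    """bp from midpoint to TSS in reading direction; negative upstream."""
    return mid - gene.tss if gene.strand == "+" else gene.tss - mid


def _signed_tts_distance(mid: int, gene: GeneModel) -> int:
    """bp from midpoint past the TTS in reading direction; positive downstream."""
    return mid - gene.tts if gene.strand == "+" else gene.tts - mid


def assign_region(region: BindingRegion, genes: list[GeneModel],
                  config: PipelineConfig) -> RegionAssignment:
    """Place one region in its compartment (see module docstring)."""
    if not genes:
        logger.warning("no gene models supplied; region %s:%d-%d is intergenic",
                       region.chrom, region.start, region.end)
        return RegionAssignment(region, "intergenic")
    mid = region.midpoint
    best: dict[str, tuple[float, str, float, float]] = {}
    for g in genes:
        if g.chrom != region.chrom:
            continue
        d_tss = _signed_tss_distance(mid, g)
        d_tts = _signed_tts_distance(mid, g)
        if -config.upstream_window <= d_tss < 0:
            cat, anchor = "upstream", d_tss
        elif g.start <= mid < g.end:
            cat, anchor = "gene", d_tss
        elif 0 < d_tts <= config.downstream_window:
            cat, anchor = "downstream", d_tts
        else:
            continue
        key = (abs(anchor), g.gene_id)
        if cat not in best or key < (best[cat][0], best[cat][1]):
            best[cat] = (abs(anchor), g.gene_id, d_tss, anchor)
    for cat in ("upstream", "gene", "downstream"):
        if cat in best:
            _, gene_id, d_tss, anchor = best[cat]
            return RegionAssignment(region, cat, gene_id, float(d_tss), float(anchor))
    return RegionAssignment(region, "intergenic")


def assign_regions(regions: list[BindingRegion], genes: list[GeneModel],
                   config: PipelineConfig) -> list[RegionAssignment]:
    return [assign_region(r, genes, config) for r in regions]


def compartment_summary(assignments: list[RegionAssignment]) -> dict:
    """Counts and integer percentages per compartment."""
    from .stats import percentage

    counts = {cat: 0 for cat in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    total = len(assignments)
    pct = {cat: (percentage(counts[cat], total, 0) if total else 0.0) for cat in CATEGORIES}
    return {"total": total, "counts": counts, "percentages": pct}


@dataclass
class PositionalProfile:
    """Histogram of region midpoints around TSS/TTS anchors, 100-bp bins.

    Upstream assignments contribute their signed TSS distance (negative
    bins); downstream assignments their signed TTS distance (positive
    bins).  ``expected`` is the uniform per-bin count total/n_bins.
    """

    bin_edges: np.ndarray  # length n_bins + 1
    observed: np.ndarray
    expected: float = 0.0
    p_values: np.ndarray | None = None
    significant: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.observed)


def tss_distance_profile(assignments: list[RegionAssignment],
                         config: PipelineConfig) -> PositionalProfile:
    """Bin upstream/downstream assignments by distance to their anchor."""
    if config.upstream_window % config.bin_size or config.downstream_window % config.bin_size:
        raise ValueError("bin_size must divide the upstream and downstream windows")
    edges = np.arange(-config.upstream_window, config.downstream_window + 1, config.bin_size)
    dists = [a.anchor_distance for a in assignments
             if a.category in ("upstream", "downstream") and a.anchor_distance is not None]
    observed, _ = np.histogram(dists, bins=edges)
    n = int(observed.sum())
    expected = n / len(observed) if n else 0.0
    return PositionalProfile(edges, observed.astype(np.int64), expected)


def positional_binomial_test(profile: PositionalProfile,
                             alpha: float = 0.01) -> PositionalProfile:
    """Per-bin binomial enrichment test with Bonferroni correction.

    For each bin, p = upper tail of Binomial(n, 1/n_bins) at the
    observed count; a bin is flagged iff p < alpha / n_bins (family
    level ``alpha``).
    """
    n = int(profile.observed.sum())
    k = profile.n_bins
    if n == 0:
        profile.p_values = np.ones(k)
        profile.significant = np.zeros(k, dtype=bool)
        return profile
    p = sps.binom.sf(profile.observed - 1, n, 1.0 / k)
    profile.p_values = p
    profile.significant = p < alpha / k
    return profile


def target_window_interval(gene: GeneModel, width: int) -> tuple[int, int]:
    """Genomic interval of the ``width`` bp immediately 5' of the TSS."""
    if gene.strand == "+":
        return max(0, gene.tss - width), gene.tss
    return gene.tss + 1, gene.tss + 1 + width


def candidate_targets(regions_by_condition: dict[str, list[BindingRegion]],
                      genes: list[GeneModel], config: PipelineConfig) -> set[str]:
    """Genes with a binding region overlapping their 400-bp upstream window.

    Overlap is interval overlap (>= 1 bp) with the strand-aware window;
    the set is the union over conditions, each gene counted once.
    """
    regions_per_chrom: dict[str, list[tuple[int, int]]] = {}
    for regions in regions_by_condition.values():
        for r in regions:
            regions_per_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out: set[str] = set()
    for g in genes:
        lo, hi = target_window_interval(g, config.target_window)
        for rs, re in regions_per_chrom.get(g.chrom, ()):
            if rs < hi and re > lo:
                out.add(g.gene_id)
                break
    return out


def nearest_upstream_region(gene: GeneModel, regions: list[BindingRegion],
                            config: PipelineConfig) -> tuple[list[BindingRegion], float | None]:
    """Supporting regions overlapping the gene's target window and the
    signed TSS distance of the nearest one (for target reporting)."""
    lo, hi = target_window_interval(gene, config.target_window)
    support = [r for r in regions
               if r.chrom == gene.chrom and r.start < hi and r.end > lo]
    if not support:
        return [], None
    dists = [_signed_tss_distance(r.midpoint, gene) for r in support]
    return support, float(min(dists, key=abs))
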