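"""Seeded synthetic genomes, reads and expression matrices with ground truth.

The generator emulates the structure of a TF ChIP-seq / expression
study: a genome carrying non-overlapping genes on both strands; binding
sites concentrated in the 400-bp windows immediately upstream of TSSs
plus a large intergenic fraction, each site optionally carrying copies
of a 6-bp recognition word; ChIP fragments (~350 bp, sequenced as one
100-bp read each) enriched over sites with the canonical plus/minus
strand offset; uniform input reads; and a WT-vs-overexpressor log2
expression matrix at 0/6/24 h in which bound genes carry a planted fold
change.

Every operation is a pure function of (params, seed, condition,
replicate): identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationParams
from .types import GeneModel, ReadSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_MAX_PLACEMENT_TRIES = 1_000


class SizingError(ValueError):
    """Requested genes/sites cannot be placed on a genome this small."""


@dataclass(frozen=True)
class PlantedSite:
    """One planted binding site and its per-condition activity flags."""

    chrom: str
    position: int  # 0-based anchor (center of ChIP enrichment)
    active: tuple[bool, ...]  # aligned with params.conditions
    word_starts: tuple[int, ...] = ()  # forward-strand starts of planted words


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    sites: list[PlantedSite] = field(default_factory=list)
    bound_genes: dict[str, int] = field(default_factory=dict)  # gene_id -> site index
    de_genes: dict[str, str] = field(default_factory=dict)  # gene_id -> "up" | "down"

    def active_sites(self, condition_index: int) -> list[PlantedSite]:
        return [s for s in self.sites if s.active[condition_index]]


def chromosome_lengths(params: SimulationParams) -> dict[str, int]:
    """Split the genome into near-equal chromosomes chr1..chrN."""
    n = params.n_chromosomes
    base, extra = divmod(params.genome_length, n)
    return {f"chr{i + 1}": base + (1 if i < extra else 0) for i in range(n)}


def _place_genes(rng: np.random.Generator, params: SimulationParams,
                 chrom_lengths: dict[str, int]) -> list[GeneModel]:
    """Non-overlapping genes with >= min_gap spacing, both strands present."""
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    # distribute gene counts proportionally to chromosome length
    counts = {c: int(round(params.n_genes * chrom_lengths[c] / total)) for c in chroms}
    drift = params.n_genes - sum(counts.values())
    counts[chroms[0]] += drift
    min_gap = 1_000  # leaves room for upstream site placement between genes
    genes: list[GeneModel] = []
    idx = 0
    for chrom in chroms:
        n_c = counts[chrom]
        if n_c == 0:
            continue
        length_c = chrom_lengths[chrom]
        lengths = np.maximum(
            200, np.round(rng.normal(params.gene_length_mean, params.gene_length_mean / 4, n_c))
        ).astype(int)
        free = length_c - int(lengths.sum()) - min_gap * (n_c + 1)
        if free < 0:
            raise SizingError(
                f"cannot place {n_c} genes of mean length {params.gene_length_mean} "
                f"on {chrom} ({length_c} bp) with {min_gap}-bp gaps"
            )
        gaps = rng.multinomial(free, np.full(n_c + 1, 1 / (n_c + 1)))
        pos = 0
        strands = rng.choice(["+", "-"], size=n_c)
        for i in range(n_c):
            pos += min_gap + int(gaps[i])
            start, end = pos, pos + int(lengths[i])
            genes.append(GeneModel(f"gene{idx:04d}", chrom, start, end, str(strands[i])))
            pos = end
            idx += 1
    # guarantee both strands appear
    present = {g.strand for g in genes}
    if len(genes) >= 2 and len(present) == 1:
        g = genes[0]
        flipped = "-" if g.strand == "+" else "+"
        genes[0] = GeneModel(g.gene_id, g.chrom, g.start, g.end, flipped)
    return genes


def _upstream_interval(gene: GeneModel, width: int) -> tuple[int, int]:
    """Genomic interval covering `width` bp immediately 5' of the TSS."""
    if gene.strand == "+":
        return max(0, gene.tss - width), gene.tss
    return gene.tss + 1, gene.tss + 1 + width


def _word_positions(position: int, strand_of_gene: str, params: SimulationParams) -> tuple[int, ...]:
    """Forward-strand starts for the planted word copies around a site anchor."""
    k = len(params.site_word)
    if params.words_per_site == 0:
        return ()
    if params.words_per_site == 1:
        return (position - k // 2,)
    # two copies separated by a 10-bp spacer, roughly centered on the anchor
    return (position - k - 5, position + 5)


def simulate_genome(params: SimulationParams):
    """Build the genome, gene models and planted sites.

    Returns ``(genome, genes, truth)`` where ``genome`` maps chromosome
    name to an uppercase A/C/G/T string.  Site placement honours the
    requested compartment fractions: ``frac_sites_upstream400`` of the
    sites fall within 400 bp upstream of a TSS (each such gene is then a
    ground-truth bound gene), ``frac_sites_intergenic`` fall outside
    every gene and its 2-kbp flanks, and the remainder fall inside gene
    bodies.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    chrom_lengths = chromosome_lengths(params)
    seqs = {c: rng.integers(0, 4, size=length) for c, length in chrom_lengths.items()}
    genes = _place_genes(rng, params, chrom_lengths)

    n_up = int(round(params.site_count * params.frac_sites_upstream400))
    n_inter = int(round(params.site_count * params.frac_sites_intergenic))
    n_inter = min(n_inter, params.site_count - n_up)
    n_body = params.site_count - n_up - n_inter

    k = len(params.site_word)
    margin = 2 * k + 20  # keep planted words clear of chromosome ends

    sites: list[tuple[str, int]] = []
    bound: dict[str, int] = {}

    # --- sites within 400 bp upstream of a TSS -------------------------
    if n_up > 0:
        eligible = [
            g for g in genes
            if _upstream_interval(g, 400)[0] >= margin
            and _upstream_interval(g, 400)[1] <= chrom_lengths[g.chrom] - margin
        ]
        if len(eligible) < n_up:
            raise SizingError(f"only {len(eligible)} genes can host upstream sites, need {n_up}")
        chosen = rng.choice(len(eligible), size=n_up, replace=False)
        for gi in chosen:
            g = eligible[gi]
            offset = int(rng.integers(margin, 390))  # site anchor within (margin, 390) bp of TSS
            pos = g.tss - offset if g.strand == "+" else g.tss + offset
            sites.append((g.chrom, pos))

    # --- intergenic sites ---------------------------------------------
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in genes:
        forbidden[g.chrom].append((max(0, g.start - 2_000), g.end + 2_000))
    for _ in range(n_inter):
        for _try in range(_MAX_PLACEMENT_TRIES):
            chrom = str(rng.choice(list(chrom_lengths)))
            pos = int(rng.integers(margin, chrom_lengths[chrom] - margin))
            if not any(a <= pos < b for a, b in forbidden[chrom]):
                sites.append((chrom, pos))
                break
        else:
            raise SizingError(
                "could not place an intergenic site clear of all gene flanks; "
                "genome too small for the requested gene density"
            )

    # --- gene-body sites ----------------------------------------------
    if n_body > 0:
        hosts = [g for g in genes if len(range(g.start + 450, g.end - 450)) > 0] or genes
        chosen = rng.choice(len(hosts), size=n_body, replace=True)
        for gi in chosen:
            g = hosts[gi]
            lo = max(g.start + margin, g.start + 450)
            hi = min(g.end - margin, g.end - 450)
            if hi <= lo:
                lo, hi = g.start + margin, g.end - margin
            sites.append((g.chrom, int(rng.integers(lo, hi))))

    # --- plant words, assign activity, resolve bound genes -------------
    site_records: list[PlantedSite] = []
    word_codes = np.frombuffer(params.site_word.encode(), dtype="S1")
    word_ints = np.array([b"ACGT".index(c) for c in word_codes], dtype=seqs[next(iter(seqs))].dtype)
    n_cond = len(params.conditions)
    for chrom, pos in sites:
        starts = _word_positions(pos, "+", params)
        for s in starts:
            if s < 0 or s + k > chrom_lengths[chrom]:
                raise SizingError("planted word extends beyond chromosome bounds")
            seqs[chrom][s:s + k] = word_ints
        if n_cond == 1:
            active = (True,)
        elif rng.random() < params.frac_sites_both_active:
            active = tuple(True for _ in range(n_cond))
        else:
            only = int(rng.integers(0, n_cond))
            active = tuple(i == only for i in range(n_cond))
        site_records.append(PlantedSite(chrom, pos, active, tuple(int(s) for s in starts)))

    # bound genes are determined by final geometry, not placement intent
    for si, site in enumerate(site_records):
        for g in genes:
            if g.chrom != site.chrom:
                continue
            lo, hi = _upstream_interval(g, 400)
            if lo <= site.position < hi:
                bound.setdefault(g.gene_id, si)

    truth = GroundTruth(sites=site_records, bound_genes=bound)

    # planted DE: every bound gene responds; a few unbound decoys respond too
    directions = rng.random(len(bound))
    for (gene_id, _), u in zip(sorted(bound.items()), directions):
        truth.de_genes[gene_id] = "down" if u < params.frac_de_down else "up"
    unbound = [g.gene_id for g in genes if g.gene_id not in bound]
    n_decoy = min(params.n_decoy_de_genes, len(unbound))
    if n_decoy > 0:
        for gi in rng.choice(len(unbound), size=n_decoy, replace=False):
            truth.de_genes[unbound[gi]] = "down" if rng.random() < params.frac_de_down else "up"

    genome = {c: _BASES[v].tobytes().decode() for c, v in seqs.items()}
    return genome, genes, truth


def _condition_index(params: SimulationParams, condition: str) -> int:
    try:
        return params.conditions.index(condition)
    except ValueError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {params.conditions}"
        ) from None


def simulate_chip_reads(genome: dict[str, str], truth: GroundTruth,
                        params: SimulationParams, condition: str, replicate: int) -> ReadSet:
    """One ChIP library: site-enriched fragments plus uniform background.

    A fragment is site-derived with probability
    ``n_active * fragment_length * (E - 1) / (L + n_active * fragment_length * (E - 1))``
    so that coverage over a site footprint is ~E-fold the uniform
    background rate (E = ``enrichment_factor``; at E = 1 the library is
    exactly uniform).  Site fragments center on the site with uniform
    jitter up to half a fragment.  Each fragment yields a single read:
    with probability 1/2 a plus-strand read at the fragment start, else
    a minus-strand read ending at the fragment end -- which produces the
    plus/minus strand offset flanking true sites.
    """
    ci = _condition_index(params, condition)
    if not 1 <= replicate <= params.n_replicates:
        raise ValueError(f"replicate must be in 1..{params.n_replicates}")
    rng = np.random.default_rng([params.seed, 101, ci, replicate])
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    active = truth.active_sites(ci)
    return _simulate_fragments(rng, chrom_lengths, active, params, params.n_chip_reads,
                               params.enrichment_factor)


def simulate_input_reads(genome: dict[str, str], params: SimulationParams,
                         replicate: int) -> ReadSet:
    """One input (non-immunoprecipitated) library: uniform starts, random strands."""
    if not 1 <= replicate <= params.n_replicates:
        raise ValueError(f"replicate must be in 1..{params.n_replicates}")
    rng = np.random.default_rng([params.seed, 202, replicate])
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    return _simulate_fragments(rng, chrom_lengths, [], params, params.n_input_reads, 1.0)


def _simulate_fragments(rng: np.random.Generator, chrom_lengths: dict[str, int],
                        active_sites: list[PlantedSite], params: SimulationParams,
                        n_reads: int, enrichment: float) -> ReadSet:
    if n_reads == 0:
        return ReadSet.empty()
    frag, rl = params.fragment_length, params.read_length
    L = sum(chrom_lengths.values())
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)

    w_sites = len(active_sites) * frag * max(0.0, enrichment - 1.0)
    p_site = w_sites / (L + w_sites) if w_sites > 0 else 0.0
    n_site = rng.binomial(n_reads, p_site) if p_site > 0 else 0
    n_bg = n_reads - n_site

    out_chrom = np.empty(n_reads, dtype=object)
    frag_start = np.empty(n_reads, dtype=np.int64)

    if n_site > 0:
        site_idx = rng.integers(0, len(active_sites), size=n_site)
        centers = np.array([s.position for s in active_sites], dtype=np.int64)[site_idx]
        site_chrom = np.array([s.chrom for s in active_sites], dtype=object)[site_idx]
        jitter = rng.integers(-(frag // 2), frag // 2 + 1, size=n_site)
        fs = centers + jitter - frag // 2
        lens = np.array([chrom_lengths[c] for c in site_chrom], dtype=np.int64)
        fs = np.clip(fs, 0, lens - frag)
        out_chrom[:n_site] = site_chrom
        frag_start[:n_site] = fs
    if n_bg > 0:
        ci = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
        lens = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)[ci]
        fs = (rng.random(n_bg) * (lens - frag)).astype(np.int64)
        out_chrom[n_site:] = np.array(chroms, dtype=object)[ci]
        frag_start[n_site:] = fs

    reverse = rng.random(n_reads) < 0.5
    starts = np.where(reverse, frag_start + frag - rl, frag_start)
    return ReadSet(out_chrom, starts, np.full(n_reads, rl, dtype=np.int64), reverse)


def sample_name(genotype: str, time: int, replicate: int) -> str:
    return f"{genotype}.{time}.{replicate}"


def simulate_expression(gene_models: list[GeneModel], truth: GroundTruth,
                        params: SimulationParams) -> pd.DataFrame:
    """Log2 expression matrix for a WT-vs-overexpressor time course.

    Rows are genes, columns ``genotype.time.replicate`` samples
    (genotype in {WT, OX}).  Each value is gene baseline + a shared
    per-gene time trajectory + the planted genotype effect
    (log2(de_fold), signed per planted direction, applied to OX samples
    of ground-truth DE genes) + Normal(0, noise_sd) noise.
    """
    if params.de_fold < 1:
        raise ValueError("de_fold must be >= 1")
    rng = np.random.default_rng([params.seed, 303])
    genes = [g.gene_id for g in gene_models]
    n_genes = len(genes)
    times = list(params.timepoints)
    reps = range(1, params.n_expression_replicates + 1)
    cols = [sample_name(g, t, r) for g in ("WT", "OX") for t in times for r in reps]

    baseline = rng.normal(8.0, 1.0, size=n_genes)
    # per-gene elicitor-response trajectory, shared between genotypes
    time_effect = rng.normal(0.0, 0.75, size=(n_genes, len(times)))
    time_effect[:, 0] = 0.0

    effect = np.zeros(n_genes)
    log_fold = math.log2(params.de_fold)
    for i, gid in enumerate(genes):
        direction = truth.de_genes.get(gid)
        if direction == "up":
            effect[i] = log_fold
        elif direction == "down":
            effect[i] = -log_fold

    values = np.empty((n_genes, len(cols)))
    j = 0
    for genotype in ("WT", "OX"):
        for ti in range(len(times)):
            for _r in reps:
                mu = baseline + time_effect[:, ti]
                if genotype == "OX":
                    mu = mu + effect
                values[:, j] = mu
                j += 1
    values += rng.normal(0.0, params.noise_sd, size=values.shape)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols)
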