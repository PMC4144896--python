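"""Binding-region detection from windowed read counts.

Detection applies three criteria to 100-bp tiles and their merged runs:

* window enrichment over a uniform-background binomial null at
  FDR < 0.001 (``peak_fdr``),
* window enrichment of ChIP over the input control, via the binomial
  split of chip vs. input counts, at FDR < 0.05
  (``input_enrichment_fdr``),
* a plus/minus strand-separation permutation test on the merged
  region's reads at FDR < 0.05 (``strand_sep_fdr``).

Regions surviving all three in both biological replicates (replicate
intersection) are the reported binding regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .stats import benjamini_hochberg
from .types import BindingRegion, ReadSet

WINDOW_COLUMNS = ["chrom", "window_index", "chip_count", "input_count",
                  "p_peak", "q_peak", "p_input", "q_input"]


def tile_counts(reads: ReadSet, chrom_lengths: dict[str, int], window_size: int) -> dict[str, np.ndarray]:
    """Count read 5' starts in non-overlapping ``window_size`` tiles.

    Returns per-chromosome count vectors; each read lands in exactly one
    tile so the tile counts sum to the number of reads.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    out: dict[str, np.ndarray] = {}
    five = reads.five_prime
    for chrom, length in chrom_lengths.items():
        n_tiles = -(-length // window_size)
        mask = reads.chroms == chrom
        pos = five[mask]
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            bad = pos[(pos < 0) | (pos >= length)][0]
            raise ValueError(f"read 5' position {bad} outside {chrom} (length {length})")
        out[chrom] = np.bincount(pos // window_size, minlength=n_tiles).astype(np.int64)
    stray = set(np.unique(reads.chroms)) - set(chrom_lengths)
    if stray:
        raise ValueError(f"reads on unknown chromosomes: {sorted(stray)}")
    return out


def window_table(chip_tiles: dict[str, np.ndarray], input_tiles: dict[str, np.ndarray]) -> pd.DataFrame:
    """Assemble the per-window statistics table from tiled counts."""
    frames = []
    for chrom in chip_tiles:
        chip = chip_tiles[chrom]
        inp = input_tiles.get(chrom, np.zeros_like(chip))
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "window_index": np.arange(len(chip)),
            "chip_count": chip,
            "input_count": inp[: len(chip)],
        }))
    df = pd.concat(frames, ignore_index=True)
    for col in ("p_peak", "q_peak", "p_input", "q_input"):
        df[col] = np.nan
    return df


def window_pvalues(stats: pd.DataFrame, chip_total: int, input_total: int,
                   genome_length: int, window_size: int) -> pd.DataFrame:
    """Fill the two one-sided binomial p-values per window.

    ``p_peak``: upper tail of Binomial(chip_total, w/L) at the observed
    chip count (uniform-background null).  ``p_input``: upper tail of
    Binomial(chip + input', chip_total/(chip_total + input_total)) at
    the chip count, where input' carries one pseudocount — the
    two-sample binomial split, which absorbs library-size differences
    without fractional counts.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    df = stats.copy()
    chip = df["chip_count"].to_numpy(dtype=np.int64)
    inp = df["input_count"].to_numpy(dtype=np.int64) + 1  # pseudocount
    p_bg = min(1.0, window_size / genome_length)
    # upper tail P(X >= chip) = sf(chip - 1)
    df["p_peak"] = sps.binom.sf(chip - 1, chip_total, p_bg)
    split = chip_total / (chip_total + input_total)
    df["p_input"] = sps.binom.sf(chip - 1, chip + inp, split)
    df["q_peak"] = benjamini_hochberg(df["p_peak"].to_numpy())
    df["q_input"] = benjamini_hochberg(df["p_input"].to_numpy())
    return df


def strand_separation_test(plus_pos: np.ndarray, minus_pos: np.ndarray,
                           rng: np.random.Generator, n_permutations: int = 1_000
                           ) -> tuple[float, float]:
    """Permutation test for the plus-upstream-of-minus read offset.

    Statistic: mean(minus 5' positions) - mean(plus 5' positions); the
    correct orientation around a protein-bound site is positive.  The
    one-sided p-value is the add-one permutation estimate over shuffled
    strand labels.  A region with either strand absent gets p = 1 by
    convention.
    """
    plus_pos = np.asarray(plus_pos, dtype=float)
    minus_pos = np.asarray(minus_pos, dtype=float)
    n_p, n_m = plus_pos.size, minus_pos.size
    if n_p == 0 or n_m == 0:
        return float("nan"), 1.0
    observed = minus_pos.mean() - plus_pos.mean()
    pos = np.concatenate([plus_pos, minus_pos])
    total = pos.sum()
    n = n_p + n_m
    # permute labels: draw n_p positions for the plus group each round
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n_p]
    plus_sums = pos[idx].sum(axis=1)
    stat = (total - plus_sums) / n_m - plus_sums / n_p
    p = (1 + int(np.sum(stat >= observed))) / (n_permutations + 1)
    return float(observed), float(p)


def _merge_windows(sig: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Merge indices of significant tiles into runs, bridging <= merge_gap gaps."""
    if sig.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(sig[0])
    for w in sig[1:]:
        w = int(w)
        if w - prev - 1 <= merge_gap:
            prev = w
        else:
            runs.append((start, prev))
            start = prev = w
    runs.append((start, prev))
    return runs


def call_regions(stats: pd.DataFrame, reads: ReadSet, config: PipelineConfig,
                 seed: int = 0, condition: str = "") -> list[BindingRegion]:
    """Merge significant windows and screen by strand separation.

    Windows passing both ``q_peak < peak_fdr`` and
    ``q_input < input_enrichment_fdr`` are merged when adjacent; each
    merged region is then tested for strand separation, with BH across
    regions at ``strand_sep_fdr``.  Survivors are returned sorted by
    coordinate.
    """
    if stats["q_peak"].isna().any():
        raise ValueError("window p/q-values must be computed before call_regions")
    rng = np.random.default_rng([seed, 404])
    w = config.window_size
    candidates: list[BindingRegion] = []
    five = reads.five_prime
    strands_rev = reads.reverse
    for chrom, sub in stats.groupby("chrom", sort=True):
        keep = sub[(sub["q_peak"] < config.peak_fdr) & (sub["q_input"] < config.input_enrichment_fdr)]
        if keep.empty:
            continue
        by_idx = keep.set_index("window_index")
        on_chrom = reads.chroms == chrom
        for first, last in _merge_windows(keep["window_index"].to_numpy(), config.merge_gap):
            start, end = first * w, (last + 1) * w
            in_region = on_chrom & (five >= start) & (five < end)
            plus = five[in_region & ~strands_rev]
            minus = five[in_region & strands_rev]
            sep, p = strand_separation_test(plus, minus, rng, config.n_permutations)
            block = by_idx.loc[first:last]
            region = BindingRegion(
                chrom=str(chrom), start=start, end=end, condition=condition,
                q_peak=float(block["q_peak"].min()),
                q_input=float(block["q_input"].min()),
                strand_sep_bp=sep,
            )
            region.strand_sep_q = p  # temporarily store raw p; BH below
            candidates.append(region)
    if not candidates:
        return []
    qs = benjamini_hochberg([r.strand_sep_q for r in candidates])
    out = []
    for region, q in zip(candidates, qs):
        if q < config.strand_sep_fdr:
            region.strand_sep_q = float(q)
            out.append(region)
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def intersect_replicates(regions_rep1: list[BindingRegion],
                         regions_rep2: list[BindingRegion]) -> list[BindingRegion]:
    """Regions reproducible across biological replicates.

    Returns the pieces of replicate-1 regions covered by replicate-2
    regions (>= 1 bp overlap), trimmed to the overlap, carrying the
    replicate-1 statistics and both-supported flags.  Swapping the
    arguments yields the same genomic base coverage.
    """
    by_chrom: dict[str, list[BindingRegion]] = {}
    for r in regions_rep2:
        by_chrom.setdefault(r.chrom, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)
    out: list[BindingRegion] = []
    for r1 in sorted(regions_rep1, key=lambda r: (r.chrom, r.start)):
        pieces: list[tuple[int, int]] = []
        for r2 in by_chrom.get(r1.chrom, []):
            lo, hi = max(r1.start, r2.start), min(r1.end, r2.end)
            if lo < hi:
                pieces.append((lo, hi))
        # merge touching/overlapping pieces into the overlap union
        pieces.sort()
        merged: list[list[int]] = []
        for lo, hi in pieces:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            out.append(BindingRegion(
                chrom=r1.chrom, start=lo, end=hi, condition=r1.condition,
                q_peak=r1.q_peak, q_input=r1.q_input,
                strand_sep_q=r1.strand_sep_q, strand_sep_bp=r1.strand_sep_bp,
                support=(True, True),
            ))
    return out


def detect_binding_regions(chip_by_rep: list[ReadSet], input_by_rep: list[ReadSet],
                           chrom_lengths: dict[str, int], config: PipelineConfig,
                           condition: str = "", seed: int = 0) -> list[BindingRegion]:
    """Per-replicate three-criteria calling followed by replicate intersection."""
    if len(chip_by_rep) != len(input_by_rep):
        raise ValueError("need matching ChIP and input replicate lists")
    genome_length = sum(chrom_lengths.values())
    per_rep: list[list[BindingRegion]] = []
    for rep, (chip, inp) in enumerate(zip(chip_by_rep, input_by_rep), start=1):
        chip_tiles = tile_counts(chip, chrom_lengths, config.window_size)
        input_tiles = tile_counts(inp, chrom_lengths, config.window_size)
        table = window_table(chip_tiles, input_tiles)
        table = window_pvalues(table, len(chip), len(inp), genome_length, config.window_size)
        per_rep.append(call_regions(table, chip, config, seed=seed + rep, condition=condition))
    regions = per_rep[0]
    for other in per_rep[1:]:
        regions = intersect_replicates(regions, other)
    return regions
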