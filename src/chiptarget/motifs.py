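"""Word scanning, enrichment in binding regions, and Gibbs motif discovery.

The recognition word of TGA-type bZIP factors (TGACGT, the as-1-like
element) is scanned exhaustively on both strands; its density inside
binding regions is compared with the rest of the genome as a fold
enrichment; and motifs are discovered de novo from region sequences
with a classic one-site-per-sequence Gibbs site sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import BindingRegion

_COMP = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class WordHit:
    """An exact word match; ``position`` is the forward-strand start."""

    chrom: str
    position: int
    strand: str


def _scan_forward(seq: str, word: str) -> list[int]:
    """All (overlapping) start positions of ``word`` in ``seq``."""
    hits = []
    i = seq.find(word)
    while i != -1:
        hits.append(i)
        i = seq.find(word, i + 1)
    return hits


def scan_word(genome: dict[str, str], word: str) -> list[WordHit]:
    """Exhaustive double-strand scan for an exact word.

    A minus-strand hit at position i means the reverse complement of
    the genome substring [i, i+k) equals the word.  Overlapping matches
    are all reported; a palindromic word yields one hit per strand.
    Ambiguity codes in the genome never match.
    """
    if not word or set(word) - set("ACGT"):
        raise ValueError(f"word must be a non-empty A/C/G/T string, got {word!r}")
    rc = reverse_complement(word)
    hits: list[WordHit] = []
    for chrom in genome:
        seq = genome[chrom].upper()
        for pos in _scan_forward(seq, word):
            hits.append(WordHit(chrom, pos, "+"))
        for pos in _scan_forward(seq, rc):
            hits.append(WordHit(chrom, pos, "-"))
    hits.sort(key=lambda h: (h.chrom, h.position, h.strand))
    return hits


def _merged_region_spans(regions: list[BindingRegion]) -> dict[str, np.ndarray]:
    """Per-chromosome sorted, merged [start, end) boundary arrays."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        per_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out: dict[str, np.ndarray] = {}
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        merged: list[list[int]] = []
        for lo, hi in ivals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        out[chrom] = np.array(merged, dtype=np.int64).reshape(-1, 2)
    return out


def word_fold_enrichment(hits: list[WordHit], regions: list[BindingRegion],
                         genome_length: int) -> float:
    """Hit-rate ratio, binding regions vs. the rest of the genome.

    fold = (hits inside / bp inside) / (hits outside / bp outside),
    attributing each hit by its start position.  Returns ``inf`` when
    hits occur inside but none outside.
    """
    spans = _merged_region_spans(regions)
    bp_in = int(sum((s[:, 1] - s[:, 0]).sum() for s in spans.values()))
    if bp_in == 0:
        raise ValueError("regions must cover at least one base pair")
    if bp_in >= genome_length:
        raise ValueError("region span must be smaller than the genome")
    n_in = 0
    for h in hits:
        s = spans.get(h.chrom)
        if s is None:
            continue
        j = np.searchsorted(s[:, 0], h.position, side="right") - 1
        if j >= 0 and h.position < s[j, 1]:
            n_in += 1
    n_out = len(hits) - n_in
    bp_out = genome_length - bp_in
    rate_in = n_in / bp_in
    rate_out = n_out / bp_out
    if rate_out == 0:
        return float("inf") if rate_in > 0 else float("nan")
    return rate_in / rate_out


def word_positional_profile(hits: list[WordHit], regions: list[BindingRegion],
                            flank: int, bin_size: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of hit offsets from the nearest region midpoint.

    Returns ``(bin_edges, counts)`` over [-flank, +flank]; a hit
    contributes iff its offset from the nearest midpoint is within the
    flank.
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    edges = np.arange(-flank, flank + 1, bin_size)
    mids: dict[str, np.ndarray] = {}
    for r in regions:
        mids.setdefault(r.chrom, [])
    for r in regions:
        mids[r.chrom].append(r.midpoint)
    mids = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}
    offsets = []
    for h in hits:
        m = mids.get(h.chrom)
        if m is None or m.size == 0:
            continue
        j = np.searchsorted(m, h.position)
        best = None
        for jj in (j - 1, j):
            if 0 <= jj < m.size:
                d = h.position - int(m[jj])
                if best is None or abs(d) < abs(best):
                    best = d
        if best is not None and -flank <= best <= flank:
            offsets.append(min(best, flank - 1) if best == flank else best)
    counts, _ = np.histogram(offsets, bins=edges)
    return edges, counts.astype(np.int64)


@dataclass
class MotifModel:
    """A position-probability matrix with the sites that produced it."""

    width: int
    matrix: np.ndarray  # width x 4, rows sum to 1, pseudocounted
    background: np.ndarray  # length 4
    sites: list[tuple[int, int, str]] = field(default_factory=list)  # (seq index, offset, strand)
    information_content: float = 0.0

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()


_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i


def _information_content(matrix: np.ndarray, background: np.ndarray) -> float:
    return float(np.sum(matrix * np.log2(matrix / background)))


def _count_matrix(codes: list[np.ndarray], rc_codes: list[np.ndarray],
                  sites: np.ndarray, strands: np.ndarray, width: int,
                  skip: int = -1) -> np.ndarray:
    counts = np.zeros((width, 4))
    for i, (c, rc) in enumerate(zip(codes, rc_codes)):
        if i == skip:
            continue
        src = rc if strands[i] else c
        window = src[sites[i]: sites[i] + width]
        counts[np.arange(width), window] += 1
    return counts


def gibbs_motif_search(sequences: list[str], width: int, iterations: int = 200,
                       seed: int = 0, pseudocount: float = 0.5) -> MotifModel:
    """Classic one-site-per-sequence Gibbs site sampler, both strands.

    One site per sequence is initialised at random; each sweep holds out
    one sequence, rebuilds the pseudocounted probability matrix from the
    remaining sites, and resamples the held-out site (over all offsets
    and both strands) proportionally to the matrix/background likelihood
    ratio.  The highest-information-content state visited across all
    sweeps is returned.  Deterministic under a fixed seed.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    for i, s in enumerate(sequences):
        if len(s) < width:
            raise ValueError(f"sequence {i} shorter than motif width {width}")
    rng = np.random.default_rng(seed)
    codes = [_CODE[_encode(s)].astype(np.int64) for s in sequences]
    rc_codes = [(3 - c)[::-1].copy() for c in codes]
    n = len(codes)
    lengths = np.array([len(c) for c in codes])

    all_counts = np.zeros(4)
    for c in codes:
        all_counts += np.bincount(c, minlength=4)
    background = (all_counts + 1) / (all_counts.sum() + 4)

    sites = np.array([rng.integers(0, L - width + 1) for L in lengths])
    strands = rng.random(n) < 0.5

    def site_window(i: int) -> np.ndarray:
        src = rc_codes[i] if strands[i] else codes[i]
        return src[sites[i]: sites[i] + width]

    counts = _count_matrix(codes, rc_codes, sites, strands, width)
    cols = np.arange(width)

    def normalized(c: np.ndarray) -> np.ndarray:
        m = c + pseudocount
        return m / m.sum(axis=1, keepdims=True)

    best_ic = _information_content(normalized(counts), background)
    best_sites, best_strands = sites.copy(), strands.copy()

    log_bg = np.log(background)
    # precompute sliding windows of every sequence once
    fwd_windows = [np.lib.stride_tricks.sliding_window_view(c, width) for c in codes]
    rev_windows = [np.lib.stride_tricks.sliding_window_view(rc, width) for rc in rc_codes]
    for _sweep in range(iterations):
        for i in range(n):
            counts[cols, site_window(i)] -= 1  # leave one out
            log_ratio = np.log(normalized(counts)) - log_bg  # width x 4
            s_fwd = log_ratio[cols, fwd_windows[i]].sum(axis=1)
            s_rev = log_ratio[cols, rev_windows[i]].sum(axis=1)
            flat = np.concatenate([s_fwd, s_rev])
            w = np.exp(flat - flat.max())
            w /= w.sum()
            pick = rng.choice(flat.size, p=w)
            n_off = lengths[i] - width + 1
            strands[i] = pick >= n_off
            sites[i] = pick - n_off if strands[i] else pick
            counts[cols, site_window(i)] += 1
        # phase-shift move: slide every site by the same offset if that
        # raises the information content (escapes shifted local optima)
        best_shift, best_shift_ic = 0, _information_content(normalized(counts), background)
        for d in (-2, -1, 1, 2):
            shifted = sites + d
            ok = np.all((shifted >= 0) & (shifted <= lengths - width))
            if not ok:
                continue
            c = np.zeros((width, 4))
            for i in range(n):
                src = rc_codes[i] if strands[i] else codes[i]
                c[cols, src[shifted[i]: shifted[i] + width]] += 1
            ic_d = _information_content(normalized(c), background)
            if ic_d > best_shift_ic:
                best_shift, best_shift_ic = d, ic_d
        if best_shift != 0:
            sites = sites + best_shift
            counts = _count_matrix(codes, rc_codes, sites, strands, width)
        ic = _information_content(normalized(counts), background)
        if ic > best_ic:
            best_ic = ic
            best_sites, best_strands = sites.copy(), strands.copy()

    sites, strands = best_sites, best_strands
    matrix = np.zeros((width, 4))
    counts = _count_matrix(codes, rc_codes, sites, strands, width)
    matrix = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
    site_list = []
    for i in range(n):
        if strands[i]:
            # offset on the forward sequence of the reverse-complement window
            fwd_off = int(lengths[i] - width - sites[i])
            site_list.append((i, fwd_off, "-"))
        else:
            site_list.append((i, int(sites[i]), "+"))
    return MotifModel(width, matrix, background, site_list,
                      _information_content(matrix, background))


def known_motif_table(genome: dict[str, str], regions: list[BindingRegion],
                      words: list[str]) -> list[tuple[str, float]]:
    """Fold enrichment for each word, sorted descending by fold."""
    genome_length = sum(len(s) for s in genome.values())
    rows = []
    for word in words:
        hits = scan_word(genome, word)
        rows.append((word, word_fold_enrichment(hits, regions, genome_length)))
    rows.sort(key=lambda t: (-(t[1] if t[1] == t[1] else float("-inf")), t[0]))
    return rows
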