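"""Simulation and pipeline parameter objects, plus YAML loading."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulationParams:
    """Everything the synthetic-data generator needs.

    Defaults describe the study conditions the pipeline is exercised
    under: a 1-Mbp two-chromosome genome with 120 single-transcript
    genes, 20 planted binding sites each carrying two copies of the
    TGACGT word, ~350-bp ChIP fragments sequenced as 100-bp single
    reads at 20-fold site enrichment, two conditions x two replicates,
    and a WT vs. overexpressor expression design at 0/6/24 h with four
    replicates and a planted 4-fold change on bound genes.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    n_genes: int = 120
    gene_length_mean: int = 2_000
    site_count: int = 20
    frac_sites_upstream400: float = 0.5
    frac_sites_intergenic: float = 0.4
    words_per_site: int = 2
    site_word: str = "TGACGT"
    enrichment_factor: float = 20.0
    fragment_length: int = 350
    read_length: int = 100
    n_chip_reads: int = 200_000
    n_input_reads: int = 200_000
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("untreated", "elicited")
    frac_sites_both_active: float = 0.7
    noise_sd: float = 0.1
    de_fold: float = 4.0
    frac_de_down: float = 0.25
    n_decoy_de_genes: int = 5
    n_expression_replicates: int = 4
    timepoints: tuple[int, ...] = (0, 6, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.timepoints = tuple(self.timepoints)
        self.validate()

    def validate(self) -> None:
        if self.frac_sites_upstream400 + self.frac_sites_intergenic > 1 + 1e-12:
            raise ValueError("frac_sites_upstream400 + frac_sites_intergenic must be <= 1")
        if not (0 <= self.frac_sites_upstream400 <= 1 and 0 <= self.frac_sites_intergenic <= 1):
            raise ValueError("site fractions must lie in [0, 1]")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.words_per_site not in (0, 1, 2):
            raise ValueError("words_per_site must be 0, 1 or 2")
        if set(self.site_word) - set("ACGT") or len(self.site_word) < 1:
            raise ValueError("site_word must be a non-empty A/C/G/T string")
        for name in ("genome_length", "n_chromosomes", "n_genes", "gene_length_mean",
                     "fragment_length", "read_length", "n_replicates",
                     "n_expression_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("site_count", "n_chip_reads", "n_input_reads", "n_decoy_de_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.de_fold < 1:
            raise ValueError("de_fold must be >= 1")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition is required")


@dataclass
class PipelineConfig:
    """Analysis thresholds and window geometry.

    The three peak-calling FDR thresholds (0.001 peak, 0.05 input
    enrichment, 0.05 strand separation) and the 100-bp window are the
    binding-region detection criteria; 2-kbp upstream/downstream windows
    and the 400-bp target window drive annotation; the fold-change and
    q-value thresholds drive differential-expression calls.
    """

    window_size: int = 100
    peak_fdr: float = 0.001
    strand_sep_fdr: float = 0.05
    input_enrichment_fdr: float = 0.05
    upstream_window: int = 2_000
    target_window: int = 400
    downstream_window: int = 2_000
    bin_size: int = 100
    positional_alpha: float = 0.01
    fc_threshold: float = 2.0
    de_q: float = 0.05
    motif_word: str = "TGACGT"
    motif_flank: int = 1_000
    merge_gap: int = 0  # max number of non-significant tiles bridged when merging
    n_permutations: int = 1_000

    def __post_init__(self) -> None:
        for name in ("peak_fdr", "strand_sep_fdr", "input_enrichment_fdr",
                     "positional_alpha", "de_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("window_size", "upstream_window", "target_window",
                     "downstream_window", "bin_size", "motif_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.target_window > self.upstream_window:
            raise ValueError("target_window must not exceed upstream_window")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")


def _filter_kwargs(cls, d: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return d


def load_config(path: str | Path) -> tuple[SimulationParams, PipelineConfig]:
    """Read a YAML file with optional ``simulation:`` and ``pipeline:`` blocks."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sim = SimulationParams(**_filter_kwargs(SimulationParams, doc.get("simulation", {}) or {}))
    pipe = PipelineConfig(**_filter_kwargs(PipelineConfig, doc.get("pipeline", {}) or {}))
    return sim, pipe


def config_digest(sim: SimulationParams, pipe: PipelineConfig, seed: int) -> str:
    """Short stable hash of the effective configuration, for output headers."""
    payload = {
        "simulation": dataclasses.asdict(sim),
        "pipeline": dataclasses.asdict(pipe),
        "seed": seed,
    }
    blob = json.dumps(payload, sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
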