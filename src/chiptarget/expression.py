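"""Differential expression for a genotype x time x replicate design.

Genes are called up/down-regulated in the overexpressor (OX) versus
wild type (WT) when a per-gene two-factor fixed-effects ANOVA genotype
main effect passes BH-FDR (q <= de_q) AND the OX-WT log2 fold change
reaches the two-fold threshold (inclusive) at >= 1 time point.
Expression profiles are clustered by average linkage on cosine
distance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .stats import benjamini_hochberg
from .types import DEResult

_SAMPLE_RE = re.compile(r"^(?P<genotype>[A-Za-z0-9]+)\.(?P<time>\d+)\.(?P<rep>\d+)$")

GENOTYPES = ("WT", "OX")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities with the sample design attached.

    ``values`` has genes as the index and ``genotype.time.replicate``
    sample names as columns; ``samples`` carries the parsed design.
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # index = sample name; columns genotype, time, replicate

    @classmethod
    def from_frame(cls, values: pd.DataFrame) -> "ExpressionMatrix":
        rows = []
        for col in values.columns:
            m = _SAMPLE_RE.match(col)
            if not m:
                raise ValueError(
                    f"sample column {col!r} is not of the form genotype.time.replicate")
            rows.append((col, m["genotype"], int(m["time"]), int(m["rep"])))
        samples = pd.DataFrame(rows, columns=["sample", "genotype", "time", "replicate"])
        samples = samples.set_index("sample")
        if values.index.hasnans or values.index.duplicated().any():
            raise ValueError("gene identifiers must be unique and non-missing")
        return cls(values, samples)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def times(self) -> list[int]:
        return sorted(self.samples["time"].unique())

    def cell(self, genotype: str, time: int) -> pd.DataFrame:
        names = self.samples.index[(self.samples["genotype"] == genotype)
                                   & (self.samples["time"] == time)]
        return self.values[names]

    def validate_design(self, min_replicates: int = 2) -> None:
        for g in self.samples["genotype"].unique():
            for t in self.times:
                n = len(self.cell(g, t).columns)
                if n < min_replicates:
                    raise ValueError(
                        f"design cell ({g}, {t} h) has {n} replicates; need >= {min_replicates}")


def _balanced_anova_genotype_f(matrix: ExpressionMatrix) -> np.ndarray:
    """Vectorized two-way fixed-effects ANOVA genotype main-effect p-values.

    Closed form for a balanced genotype x time design with r replicates
    per cell: partition SS into genotype, time, interaction and error;
    F = MS_genotype / MS_error with (a-1, ab(r-1)) df.
    """
    times = matrix.times
    a, b = 2, len(times)
    cells = []
    r = None
    for g in GENOTYPES:
        for t in times:
            cell = matrix.cell(g, t).to_numpy()
            if r is None:
                r = cell.shape[1]
            elif cell.shape[1] != r:
                raise ValueError("unbalanced design")
            cells.append(cell)
    data = np.stack(cells, axis=1)  # genes x (a*b) x r
    n_genes = data.shape[0]
    data = data.reshape(n_genes, a, b, r)
    grand = data.mean(axis=(1, 2, 3))
    cell_mean = data.mean(axis=3)
    geno_mean = data.mean(axis=(2, 3))
    ss_geno = r * b * ((geno_mean - grand[:, None]) ** 2).sum(axis=1)
    ss_err = ((data - cell_mean[..., None]) ** 2).sum(axis=(1, 2, 3))
    df_err = a * b * (r - 1)
    f = (ss_geno / (a - 1)) / (ss_err / df_err)
    return sps.f.sf(f, a - 1, df_err)


def _statsmodels_anova_genotype_p(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene OLS two-way ANOVA fallback for unbalanced designs."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    design = matrix.samples.copy()
    pvals = np.empty(len(matrix.genes))
    for i, gene in enumerate(matrix.genes):
        df = design.assign(y=matrix.values.loc[gene].to_numpy())
        df["time"] = df["time"].astype("category")
        model = ols("y ~ C(genotype) * time", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        pvals[i] = table.loc["C(genotype)", "PR(>F)"]
    return pvals


def per_gene_de(matrix: ExpressionMatrix, config: PipelineConfig) -> list[DEResult]:
    """ANOVA-FDR + fold-change differential-expression calls.

    Fold change at time t is mean(OX, t) - mean(WT, t) in log2 units.
    A gene is called ``up`` iff its BH q-value is <= ``de_q`` and its
    fold change reaches +log2(fc_threshold) (inclusive) at >= 1 time
    point; ``down`` symmetrically.  If both thresholds are reached in
    opposite directions at different times, the direction of the larger
    magnitude wins.
    """
    matrix.validate_design()
    times = matrix.times
    lfc = {}
    for t in times:
        lfc[t] = (matrix.cell("OX", t).mean(axis=1) - matrix.cell("WT", t).mean(axis=1))
    reps = {(g, t): len(matrix.cell(g, t).columns)
            for g in GENOTYPES for t in times}
    balanced = len(set(reps.values())) == 1
    if balanced:
        p = _balanced_anova_genotype_f(matrix)
    else:
        p = _statsmodels_anova_genotype_p(matrix)
    q = benjamini_hochberg(p)
    thr = np.log2(config.fc_threshold)
    results = []
    for i, gene in enumerate(matrix.genes):
        fold = {t: float(lfc[t].loc[gene]) for t in times}
        up_times = tuple(t for t in times if fold[t] >= thr)
        down_times = tuple(t for t in times if fold[t] <= -thr)
        call = "none"
        passing: tuple[int, ...] = ()
        if q[i] <= config.de_q and (up_times or down_times):
            max_up = max((fold[t] for t in up_times), default=float("-inf"))
            max_down = max((-fold[t] for t in down_times), default=float("-inf"))
            if max_up >= max_down:
                call, passing = "up", up_times
            else:
                call, passing = "down", down_times
        results.append(DEResult(str(gene), fold, float(p[i]), float(q[i]), call, passing))
    return results


def relative_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean log2 expression relative to WT at 0 h.

    Columns are ``genotype.time`` cell labels; the WT.0 column is zero
    by construction.
    """
    times = matrix.times
    ref_cols = matrix.cell("WT", 0)
    if ref_cols.shape[1] == 0:
        raise ValueError("design lacks the WT 0 h reference cell")
    ref = ref_cols.mean(axis=1)
    out = {}
    for g in GENOTYPES:
        for t in times:
            cell = matrix.cell(g, t)
            if cell.shape[1] == 0:
                raise ValueError(f"design lacks the ({g}, {t} h) cell")
            out[f"{g}.{t}"] = cell.mean(axis=1) - ref
    return pd.DataFrame(out, index=matrix.genes)


def _cosine_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(profiles, axis=1)
    norms = np.where(norms == 0, 1.0, norms)  # unit pseudo-norm for all-zero profiles
    unit = profiles / norms[:, None]
    d = 1.0 - unit @ unit.T
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def hierarchical_cluster(profiles: pd.DataFrame, n_groups: int
                         ) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage (UPGMA) clustering on cosine-correlation distance.

    Returns the scipy linkage matrix and per-gene group labels
    (1..n_groups) from cutting the tree.  Distances use
    1 - cosine similarity; all-zero profiles are given unit pseudo-norm
    so the distance stays defined.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if n_groups > len(profiles):
        raise ValueError("n_groups cannot exceed the number of profiles")
    d = _cosine_distance_matrix(profiles.to_numpy(dtype=float))
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=n_groups, criterion="maxclust")
    return z, pd.Series(labels, index=profiles.index, name="group")
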