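"""Differential-expression calls, relative expression, clustering."""

import numpy as np
import pandas as pd
import pytest

from chiptarget.config import PipelineConfig, SimulationParams
from chiptarget.expression import (ExpressionMatrix, hierarchical_cluster,
                                   per_gene_de, relative_expression)
from chiptarget.simulate import simulate_expression, simulate_genome


def make_matrix(values_by_gene, times=(0, 6, 24), reps=4):
    """Build an ExpressionMatrix from {gene: {(genotype, time): mean}} + tiny noise."""
    rng = np.random.default_rng(0)
    cols = [f"{g}.{t}.{r}" for g in ("WT", "OX") for t in times for r in range(1, reps + 1)]
    rows = {}
    for gene, means in values_by_gene.items():
        row = []
        for g in ("WT", "OX"):
            for t in times:
                mu = means.get((g, t), 8.0)
                row += list(mu + rng.normal(0, 1e-6, reps))
        rows[gene] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "gene_id"
    return ExpressionMatrix.from_frame(df)


class TestPerGeneDE:
    def test_identical_genotypes_all_none(self, config):
        m = make_matrix({f"g{i}": {} for i in range(10)})
        results = per_gene_de(m, config)
        assert all(r.call == "none" for r in results)
        assert all(abs(fc) < 1e-4 for r in results for fc in r.log2fc.values())

    def test_boundary_fold_change_inclusive(self, config):
        """A gene at exactly two-fold with tiny q is called."""
        m = make_matrix({
            "hit": {("OX", 0): 9.0, ("OX", 6): 9.0, ("OX", 24): 9.0},  # +1.0 log2... below 2x
            "exact": {("OX", 0): 10.0, ("OX", 6): 10.0, ("OX", 24): 10.0},  # exactly +2 log2? no: +2.0
        })
        # "exact" has log2fc = 2.0 >= log2(2) = 1 -> called; "hit" has 1.0 >= 1 -> also called
        results = {r.gene_id: r for r in per_gene_de(m, config)}
        assert results["exact"].call == "up"
        assert results["hit"].call == "up"  # threshold inclusive at log2fc == 1.0

    def test_union_over_time_semantics(self, config):
        m = make_matrix({
            "late": {("OX", 24): 10.0},  # two-fold only at 24 h
            "null": {},
        } | {f"bg{i}": {} for i in range(20)})
        results = {r.gene_id: r for r in per_gene_de(m, config)}
        assert results["late"].call == "up"
        assert results["late"].times_passing == (24,)
        assert results["null"].call == "none"

    def test_down_call_symmetric(self, config):
        m = make_matrix({"dn": {("OX", t): 6.0 for t in (0, 6, 24)}}
                        | {f"bg{i}": {} for i in range(10)})
        results = {r.gene_id: r for r in per_gene_de(m, config)}
        assert results["dn"].call == "down"

    def test_label_swap_antisymmetry(self, config):
        """Swapping OX and WT negates fold changes and swaps calls."""
        p = SimulationParams(genome_length=100_000, n_chromosomes=1, n_genes=30,
                             site_count=4, frac_sites_upstream400=1.0,
                             frac_sites_intergenic=0.0, seed=5)
        _, genes, truth = simulate_genome(p)
        expr = simulate_expression(genes, truth, p)
        m = ExpressionMatrix.from_frame(expr)
        swapped_cols = {c: c.replace("WT.", "TMP.").replace("OX.", "WT.").replace("TMP.", "OX.")
                        for c in expr.columns}
        m_swapped = ExpressionMatrix.from_frame(expr.rename(columns=swapped_cols))
        res = {r.gene_id: r for r in per_gene_de(m, config)}
        res_sw = {r.gene_id: r for r in per_gene_de(m_swapped, config)}
        flip = {"up": "down", "down": "up", "none": "none"}
        for gid in res:
            for t, fc in res[gid].log2fc.items():
                assert res_sw[gid].log2fc[t] == pytest.approx(-fc, abs=1e-9)
            assert res_sw[gid].call == flip[res[gid].call]

    def test_anova_p_matches_statsmodels_oracle(self, config):
        """Vectorized balanced two-way ANOVA equals statsmodels anova_lm."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        p = SimulationParams(genome_length=100_000, n_chromosomes=1, n_genes=20,
                             site_count=3, seed=8)
        _, genes, truth = simulate_genome(p)
        expr = simulate_expression(genes, truth, p)
        m = ExpressionMatrix.from_frame(expr)
        results = {r.gene_id: r for r in per_gene_de(m, config)}
        design = m.samples
        for gene in list(m.genes)[:8]:
            df = design.assign(y=m.values.loc[gene].to_numpy())
            fit = ols("y ~ C(genotype) * C(time)", data=df).fit()
            table = sm.stats.anova_lm(fit, typ=2)
            assert results[gene].p_anova == pytest.approx(
                table.loc["C(genotype)", "PR(>F)"], rel=1e-6, abs=1e-12)

    def test_too_few_replicates_rejected(self, config):
        cols = [f"{g}.{t}.1" for g in ("WT", "OX") for t in (0, 6, 24)]
        df = pd.DataFrame(np.ones((3, 6)), index=["a", "b", "c"], columns=cols)
        with pytest.raises(ValueError, match="replicates"):
            per_gene_de(ExpressionMatrix.from_frame(df), config)

    def test_recovery_of_planted_genes(self, config):
        p = SimulationParams(genome_length=200_000, n_chromosomes=1, n_genes=50,
                             site_count=8, frac_sites_upstream400=1.0,
                             frac_sites_intergenic=0.0, de_fold=4.0, noise_sd=0.1, seed=13)
        _, genes, truth = simulate_genome(p)
        m = ExpressionMatrix.from_frame(simulate_expression(genes, truth, p))
        results = {r.gene_id: r for r in per_gene_de(m, config)}
        for gid, direction in truth.de_genes.items():
            assert results[gid].call == direction


class TestRelativeExpression:
    def test_wt_0h_column_is_zero(self):
        m = make_matrix({f"g{i}": {("OX", 6): 9.0} for i in range(5)})
        rel = relative_expression(m)
        assert np.allclose(rel["WT.0"], 0.0, atol=1e-4)

    def test_doubling_gives_one_log2_unit(self):
        m = make_matrix({"g": {("OX", 6): 9.0}})
        rel = relative_expression(m)
        assert rel.loc["g", "OX.6"] == pytest.approx(1.0, abs=1e-4)

    def test_recovers_planted_effects_from_simulation(self):
        p = SimulationParams(genome_length=100_000, n_chromosomes=1, n_genes=30,
                             site_count=4, frac_sites_upstream400=1.0,
                             frac_sites_intergenic=0.0, de_fold=4.0, noise_sd=0.1,
                             frac_de_down=0.0, seed=9)
        _, genes, truth = simulate_genome(p)
        m = ExpressionMatrix.from_frame(simulate_expression(genes, truth, p))
        rel = relative_expression(m)
        sem2 = 2 * p.noise_sd / np.sqrt(p.n_expression_replicates)
        for gid in truth.de_genes:
            # OX - WT at matched time isolates the planted genotype effect
            for t in p.timepoints:
                diff = rel.loc[gid, f"OX.{t}"] - rel.loc[gid, f"WT.{t}"]
                assert abs(diff - 2.0) < 3 * sem2 + 0.1


def naive_average_linkage(d: np.ndarray) -> np.ndarray:
    """Cubic-time UPGMA oracle returning a scipy-style linkage matrix."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    z = []
    next_id = n
    ids = {i: i for i in range(n)}
    while len(active) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[i] + active[j]
        z.append([ids[i], ids[j], dij, len(members)])
        del dist[(i, j)]
        for k in list(active):
            if k in (i, j):
                continue
            a = dist.pop((min(i, k), max(i, k)))
            b = dist.pop((min(j, k), max(j, k)))
            na, nb = len(active[i]), len(active[j])
            dist[(min(i, k), max(i, k))] = (na * a + nb * b) / (na + nb)
        del active[j]
        active[i] = members
        ids[i] = next_id
        next_id += 1
    return np.array(z)


class TestHierarchicalCluster:
    def test_identical_profiles_merge_first_at_zero(self):
        profiles = pd.DataFrame([[1, 2, 3], [1, 2, 3], [9, 1, 1]],
                                index=["a", "b", "c"], dtype=float)
        z, labels = hierarchical_cluster(profiles, 2)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_orthogonal_profiles_distance_one(self):
        profiles = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"], dtype=float)
        z, _ = hierarchical_cluster(profiles, 1)
        assert z[0, 2] == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(10, 6)))
        z1, l1 = hierarchical_cluster(profiles, 3)
        z2, l2 = hierarchical_cluster(profiles * 7.3, 3)
        assert np.allclose(z1[:, 2], z2[:, 2], atol=1e-9)
        assert (l1 == l2).all()

    def test_all_zero_profile_handled(self):
        profiles = pd.DataFrame([[0, 0, 0], [1, 2, 3], [3, 2, 1]], dtype=float)
        z, labels = hierarchical_cluster(profiles, 2)
        assert len(labels) == 3

    def test_tree_equals_naive_cubic_oracle(self, rng):
        """Average-linkage merge heights match a brute-force UPGMA."""
        from scipy.cluster.hierarchy import cophenet
        from chiptarget.expression import _cosine_distance_matrix

        for _ in range(20):
            n = int(rng.integers(3, 9))
            profiles = rng.normal(size=(n, 5))
            d = _cosine_distance_matrix(profiles)
            z_oracle = naive_average_linkage(d)
            z, _ = hierarchical_cluster(pd.DataFrame(profiles), 2)
            assert np.allclose(np.sort(z[:, 2]), np.sort(z_oracle[:, 2]), atol=1e-10)
            # cophenetic distances identify the tree beyond merge heights
            from scipy.spatial.distance import squareform
            c1 = cophenet(z)
            c2 = cophenet(z_oracle)
            assert np.allclose(c1, c2, atol=1e-10)

    def test_too_many_groups_rejected(self):
        profiles = pd.DataFrame([[1, 0], [0, 1]], dtype=float)
        with pytest.raises(ValueError):
            hierarchical_cluster(profiles, 3)


def test_malformed_sample_name_rejected():
    df = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["WT.0.1", "bad-name"])
    with pytest.raises(ValueError, match="bad-name"):
        ExpressionMatrix.from_frame(df)
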