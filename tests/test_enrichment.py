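import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ontomodules.enrichment import (assign_domains, bonferroni, chi2_2x2,
                                    holm_bonferroni, module_arm_fractions,
                                    module_by_chromosome, module_by_domain,
                                    module_by_geneset, read_breakpoints)


def chi2_oracle(table):
    """Independent Sum (O-E)^2 / E computation."""
    t = np.asarray(table, dtype=float)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()
    e = np.outer(rows, cols) / n
    return float(((t - e) ** 2 / e).sum())


def holm_oracle(p):
    """Hand step-down rule: sort, multiply by (m-i), enforce monotone, cap."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


class TestChi2:
    def test_hand_computed_example(self):
        # E = {5, 45, 95, 855}; chi2 = 25/5 + 25/45 + 25/95 + 25/855
        r = chi2_2x2([[10, 40], [90, 860]])
        assert r.chi2 == pytest.approx(5.848, abs=1e-3)
        assert r.df == 1
        assert r.p == pytest.approx(stats.chi2.sf(r.chi2, 1))

    def test_independent_table_gives_zero(self):
        r = chi2_2x2([[10, 20], [30, 60]])  # outer product of margins
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_row_swap_invariance(self):
        a = chi2_2x2([[10, 40], [90, 860]])
        b = chi2_2x2([[90, 860], [10, 40]])
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_degenerate_margin_flagged(self):
        r = chi2_2x2([[0, 0], [5, 10]])
        assert (r.chi2, r.p, r.degenerate) == (0.0, 1.0, True)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(1000):
            t = rng.integers(1, 200, size=(2, 2))
            assert chi2_2x2(t).chi2 == pytest.approx(chi2_oracle(t), abs=1e-9)

    def test_yates_reduces_statistic(self):
        plain = chi2_2x2([[10, 40], [90, 860]])
        corr = chi2_2x2([[10, 40], [90, 860]], yates=True)
        assert corr.chi2 < plain.chi2


class TestHolm:
    def test_hand_stepdown_example(self):
        adj = holm_bonferroni([0.01, 0.02, 0.05])
        assert adj == pytest.approx([0.03, 0.04, 0.05])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.2]) == pytest.approx([0.2])

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(holm_bonferroni(p), holm_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_at_most_bonferroni(self, rng):
        p = rng.random(25)
        holm = holm_bonferroni(p)
        bonf = bonferroni(p)
        assert (holm >= p - 1e-15).all()
        assert (holm <= bonf + 1e-15).all()
        # nondecreasing when sorted by raw p
        assert (np.diff(holm[np.argsort(p)]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])
        with pytest.raises(ValueError):
            holm_bonferroni([-0.1])


class TestModuleByChromosome:
    def test_obs_exp_ratio_formula(self):
        # module of 20 genes, 10 on chr II; universe arranged so chr II is 25%
        genes = [f"g{i}" for i in range(80)]
        chrom = ["II"] * 10 + ["I"] * 10 + ["II"] * 10 + ["I"] * 30 + ["III"] * 20
        labels = pd.Series([1] * 20 + [2] * 60, index=genes)
        ann = pd.DataFrame({"chromosome": chrom}, index=pd.Index(genes, name="gene_id"))
        res = module_by_chromosome(labels, ann)
        row = res[(res.module == 1) & (res.category == "II")].iloc[0]
        assert row.obs_exp_ratio == pytest.approx(10 / (20 * 0.25))

    def test_mtdna_excluded_and_counts_partition(self, toy_annotation):
        labels = pd.Series([1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2],
                           index=toy_annotation.index)
        res = module_by_chromosome(labels, toy_annotation)
        assert "MtDNA" not in set(res.category)
        # observed counts per chromosome sum to that chromosome's size
        nuclear = toy_annotation[toy_annotation.chromosome != "MtDNA"]
        for c, sub in res.groupby("category"):
            assert sub.observed.sum() == (nuclear.chromosome == c).sum()

    def test_null_annotation_rarely_significant(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(1200)]
            labels = pd.Series(rng.integers(1, 7, 1200), index=genes)
            ann = pd.DataFrame(
                {"chromosome": rng.choice(["I", "II", "III", "IV", "V", "X"], 1200)},
                index=pd.Index(genes, name="gene_id"))
            res = module_by_chromosome(labels, ann)
            flagged += res.significant.any()
        assert flagged <= 2

    def test_test_count_is_modules_times_chromosomes(self, rng):
        genes = [f"g{i}" for i in range(1400)]
        labels = pd.Series(rng.integers(1, 15, 1400), index=genes)
        ann = pd.DataFrame(
            {"chromosome": rng.choice(["I", "II", "III", "IV", "V", "X"], 1400)},
            index=pd.Index(genes, name="gene_id"))
        res = module_by_chromosome(labels, ann)
        assert len(res) == 14 * 6


class TestDomains:
    def test_all_center_module_ratio_zero(self):
        genes = [f"g{i}" for i in range(40)]
        ann = pd.DataFrame(
            {"chromosome": ["I"] * 40,
             "domain": ["center"] * 10 + ["arm", "center"] * 15},
            index=pd.Index(genes, name="gene_id"))
        labels = pd.Series([1] * 10 + [2] * 30, index=genes)
        res = module_by_domain(labels, ann)
        row = res[(res.module == 1)].iloc[0]
        assert row.observed == 0
        assert row.obs_exp_ratio == 0.0

    def test_proportional_module_chi2_zero(self):
        genes = [f"g{i}" for i in range(40)]
        ann = pd.DataFrame(
            {"chromosome": ["I"] * 40, "domain": ["arm", "center"] * 20},
            index=pd.Index(genes, name="gene_id"))
        labels = pd.Series(([1] * 2 + [2] * 2) * 10, index=genes)
        res = module_by_domain(labels, ann)
        assert res.chi2.max() == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.obs_exp_ratio, 1.0)

    def test_breakpoint_interval_lookup(self, tmp_path):
        bp = tmp_path / "bp.tsv"
        bp.write_text("I\t1\t1000\tarm\nI\t1001\t4000\tcenter\nI\t4001\t5000\tarm\n")
        table = read_breakpoints(bp)
        pos = pd.DataFrame(
            {"chromosome": ["I", "I", "I", "I", "II"],
             "position": [500, 1001, 4001, 6000, 500]},
            index=pd.Index(["a", "b", "c", "d", "e"], name="gene_id"))
        dom = assign_domains(pos, table)
        assert dom["a"] == "arm"
        assert dom["b"] == "center"   # boundary belongs to the starting interval
        assert dom["c"] == "arm"
        assert pd.isna(dom["d"])      # outside every interval
        assert pd.isna(dom["e"])

    def test_arm_fraction_summary_excludes_x(self, toy_annotation):
        labels = pd.Series(1, index=toy_annotation.index)
        out = module_arm_fractions(labels, toy_annotation)
        auto = toy_annotation[(toy_annotation.chromosome != "X")
                              & (toy_annotation.chromosome != "MtDNA")
                              & toy_annotation.domain.notna()]
        assert out.loc[1, "arm_fraction"] == pytest.approx(
            (auto.domain == "arm").mean())


class TestGenesets:
    def test_fully_operonic_module_ratio(self):
        genes = [f"g{i}" for i in range(100)]
        operon = [True] * 10 + [True] * 10 + [False] * 80  # background 20%
        labels = pd.Series([1] * 10 + [2] * 90, index=genes)
        ann = pd.DataFrame({"operon": operon}, index=pd.Index(genes, name="gene_id"))
        res = module_by_geneset(labels, ann, "operon")
        row = res[res.module == 1].iloc[0]
        assert row.obs_exp_ratio == pytest.approx(1.0 / 0.2)

    def test_annotated_universe_restriction(self, toy_annotation):
        labels = pd.Series([1] * 6 + [2] * 6, index=toy_annotation.index)
        res = module_by_geneset(labels, toy_annotation, "gamete_class")
        n_annot = toy_annotation.gamete_class.notna().sum()
        for c, sub in res.groupby("category"):
            assert sub.observed.sum() == (toy_annotation.gamete_class == c).sum()
        assert set(res.category) == {"oogenic", "spermatogenic", "sex-neutral"}
        # universe excludes unannotated genes entirely
        assert res[["observed"]].to_numpy().sum() <= n_annot * res.category.nunique()

    def test_embryo_categories_not_mutually_exclusive(self, toy_annotation):
        labels = pd.Series([1] * 6 + [2] * 6, index=toy_annotation.index)
        res = module_by_geneset(labels, toy_annotation, "embryo_category")
        mat = res[res.category == "maternal"].observed.sum()
        deg = res[res.category == "degradation"].observed.sum()
        assert mat == 3  # g0, g3, g8
        assert deg == 2  # g3 (dual), g10

    def test_null_geneset_false_positive_rate(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            genes = [f"g{i}" for i in range(800)]
            labels = pd.Series(rng.integers(1, 7, 800), index=genes)
            ann = pd.DataFrame({"operon": rng.random(800) < 0.2},
                               index=pd.Index(genes, name="gene_id"))
            res = module_by_geneset(labels, ann, "operon")
            flagged += res.significant.any()
        assert flagged <= 2
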