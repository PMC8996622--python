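"""Per-gene variation, running-median correction, orthology, correlations."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import devstab as ds
from devstab.genestab import _spearman_exact_p
from conftest import make_matrix


def _pairs(*records):
    return ds.pair_design_from_records(records)


class TestGeneVariation:
    def test_mean_absolute_difference(self):
        """Pair diffs {0.2, 0.4} average to 0.3."""
        m = make_matrix([[1.0, 1.2, 2.0, 2.4]])
        tab = ds.gene_variation(m, _pairs(("s0", "s1", "twin"), ("s2", "s3", "twin")))
        assert tab["raw"].iloc[0] == pytest.approx(0.3)
        assert tab["mean_expr"].iloc[0] == pytest.approx(1.65)

    def test_identical_pairs_zero(self):
        m = make_matrix(np.tile(np.arange(4.0)[:, None], (1, 2)))
        tab = ds.gene_variation(m, _pairs(("s0", "s1", "twin")))
        assert (tab["raw"] == 0).all()

    def test_pair_order_invariance(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 4)))
        t1 = ds.gene_variation(m, _pairs(("s0", "s1", "twin"), ("s2", "s3", "twin")))
        t2 = ds.gene_variation(m, _pairs(("s2", "s3", "twin"), ("s0", "s1", "twin")))
        pd.testing.assert_series_equal(t1["raw"], t2["raw"])

    def test_empty_pairs_rejected(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            ds.gene_variation(m, ds.PairDesign(()))


def brute_force_running_median(mean_expr, raw, gene_ids, window):
    """Independent oracle: explicit sort and per-gene symmetric-shrink window."""
    order = sorted(range(len(raw)), key=lambda j: (mean_expr[j], gene_ids[j]))
    raw_sorted = [raw[j] for j in order]
    n = len(raw_sorted)
    half = (window - 1) // 2
    corrected = {}
    for pos, j in enumerate(order):
        h = min(pos, n - 1 - pos, half)
        window_vals = sorted(raw_sorted[pos - h : pos + h + 1])
        m = len(window_vals)
        med = (
            window_vals[m // 2]
            if m % 2
            else 0.5 * (window_vals[m // 2 - 1] + window_vals[m // 2])
        )
        corrected[gene_ids[j]] = raw[j] - med
    return corrected


class TestRunningMedianCorrect:
    def _table(self, mean_expr, raw, genes=None):
        genes = genes or [f"g{j}" for j in range(len(raw))]
        return pd.DataFrame({"mean_expr": mean_expr, "raw": raw}, index=genes)

    def test_constant_raw_corrected_zero(self):
        t = self._table(np.arange(10.0), np.full(10, 0.4))
        out = ds.running_median_correct(t, window=5)
        np.testing.assert_allclose(out["corrected"], 0.0)

    def test_window_five_linear_raws(self):
        """Sorted raws (1..5) with window 5: shrunk windows give medians equal
        to each gene's own raw, so corrected is identically zero."""
        t = self._table(np.arange(5.0), [1.0, 2.0, 3.0, 4.0, 5.0])
        out = ds.running_median_correct(t, window=5)
        np.testing.assert_allclose(out["corrected"], 0.0)

    def test_edge_genes_have_singleton_windows(self):
        rng = np.random.default_rng(1)
        t = self._table(np.arange(20.0), rng.exponential(size=20))
        out = ds.running_median_correct(t, window=7)
        order = t.sort_values("mean_expr").index
        assert out.loc[order[0], "corrected"] == 0.0
        assert out.loc[order[-1], "corrected"] == 0.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ds.running_median_correct(self._table([1.0], [1.0]), window=4)

    def test_oversized_window_shrinks_with_warning(self):
        t = self._table(np.arange(5.0), np.random.default_rng(2).exponential(size=5))
        with pytest.warns(UserWarning, match="exceeds"):
            out = ds.running_median_correct(t, window=501)
        oracle = brute_force_running_median(
            t["mean_expr"].tolist(), t["raw"].tolist(), list(t.index), 501
        )
        for g in t.index:
            assert out.loc[g, "corrected"] == pytest.approx(oracle[g])

    @pytest.mark.parametrize("n,window", [(50, 7), (501, 101), (2000, 501)])
    def test_matches_brute_force_oracle(self, n, window):
        rng = np.random.default_rng(n + window)
        mean_expr = rng.normal(size=n).round(2)  # duplicates exercise the tie rule
        raw = rng.exponential(size=n)
        t = self._table(mean_expr, raw)
        out = ds.running_median_correct(t, window=window)
        oracle = brute_force_running_median(list(mean_expr), list(raw), list(t.index), window)
        np.testing.assert_allclose(
            out["corrected"].to_numpy(), [oracle[g] for g in t.index], atol=1e-12
        )

    def test_original_order_preserved(self):
        t = self._table([3.0, 1.0, 2.0], [0.1, 0.2, 0.3], genes=["c", "a", "b"])
        out = ds.running_median_correct(t, window=3)
        assert list(out.index) == ["c", "a", "b"]

    def test_removes_planted_mean_variance_trend(self):
        """Planted decreasing trend: |rho| > 0.3 before, < 0.05 after correction."""
        cfg = ds.SimulationConfig(n_genes=5000, n_pairs_per_stage=20, seed=50)
        m, _ = ds.simulate_twin_matrix(cfg, "phylo1")
        logm = ds.log_transform(m)
        tab = ds.gene_variation(logm, ds.twin_pairs(logm.metadata))
        out = ds.running_median_correct(tab)
        r_raw = stats.spearmanr(out["raw"], out["mean_expr"]).statistic
        r_cor = stats.spearmanr(out["corrected"], out["mean_expr"]).statistic
        assert abs(r_raw) > 0.3
        assert abs(r_cor) < 0.05


class TestIntraspeciesGeneVariation:
    def test_identical_populations_zero_raw(self):
        cfg = ds.SimulationConfig(
            n_genes=100, n_pairs_per_stage=4, seed=51,
            stage_noise_sd=(0.0,) * 4, divergence_sd=0.0,
        )
        a, b, _ = ds.simulate_population_matrices(cfg, "early")
        la, lb = ds.log_transform(a), ds.log_transform(b)
        cp = ds.cross_population_pairs(pd.concat([la.metadata, lb.metadata]), "popA", "popB")
        tab = ds.intraspecies_gene_variation(la, lb, cp, window=21)
        assert (tab["raw"] == 0).all()

    def test_correlates_with_twin_variation_through_shared_multipliers(self):
        cfg = ds.SimulationConfig(n_genes=3000, n_pairs_per_stage=15, seed=52)
        m, _ = ds.simulate_twin_matrix(cfg, "phylo1")
        logm = ds.log_transform(m)
        twin = ds.running_median_correct(ds.gene_variation(logm, ds.twin_pairs(logm.metadata)))
        a, b, _ = ds.simulate_population_matrices(cfg, "phylo1")
        la, lb = ds.log_transform(a), ds.log_transform(b)
        cp = ds.cross_population_pairs(pd.concat([la.metadata, lb.metadata]), "popA", "popB")
        intra = ds.intraspecies_gene_variation(la, lb, cp)
        rho, p = ds.stability_conservation_correlation(twin, intra)
        assert rho > 0.3 and p < 1e-10


class TestResolveRBH:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])

    def test_mutual_best_included_non_mutual_excluded(self):
        ab = self._hits([("a1", "b1", 1e-50, 200), ("a2", "b2", 1e-40, 150)])
        ba = self._hits([("b1", "a1", 1e-50, 200), ("b2", "a3", 1e-45, 160)])
        out = ds.resolve_rbh(ab, ba)
        assert out.values.tolist() == [["a1", "b1"]]

    def test_tie_breaking_evalue_bitscore_lexicographic(self):
        ab = self._hits(
            [("a", "b2", 1e-30, 100), ("a", "b1", 1e-30, 100), ("a", "b3", 1e-30, 150)]
        )
        ba = self._hits([("b3", "a", 1e-30, 150)])
        out = ds.resolve_rbh(ab, ba)  # b3 wins on bitscore
        assert out.values.tolist() == [["a", "b3"]]
        ba2 = self._hits([("b1", "a", 1e-30, 100)])
        ab2 = self._hits([("a", "b2", 1e-30, 100), ("a", "b1", 1e-30, 100)])
        out2 = ds.resolve_rbh(ab2, ba2)  # equal scores: lexicographic b1
        assert out2.values.tolist() == [["a", "b1"]]

    def test_evalue_cutoff_semantics(self):
        ab = self._hits([("a", "b", 1e-3, 50)])
        ba = self._hits([("b", "a", 1e-3, 50)])
        assert ds.resolve_rbh(ab, ba).empty  # 1e-3 not < 1e-5
        assert not ds.resolve_rbh(ab, ba, literal_inequality=True).empty

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(53)
        a_genes = [f"a{j}" for j in range(15)]
        b_genes = [f"b{j}" for j in range(12)]

        def random_hits(qs, ss):
            rows = []
            for q in qs:
                for s in ss:
                    if rng.random() < 0.4:
                        rows.append((q, s, 10.0 ** -rng.integers(6, 40),
                                     float(rng.integers(50, 300))))
            return self._hits(rows)

        ab, ba = random_hits(a_genes, b_genes), random_hits(b_genes, a_genes)

        def oracle_best(hits):
            best = {}
            for q, s, e, bs in hits.itertuples(index=False):
                if e >= 1e-5:
                    continue
                cur = best.get(q)
                if cur is None or (e, -bs, s) < (cur[1], -cur[2], cur[0]):
                    best[q] = (s, e, bs)
            return {q: v[0] for q, v in best.items()}

        fa, fb = oracle_best(ab), oracle_best(ba)
        expected = sorted(
            (a, b) for a, b in fa.items() if fb.get(b) == a
        )
        got = sorted(map(tuple, ds.resolve_rbh(ab, ba).values.tolist()))
        assert got == expected

    def test_malformed_hit_file_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q\ts\t0\t0\t0\t0\t0\t0\t0\t0\t1e-20\t100\nbad\tline\n")
        with pytest.raises(ValueError, match="line 2"):
            ds.read_hit_table(path)

    def test_hit_file_round_trip(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "a1\tb1\t90\t100\t5\t0\t1\t100\t1\t100\t1e-30\t180\n"
            "a2\tb2\t80\t90\t9\t1\t1\t90\t1\t90\t1e-12\t120\n"
        )
        hits = ds.read_hit_table(path)
        assert hits.shape == (2, 4)
        assert hits["evalue"].tolist() == [1e-30, 1e-12]


class TestInterspeciesGeneVariation:
    def test_identical_profiles_all_zero(self):
        prof = pd.Series([1.0, 2.0], index=["a1", "a2"])
        other = pd.Series([1.0, 2.0], index=["b1", "b2"])
        omap = pd.DataFrame({"gene_a": ["a1", "a2"], "gene_b": ["b1", "b2"]})
        tab = ds.interspecies_gene_variation(prof, other, omap, window=1)
        assert (tab["raw"] == 0).all()

    def test_empty_map_gives_empty_table(self):
        tab = ds.interspecies_gene_variation(
            pd.Series(dtype=float), pd.Series(dtype=float),
            pd.DataFrame(columns=["gene_a", "gene_b"]), window=1,
        )
        assert tab.empty

    def test_missing_orthologs_dropped(self, caplog):
        prof = pd.Series([1.0], index=["a1"])
        other = pd.Series([3.0], index=["b1"])
        omap = pd.DataFrame({"gene_a": ["a1", "a2"], "gene_b": ["b1", "b9"]})
        tab = ds.interspecies_gene_variation(prof, other, omap, window=1)
        assert list(tab.index) == ["a1"]
        assert tab["raw"].iloc[0] == pytest.approx(2.0)


class TestStabilityConservationCorrelation:
    def _table(self, values):
        return pd.DataFrame(
            {"mean_expr": np.arange(len(values), dtype=float),
             "raw": values, "corrected": values},
            index=[f"g{j}" for j in range(len(values))],
        )

    def test_self_correlation_one(self):
        t = self._table(np.random.default_rng(5).normal(size=30))
        rho, _ = ds.stability_conservation_correlation(t, t)
        assert rho == pytest.approx(1.0)

    def test_rank_reversal_minus_one(self):
        vals = np.random.default_rng(6).normal(size=30)
        t1, t2 = self._table(vals), self._table(-vals)
        rho, _ = ds.stability_conservation_correlation(t1, t2)
        assert rho == pytest.approx(-1.0)

    def test_too_few_shared_genes_rejected(self):
        t = self._table(np.arange(5.0))
        with pytest.raises(ValueError, match=">= 10"):
            ds.stability_conservation_correlation(t, t)

    def test_exact_permutation_helper_matches_enumeration(self):
        """n=6: all 720 pairings enumerated directly with the rho formula."""
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=6), rng.normal(size=6)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(stats.spearmanr(x, y).statistic)
        count = total = 0
        for perm in itertools.permutations(range(6)):
            r = stats.pearsonr(rx[list(perm)], ry).statistic
            count += abs(r) >= obs - 1e-12
            total += 1
        assert _spearman_exact_p(x, y) == pytest.approx(count / total)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            t1 = self._table(rng.normal(size=60))
            t2 = self._table(rng.normal(size=60))
            ps.append(ds.stability_conservation_correlation(t1, t2)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestExpressionQuintileSplit:
    def test_equal_sizes(self):
        t = pd.DataFrame({"mean_expr": np.arange(10.0), "raw": np.zeros(10)},
                         index=[f"g{j}" for j in range(10)])
        groups = ds.expression_quintile_split(t)
        assert [len(g) for g in groups] == [2, 2, 2, 2, 2]

    def test_remainder_to_lowest_groups(self):
        t = pd.DataFrame({"mean_expr": np.arange(12.0), "raw": np.zeros(12)},
                         index=[f"g{j:02d}" for j in range(12)])
        groups = ds.expression_quintile_split(t)
        assert [len(g) for g in groups] == [3, 3, 2, 2, 2]

    def test_union_equals_input(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame({"mean_expr": rng.normal(size=23), "raw": rng.normal(size=23)},
                         index=[f"g{j:02d}" for j in range(23)])
        groups = ds.expression_quintile_split(t)
        union = set().union(*[set(g.index) for g in groups])
        assert union == set(t.index)
        assert sum(len(g) for g in groups) == 23
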