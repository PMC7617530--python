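"""Gene-level enrichment statistics, exact tests and candidate ranking."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from oncostruct import (
    EdcResult,
    GeneEnrichmentResult,
    VariantKey,
    bonferroni_threshold,
    compare_groups,
    ddg_rank,
    fisher_2x2,
    gene_damage_enrichment,
    rank_candidates,
    wilcoxon_two_sample,
)
from oncostruct.enrichment import mark_significance


def wilcoxon_oracle(a, b):
    """Enumeration oracle on the rank-sum W of sample a (doubled tail)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    ws = [
        ranks[list(chosen)].sum()
        for chosen in combinations(range(len(pooled)), n_a)
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def fisher_oracle(table):
    """Sum hypergeometric probabilities no larger than the observed table's."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d
    pmf = stats.hypergeom(total, row1, col1).pmf
    p_obs = pmf(a)
    support = range(max(0, col1 - (total - row1)), min(row1, col1) + 1)
    return float(sum(pmf(x) for x in support if pmf(x) <= p_obs * (1 + 1e-7)))


class TestWilcoxon:
    def test_separated_samples_exact_p(self):
        u, p = wilcoxon_two_sample([5, 6, 7], [1, 2, 3])
        assert u == 9.0
        assert p == pytest.approx(0.10, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_two_sample([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_two_sample([], [1.0])

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_a = int(rng.integers(1, 7))
            n_b = int(rng.integers(1, 13 - n_a))
            with_ties = rng.random() < 0.5
            a = rng.integers(0, 5, n_a).astype(float) if with_ties else rng.normal(size=n_a)
            b = rng.integers(0, 5, n_b).astype(float) if with_ties else rng.normal(size=n_b)
            _, p = wilcoxon_two_sample(a, b)
            assert p == pytest.approx(wilcoxon_oracle(a, b), abs=1e-12)

    def test_exact_path_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            _, p = wilcoxon_two_sample(a, b)
            expected = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact"
            ).pvalue
            assert p == pytest.approx(float(expected), abs=1e-12)

    def test_asymptotic_path_is_calibrated_under_null(self):
        """p-values from same-distribution samples are roughly uniform."""
        rng = np.random.default_rng(5)
        pvals = [
            wilcoxon_two_sample(rng.normal(size=30), rng.normal(size=30))[1]
            for _ in range(200)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestFisher:
    def test_balanced_table_is_null(self):
        odds_ratio, p = fisher_2x2([[5, 5], [5, 5]])
        assert odds_ratio == 1.0
        assert p == 1.0

    def test_cross_product_example(self):
        odds_ratio, p = fisher_2x2([[8, 2], [2, 8]])
        assert odds_ratio == pytest.approx(16.0)
        assert p == pytest.approx(0.0230, abs=5e-4)

    def test_minimal_support_table(self):
        odds_ratio, p = fisher_2x2([[1, 0], [0, 1]])
        assert odds_ratio == np.inf
        assert p == 1.0

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError):
            fisher_2x2([[0, 0], [3, 4]])

    def test_matches_hypergeometric_oracle_small_tables(self):
        tables = [
            [[a, b], [c, d]]
            for a in range(4) for b in range(4)
            for c in range(4) for d in range(4)
            if (a + b) and (c + d) and (a + c) and (b + d)
        ]
        for table in tables:
            _, p = fisher_2x2(table)
            assert p == pytest.approx(fisher_oracle(table), abs=1e-9), table


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 10, 0.005), (0.05, 1, 0.05)]
    )
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_zero_tests_is_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _table(values, pid="P1"):
    raw = {
        VariantKey(pid, i + 1, "A", "G"): v for i, v in enumerate(values)
    }
    return ddg_rank(raw)


class TestGeneDamageEnrichment:
    def test_top_variant_observed_gives_hand_computed_diff(self):
        table = _table([0.1, 0.5, -1.2, 2.0])  # ranks 0, 1/3, 2/3, 1
        observed = {VariantKey("P1", 4, "A", "G")}
        result = gene_damage_enrichment(table, observed)
        assert result.ddg_rank_diff == pytest.approx(1 - (0 + 1 / 3 + 2 / 3) / 3)

    def test_interleaved_observed_is_null(self):
        values = list(range(1, 21))
        table = _table(values)
        observed = {VariantKey("P1", i, "A", "G") for i in range(2, 21, 2)}
        result = gene_damage_enrichment(table, observed)
        assert abs(result.ddg_rank_diff) < 0.06
        assert result.p_value > 0.5

    def test_top_half_ranks_exact_p(self):
        table = _table([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        observed = {VariantKey("P1", i, "A", "G") for i in (4, 5, 6)}
        result = gene_damage_enrichment(table, observed)
        assert result.p_value == pytest.approx(0.10, abs=1e-12)
        assert result.n_observed == 3 and result.n_unobserved == 3

    def test_antisymmetric_under_swap(self):
        table = _table([0.3, 1.4, -0.2, 2.5, 0.9, 5.0])
        keys = sorted(table.entries)
        observed = set(keys[:2])
        unobserved = set(keys[2:])
        forward = gene_damage_enrichment(table, observed)
        backward = gene_damage_enrichment(table, unobserved)
        # swapping observed/unobserved flips the sign of the difference
        assert forward.ddg_rank_diff == pytest.approx(
            -backward.ddg_rank_diff, abs=1e-12
        )
        assert forward.p_value == pytest.approx(backward.p_value, abs=1e-12)

    def test_unscorable_observed_dropped_and_empty_side_skipped(self):
        table = _table([1.0, 2.0, 3.0])
        stray = {VariantKey("P1", 99, "A", "G")}
        assert gene_damage_enrichment(table, stray) is None
        everything = set(table.entries)
        assert gene_damage_enrichment(table, everything) is None

    def test_null_cohort_bonferroni_false_positive_rate(self):
        """Uniform-random observed sets rarely pass the corrected threshold."""
        rng = np.random.default_rng(11)
        n_genes = 300
        results = []
        for g in range(n_genes):
            values = rng.lognormal(size=60)
            table = _table(values, pid=f"G{g}")
            keys = list(table.entries)
            observed = {keys[i] for i in rng.choice(len(keys), 10, replace=False)}
            result = gene_damage_enrichment(table, observed)
            results.append(result)
        flagged, threshold = mark_significance(results, alpha=0.05)
        frac = np.mean([r.significant for r in flagged])
        assert threshold == pytest.approx(0.05 / n_genes)
        assert frac <= 0.05


class TestRankCandidates:
    def _enr(self, pid, diff, p, source="predicted", significant=True):
        return GeneEnrichmentResult(
            protein_id=pid, ddg_rank_diff=diff, p_value=p, n_observed=10,
            n_unobserved=100, structure_source=source, significant=significant,
        )

    def test_most_significant_source_wins(self):
        enrichments = {
            "experimental": [self._enr("G1", 0.2, 1e-8, "experimental")],
            "predicted": [self._enr("G1", 0.15, 1e-3)],
        }
        damage, _, _ = rank_candidates(enrichments, [])
        assert damage.loc[0, "p_value"] == pytest.approx(1e-8)
        assert damage.loc[0, "structure_source"] == "experimental"

    def test_ties_broken_by_effect_size_then_name(self):
        enrichments = {
            "predicted": [
                self._enr("GB", 0.1, 1e-4),
                self._enr("GA", 0.3, 1e-4),
                self._enr("GC", 0.3, 1e-4),
            ]
        }
        damage, _, _ = rank_candidates(enrichments, [])
        assert damage["protein_id"].tolist() == ["GA", "GC", "GB"]

    def test_negative_diff_genes_excluded_and_empty_edc_ok(self):
        enrichments = {
            "predicted": [self._enr("G1", -0.2, 1e-9), self._enr("G2", 0.1, 0.5)]
        }
        damage, clustering, overlap = rank_candidates(enrichments, [])
        assert damage["protein_id"].tolist() == ["G2"]
        assert clustering.empty and overlap == set()

    def test_clustering_sorted_by_edc_and_overlap_found(self):
        enrichments = {"predicted": [self._enr("G1", 0.2, 1e-8)]}
        edcs = [
            EdcResult("G9", 1.2, 6, 100, recurrent=True),
            EdcResult("G1", 2.3, 6, 100, recurrent=True),
        ]
        damage, clustering, overlap = rank_candidates(enrichments, edcs)
        assert clustering["protein_id"].tolist() == ["G1", "G9"]
        assert overlap == {"G1"}


class TestCompareGroups:
    def test_wilcoxon_and_fisher_paths(self):
        comparisons = compare_groups(
            values={"tsg": [0.7, 0.8, 0.9], "onc": [0.1, 0.2, 0.3]},
            categories={"tsg": (8, 2), "onc": (2, 8)},
            pairs=[("tsg", "onc")],
        )
        by_stat = {c.statistic: c for c in comparisons}
        assert by_stat["wilcoxon"].p_value == pytest.approx(0.10, abs=1e-12)
        assert by_stat["fisher"].estimate == pytest.approx(16.0)
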