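"""Filters, Shannon diversity, core sets, paired tests, beta diversity."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dysbiosis.data import TaxonCountTable, ValidationError, build_paired_design
from dysbiosis.profiling import (
    _paired_wilcoxon,
    alpha_diversity,
    beta_diversity,
    bray_curtis,
    core_microbiome,
    paired_alpha_test,
    paired_genus_tests,
    prevalence_count_filter,
    relative_abundance,
    set_partition,
    shannon_index,
)
from dysbiosis.simulate import SubtypeSpec, SyntheticConfig, null_config, simulate_cohort

from conftest import random_table


def wilcoxon_enumeration_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    total = n * (n + 1) / 2
    w_obs = min(ranks[d > 0].sum(), total - ranks[d > 0].sum())
    count = sum(
        min(ranks[np.array(signs) > 0].sum(),
            total - ranks[np.array(signs) > 0].sum()) <= w_obs
        for signs in itertools.product([-1, 1], repeat=n)
    )
    return min(1.0, count / 2**n)


class TestRelativeAbundance:
    def test_simple_proportions(self):
        table = TaxonCountTable(
            ["s1"], ["a", "b", "c"], np.array([[2, 3, 5]]),
            {t: t for t in "abc"},
        )
        np.testing.assert_allclose(
            relative_abundance(table).values, [[0.2, 0.3, 0.5]]
        )

    def test_single_taxon_is_one(self):
        table = TaxonCountTable(["s1"], ["a"], np.array([[7]]), {"a": "a"})
        np.testing.assert_allclose(relative_abundance(table).values, [[1.0]])

    def test_rows_sum_to_one_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            rel = relative_abundance(random_table(rng))
            np.testing.assert_allclose(rel.values.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_named(self):
        table = TaxonCountTable(
            ["ok", "empty"], ["a"], np.array([[1], [0]]), {"a": "a"}
        )
        with pytest.raises(ValidationError, match="empty"):
            relative_abundance(table)


class TestPrevalenceFilter:
    def _table(self, presence_counts, n_samples=10):
        """One taxon per requested presence count; counts of 5 where present."""
        taxa = [f"t{k}" for k in range(len(presence_counts))]
        counts = np.zeros((n_samples, len(taxa)), dtype=int)
        for j, npres in enumerate(presence_counts):
            counts[:npres, j] = 5
        return TaxonCountTable(
            [f"s{i}" for i in range(n_samples)], taxa, counts,
            {t: t for t in taxa},
        )

    def test_boundary_prevalence_kept(self):
        table = self._table([4, 3])
        out = prevalence_count_filter(table, min_prevalence=0.4, min_total=0)
        assert out.taxon_ids == ["t0"]  # present in exactly ceil(0.4*10)=4

    def test_min_total_boundary(self):
        table = TaxonCountTable(
            [f"s{i}" for i in range(10)], ["low", "high"],
            np.column_stack([np.repeat([1, 0], [9, 1]), np.repeat(1, 10)]),
            {"low": "low", "high": "high"},
        )
        out = prevalence_count_filter(table, min_prevalence=0.4, min_total=10)
        assert out.taxon_ids == ["high"]  # total 9 < 10 removed

    def test_presence_threshold_is_ceiling(self):
        assert math.ceil(0.6 * 40) == 24  # documented boundary
        table = self._table([24, 23], n_samples=40)
        out = prevalence_count_filter(table, min_prevalence=0.6, min_total=0)
        assert out.taxon_ids == ["t0"]

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(8)
        table = random_table(rng, n_samples=12, n_taxa=15)
        once = prevalence_count_filter(table, 0.5, 5)
        twice = prevalence_count_filter(once, 0.5, 5)
        assert set(once.taxon_ids) <= set(table.taxon_ids)
        assert once.taxon_ids == twice.taxon_ids
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_all_removed_raises(self):
        table = self._table([1, 1])
        with pytest.raises(ValidationError, match="filter"):
            prevalence_count_filter(table, min_prevalence=0.9, min_total=0)


class TestShannon:
    def test_uniform_four_is_ln4(self):
        assert shannon_index([0.25] * 4) == pytest.approx(1.386294, abs=1e-6)

    def test_degenerate_is_zero(self):
        assert shannon_index([1.0, 0.0, 0.0]) == 0.0

    def test_direct_summation_value(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(
            1.039721, abs=1e-6
        )

    def test_base2_is_base_e_over_ln2(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            assert shannon_index(p, base=2) == pytest.approx(
                shannon_index(p) / math.log(2), abs=1e-12
            )

    def test_bounded_by_log_richness(self, default_cohort):
        from dysbiosis.profiling import relative_abundance

        rel = relative_abundance(default_cohort.table)
        h = alpha_diversity(rel)
        richness = (rel.values > 0).sum(axis=1)
        assert (h.to_numpy() <= np.log(richness) + 1e-9).all()
        assert (h.to_numpy() >= 0).all()

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([1.2, -0.2])


class TestPairedWilcoxon:
    def test_six_all_positive_pairs(self):
        _, p = _paired_wilcoxon(np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]))
        assert p == pytest.approx(0.03125, abs=1e-12)

    def test_symmetric_differences_give_p_one(self):
        _, p = _paired_wilcoxon(np.array([1.0, -1.0, 2.0, -2.0]))
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = _paired_wilcoxon(np.zeros(8))
        assert p == 1.0

    def test_exact_p_matches_enumeration(self):
        """Oracle equivalence: exact p equals full 2^n enumeration, n <= 10."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 11))
            mags = 0.5 + rng.uniform(0.1, 10, n).cumsum()  # distinct, no ties
            d = mags * rng.choice([-1, 1], n)
            _, p = _paired_wilcoxon(d)
            assert p == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-12)

    def test_label_swap_flips_sign_only(self, default_cohort):
        from dysbiosis.data import PairedDesign
        from dysbiosis.profiling import relative_abundance

        design = default_cohort.design
        rel = relative_abundance(default_cohort.table)
        swapped = PairedDesign(
            pairs=[(s, p, l) for s, l, p in design.pairs]
        )
        h = alpha_diversity(rel)
        s1, p1 = paired_alpha_test(design, h)
        s2, p2 = paired_alpha_test(swapped, h)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_planted_shannon_drop_power(self):
        """A lesion-wide boost of the dominant genus depresses Shannon."""
        hits, n_seeds = 0, 30
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                subtypes=[SubtypeSpec("C1", 1.0, (0,), 2.0, (1,))], seed=seed
            )
            cohort = simulate_cohort(cfg)
            rel = relative_abundance(cohort.table)
            h = alpha_diversity(rel)
            _, p = paired_alpha_test(cohort.design, h)
            les = h[cohort.design.lesion_samples].mean()
            per = h[cohort.design.peri_samples].mean()
            hits += (p < 0.05) and (les < per)
        assert hits / n_seeds >= 0.8


class TestCoreAndPartition:
    def _presence_table(self, n_present, n_samples=10):
        counts = np.zeros((n_samples, 1), dtype=int)
        counts[:n_present, 0] = 1
        return TaxonCountTable(
            [f"s{i}" for i in range(n_samples)], ["t"], counts, {"t": "t"}
        )

    def test_boundary_inclusive(self):
        table = self._presence_table(9)
        assert core_microbiome(table, table.sample_ids, 0.9) == {"t"}

    def test_below_boundary_excluded(self):
        table = self._presence_table(8)
        assert core_microbiome(table, table.sample_ids, 0.9) == set()

    def test_set_partition_cases(self):
        part = set_partition({"a", "b", "c"}, {"b", "c", "d"})
        assert part.common == {"b", "c"}
        assert part.unique_to_a == {"a"}
        assert part.unique_to_b == {"d"}
        same = set_partition({"x"}, {"x"})
        assert same.cardinalities == (1, 0, 0)
        disjoint = set_partition({"x"}, {"y"})
        assert disjoint.common == set()

    def test_partition_invariants(self):
        rng = np.random.default_rng(2)
        universe = [f"t{i}" for i in range(20)]
        for _ in range(10):
            a = set(rng.choice(universe, rng.integers(0, 15), replace=False))
            b = set(rng.choice(universe, rng.integers(0, 15), replace=False))
            part = set_partition(a, b)
            assert part.common | part.unique_to_a | part.unique_to_b == a | b
            assert not part.common & part.unique_to_a
            assert not part.common & part.unique_to_b
            assert not part.unique_to_a & part.unique_to_b


class TestPairedGenusTests:
    def test_planted_single_genus_shift_found(self):
        """The shifted genus attains the smallest p among prevalent genera."""
        hits, n_seeds = 0, 25
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                subtypes=[SubtypeSpec("C1", 1.0, (5,), 2.0, (1,))], seed=seed
            )
            cohort = simulate_cohort(cfg)
            rel = relative_abundance(cohort.table)
            prevalent = [
                t for t, f in zip(
                    cohort.table.taxon_ids,
                    (cohort.table.counts > 0).mean(axis=0),
                ) if f >= 0.4
            ]
            res = paired_genus_tests(cohort.design, rel, prevalent)
            shifted = cohort.table.taxon_ids[5]
            hits += res["p"].idxmin() == shifted
        assert hits / n_seeds >= 0.8

    def test_bh_q_dominates_p(self, default_cohort):
        rel = relative_abundance(default_cohort.table)
        res = paired_genus_tests(
            default_cohort.design, rel, default_cohort.table.taxon_ids[:20]
        )
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_absent_genus_is_error(self, default_cohort):
        from dysbiosis.profiling import paired_genus_test

        rel = relative_abundance(default_cohort.table)
        with pytest.raises(KeyError):
            paired_genus_test(default_cohort.design, rel, "NotAGenus")


class TestBetaDiversity:
    def test_identical_samples_distance_zero(self):
        table = TaxonCountTable(
            ["s1", "s2"], ["a", "b"], np.array([[5, 5], [5, 5]]),
            {"a": "a", "b": "b"},
        )
        dm = bray_curtis(relative_abundance(table))
        assert dm.loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_samples_distance_one(self):
        table = TaxonCountTable(
            ["s1", "s2"], ["a", "b"], np.array([[10, 0], [0, 10]]),
            {"a": "a", "b": "b"},
        )
        dm = bray_curtis(relative_abundance(table))
        assert dm.loc["s1", "s2"] == pytest.approx(1.0)

    def test_pseudo_f_matches_skbio_permanova(self):
        """Independent oracle: scikit-bio's PERMANOVA statistic."""
        skbio = pytest.importorskip("skbio")
        from dysbiosis.profiling import _pseudo_f

        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(6), size=12)
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(x, metric="braycurtis"))
        groups = np.array([0] * 6 + [1] * 6)
        ours = _pseudo_f(dm, groups)
        res = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm), grouping=[str(g) for g in groups],
            permutations=9,
        )
        assert ours == pytest.approx(res["test statistic"], abs=1e-10)

    def test_null_type_one_error_controlled(self):
        """Paired-permutation PERMANOVA rejects rarely on null cohorts."""
        hits, n_seeds = 0, 40
        for seed in range(n_seeds):
            cohort = simulate_cohort(null_config(n_taxa=60, seed=seed))
            rel = relative_abundance(cohort.table)
            _, _, p = beta_diversity(
                rel, cohort.design, n_permutations=199, seed=seed
            )
            hits += p < 0.05
        assert hits / n_seeds <= 0.10
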