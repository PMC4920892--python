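"""ECDFs, K-S / Mann-Whitney tests, fold-change sets, occupancy changes."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enhancerkit import (
    ECDF,
    ExpressionTable,
    GenomicInterval,
    assign_genes,
    call_superenhancers,
    compare_change_groups,
    dependent_sites,
    foldchange_gene_sets,
    ks_two_sample,
    mann_whitney_u,
    occupancy_changes,
)
from enhancerkit.diffstats import changes_at, pearson_correlation


def brute_force_ks_d(x, y):
    """Max ECDF gap over the pooled support, by explicit counting."""
    x, y = np.asarray(x), np.asarray(y)
    return max(
        abs((x <= v).mean() - (y <= v).mean())
        for v in np.concatenate([x, y])
    )


def brute_force_mwu_p(x, y):
    """Exact two-sided permutation p for U, counting greater/tied pairs."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(sample_x, sample_y):
        return sum(
            (xi > yi) + 0.5 * (xi == yi) for xi in sample_x for yi in sample_y
        )

    mu = n1 * len(y) / 2.0
    obs = abs(u_stat(x, y) - mu)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(chosen, rest) - mu) >= obs - 1e-9:
            count += 1
    return count / total


class TestECDF:
    def test_single_value_step(self):
        f = ECDF([5.0])
        assert f(4.999) == 0.0
        assert f(5.0) == 1.0

    def test_counted_fraction_with_ties(self):
        f = ECDF([1, 2, 2, 4])
        assert f(2) == pytest.approx(0.75)
        assert f(-1e18) == 0.0
        assert f(4) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ECDF([])


class TestKS:
    def test_identical_samples_d_zero(self):
        r = ks_two_sample([1, 2, 3], [3, 2, 1])
        assert r.D == 0.0
        assert r.p == 1.0

    def test_disjoint_supports_d_one(self):
        r = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert r.D == 1.0

    def test_d_matches_brute_force_on_random_small_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n1, n2 = rng.integers(1, 9, 2)
            x = rng.integers(0, 6, n1) + rng.random(n1) * rng.integers(0, 2)
            y = rng.integers(0, 6, n2) + rng.random(n2) * rng.integers(0, 2)
            r = ks_two_sample(x, y)
            assert r.D == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)

    def test_p_close_to_permutation_p(self):
        """For tie-free small samples the returned p matches the full
        permutation distribution of D within 10% relative."""
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(100):
            n1, n2 = rng.integers(3, 7, 2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.7, 1, n2)
            pooled = np.concatenate([x, y])
            d_obs = brute_force_ks_d(x, y)
            count = total = 0
            for idx in combinations(range(len(pooled)), n1):
                mask = np.zeros(len(pooled), bool)
                mask[list(idx)] = True
                total += 1
                if brute_force_ks_d(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
                    count += 1
            p_perm = count / total
            p = ks_two_sample(x, y).p
            if p_perm >= 0.01:
                checked += 1
                assert p == pytest.approx(p_perm, rel=0.10)
        assert checked > 50

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.integers(0, 10**6))
    def test_d_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(0.5, 1.2, size=12)
        d0 = ks_two_sample(x, y).D
        d1 = ks_two_sample(np.exp(x), np.exp(y)).D
        assert d0 == pytest.approx(d1, abs=1e-12)


class TestMWU:
    def test_complete_separation(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.U == 0.0

    def test_u_sum_identity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=9), rng.normal(size=7)
        ux = mann_whitney_u(x, y).U
        uy = mann_whitney_u(y, x).U
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_all_identical_values(self):
        r = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.U == pytest.approx(3.0)
        assert r.p == 1.0

    def test_p_agrees_with_exact_enumeration(self):
        """Small-sample p within 15% relative of independent enumeration
        (including tied data) whenever the exact p is not tiny."""
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(200):
            n1, n2 = rng.integers(2, 8, 2)
            if rng.random() < 0.5:
                x = rng.integers(0, 4, n1).astype(float)  # tie-prone
                y = rng.integers(0, 4, n2).astype(float)
            else:
                x = rng.normal(0, 1, n1)
                y = rng.normal(0.5, 1, n2)
            p_exact = brute_force_mwu_p(x, y)
            p = mann_whitney_u(x, y).p
            if p_exact >= 0.01:
                checked += 1
                assert p == pytest.approx(p_exact, rel=0.15)
        assert checked > 100

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.integers(0, 10**6))
    def test_p_invariant_under_rank_preserving_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(0.3, 1, size=25)
        p0 = mann_whitney_u(x, y).p
        p1 = mann_whitney_u(np.arctan(x), np.arctan(y)).p
        assert p0 == pytest.approx(p1, abs=1e-12)


class TestNullCalibration:
    def test_type_one_error_near_alpha(self):
        """With no planted effect both tests reject at ~5% at alpha=0.05."""
        rng = np.random.default_rng(99)
        reps = 400
        ks_rej = mwu_rej = 0
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            ks_rej += ks_two_sample(x, y).p < 0.05
            mwu_rej += mann_whitney_u(x, y).p < 0.05
        assert 0.02 <= ks_rej / reps <= 0.08
        assert 0.02 <= mwu_rej / reps <= 0.08


class TestFoldchangeSets:
    def _table(self):
        return ExpressionTable(
            pd.DataFrame(
                {"a": [10.0, 5.0, 1.0], "b": [1.0, 5.0, 10.0]},
                index=["up_a", "flat", "up_b"],
            )
        )

    def test_threshold_splits_sets(self):
        a_set, b_set = foldchange_gene_sets(self._table(), "a", "b")
        assert a_set == {"up_a"}
        assert b_set == {"up_b"}

    def test_threshold_at_most_one_is_error(self):
        with pytest.raises(ValueError):
            foldchange_gene_sets(self._table(), "a", "b", threshold=1.0)

    def test_planted_lineage_recall(self):
        """8-fold planted lineage genes are recovered at >=0.95 recall under
        default expression noise (plants at the scale of the full design)."""
        from enhancerkit.simulate import scenario, simulate

        st_ = simulate(
            scenario(
                "baseline", seed=77, n_genes=800, n_lineage_a=300, n_lineage_b=100,
                chrom_length=12_000_000,
            )
        )
        a_set, b_set = foldchange_gene_sets(st_.expression, "a", "b")
        planted_a = set(st_.truth.lineage_a)
        recall = len(a_set & planted_a) / len(planted_a)
        assert recall >= 0.95
        assert not (a_set & b_set)


class TestOccupancyChanges:
    def test_equal_signal_zero_log2fc(self, uniform_track_factory):
        t = uniform_track_factory({"chr1": 10_000}, 1.0)
        (c,) = occupancy_changes([GenomicInterval("chr1", 100, 500)], t, t)
        assert c.log2fc == 0.0
        assert c.group == "other"

    def test_se_grouping_and_depletion_signal(self, knockout_study):
        st_ = knockout_study
        cs = call_superenhancers(
            st_.peaks_for("tbet"), st_.tracks["tbet_a"], st_.tracks["control"],
            st_.genes,
        )
        gm = assign_genes(cs, st_.genes)
        changes = occupancy_changes(
            st_.peaks_for("ptefb"), st_.tracks["ptefb_a"], st_.tracks["ptefb_b"],
            cs, gm,
        )
        groups = {c.group for c in changes}
        assert groups == {"SE", "typical", "other"}
        constituent_names = set(st_.truth.constituent_names)
        for c in changes:
            if c.name in constituent_names:
                assert c.group == "SE"
        se = [c.log2fc for c in changes if c.group == "SE"]
        other = [c.log2fc for c in changes if c.group == "other"]
        # planted 4-fold depletion at SE sites
        assert np.median(se) == pytest.approx(-2.0, abs=0.3)
        assert mann_whitney_u(se, other).p < 0.05

    def test_undepleted_factor_shows_no_shift(self, knockout_study):
        st_ = knockout_study
        cs = call_superenhancers(
            st_.peaks_for("tbet"), st_.tracks["tbet_a"], st_.tracks["control"],
            st_.genes,
        )
        gm = assign_genes(cs, st_.genes)
        changes = occupancy_changes(
            st_.peaks_for("brd4"), st_.tracks["brd4_a"], st_.tracks["brd4_b"],
            cs, gm,
        )
        se = [c.log2fc for c in changes if c.group == "SE"]
        assert abs(np.median(se)) < 0.2

    def test_group_labels_partition_sites(self, knockout_study):
        st_ = knockout_study
        cs = call_superenhancers(
            st_.peaks_for("tbet"), st_.tracks["tbet_a"], st_.tracks["control"],
            st_.genes,
        )
        gm = assign_genes(cs, st_.genes)
        sites = st_.peaks_for("ptefb")
        changes = occupancy_changes(
            sites, st_.tracks["ptefb_a"], st_.tracks["ptefb_b"], cs, gm
        )
        comparison = compare_change_groups(changes)
        assert sum(comparison.counts.values()) == len(sites)


class TestCompareGroups:
    def test_single_element_groups_do_not_crash(self, uniform_track_factory):
        from enhancerkit.diffstats import OccupancyChange

        changes = [
            OccupancyChange(GenomicInterval("chr1", 0, 10), "a", 1, 1, 0.0, "SE"),
            OccupancyChange(GenomicInterval("chr1", 20, 30), "b", 1, 2, 1.0, "other"),
        ]
        out = compare_change_groups(changes)
        assert len(out.tests) == 1
        assert np.isfinite(out.tests["ks_p"]).all()

    def test_empty_comparison_skipped(self):
        from enhancerkit.diffstats import OccupancyChange

        changes = [
            OccupancyChange(GenomicInterval("chr1", 0, 10), "a", 1, 1, 0.0, "SE"),
            OccupancyChange(GenomicInterval("chr1", 20, 30), "b", 1, 2, 1.0, "other"),
        ]
        out = compare_change_groups(changes)  # no "typical" group
        assert list(out.tests["comparison"]) == ["SE_vs_other"]


class TestDependentSites:
    def test_threshold_inclusion(self):
        from enhancerkit.diffstats import OccupancyChange

        mk = lambda s, fc: OccupancyChange(
            GenomicInterval("chr1", s, s + 10), "", 1, 1, fc, "other"
        )
        sites = dependent_sites([mk(0, -2.0), mk(20, 0.0), mk(40, -1.0)])
        assert [s.start for s in sites] == [0, 40]

    def test_coupled_factor_loss(self, knockout_study):
        """P-TEFb loss concentrates at Med1-dependent sites when both are
        depleted at the same planted super-enhancer sites."""
        st_ = knockout_study
        cs = call_superenhancers(
            st_.peaks_for("tbet"), st_.tracks["tbet_a"], st_.tracks["control"],
            st_.genes,
        )
        gm = assign_genes(cs, st_.genes)
        med1 = occupancy_changes(
            st_.peaks_for("med1"), st_.tracks["med1_a"], st_.tracks["med1_b"], cs, gm
        )
        dep = dependent_sites(med1)
        ptefb = occupancy_changes(
            st_.peaks_for("ptefb"), st_.tracks["ptefb_a"], st_.tracks["ptefb_b"],
            cs, gm,
        )
        at_dep = [c.log2fc for c in changes_at(ptefb, dep)]
        dep_keys = {(s.chrom, s.start, s.end) for s in dep}
        at_ind = [
            c.log2fc
            for c in ptefb
            if (c.site.chrom, c.site.start, c.site.end) not in dep_keys
        ]
        assert np.median(at_dep) < np.median(at_ind)


def test_pearson_utility():
    rng = np.random.default_rng(2)
    x = rng.normal(size=100)
    assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
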