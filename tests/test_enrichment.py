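import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2 as chi2_dist

import elevexpr as ex
from elevexpr.enrichment import (
    EnrichmentError,
    _largest_remainder,
    drop_unexpressed,
)


def brute_force_yates(table):
    """Textbook 2x2 Yates chi-square, written independently of the package."""
    O = np.asarray(table, float)
    total = O.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            E = O[i].sum() * O[:, j].sum() / total
            d = max(abs(O[i, j] - E) - 0.5, 0.0)
            stat += d * d / E
    return stat, chi2_dist.sf(stat, 1)


class TestMeanExpression:
    def test_constant_gene(self):
        df = pd.DataFrame({"s1": [3.0], "s2": [3.0]}, index=["g1"])
        assert ex.mean_expression(df)["g1"] == 3.0

    def test_missing_gene_listed_in_error(self, normalized):
        with pytest.raises(EnrichmentError, match="NOPE"):
            ex.mean_expression(normalized, {"NOPE1", "NOPE2"})

    def test_matches_row_mean_oracle(self, normalized):
        sub = normalized.iloc[:50]
        means = ex.mean_expression(normalized, set(sub.index))
        expected = sub.to_numpy().mean(axis=1)
        assert np.allclose(means.loc[sub.index.sort_values()].to_numpy(),
                           pd.Series(expected, index=sub.index).sort_index().to_numpy())

    def test_zero_expression_genes_dropped(self):
        means = pd.Series([0.0, 2.0, 0.0, 5.0], index=list("abcd"))
        assert list(drop_unexpressed(means).index) == ["b", "d"]


class TestComputeBins:
    def test_unit_edges(self):
        means = pd.Series(np.linspace(0, 10, 50))
        scheme = ex.compute_bins(means, n_bins=10)
        assert np.allclose(scheme.edges, np.arange(11))

    def test_reproduces_published_edges(self):
        """Candidate means spanning [0.02, 7600]: first two upper edges land
        at ~760.02 and ~1520.02 (printed as 760.01 and 1,520)."""
        means = pd.Series(np.linspace(0.02, 7600.0, 179))
        scheme = ex.compute_bins(means, n_bins=10)
        assert scheme.edges[1] == pytest.approx(760.01, abs=0.5)
        assert scheme.edges[2] == pytest.approx(1520.0, abs=0.5)

    def test_occupancy_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        means = pd.Series(rng.uniform(0, 100, 200))
        scheme = ex.compute_bins(means, n_bins=10)
        edges = scheme.edges
        brute = np.zeros(10, dtype=int)
        for x in means:
            for k in range(10):
                hi_ok = x < edges[k + 1] or (k == 9 and x == edges[10])
                if edges[k] <= x and hi_ok:
                    brute[k] += 1
                    break
        assert np.array_equal(scheme.candidate_counts, brute)
        assert scheme.candidate_counts.sum() == 200

    def test_degenerate_range_rejected(self):
        with pytest.raises(EnrichmentError):
            ex.compute_bins(pd.Series(np.full(20, 5.0)), n_bins=10)


class TestFilterBins:
    def _paper_like_scheme(self):
        # 179 genes spanning [0.02, 7600]: 156 in bin 1, 15 in bin 2, a
        # small mid tail, and 4 genes scattered over sparse (<=2-gene)
        # bins whose lower edges lie above 3,000 counts
        counts = [156, 15, 2, 2, 1, 1, 1, 0, 0, 1]
        edges = np.linspace(0.02, 7600.0, 11)
        vals = []
        for k, c in enumerate(counts):
            vals.extend(np.linspace(edges[k] + 1, edges[k + 1] - 1, c))
        means = pd.Series(vals, index=[f"g{i}" for i in range(len(vals))])
        means.iloc[0] = 0.02
        means.iloc[-1] = 7600.0
        scheme = ex.compute_bins(means, n_bins=10)
        assert list(scheme.candidate_counts) == counts
        return scheme

    def test_paper_like_occupancy_drops_to_175(self):
        scheme = self._paper_like_scheme()
        filtered = ex.filter_bins(scheme)
        # bins with lower edge > 3000 (bins 5..10) and <=2 genes drop
        assert filtered.n_candidates == 175
        assert np.isclose(filtered.candidate_props.sum(), 1.0)

    def test_no_bin_meets_criterion_is_identity(self):
        means = pd.Series(np.linspace(0, 100, 100))
        scheme = ex.compute_bins(means, n_bins=10)
        filtered = ex.filter_bins(scheme)
        assert np.array_equal(filtered.retained, scheme.retained)
        assert filtered.n_candidates == scheme.n_candidates

    def test_sparse_high_bins_dropped_and_props_renormalize(self):
        scheme = self._paper_like_scheme()
        filtered = ex.filter_bins(scheme)
        dropped = scheme.retained & ~filtered.retained
        assert scheme.candidate_counts[dropped].sum() == 4
        assert np.isclose(filtered.candidate_props.sum(), 1.0)

    def test_all_bins_removed_rejected(self):
        means = pd.Series(np.linspace(4000, 40000, 20))
        scheme = ex.compute_bins(means, n_bins=10)
        with pytest.raises(EnrichmentError):
            ex.filter_bins(ex.filter_bins(scheme, min_genes=100), min_genes=100)


class TestBuildBackground:
    def test_disjoint_union_arithmetic(self):
        bg = ex.build_background(
            {f"u{i}" for i in range(100)},
            {f"d{i}" for i in range(10)},
            {f"c{i}" for i in range(5)},
        )
        assert len(bg) == 115

    def test_nested_de_genes_leave_size_unchanged(self):
        uni = {f"u{i}" for i in range(100)}
        assert len(ex.build_background(uni, {"u1", "u2"}, {"u3"})) == 100

    def test_matches_set_union_oracle(self, bundle, fitted_model):
        de = fitted_model.de_genes(("highland", "lowland"))
        got = ex.build_background(bundle.background, de, bundle.candidates)
        assert got == (
            bundle.background.gene_ids | de | bundle.candidates.gene_ids
        )


class TestMatchBackground:
    def _scheme(self, props, total=100):
        counts = (np.asarray(props) * total).astype(int)
        vals, idx = [], []
        edges = np.linspace(0, 10 * len(props), len(props) + 1)
        for k, c in enumerate(counts):
            for i in range(c):
                vals.append(edges[k] + 5.0)
                idx.append(f"c{k}_{i}")
        means = pd.Series(vals, index=idx)
        scheme = ex.compute_bins(means, n_bins=len(props))
        # force exact span so bins align with constructed edges
        return scheme

    def test_proportional_availability_exhausted(self):
        """Availability c x candidate counts => N = c x candidate total."""
        cand = pd.Series(
            np.repeat([5, 15, 25, 35, 45, 55, 65, 75, 85, 95.0], 10)
        )
        scheme = ex.compute_bins(cand, n_bins=10)
        bg_vals = np.repeat(cand.to_numpy(), 3)
        bg = pd.Series(bg_vals, index=[f"b{i}" for i in range(len(bg_vals))])
        matched = ex.match_background(bg, scheme, seed=0)
        assert matched.total_n == 3 * len(cand)
        assert np.array_equal(
            matched.per_bin_counts, 3 * scheme.candidate_counts[scheme.retained]
        )

    def test_two_bin_quota_maximization(self):
        """Props (0.9, 0.1), availability (900, 5): the maximal feasible N
        under largest-remainder apportionment, checked against an
        independent brute-force maximization over N (which gives 55,
        quotas (50, 5))."""
        props = np.array([0.9, 0.1])
        avail = np.array([900, 5])
        best, best_q = 0, None
        for n in range(1, 906):
            q = _largest_remainder(n, props)
            if np.all(q <= avail):
                best, best_q = n, q
        assert best == 55
        assert np.array_equal(best_q, [50, 5])

        cand = pd.Series(
            np.concatenate([np.linspace(0, 9.99, 90), np.linspace(10.1, 20, 10)])
        )
        scheme = ex.compute_bins(cand, n_bins=2)
        bg_vals = np.concatenate(
            [np.random.default_rng(1).uniform(0, 9.9, 900),
             np.random.default_rng(2).uniform(10.1, 19.9, 5)]
        )
        bg = pd.Series(bg_vals, index=[f"b{i}" for i in range(905)])
        matched = ex.match_background(bg, scheme, seed=0)
        assert matched.total_n == best
        assert np.array_equal(matched.per_bin_counts, best_q)

    def test_out_of_range_genes_excluded(self):
        cand = pd.Series(np.linspace(10, 20, 50))
        scheme = ex.compute_bins(cand, n_bins=5)
        bg = pd.Series(
            np.concatenate([np.linspace(11, 19, 40), [5.0, 25.0, 30.0]]),
            index=[f"b{i}" for i in range(43)],
        )
        matched = ex.match_background(bg, scheme, seed=3)
        assert not set(matched.gene_ids) & {"b40", "b41", "b42"}

    def test_empty_retained_bin_is_error(self):
        cand = pd.Series(np.linspace(0, 10, 50))
        scheme = ex.compute_bins(cand, n_bins=5)
        bg = pd.Series(np.linspace(0, 1.9, 30), index=[f"b{i}" for i in range(30)])
        with pytest.raises(EnrichmentError, match="bin"):
            ex.match_background(bg, scheme, seed=0)

    def test_seeded_determinism(self, normalized, bundle):
        cand_means = drop_unexpressed(
            ex.mean_expression(normalized, bundle.candidates)
        )
        scheme = ex.filter_bins(ex.compute_bins(cand_means))
        bg_means = ex.mean_expression(normalized, bundle.background)
        m1 = ex.match_background(bg_means, scheme, seed=9)
        m2 = ex.match_background(bg_means, scheme, seed=9)
        assert m1.gene_ids == m2.gene_ids

    def test_proportions_within_one_over_n(self, normalized, bundle):
        cand_means = drop_unexpressed(
            ex.mean_expression(normalized, bundle.candidates)
        )
        scheme = ex.filter_bins(ex.compute_bins(cand_means))
        bg_means = ex.mean_expression(normalized, bundle.background)
        for seed in range(20):
            m = ex.match_background(bg_means, scheme, seed=seed)
            got = m.per_bin_counts / m.total_n
            assert np.max(np.abs(got - scheme.candidate_props)) <= 1.0 / m.total_n
            chi2_m, p_m = ex.verify_match(
                scheme.candidate_counts[scheme.retained], m.per_bin_counts
            )
            assert p_m > 0.99


class TestVerifyMatch:
    def test_identical_distributions(self):
        chi2, p = ex.verify_match(np.array([50, 30, 20]), np.array([50, 30, 20]))
        assert chi2 == 0.0
        assert p == 1.0

    def test_two_bin_hand_computation(self):
        """2 bins => 2x2 with Yates; checked against the textbook formula."""
        chi2, p = ex.verify_match(np.array([90, 10]), np.array([45, 5]))
        ref_chi2, ref_p = brute_force_yates([[90, 45], [10, 5]])
        assert chi2 == pytest.approx(ref_chi2, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=1e-12)

    def test_empty_bins_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            chi2, p = ex.verify_match(
                np.array([50, 0, 50]), np.array([25, 0, 25])
            )
        assert chi2 == 0.0
        assert any("dropped" in r.message for r in caplog.records)


class TestYatesChi2:
    @pytest.mark.parametrize(
        "cells,expected_chi2,expected_p",
        [
            ((29, 813, 175, 11656), 17.94, 2.3e-5),
            ((18, 669, 175, 11656), 4.84, 0.028),
            ((18, 703, 175, 11656), 4.00, 0.046),
        ],
    )
    def test_published_tables(self, cells, expected_chi2, expected_p):
        chi2, p = ex.yates_chi2(*cells)
        assert chi2 == pytest.approx(expected_chi2, abs=0.01)
        assert p == pytest.approx(expected_p, rel=0.05)

    def test_proportional_table_scores_zero(self):
        chi2, p = ex.yates_chi2(10, 100, 10, 100)
        assert chi2 == 0.0
        assert p == 1.0

    def test_symmetry_under_row_and_column_swap(self):
        base = ex.yates_chi2(29, 813, 175, 11656)
        assert ex.yates_chi2(175, 11656, 29, 813) == base      # row swap
        assert ex.yates_chi2(813, 29, 11656, 175) == base      # column swap

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 2000, size=4)
            got = ex.yates_chi2(a, b, c, d)
            ref = brute_force_yates([[a, b], [c, d]])
            assert got[0] == pytest.approx(ref[0], abs=1e-10)
            assert got[1] == pytest.approx(ref[1], abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(EnrichmentError, match="margin"):
            ex.yates_chi2(0, 0, 5, 10)

    @given(
        a=st.integers(1, 5000), b=st.integers(1, 5000),
        c=st.integers(1, 5000), d=st.integers(1, 5000),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_statistic_nonnegative_p_valid(self, a, b, c, d):
        chi2, p = ex.yates_chi2(a, b, c, d)
        assert chi2 >= 0.0
        assert 0.0 <= p <= 1.0


class TestNestedConstruction:
    def test_agrees_with_scipy_on_well_separated_tables(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            cd = int(rng.integers(5, 50))
            dt = cd + int(rng.integers(50, 500))
            cb = cd + int(rng.integers(50, 300))
            bt = dt + cb + int(rng.integers(1000, 9000))
            table = np.array(
                [[cd, dt - cd], [cb - cd, bt - dt - (cb - cd)]]
            )
            E = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if np.abs(table - E).min() < 0.5:
                continue  # scipy's uncapped correction differs there
            got = ex.nested_yates_chi2(cd, dt, cb, bt)
            ref = chi2_contingency(table, correction=True)
            assert got[0] == pytest.approx(ref.statistic, abs=1e-10)
            assert got[1] == pytest.approx(ref.pvalue, abs=1e-10)
            checked += 1

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(EnrichmentError):
            ex.nested_yates_chi2(50, 40, 10, 1000)


class TestEnrichmentCall:
    def test_depleted_case_not_flagged(self):
        """Strong depletion: significant p but candidate rate lower in DE."""
        res = ex.test_enrichment("x", 1, 500, 175, 1000)
        assert res.p < 0.05
        assert not res.enriched

    def test_flag_agrees_with_manual_rate_comparison(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            cd, dt, cb, bt = rng.integers(1, 1000, size=4)
            res = ex.test_enrichment("x", cd, dt, cb, bt)
            manual = res.p < 0.05 and cd / dt > cb / bt
            assert res.enriched == manual

    def test_report_shape(self):
        rows = [
            ex.test_enrichment("highland-lowland", 29, 813, 175, 11656),
            ex.test_enrichment("highland-midland", 18, 669, 175, 11656),
            ex.test_enrichment("midland-lowland", 18, 703, 175, 11656),
        ]
        report = ex.enrichment_report(rows)
        assert list(report["enriched"]) == ["Yes", "Yes", "Yes"]
        assert report.loc[0, "de_ratio"] == "29/813"
        assert report.loc[0, "background_ratio"] == "175/11656"


class TestEndToEndPhiRecovery:
    def test_odds_ratio_increases_with_planted_enrichment(self):
        """Estimated candidate/background DE odds ratio rises over phi in
        {1, 2, 4} (2 seeds per level)."""
        mean_or = []
        for phi in (1.0, 2.0, 4.0):
            ors = []
            for seed in (100, 101):
                cfg = ex.SimConfig(
                    n_background_genes=1500, n_candidate_genes=150,
                    de_fraction=0.12, min_abs_log2fc=1.0,
                    enrichment_factor=phi, dispersion=0.1, seed=seed,
                )
                b = ex.simulate(cfg)
                cm = b.counts
                model = ex.NegativeBinomialDE()
                model.fit(cm.counts.T, zones=cm.zones(), blocks=cm.blocks(),
                          gene_ids=cm.gene_ids)
                de = model.de_genes(("highland", "lowland"))
                cand = b.candidates.gene_ids
                bg = b.background.gene_ids
                p_c = len(de & cand) / len(cand)
                p_b = max(len(de & bg) / len(bg), 1e-9)
                ors.append((p_c / max(1 - p_c, 1e-9)) / (p_b / (1 - p_b)))
            mean_or.append(np.mean(ors))
        assert mean_or[0] < mean_or[1] < mean_or[2]
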