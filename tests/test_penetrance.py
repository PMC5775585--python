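import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import newton_logistic_dose
from riskallele.penetrance import (
    CohortCounts,
    association_pvalue,
    expected_counts,
    genotype_distribution,
    penetrances_from_or,
    relative_difference,
    s_prime,
    scenario_curves,
    scenario_pair,
    sweep_r_d1,
    sweep_r_nc,
)


def _odds(d):
    return d / (1.0 - d)


class TestPenetrances:
    def test_unit_odds_ratio_is_identity(self):
        assert penetrances_from_or(0.17, 1.0) == pytest.approx((0.17, 0.17))

    def test_worked_value(self):
        d2, d3 = penetrances_from_or(0.02, 1.3)
        assert d2 == pytest.approx(0.025845, abs=1e-6)
        assert _odds(d2) / _odds(0.02) == pytest.approx(1.3, rel=1e-12)

    def test_homozygote_odds_chain(self):
        d2, d3 = penetrances_from_or(0.03, 2.0)
        assert _odds(d3) == pytest.approx(4.0 * _odds(0.03), rel=1e-12)

    @given(
        st.floats(min_value=0.001, max_value=0.95),
        st.floats(min_value=0.2, max_value=5.0),
    )
    def test_odds_identity_everywhere(self, d1, r):
        d2, d3 = penetrances_from_or(d1, r)
        assert 0.0 < d2 < 1.0 and 0.0 < d3 < 1.0
        assert _odds(d2) / _odds(d1) == pytest.approx(r, rel=1e-10)
        assert _odds(d3) / _odds(d2) == pytest.approx(r, rel=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            penetrances_from_or(0.0, 1.3)
        with pytest.raises(ValueError):
            penetrances_from_or(0.1, 0.0)


class TestGenotypeDistribution:
    def test_no_association_reduces_to_hwe(self):
        q = 0.3
        dist = genotype_distribution(q, 0.1, 0.1, 0.1)
        hwe = ((1 - q) ** 2, 2 * q * (1 - q), q**2)
        assert dist.case_props == pytest.approx(hwe, abs=1e-12)
        assert dist.control_props == pytest.approx(hwe, abs=1e-12)

    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.005, max_value=0.5),
        st.floats(min_value=1.0, max_value=3.0),
    )
    def test_triples_normalized(self, q, d1, r):
        d2, d3 = penetrances_from_or(d1, r)
        dist = genotype_distribution(q, d1, d2, d3)
        assert sum(dist.case_props) == pytest.approx(1.0, abs=1e-12)
        assert sum(dist.control_props) == pytest.approx(1.0, abs=1e-12)

    def test_risk_homozygotes_enriched_in_cases(self):
        q = 0.2
        d2, d3 = penetrances_from_or(0.02, 1.3)
        dist = genotype_distribution(q, 0.02, d2, d3)
        assert dist.case_props[2] > q**2  # above the HWE share

    def test_allele_swap_reverses_genotype_order(self):
        d2, d3 = penetrances_from_or(0.05, 1.5)
        a = genotype_distribution(0.2, 0.05, d2, d3)
        b = genotype_distribution(0.8, 0.05, d2, d3)
        # same penetrances, mirrored frequency: HWE weights reverse
        hwe_a = np.array([0.8**2, 2 * 0.2 * 0.8, 0.2**2])
        hwe_b = hwe_a[::-1]
        expect = hwe_b * np.array([0.05, d2, d3])
        assert b.case_props == pytest.approx(tuple(expect / expect.sum()), abs=1e-12)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            genotype_distribution(0.0, 0.1, 0.1, 0.1)


class TestExpectedCounts:
    def test_exact_quarters(self):
        from riskallele.penetrance import GenotypeDistribution

        dist = GenotypeDistribution((0.25, 0.5, 0.25), (0.25, 0.5, 0.25))
        counts = expected_counts(1000, 1000, dist)
        assert counts.case_counts == (250, 500, 250)

    def test_thirds_round_to_near_total(self):
        from riskallele.penetrance import GenotypeDistribution

        third = (1 / 3, 1 / 3, 1 / 3)
        counts = expected_counts(1000, 1000, GenotypeDistribution(third, third))
        assert sum(counts.case_counts) in (999, 1000, 1001)

    def test_half_to_even_per_cell(self):
        from riskallele.penetrance import GenotypeDistribution

        dist = GenotypeDistribution((0.05, 0.15, 0.80), (0.25, 0.5, 0.25))
        counts = expected_counts(10, 10, dist)
        # 0.5 rounds to 0 (even), 1.5 to 2, 8.0 stays
        assert counts.case_counts == (0, 2, 8)

    def test_degenerate_detection(self):
        assert CohortCounts(10, 10, (10, 0, 0), (10, 0, 0)).degenerate
        assert CohortCounts(10, 10, (0, 0, 0), (5, 5, 0)).degenerate
        assert CohortCounts(10, 10, (10, 0, 0), (0, 5, 5)).degenerate  # separated
        assert not CohortCounts(10, 10, (4, 4, 2), (5, 4, 1)).degenerate


class TestAssociationTest:
    def test_null_table_gives_unit_pvalue(self):
        counts = CohortCounts(300, 300, (100, 150, 50), (100, 150, 50))
        res = association_pvalue(counts)
        assert abs(res.beta) < 1e-8 and res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_matches_newton_oracle_on_chain_table(self):
        d2, d3 = penetrances_from_or(0.03, 1.3)
        dist = genotype_distribution(0.2, 0.03, d2, d3)
        counts = expected_counts(1000, 1000, dist)
        res = association_pvalue(counts)
        beta, se, p = newton_logistic_dose(counts.case_counts, counts.control_counts)
        assert res.beta == pytest.approx(beta, rel=1e-6)
        assert res.se == pytest.approx(se, rel=1e-6)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_scaling_counts_shrinks_pvalue(self):
        counts = CohortCounts(100, 100, (50, 40, 10), (60, 32, 8))
        big = CohortCounts(
            1000,
            1000,
            tuple(10 * c for c in counts.case_counts),
            tuple(10 * c for c in counts.control_counts),
        )
        small, large = association_pvalue(counts), association_pvalue(big)
        assert large.beta == pytest.approx(small.beta, rel=1e-6)
        assert large.p_value < small.p_value

    def test_degenerate_flagged_not_raised(self):
        res = association_pvalue(CohortCounts(10, 10, (10, 0, 0), (10, 0, 0)))
        assert res.flagged and res.p_value == 1.0 and res.beta is None

    def test_likelihood_ratio_variant_agrees_for_large_counts(self):
        counts = CohortCounts(2000, 2000, (900, 800, 300), (1000, 780, 220))
        wald = association_pvalue(counts, test="wald")
        lrt = association_pvalue(counts, test="lrt")
        assert lrt.p_value == pytest.approx(wald.p_value, rel=0.2)


class TestScenarios:
    def test_symmetric_at_half(self):
        cmp_ = scenario_pair(500, 500, 0.05, 1.4, 0.5)
        assert cmp_.p_minor_risk == pytest.approx(cmp_.p_major_risk, rel=1e-9)

    def test_minor_risk_more_significant(self):
        cmp_ = scenario_pair(1000, 1000, 0.03, 1.5, 0.1)
        assert cmp_.p_minor_risk < cmp_.p_major_risk

    def test_null_odds_ratio_flat(self):
        cmp_ = scenario_pair(1000, 1000, 0.03, 1.0, 0.2)
        assert cmp_.p_minor_risk == pytest.approx(1.0, abs=1e-6)
        assert cmp_.p_major_risk == pytest.approx(1.0, abs=1e-6)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            scenario_pair(100, 100, 0.03, 1.5, 0.7)

    def test_rounding_only_flips_near_ties(self):
        """Integer rounding may flip the minor-vs-major ordering, but only
        when the exact expected tables put the two scenarios in a near-tie."""
        rng = np.random.default_rng(11)
        for _ in range(60):
            r = rng.uniform(1.1, 2.0)
            d1 = rng.uniform(0.01, 0.25)
            p = rng.uniform(0.05, 0.45)
            rounded = scenario_pair(1000, 1000, d1, r, p, round_counts=True)
            if rounded.p_minor_risk > rounded.p_major_risk:
                exact = scenario_pair(1000, 1000, d1, r, p, round_counts=False)
                assert exact.p_minor_risk <= exact.p_major_risk * (1 + 1e-9)


class TestRelativeDifference:
    def test_identical_curves_zero(self):
        grid = np.linspace(0.05, 0.5, 10)
        curve = np.column_stack([grid, -2.0 * np.ones_like(grid)])
        assert relative_difference(curve, curve.copy()) == 0.0

    def test_double_depth_gives_half(self):
        grid = np.linspace(0.05, 0.5, 10)
        minor = np.column_stack([grid, -4.0 * np.ones_like(grid)])
        major = np.column_stack([grid, -2.0 * np.ones_like(grid)])
        assert relative_difference(minor, major) == pytest.approx(0.5)

    def test_mismatched_grids_rejected(self):
        a = np.column_stack([np.linspace(0.05, 0.5, 10), np.zeros(10)])
        b = np.column_stack([np.linspace(0.1, 0.5, 10), np.zeros(10)])
        with pytest.raises(ValueError):
            relative_difference(a, b)

    def test_sprime_positive_for_typical_parameters(self):
        value, excluded = s_prime(1000, 1000, 0.03, 1.5)
        assert value > 0.0 and excluded == 0

    def test_curves_share_grid(self):
        cm, cM, _ = scenario_curves(500, 500, 0.05, 1.3)
        assert np.allclose(cm[:, 0], cM[:, 0])


class TestSweeps:
    def test_small_grid_is_finite(self):
        grid = sweep_r_d1(400, 400, d1_range=(0.05, 0.1), r_range=(1.3, 1.6))
        assert grid.s_prime.shape == (2, 2)
        assert np.isfinite(grid.s_prime).all()

    def test_equal_split_consistency(self):
        """The nc sweep at nc = n_total/2 equals the d1 sweep entry with the
        same cohort sizes."""
        g1 = sweep_r_d1(1000, 1000, d1_range=(0.03,), r_range=(1.4,))
        g2 = sweep_r_nc(2000, 0.03, r_range=(1.4,), nc_range=(1000,))
        assert g2.s_prime[0, 0] == pytest.approx(g1.s_prime[0, 0], rel=1e-12)

    def test_frame_axes(self):
        grid = sweep_r_nc(600, 0.05, r_range=(1.5, 1.8), nc_range=(200, 400))
        df = grid.to_frame()
        assert list(df.index) == [1.5, 1.8] and list(df.columns) == [200, 400]

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            sweep_r_d1(100, 100, d1_range=(), r_range=(1.2,))
        with pytest.raises(ValueError):
            sweep_r_nc(1000, 0.03, r_range=(1.2,), nc_range=(1200,))
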