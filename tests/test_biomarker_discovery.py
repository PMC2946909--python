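"""Differential testing, BH correction, covariate exclusion and validation.

The Mann-Whitney engine is checked against an independent brute-force
oracle that enumerates all group assignments and scores extremeness by the
pairwise-win count; the discovery z-test against its closed form; BH
against a hand-stepped example.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from uromarker import (
    PanelDefinition,
    SimConfig,
    adjust_bh,
    discover_biomarkers,
    exclude_covariate_associated,
    generate_cohort,
    mann_whitney_p,
    regulation_factor,
    validate_mann_whitney,
)
from uromarker.workflows import empirical_bh_fdr
from uromarker.biomarker_discovery import (
    test_peptide_discovery as welch_discovery,
)

from conftest import make_matrix


def _matrix_from_groups(vals_a, vals_b):
    """One-peptide matrix with group labels, detected everywhere."""
    amps = np.array([list(vals_a) + list(vals_b)], dtype=float)
    m = make_matrix([1000.0], [30.0], amps)
    groups = pd.Series(
        ["a"] * len(vals_a) + ["b"] * len(vals_b), index=m.sample_ids
    )
    return m, groups


class TestDiscoveryZTest:
    def test_identical_groups_give_p_one(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        m, groups = _matrix_from_groups(vals, vals)
        rec = welch_discovery(m, groups, min_group_freq=0.0)
        assert rec["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_z_for_designed_separation(self):
        # log10 groups with sample mean exactly 3.0 vs 4.0, sample SD exactly
        # 0.1, n = 20 each: z = 1.0 / sqrt(0.01/20 + 0.01/20)
        n = 20
        c = np.sqrt((n - 1) / n)  # ddof=1 correction for the +/- pattern
        pat = np.tile([1.0, -1.0], n // 2)
        log_a = 3.0 + 0.1 / c * pat
        log_b = 4.0 + 0.1 / c * pat
        m, groups = _matrix_from_groups(10.0**log_a, 10.0**log_b)
        rec = welch_discovery(m, groups)
        z_expected = 1.0 / np.sqrt(0.01 / n + 0.01 / n)
        assert z_expected == pytest.approx(np.sqrt(1000), rel=1e-12)
        p_expected = 2 * stats.norm.sf(z_expected)
        assert rec["p_raw"].iloc[0] == pytest.approx(p_expected, rel=1e-9)
        assert p_expected < 1e-100

    def test_frequency_gate_blocks_sparse_peptides(self):
        # detected in 40% and 45% of the groups: below the 50% rule
        amps = np.zeros((1, 40))
        amps[0, :8] = 100.0  # 8 of 20 in group a
        amps[0, 20:29] = 100.0  # 9 of 20 in group b
        m = make_matrix([1000.0], [30.0], amps)
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=m.sample_ids)
        rec = welch_discovery(m, groups)
        assert not rec["tested"].iloc[0]
        assert np.isnan(rec["p_raw"].iloc[0])

    def test_one_group_at_half_frequency_is_tested(self):
        amps = np.zeros((1, 40))
        amps[0, :10] = 100.0  # exactly 50% of group a
        amps[0, 20:24] = 100.0  # 20% of group b
        m = make_matrix([1000.0], [30.0], amps)
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=m.sample_ids)
        assert welch_discovery(m, groups)["tested"].iloc[0]
        assert not welch_discovery(m, groups, scope="both_groups")["tested"].iloc[0]

    def test_under_three_detected_is_untestable_not_fatal(self):
        amps = np.array([[5.0, 6.0, 0, 0, 7.0, 8.0, 9.0, 2.0]])
        m = make_matrix([1000.0], [30.0], amps)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=m.sample_ids)
        rec = welch_discovery(m, groups, min_group_freq=0.0)
        assert not rec["tested"].iloc[0]

    def test_normal_reference_never_exceeds_t_reference(self, small_cohort):
        _, cohort, matrix, _ = small_cohort
        groups = cohort.diagnosis()
        p_norm = welch_discovery(matrix, groups, reference="normal")["p_raw"]
        p_t = welch_discovery(matrix, groups, reference="t")["p_raw"]
        ok = p_norm.notna()
        assert (p_norm[ok] <= p_t[ok] + 1e-15).all()


class TestBH:
    def test_hand_stepped_example(self):
        q, sig = adjust_bh([0.01, 0.02, 0.04, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04 / 0.75, 0.5])
        assert sig.sum() == 2

    def test_single_p_unchanged(self):
        q, _ = adjust_bh([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_all_ones(self):
        q, sig = adjust_bh([1.0, 1.0, 1.0])
        assert np.all(q == 1.0) and not sig.any()

    def test_empty_input(self):
        q, sig = adjust_bh([])
        assert len(q) == 0 and len(sig) == 0

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q, _ = adjust_bh(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_fdr_controlled_with_t_reference(self):
        # calibrated reference, independent peptides, 10% true effects:
        # mean false-discovery proportion stays at or below the nominal 0.05
        cfg = SimConfig(
            n_peptides=400, n_differential_type=40, n_age_correlated=0,
            n_housekeeping=0, n_calibrants=0, dilution_sd=0.0, seed=0,
        )
        df = empirical_bh_fdr(cfg, n_replicates=200, base_seed=77, reference="t")
        se = df["fdp"].std() / np.sqrt(len(df))
        assert df["fdp"].mean() <= 0.05 + 2 * se

    def test_complete_null_rarely_discovers_with_t_reference(self):
        cfg = SimConfig(
            n_peptides=400, n_differential_type=0, n_age_correlated=0,
            n_housekeeping=0, n_calibrants=0, dilution_sd=0.0, seed=0,
        )
        df = empirical_bh_fdr(cfg, n_replicates=200, base_seed=99, reference="t")
        frac_any = (df["n_significant"] > 0).mean()
        assert frac_any <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 200)


def oracle_mann_whitney(x, y):
    """Independent enumeration oracle: p = fraction of assignments whose
    pairwise-win count is at least as extreme as observed."""
    pooled = np.concatenate([x, y])
    m = len(x)
    center = m * len(y) / 2

    def wins(a, b):
        return sum(
            (1.0 if u > v else 0.5 if u == v else 0.0) for u in a for v in b
        )

    obs = abs(wins(x, y) - center)
    hits = total = 0
    for comb in combinations(range(len(pooled)), m):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb)] = True
        total += 1
        if abs(wins(pooled[sel], pooled[~sel]) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_disjoint_groups_exact_enumeration(self):
        p = mann_whitney_p([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_identical_groups(self):
        assert mann_whitney_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_all_tied(self):
        assert mann_whitney_p([5, 5, 5], [5, 5, 5, 5]) == 1.0

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        assert mann_whitney_p(x, y) == pytest.approx(mann_whitney_p(y, x))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
        if seed % 2:
            # tied data: small integer support
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
        else:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.8, 1, n2)
        assert mann_whitney_p(x, y) == pytest.approx(oracle_mann_whitney(x, y), abs=1e-12)

    def test_large_sample_tie_corrected_approximation(self):
        rng = np.random.default_rng(2)
        x = np.round(rng.normal(0, 1, 60), 1)
        y = np.round(rng.normal(0.4, 1, 50), 1)
        p = mann_whitney_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))


class TestValidation:
    def test_zeros_enter_as_bottom_ties(self):
        amps = np.array([[0, 0, 0, 5.0, 6.0, 7.0]])
        m = make_matrix([1000.0], [30.0], amps)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=m.sample_ids)
        panel = PanelDefinition(["p1"])
        res = validate_mann_whitney(m, panel, groups)
        assert res["p"].iloc[0] == pytest.approx(0.1)  # 2/20 of C(6,3)

    def test_missing_panel_peptide_recorded(self):
        m = make_matrix([1000.0], [30.0], [[1.0, 2.0, 3.0, 4.0]])
        groups = pd.Series(["a", "a", "b", "b"], index=m.sample_ids)
        res = validate_mann_whitney(m, PanelDefinition(["p1", "ghost"]), groups)
        assert res.loc["ghost", "missing"]
        assert not res.loc["p1", "missing"]

    def test_significance_threshold_inclusive(self):
        # p <= alpha counts as significant
        m, groups = _matrix_from_groups([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        res = validate_mann_whitney(m, PanelDefinition(["p1"]), groups, alpha=2 / 252)
        assert res["significant"].iloc[0]
        assert res.attrs["n_significant"] == 1


class TestCovariateExclusion:
    def _matrix_with_age(self, n=110, seed=0):
        rng = np.random.default_rng(seed)
        age = np.sort(rng.uniform(20, 80, n))
        dep = 10 ** (3 + 0.05 * (age - 50))  # deterministic increasing
        flat = 10 ** rng.normal(3, 0.3, n)
        amps = np.vstack([dep, flat])
        m = make_matrix([1000.0, 2000.0], [25.0, 35.0], amps)
        return m, pd.Series(age, index=m.sample_ids)

    def test_deterministic_age_function_excluded(self):
        m, age = self._matrix_with_age()
        excluded, retained, pv = exclude_covariate_associated(m, ["p1", "p2"], age)
        assert "p1" in excluded
        assert "p2" in retained

    def test_identical_bins_retained(self):
        amps = np.full((1, 40), 100.0)
        m = make_matrix([1000.0], [30.0], amps)
        cov = pd.Series(np.arange(40, dtype=float), index=m.sample_ids)
        excluded, retained, pv = exclude_covariate_associated(m, ["p1"], cov)
        assert retained == ["p1"] and pv["p1"] == 1.0

    def test_constant_covariate_rejected(self):
        m, _ = self._matrix_with_age(n=20)
        cov = pd.Series(50.0, index=m.sample_ids)
        with pytest.raises(ValueError):
            exclude_covariate_associated(m, ["p1"], cov)

    def test_most_age_correlated_candidates_excluded(self):
        # study-scale run: 91 designed age-correlated peptides among the
        # discovery cohort; the screen must catch >= 85% of those reaching it
        cfg = SimConfig(seed=31)  # defaults: 68+42, 1500 peptides, 91 age
        cohort, matrix, truth = generate_cohort(cfg)
        age = cohort.data["age"].astype(float)
        age_ids = list(truth.peptides.index[truth.peptides.is_age_correlated])
        excluded, _, _ = exclude_covariate_associated(matrix, age_ids, age)
        assert len(excluded) >= 0.85 * len(age_ids)


class TestRegulationFactor:
    def test_up_regulated(self):
        assert regulation_factor(10, 20) == pytest.approx(2.0)

    def test_down_regulated(self):
        assert regulation_factor(10, 5) == pytest.approx(-2.0)

    def test_equal_means_convention(self):
        assert regulation_factor(7, 7) == 1.0

    def test_zero_mean_flagged_missing(self):
        assert np.isnan(regulation_factor(0, 5))

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(1e-6, 1e6, allow_nan=False),
        b=st.floats(1e-6, 1e6, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        if a != b:
            assert regulation_factor(a, b) == pytest.approx(-regulation_factor(b, a))
        mag = abs(regulation_factor(a, b))
        assert mag >= 1.0


def test_report_ordering_is_deterministic(small_cohort):
    _, cohort, matrix, _ = small_cohort
    rec = discover_biomarkers(matrix, cohort.diagnosis())
    qs = rec["q_bh"].to_numpy()
    tested = ~np.isnan(qs)
    assert np.all(np.diff(qs[tested]) >= -1e-15)
    assert not rec["tested"].iloc[-1] or rec["tested"].all()
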