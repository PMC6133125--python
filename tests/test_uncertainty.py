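"""Recovery statistics and variance-component / uncertainty analysis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import olfpt
from olfpt.datamodel import measurements_from_records
from olfpt.synthetic import TRUE_THRESHOLDS
from olfpt.uncertainty import VarianceComponents


from oracles import brute_force_anova


def _study_from_groups(groups, component="NBU"):
    """One lab per group, dosing 1 ug/m3, so log10(c/x) = group value."""
    rows = []
    for lab, values in enumerate(groups):
        for rep, v in enumerate(values, start=1):
            rows.append(
                {
                    "test_id": "T",
                    "participant_id": f"P{lab:02d}",
                    "component": component,
                    "replicate": rep,
                    "dosed_mass_conc_ug_m3": 1.0,
                    "measured_odor_conc_oue_m3": 10.0 ** (-v),
                }
            )
    return measurements_from_records(rows)


class TestVarianceComponents:
    def test_hand_example_two_labs(self):
        vc = olfpt.estimate_variance_components(
            _study_from_groups([[0.0, 0.0], [1.0, 1.0]]), "NBU"
        )
        assert vc.s_w == 0.0
        assert vc.s_L == pytest.approx(math.sqrt(0.5), rel=1e-12)
        assert vc.s_R == pytest.approx(0.7071, abs=5e-5)

    def test_identical_values(self):
        vc = olfpt.estimate_variance_components(
            _study_from_groups([[0.3, 0.3], [0.3, 0.3], [0.3, 0.3]]), "NBU"
        )
        assert (vc.s_w, vc.s_L, vc.s_R) == (0.0, 0.0, 0.0)

    def test_negative_between_lab_variance_truncated(self):
        # within-lab spread large, lab means equal -> MS_between < s_w^2
        vc = olfpt.estimate_variance_components(
            _study_from_groups([[-1.0, 1.0], [-1.0, 1.0], [-1.0, 1.0]]), "NBU"
        )
        assert vc.s_L == 0.0
        assert vc.s_R == vc.s_w

    def test_composition_of_printed_magnitudes(self):
        vc = VarianceComponents(component="NBU", s_w=0.064, s_L=0.198)
        assert round(vc.s_R, 3) == 0.208

    def test_matches_bruteforce_oracle_on_balanced_grid(self):
        rng = np.random.default_rng(20160451)
        for p, n in itertools.product(range(2, 6), range(2, 5)):
            groups = [list(rng.normal(2.0, 0.3, n)) for _ in range(p)]
            vc = olfpt.estimate_variance_components(_study_from_groups(groups), "NBU")
            s_w_ref, s_L_ref = brute_force_anova(groups)
            assert vc.s_w == pytest.approx(s_w_ref, abs=1e-10)
            assert vc.s_L == pytest.approx(s_L_ref, abs=1e-10)

    def test_matches_bruteforce_oracle_unbalanced(self):
        rng = np.random.default_rng(7)
        groups = [list(rng.normal(0.0, 0.2, n)) for n in (2, 3, 4, 2, 5)]
        vc = olfpt.estimate_variance_components(_study_from_groups(groups), "NBU")
        s_w_ref, s_L_ref = brute_force_anova(groups)
        assert vc.s_w == pytest.approx(s_w_ref, abs=1e-10)
        assert vc.s_L == pytest.approx(s_L_ref, abs=1e-10)
        assert vc.n_labs == 5 and vc.n_results == 16

    def test_single_replicate_labs_are_excluded(self):
        groups = [[0.1, 0.2], [0.3, 0.1], [9.9]]
        vc = olfpt.estimate_variance_components(_study_from_groups(groups), "NBU")
        ref = olfpt.estimate_variance_components(_study_from_groups(groups[:2]), "NBU")
        assert (vc.s_w, vc.s_L) == (ref.s_w, ref.s_L)

    def test_insufficient_replication(self):
        with pytest.raises(ValueError, match="laboratories"):
            olfpt.estimate_variance_components(
                _study_from_groups([[0.1, 0.2], [0.3]]), "NBU"
            )

    def test_invariant_s_R_composition(self, default_study):
        for comp in TRUE_THRESHOLDS:
            vc = olfpt.estimate_variance_components(default_study, comp)
            assert vc.s_R**2 == pytest.approx(vc.s_w**2 + vc.s_L**2, abs=1e-12)
            assert vc.rel_low_pct * vc.rel_high_pct == pytest.approx(1e4, rel=1e-9)


class TestExpandedUncertainty:
    def test_en13725_limit(self):
        u = olfpt.expanded_uncertainty(olfpt.EN13725_SR_LIMIT)
        assert 2 * olfpt.EN13725_SR_LIMIT == pytest.approx(0.3442)
        assert u.U95_db == pytest.approx(3.442, abs=5e-4)
        assert round(u.rel_low_pct) == 45
        assert float(f"{u.rel_high_pct:.2g}") == 220.0

    def test_zero(self):
        assert olfpt.expanded_uncertainty(0.0) == (0.0, 100.0, 100.0)

    def test_aac_magnitude(self):
        u = olfpt.expanded_uncertainty(0.359, rounded=True)
        assert u == (7.18, 19.0, 522.0)

    @given(st.floats(0.0, 0.6))
    @settings(max_examples=200, deadline=None)
    def test_reciprocal_bounds_and_monotonicity(self, s_R):
        u = olfpt.expanded_uncertainty(s_R)
        assert u.rel_low_pct * u.rel_high_pct == pytest.approx(1e4, rel=1e-9)
        assert olfpt.expanded_uncertainty(s_R + 0.01).U95_db > u.U95_db


class TestReproducibilityFactor:
    @pytest.mark.parametrize(
        "s_R,expected,tol",
        [(0.0, 1.0, 1e-12), (0.208, 3.88, 5e-3), (0.1721, 3.07, 5e-3)],
    )
    def test_values(self, s_R, expected, tol):
        assert olfpt.reproducibility_factor(s_R) == pytest.approx(expected, abs=tol)

    def test_is_k2_quantile_of_measurement_ratio(self):
        # simulation cross-check: the k = 2 convention bounds the ratio of
        # two iid lognormal measurements at the two-sigma (95.45 %) quantile
        rng = np.random.default_rng(11)
        s_R = 0.208
        a, b = rng.normal(0, s_R, (2, 200_000))
        ratio = 10.0 ** np.abs(a - b)
        q = np.quantile(ratio, 0.954499736)
        assert olfpt.reproducibility_factor(s_R) == pytest.approx(q, rel=0.02)


class TestRecoveries:
    def test_definition_and_noise_free(self, noise_free_study):
        rec = olfpt.recoveries(noise_free_study, TRUE_THRESHOLDS)
        assert np.allclose(rec["recovery"], 1.0, atol=1e-12)
        assert np.allclose(rec["log10_recovery"], 0.0, atol=1e-12)

    def test_quotient(self):
        df = _study_from_groups([[0.0], [math.log10(585 / 234)]])
        rec = olfpt.recoveries(df, {"NBU": 1.0})
        assert rec["recovery"].iloc[1] == pytest.approx(234 / 585, rel=1e-12)

    def test_missing_threshold(self, noise_free_study):
        with pytest.raises(KeyError, match="AAC"):
            olfpt.recoveries(noise_free_study, {"NBU": 123.0})

    def test_within_margin_fraction(self):
        df = _study_from_groups(
            [[-math.log10(0.4)], [0.0], [-math.log10(2.5)]]
        )
        rec = olfpt.recoveries(df, {"NBU": 1.0})
        frac = olfpt.within_margin_fraction(rec)
        assert frac["NBU"] == pytest.approx(1 / 3)
        assert olfpt.within_margin_fraction(rec, low=0.1, high=10)["NBU"] == 1.0

    def test_margin_fraction_matches_normal_model(self):
        # share inside 50-200% vs the closed-form 2*Phi(0.30103/s) - 1
        from scipy.stats import norm

        rng = np.random.default_rng(5)
        s = 0.208
        logs = rng.normal(0.0, s, 60_000)
        groups = [[-v] for v in logs]  # one measurement per lab
        rec = olfpt.recoveries(_study_from_groups(groups), {"NBU": 1.0})
        frac = olfpt.within_margin_fraction(rec)["NBU"]
        expected = 2 * norm.cdf(math.log10(2.0) / s) - 1
        assert frac == pytest.approx(expected, abs=0.01)


class TestRecoverySummary:
    def test_relative_sd(self):
        groups = [[-math.log10(v)] for v in (1.0, 2.0, 3.0)]
        summaries = olfpt.recovery_summary(
            _study_from_groups(groups), {"NBU": 1.0}
        )
        (s,) = summaries
        assert s.X_mean_measured == pytest.approx(2.0)
        assert s.rel_sd_pct == pytest.approx(50.0)
        assert s.X_mean_assigned == pytest.approx(1.0)

    def test_symmetric_quartiles(self):
        a = 0.4
        groups = [[-v] for v in (-a, 0.0, a)]
        (s,) = olfpt.recovery_summary(_study_from_groups(groups), {"NBU": 1.0})
        q1, med, q3 = s.log_recovery_quartiles
        assert med == pytest.approx(0.0, abs=1e-12)
        assert q1 == pytest.approx(-q3, abs=1e-12)
        assert q1 <= med <= q3

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="single measurement"):
            olfpt.recovery_summary(_study_from_groups([[0.1]]), {"NBU": 1.0})
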