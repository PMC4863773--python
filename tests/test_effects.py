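"""Transition-row algebra: hazard-ratio transform, mixture, age trend."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chf_cea import (
    AgeTrend,
    ArmLabel,
    HazardRatioSet,
    ModelConfig,
    NYHAState,
    apply_age_trend,
    apply_hazard_ratios,
    blend_usual_care,
    build_arm_tables,
)
from chf_cea.params import HOSP_IDX, LIVING_STATES, TransitionRow

from conftest import make_row, uniform_table


def hrs(hf=1.0, cv=1.0, ac=1.0):
    return HazardRatioSet(
        hr_hf_hosp=hf, hr_hf_hosp_ci=(hf, hf),
        hr_cv_death=cv, hr_cv_death_ci=(cv, cv),
        hr_all_cause_death=ac, hr_all_cause_death_ci=(ac, ac))


def _blend_endpoints():
    table = uniform_table(toII_noh=0.55, toII_h=0.20, toIII_noh=0.10,
                          toIII_h=0.05, cv_death=0.06, noncv_death=0.04)
    placebo = table.rows[NYHAState.II]
    treated = apply_hazard_ratios(placebo, hrs(hf=0.58, cv=0.76))
    return placebo, treated


@st.composite
def random_rows(draw):
    raw = draw(st.lists(st.floats(0.0, 1.0), min_size=10, max_size=10)
               .filter(lambda v: sum(v) > 1e-6))
    p = np.array(raw)
    return TransitionRow(NYHAState.II, p / p.sum())


class TestApplyHazardRatios:
    def test_identity_when_all_hrs_one(self, simple_table):
        row = simple_table.rows[NYHAState.II]
        out = apply_hazard_ratios(row, hrs(1.0, 1.0))
        np.testing.assert_array_equal(out.probs, row.probs)

    def test_full_effect_limit_hr_zero(self):
        """hr_hf_hosp = 0 moves all hospitalization mass to the matching
        no-hospitalization entries."""
        row = make_row(NYHAState.II, toII_noh=0.5, toII_h=0.2,
                       toIII_noh=0.2, cv_death=0.1)
        out = apply_hazard_ratios(row, hrs(hf=0.0))
        assert out.p_dest(NYHAState.II, True) == 0.0
        assert out.p_dest(NYHAState.II, False) == pytest.approx(0.7)
        assert out.p_dest(NYHAState.III, False) == pytest.approx(0.2)

    def test_hand_arithmetic_oracle_cv_only(self):
        """Frozen hand-computed expectation for the published point HRs.

        hosp entries x0.58 with freed mass to the matching noh entries;
        cv_death 0.06 x 0.76 = 0.0456; the 0.0144 freed death mass scales
        the living entries by (0.900 + 0.0144)/0.900 = 1.016.
        """
        row = make_row(NYHAState.II, toII_noh=0.55, toII_h=0.20,
                       toIII_noh=0.10, toIII_h=0.05,
                       cv_death=0.06, noncv_death=0.04)
        out = apply_hazard_ratios(row, hrs(hf=0.58, cv=0.76), mode="cv-only")
        expected = {
            "toII_noh": (0.55 + 0.2 * 0.42) * 1.016,   # 0.644144
            "toII_h": 0.2 * 0.58 * 1.016,              # 0.117856
            "toIII_noh": (0.10 + 0.05 * 0.42) * 1.016,  # 0.122936
            "toIII_h": 0.05 * 0.58 * 1.016,            # 0.029464
            "cv_death": 0.0456,
            "noncv_death": 0.04,
        }
        got = out.as_dict()
        for k, v in expected.items():
            assert got[k] == pytest.approx(v, abs=1e-12), k
        assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_cause_split_preserves_cause_shares(self):
        row = make_row(NYHAState.II, toII_noh=0.8, cv_death=0.15,
                       noncv_death=0.05)
        out = apply_hazard_ratios(row, hrs(ac=0.76), mode="all-cause-split")
        assert out.p_death == pytest.approx(0.2 * 0.76)
        assert out.p_cv_death / out.p_death == pytest.approx(0.75)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cv_only_leaves_noncv_untouched(self):
        row = make_row(NYHAState.II, toII_noh=0.8, cv_death=0.15,
                       noncv_death=0.05)
        out = apply_hazard_ratios(row, hrs(cv=0.5), mode="cv-only")
        assert out.p_noncv_death == pytest.approx(0.05)

    @settings(deadline=None, derandomize=True)
    @given(row=random_rows(),
           hf=st.floats(0.05, 1.5), cv=st.floats(0.05, 1.5))
    def test_row_sum_and_range_preserved(self, row, hf, cv):
        """Any HR transform keeps the row a probability row (sum 1, [0,1])."""
        try:
            out = apply_hazard_ratios(row, hrs(hf=hf, cv=cv))
        except Exception:
            # infeasible transforms must raise, never emit a bad row
            return
        assert abs(out.probs.sum() - 1.0) < 1e-12
        assert np.all(out.probs >= -1e-15) and np.all(out.probs <= 1 + 1e-15)

    @settings(deadline=None, derandomize=True)
    @given(row=random_rows(), hf1=st.floats(0.1, 1.0), hf2=st.floats(0.1, 1.0))
    def test_hosp_monotone_in_hr(self, row, hf1, hf2):
        """A smaller hospitalization HR never increases any hosp entry."""
        lo, hi = sorted((hf1, hf2))
        out_lo = apply_hazard_ratios(row, hrs(hf=lo))
        out_hi = apply_hazard_ratios(row, hrs(hf=hi))
        assert np.all(out_lo.probs[HOSP_IDX] <= out_hi.probs[HOSP_IDX] + 1e-12)


class TestBlend:
    def test_endpoints_exact(self, simple_table):
        placebo = simple_table.rows[NYHAState.II]
        treated = apply_hazard_ratios(placebo, hrs(hf=0.58, cv=0.76))
        np.testing.assert_array_equal(
            blend_usual_care(placebo, treated, 0.0).probs, placebo.probs)
        np.testing.assert_array_equal(
            blend_usual_care(placebo, treated, 1.0).probs, treated.probs)

    def test_entrywise_weighted_average(self, simple_table):
        placebo = simple_table.rows[NYHAState.II]
        treated = apply_hazard_ratios(placebo, hrs(hf=0.58, cv=0.76))
        out = blend_usual_care(placebo, treated, 0.437)
        np.testing.assert_allclose(
            out.probs, 0.437 * treated.probs + 0.563 * placebo.probs,
            atol=1e-15)

    @settings(deadline=None, derandomize=True)
    @given(f=st.floats(0.0, 1.0), g=st.floats(0.0, 1.0))
    def test_affine_composition(self, f, g):
        """Blending at f then g along the same endpoints composes affinely:
        blend(blend(f), treated, g) == blend(f + g - f*g)."""
        placebo, treated = _blend_endpoints()
        step = blend_usual_care(blend_usual_care(placebo, treated, f),
                                treated, g)
        direct = blend_usual_care(placebo, treated, f + g - f * g)
        np.testing.assert_allclose(step.probs, direct.probs, atol=1e-12)

    def test_fraction_out_of_range(self, simple_table):
        row = simple_table.rows[NYHAState.II]
        with pytest.raises(Exception):
            blend_usual_care(row, row, 1.2)


class TestAgeTrend:
    def test_baseline_age_identity(self, simple_table):
        tr = AgeTrend.exponential()
        row = simple_table.rows[NYHAState.II]
        out = apply_age_trend(row, 68, tr)
        np.testing.assert_array_equal(out.probs, row.probs)

    def test_flat_trend_identity(self, simple_table):
        row = simple_table.rows[NYHAState.II]
        out = apply_age_trend(row, 90, AgeTrend.flat())
        np.testing.assert_array_equal(out.probs, row.probs)

    def test_hand_arithmetic_at_ratio_1_2(self):
        """trend ratio 1.2 on cv=noncv=0.05: deaths become 0.06 each and the
        living mass rescales by 0.88/0.90."""
        row = make_row(NYHAState.II, toII_noh=0.6, toIII_noh=0.3,
                       cv_death=0.05, noncv_death=0.05)
        tr = AgeTrend({68: 1.0, 70: 1.2}, baseline_age=68)
        out = apply_age_trend(row, 70, tr)
        assert out.p_cv_death == pytest.approx(0.06, abs=1e-12)
        assert out.p_noncv_death == pytest.approx(0.06, abs=1e-12)
        assert out.p_dest(NYHAState.II, False) == \
            pytest.approx(0.6 * 0.88 / 0.90, abs=1e-12)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_death_mass_capped_at_one(self):
        row = make_row(NYHAState.II, toII_noh=0.1, cv_death=0.6,
                       noncv_death=0.3)
        tr = AgeTrend({68: 1.0, 90: 5.0}, baseline_age=68)
        out = apply_age_trend(row, 90, tr)
        assert out.p_death == pytest.approx(1.0)
        assert np.all(out.probs >= 0)


class TestBuildArmTables:
    def test_mixture_endpoint_zero_equals_placebo(self, base_config):
        from dataclasses import replace
        from chf_cea import TreatmentMix
        cfg = replace(base_config, mix=TreatmentMix(
            {s: 0.0 for s in LIVING_STATES}))
        ucg = build_arm_tables(cfg, ArmLabel.UCG)
        plc = build_arm_tables(cfg, ArmLabel.PLACEBO)
        for t_u, t_p in zip(ucg, plc):
            for s in LIVING_STATES:
                np.testing.assert_array_equal(t_u.rows[s].probs,
                                              t_p.rows[s].probs)

    def test_mixture_endpoint_one_equals_eg(self, base_config):
        from dataclasses import replace
        from chf_cea import TreatmentMix
        cfg = replace(base_config, mix=TreatmentMix(
            {s: 1.0 for s in LIVING_STATES}))
        ucg = build_arm_tables(cfg, ArmLabel.UCG)
        eg = build_arm_tables(cfg, ArmLabel.EG)
        for t_u, t_e in zip(ucg, eg):
            for s in LIVING_STATES:
                np.testing.assert_array_equal(t_u.rows[s].probs,
                                              t_e.rows[s].probs)

    def test_eg_cycle1_hosp_entries_scaled_by_hr(self, base_config):
        """At cycle 1 (age 68, trend multiplier 1) the eplerenone arm's
        hospitalization entries are 0.58 x placebo, up to the uniform living
        rescale that absorbs the averted cardiovascular-death mass."""
        eg = build_arm_tables(base_config, ArmLabel.EG)[0]
        plc = build_arm_tables(base_config, ArmLabel.PLACEBO)[0]
        for s in LIVING_STATES:
            p = plc.rows[s].probs
            freed_death = p[8] * (1 - 0.76)
            living = p[:8].sum()
            scale = (living + freed_death) / living
            np.testing.assert_allclose(
                eg.rows[s].probs[HOSP_IDX],
                0.58 * scale * p[HOSP_IDX], rtol=1e-9)

    def test_order_flag_changes_results_but_keeps_invariants(self, base_config):
        from dataclasses import replace
        cfg_after = replace(base_config, age_trend_order="after-treatment")
        a = build_arm_tables(base_config, ArmLabel.EG)
        b = build_arm_tables(cfg_after, ArmLabel.EG)
        # cycle 1 is at baseline age (trend 1) so only later cycles differ
        diffs = [np.abs(x.rows[s].probs - y.rows[s].probs).max()
                 for x, y in zip(a[1:], b[1:]) for s in LIVING_STATES]
        assert max(diffs) > 0
        for tables in (a, b):
            for t in tables:
                t.validate(1e-9)

    def test_hr_unity_from_cycle_reverts_to_placebo(self, base_config):
        from dataclasses import replace
        cfg = replace(base_config, hr_unity_from_cycle=2)
        eg = build_arm_tables(cfg, ArmLabel.EG)
        plc = build_arm_tables(cfg, ArmLabel.PLACEBO)
        for s in LIVING_STATES:
            # cycle 1 still treated
            assert not np.array_equal(eg[0].rows[s].probs, plc[0].rows[s].probs)
            # cycles >= 2 identical to placebo
            for c in range(1, cfg.horizon):
                np.testing.assert_array_equal(eg[c].rows[s].probs,
                                              plc[c].rows[s].probs)
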