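"""DSA and PSA: parameter paths, distribution building, Monte Carlo runs."""

import math


import numpy as np
import pytest

from chf_cea import (
    ArmLabel,
    DSASpec,
    NYHAState,
    build_psa_distributions,
    icer,
    run_arms,
    run_dsa,
    run_psa,
)
from chf_cea.sensitivity import get_param, set_param


def _base_icer(config):
    arms = run_arms(config)
    return icer(arms[ArmLabel.UCG], arms[ArmLabel.EG])


class TestParamPaths:
    @pytest.mark.parametrize("path, expected", [
        ("hrs.hr_hf_hosp", 0.58),
        ("utilities.II", 0.720),
        ("mix.III", 0.937),
        ("costs.hf_hosp_event", 7136.0),
        ("costs.background_annual.I", 151.0),
        ("discount.rate", 0.05),
    ])
    def test_get(self, base_config, path, expected):
        assert get_param(base_config, path) == expected

    def test_set_roundtrip(self, base_config):
        cfg = set_param(base_config, "utilities.II", 0.5)
        assert get_param(cfg, "utilities.II") == 0.5
        assert get_param(base_config, "utilities.II") == 0.720  # original intact

    def test_set_transition_renormalizes_and_mirrors_iv(self, base_config):
        cfg = set_param(base_config, "transition.III.cv_death", 0.2)
        row = cfg.placebo_table.rows[NYHAState.III]
        assert row.probs.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(
            row.probs, cfg.placebo_table.rows[NYHAState.IV].probs)


class TestDSA:
    def test_degenerate_spec_returns_base_icer(self, base_config):
        u = get_param(base_config, "utilities.II")
        df = run_dsa(base_config, [DSASpec("utilities.II", u, u)])
        base = _base_icer(base_config)
        assert df.loc[0, "icer_qaly_low"] == pytest.approx(base.icer_per_qaly)
        assert df.loc[0, "icer_qaly_high"] == pytest.approx(base.icer_per_qaly)

    def test_utility_bounds_bracket_base_monotonically(self, base_config):
        """Higher NYHA II utility widens the QALY gain and lowers the ICER,
        so the two bounds bracket the base case."""
        u = get_param(base_config, "utilities.II")
        df = run_dsa(base_config,
                     [DSASpec("utilities.II", 0.5 * u, min(1.5 * u, 1.0))])
        base = _base_icer(base_config).icer_per_qaly
        lo, hi = df.loc[0, "icer_qaly_low"], df.loc[0, "icer_qaly_high"]
        assert hi < base < lo  # utility up -> ICER down

    def test_cv_death_hr_upper_ci_raises_icer(self, base_config):
        """At the upper confidence limit of the cardiovascular-death HR the
        survival benefit shrinks and the ICER rises above base."""
        df = run_dsa(base_config, [DSASpec(
            "hrs.hr_cv_death", *base_config.hrs.hr_cv_death_ci)])
        base = _base_icer(base_config).icer_per_qaly
        assert df.loc[0, "icer_qaly_high"] > base
        assert df.loc[0, "icer_qaly_low"] < base

    def test_tornado_ordering(self, base_config):
        df = run_dsa(base_config)
        ranges = df["range_qaly"].to_numpy()
        finite = ranges[np.isfinite(ranges)]
        assert np.all(np.diff(finite) <= 1e-9)  # sorted descending


class TestBuildDistributions:
    def test_families_per_parameter_class(self, base_config):
        dists = {d.path: d for d in build_psa_distributions(base_config)}
        assert dists["utilities.II"].family == "beta"
        assert dists["costs.hf_hosp_event"].family == "uniform"
        assert dists["transition.II.toIII_h"].family == "triangular"
        # fixed treatment costs are not sampled
        assert not any("eplerenone" in p or "spiro" in p or "monitor" in p
                       for p in dists)

    def test_beta_moment_match(self, base_config):
        d = {x.path: x for x in build_psa_distributions(base_config)}[
            "utilities.II"]
        a, b = d.args["a"], d.args["b"]
        assert a / (a + b) == pytest.approx(0.720, rel=1e-9)

    def test_uniform_pm50_range(self, base_config):
        d = {x.path: x for x in build_psa_distributions(base_config)}[
            "costs.hf_hosp_event"]
        assert (d.args["lo"], d.args["hi"]) == (3568.0, 10704.0)

    def test_triangular_mode_at_base(self, base_config):
        d = {x.path: x for x in build_psa_distributions(base_config)}[
            "transition.II.cv_death"]
        assert d.args["mode"] == get_param(base_config, "transition.II.cv_death")

    def test_sampled_means_converge(self, base_config):
        """Empirical means of each sampled parameter sit within 3 SE of the
        configured mean at 10,000 draws."""
        rng = np.random.default_rng(7)
        for d in build_psa_distributions(base_config):
            draws = np.array([d.sample(rng) for _ in range(10_000)])
            if d.family == "beta":
                expected = d.base
            elif d.family == "uniform":
                expected = (d.args["lo"] + d.args["hi"]) / 2
            elif d.family == "triangular":
                expected = (d.args["lo"] + d.args["mode"] + d.args["hi"]) / 3
            else:
                continue
            se = draws.std(ddof=1) / math.sqrt(len(draws))
            assert abs(draws.mean() - expected) < 3 * se + 1e-12, d.path


class TestRunPSA:
    def test_degenerate_distributions_reproduce_base_exactly(self, base_config):
        base = _base_icer(base_config)
        res = run_psa(base_config, n_iter=3, seed=1,
                      dists=build_psa_distributions(base_config, rel_width=0.0))
        assert np.all(res.delta_cost == base.delta_cost)
        assert np.all(res.delta_qaly == base.delta_qaly)
        assert np.all(res.delta_ly == base.delta_ly)

    def test_same_seed_reproducible(self, base_config):
        a = run_psa(base_config, n_iter=20, seed=42)
        b = run_psa(base_config, n_iter=20, seed=42)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)
        assert a.ceac == b.ceac

    def test_different_seed_differs(self, base_config):
        a = run_psa(base_config, n_iter=20, seed=1)
        b = run_psa(base_config, n_iter=20, seed=2)
        assert not np.array_equal(a.delta_cost, b.delta_cost)

    def test_ceac_nondecreasing(self, base_config):
        res = run_psa(base_config, n_iter=200, seed=3)
        fracs = res.ceac_frame()["fraction_cost_effective"].to_numpy()
        assert np.all(np.diff(fracs) >= -1e-12)
        assert np.all((fracs >= 0) & (fracs <= 1))

    def test_sampled_rows_validate(self, base_config):
        """Every sampled configuration carries valid probability rows."""
        from chf_cea.sensitivity import _sampled_config
        dists = build_psa_distributions(base_config)
        for i in range(50):
            rng = np.random.default_rng(i)
            cfg = _sampled_config(base_config, dists, rng)
            cfg.placebo_table.validate(1e-9)

    def test_summary_and_exports(self, base_config, tmp_path):
        res = run_psa(base_config, n_iter=50, seed=5)
        s = res.summary()
        assert s["n_iter"] == 50 and s["n_failed"] == 0
        assert 0.0 <= s["pct_ce_at_threshold"] <= 1.0
        assert sum(s["quadrants"].values()) == 50
        res.scatter_frame().to_csv(tmp_path / "scatter.csv", index=False)
        res.ceac_frame().to_csv(tmp_path / "ceac.csv", index=False)
        assert (tmp_path / "scatter.csv").exists()
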