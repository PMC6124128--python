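"""LRT/AIC comparison, Kendall screening and the staged winnowing pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phylospatial.gls_core import FitOptions, GLSFit, ModelSpec, fit_ols
from phylospatial.model_compare import (
    WinnowConfig,
    aic_rank,
    kendall_screen,
    lr_test,
    run_winnow,
    stage2_covariation,
    stage3_external,
)
from phylospatial.synthetic_data import (
    SimulationConfig,
    simulate_benchmark_suite,
)


class TestLrTest:
    def test_worked_examples(self):
        # LR = 2 * delta logLik at printed log-likelihood pairs
        r1 = lr_test(-54.021, -54.015, df=1)
        assert r1.lr == pytest.approx(0.012, abs=2e-3)
        r2 = lr_test(-101.543, -100.649, df=1)
        assert r2.lr == pytest.approx(1.788, abs=2e-3)
        assert not r2.significant_05

    def test_equal_logliks(self):
        r = lr_test(-10.0, -10.0, df=1)
        assert r.lr == 0.0
        assert r.p == pytest.approx(1.0)

    def test_small_negative_clamped_large_negative_raises(self):
        assert lr_test(-10.0, -10.0 - 1e-8, df=1).lr == 0.0
        with pytest.raises(ValueError, match="not nested"):
            lr_test(-10.0, -11.0, df=1)

    def test_bad_df_rejected(self):
        with pytest.raises(ValueError):
            lr_test(-10.0, -9.0, df=0)

    def test_chi2_tail(self):
        from scipy.stats import chi2

        r = lr_test(-20.0, -16.0, df=2)
        assert r.p == pytest.approx(chi2.sf(8.0, 2))
        assert r.significant_05 and r.significant_bonferroni == (r.p < 0.003)


def _mock_fit(label_y, predictors, loglik, n_params, societies):
    spec = ModelSpec(label_y, tuple(predictors))
    params = pd.DataFrame(
        {"beta": [0.0], "se": [1.0], "t": [0.0], "p": [1.0]}, index=["(Intercept)"]
    )
    from phylospatial.gls_core import CovarianceModel

    return GLSFit(
        spec=spec,
        params=params,
        n=len(societies),
        k=n_params - 1,
        loglik=loglik,
        cov=CovarianceModel(w_p=0, w_s=0),
        method="gls",
        n_free_cov=1,
        societies=tuple(societies),
    )


class TestAicRank:
    def test_aic_definition(self):
        f = _mock_fit("y", ["a"], loglik=-10.0, n_params=3, societies=["s1"] * 5)
        assert f.aic == pytest.approx(26.0)

    def test_tie_flags_neither_way(self):
        socs = [f"s{i}" for i in range(10)]
        f1 = _mock_fit("y", ["a"], -10.0, 3, socs)
        f2 = _mock_fit("y", ["b"], -10.0, 3, socs)
        r = aic_rank([f1, f2])
        assert not r.better(f1.spec.label, f2.spec.label)
        assert not r.better(f2.spec.label, f1.spec.label)

    def test_pairwise_threshold_flags(self):
        # AICs 100, 101.5, 104: pairwise differences 1.5, 4.0, 2.5 -> only
        # the 104 model is ever beaten (by both others); 100 vs 101.5 is a tie
        socs = [f"s{i}" for i in range(10)]
        fits = [
            _mock_fit("y", [p], -(a - 2 * 3) / 2, 3, socs)
            for p, a in zip("abc", (100.0, 101.5, 104.0))
        ]
        r = aic_rank(fits)
        labels = [f.spec.label for f in fits]
        better_pairs = [
            (i, j)
            for i, j in itertools.permutations(range(3), 2)
            if r.better(labels[i], labels[j])
        ]
        assert better_pairs == [(0, 2), (1, 2)]
        beaten = {j for _, j in better_pairs}
        assert beaten == {2}

    def test_differing_case_sets_rejected(self):
        f1 = _mock_fit("y", ["a"], -10.0, 3, [f"s{i}" for i in range(10)])
        f2 = _mock_fit("y", ["b"], -10.0, 3, [f"s{i}" for i in range(9)])
        with pytest.raises(ValueError, match="case set"):
            aic_rank([f1, f2])


class TestKendallScreen:
    def test_perfect_concordance_and_discordance(self):
        t = pd.DataFrame(
            {
                "a": np.arange(10.0),
                "b": np.arange(10.0) * 2,
                "c": -np.arange(10.0),
            }
        )
        s = kendall_screen(t, ["a", "b", "c"])
        assert s.tau.loc["a", "b"] == pytest.approx(1.0)
        assert s.tau.loc["a", "c"] == pytest.approx(-1.0)

    def test_brute_force_pair_counting_oracle(self):
        # tau from explicit concordant/discordant enumeration (no ties)
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.permutation(9).astype(float)
            y = rng.permutation(9).astype(float)
            conc = disc = 0
            for (i, j) in itertools.combinations(range(9), 2):
                s = (x[i] - x[j]) * (y[i] - y[j])
                conc += s > 0
                disc += s < 0
            expected = (conc - disc) / (conc + disc)
            t = pd.DataFrame({"x": x, "y": y})
            got = kendall_screen(t, ["x", "y"]).tau.loc["x", "y"]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_four_point_example(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        s = kendall_screen(t, ["x", "y"], min_pairs=4)
        assert s.tau.loc["x", "y"] == pytest.approx(2 / 3)

    def test_constant_variable_reported_missing(self):
        t = pd.DataFrame({"x": np.arange(10.0), "y": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            s = kendall_screen(t, ["x", "y"])
        assert np.isnan(s.tau.loc["x", "y"])

    def test_too_few_pairs_skipped(self):
        t = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 1, 3]})
        with pytest.warns(UserWarning, match="complete pairs"):
            s = kendall_screen(t, ["x", "y"])
        assert np.isnan(s.tau.loc["x", "y"])


@pytest.fixture(scope="module")
def direct_data():
    return simulate_benchmark_suite(
        SimulationConfig(n_societies=60, seed=1, scenario="direct")
    )


class TestStages:
    def test_trait_without_covariates_passes_stage2(self, direct_data):
        d = direct_data
        screen = kendall_screen(d.traits, list(d.cultural_vars))
        # force a screen with no significant partners for T1
        screen.p.loc[:, :] = 1.0
        res = stage2_covariation(
            d.traits,
            d.P,
            d.D,
            ["T1"],
            d.parasite_vars,
            screen,
            sig_pairs={"T1": ["PAR"]},
            options=FitOptions(restarts=2),
        )
        assert res.retained == ["T1"]
        assert "no covariates" in res.table["note"].iloc[0]

    def test_stage3_empty_covariate_sets_reduces_to_stage1(self, direct_data):
        d = direct_data
        res = stage3_external(
            d.traits,
            d.P,
            d.D,
            ["T1"],
            d.parasite_vars,
            covariate_sets={},
            sig_pairs={"T1": ["PAR"]},
            options=FitOptions(restarts=2),
        )
        assert res.verdicts == {"T1": "parasite retained"}
        assert res.retained == ["T1"]


class TestRunWinnow:
    def test_empty_cultural_list_exits_cleanly(self, direct_data):
        d = direct_data
        cfg = WinnowConfig(
            traits=d.traits,
            P=d.P,
            D=d.D,
            cultural_vars=(),
            parasite_vars=d.parasite_vars,
        )
        report = run_winnow(cfg)
        assert report.final_retained == []
        assert report.trail == []

    def test_deterministic_given_seed(self, direct_data, tmp_path):
        from phylospatial.io import render_report

        d = direct_data
        cfg = dict(
            traits=d.traits,
            P=d.P,
            D=d.D,
            cultural_vars=("T1", "T2"),
            parasite_vars=d.parasite_vars,
            covariate_sets={"environment": ("LAT",)},
            restarts=2,
            seed=3,
        )
        r1 = run_winnow(WinnowConfig(**cfg))
        r2 = run_winnow(WinnowConfig(**cfg))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        render_report(r1, d1)
        render_report(r2, d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_drop_forward_rule(self, direct_data):
        d = direct_data
        cfg = WinnowConfig(
            traits=d.traits,
            P=d.P,
            D=d.D,
            cultural_vars=d.cultural_vars,
            parasite_vars=d.parasite_vars,
            covariate_sets=d.covariate_sets,
            restarts=2,
            seed=0,
        )
        report = run_winnow(cfg)
        # every variable appears exactly once in the trail
        assert sorted(r["variable"] for r in report.trail) == sorted(d.cultural_vars)
        dropped1 = set(report.stage1.dropped)
        if not report.stage2.table.empty:
            fitted2 = set(report.stage2.table["y"].dropna())
            assert not dropped1 & fitted2
        dropped12 = dropped1 | set(report.stage2.dropped)
        if not report.stage3.table.empty:
            fitted3 = set(report.stage3.table["y"].dropna())
            assert not dropped12 & fitted3
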