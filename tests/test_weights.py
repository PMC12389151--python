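"""Weight engine: propensity and censoring models, weight identities,
trimming, and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from jshape.cohort import CATEGORIES
from jshape.simulate import (
    SimulationConfig,
    simulate_cohort,
    _baseline_intercepts,
)
from jshape.weights import (
    PropensityModelSpec,
    balance_report,
    combine_and_trim,
    compute_ipcw,
    compute_iptw,
    fit_censoring_model,
    fit_exposure_model,
    standardized_mean_difference,
)


@pytest.fixture(scope="module")
def cohort10k():
    return simulate_cohort(SimulationConfig(n_participants=10_000, n_waves=4, seed=21))


@pytest.fixture(scope="module")
def probs10k(cohort10k):
    spec = PropensityModelSpec(covariates=("L", "age", "female"))
    return fit_exposure_model(cohort10k.data, spec)


class TestExposureModel:
    def test_probabilities_sum_to_one(self, probs10k):
        total = probs10k[[f"prob_{c}" for c in CATEGORIES]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_intercept_only_limit_reproduces_frequencies(self, cohort10k):
        """With a constant covariate the fitted probabilities are the
        empirical category frequencies."""
        base = cohort10k.data[cohort10k.data.wave == 0].copy()
        base["one"] = 1.0
        spec = PropensityModelSpec(covariates=("one",), include_previous_category=False)
        probs = fit_exposure_model(base, spec)
        freq = base.alcohol_category.value_counts(normalize=True)
        for c in CATEGORIES:
            assert probs[f"prob_{c}"].iloc[0] == pytest.approx(freq[c], abs=1e-6)

    def test_baseline_coefficient_recovery_within_2_se(self, cohort10k):
        """Multinomial fit on the baseline wave recovers the generating
        coefficients (confounder and sex effects per category)."""
        import statsmodels.api as sm

        cfg = SimulationConfig(n_participants=10_000, n_waves=4, seed=21)
        base = cohort10k.data[cohort10k.data.wave == 0]
        X = pd.DataFrame(
            {"const": 1.0, "L": base.L.to_numpy(), "female": base.female.to_numpy()}
        )
        y = base.alcohol_category.astype(str).map(
            {c: i for i, c in enumerate(CATEGORIES)}
        )
        fit = sm.MNLogit(y.to_numpy(), X).fit(disp=0)
        b0 = _baseline_intercepts(cfg)
        bl = np.asarray(cfg.confounder_to_exposure)
        bf = np.asarray(cfg.female_to_exposure)
        # statsmodels uses category 0 (abstainer) as reference
        for j, cat_idx in enumerate(range(1, 4)):
            for row, truth in (
                (0, b0[cat_idx] - b0[0]),
                (1, bl[cat_idx] - bl[0]),
                (2, bf[cat_idx] - bf[0]),
            ):
                est = fit.params.iloc[row, j]
                se = fit.bse.iloc[row, j]
                assert abs(est - truth) < 2.5 * se

    def test_one_vs_rest_renormalizes(self, cohort10k):
        spec = PropensityModelSpec(
            covariates=("L", "age", "female"), method="one_vs_rest"
        )
        probs = fit_exposure_model(cohort10k.data, spec)
        total = probs[[f"prob_{c}" for c in CATEGORIES]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_missing_covariate_rejected(self, cohort10k):
        with pytest.raises(KeyError):
            fit_exposure_model(
                cohort10k.data, PropensityModelSpec(covariates=("nope",))
            )


class TestIptw:
    def test_reciprocal(self):
        probs = pd.DataFrame({"prob_observed": [0.25, 0.5]})
        table = pd.DataFrame({"participant_id": [1, 2], "wave": [0, 0],
                              "alcohol_category": ["moderate", "moderate"]})
        w = compute_iptw(probs, table, cumulative=False)
        assert list(w) == [4.0, 2.0]

    def test_unstabilized_mean_near_category_count(self, cohort10k, probs10k):
        """E[1/P(A|X)] = number of categories: per-wave mean ~ 4."""
        w = compute_iptw(probs10k, cohort10k.data, stabilized=False, cumulative=False)
        per_wave = w.groupby(cohort10k.data.wave).mean()
        assert np.allclose(per_wave, 4.0, atol=0.35)

    def test_stabilized_mean_near_one(self, cohort10k, probs10k):
        for numerator in ("marginal", "transition"):
            w = compute_iptw(
                cohort10k.data.pipe(lambda d: probs10k),
                cohort10k.data,
                stabilized=True,
                cumulative=False,
                numerator=numerator,
            )
            per_wave = w.groupby(cohort10k.data.wave).mean()
            assert np.allclose(per_wave, 1.0, atol=0.15)

    def test_pseudo_population_property(self, cohort10k, probs10k):
        """Unstabilized weights inflate each category arm to the whole
        sample, wave by wave."""
        w = compute_iptw(probs10k, cohort10k.data, stabilized=False, cumulative=False)
        df = cohort10k.data.assign(w=w)
        for t in (0, 2):
            wave = df[df.wave == t]
            n = len(wave)
            arm = wave.groupby("alcohol_category", observed=True).w.sum()
            assert np.allclose(arm / n, 1.0, atol=0.12)

    def test_cumulative_is_running_product(self, cohort10k, probs10k):
        flat = compute_iptw(probs10k, cohort10k.data, cumulative=False)
        cum = compute_iptw(probs10k, cohort10k.data, cumulative=True)
        df = cohort10k.data
        one = df[df.participant_id == df.participant_id.iloc[0]].index
        assert cum[one].to_numpy() == pytest.approx(np.cumprod(flat[one].to_numpy()))


class TestIpcw:
    def test_cumulative_arithmetic(self):
        ret = pd.DataFrame(
            {"participant_id": [1, 1, 1], "wave": [0, 1, 2], "p_retained": [1.0, 0.8, 0.8]}
        )
        w = compute_ipcw(ret, cumulative=True)
        assert list(w) == pytest.approx([1.0, 1.25, 1.5625])
        w2 = compute_ipcw(ret, cumulative=False)
        assert list(w2) == pytest.approx([1.0, 1.25, 1.25])

    def test_weights_at_least_one(self, cohort10k):
        ret = fit_censoring_model(cohort10k, ["L", "age", "female"])
        assert (ret.p_retained <= 1.0 + 1e-12).all() and (ret.p_retained > 0).all()
        assert (compute_ipcw(ret) >= 1.0 - 1e-12).all()

    def test_no_censoring_gives_unit_weights(self, no_confounding_config):
        from dataclasses import replace

        cfg = replace(no_confounding_config, censoring_base_rate=0.0, n_participants=500)
        cohort = simulate_cohort(cfg)
        ret = fit_censoring_model(cohort, ["L", "age", "female"])
        assert np.allclose(compute_ipcw(ret), 1.0)

    def test_ipcw_corrects_informative_censoring(self):
        """Weighted outcome prevalence among completers is closer to the
        full-cohort prevalence than the unweighted one."""
        cfg = SimulationConfig(
            n_participants=20_000,
            n_waves=3,
            seed=9,
            censoring_base_rate=0.15,
            confounder_to_censoring=1.2,
        )
        observed = simulate_cohort(cfg)
        from dataclasses import replace

        full = simulate_cohort(replace(cfg, censoring_base_rate=0.0,
                                       confounder_to_censoring=0.0))
        t = cfg.n_waves - 1
        truth = full.data[full.data.wave == t].depressed.mean()
        ret = fit_censoring_model(observed, ["L", "age", "female"])
        ret["ipcw"] = compute_ipcw(ret)
        last = observed.data.merge(ret, on=["participant_id", "wave"])
        last = last[last.wave == t]
        naive = last.depressed.mean()
        weighted = np.average(last.depressed, weights=last.ipcw)
        assert abs(weighted - truth) < abs(naive - truth)


class TestCombineAndTrim:
    def _keys(self, n):
        return pd.DataFrame({"participant_id": np.arange(n), "wave": 0})

    def test_uniform_weights_nothing_excluded(self):
        n = 500
        ws = combine_and_trim(pd.Series(np.ones(n)), pd.Series(np.ones(n)), self._keys(n))
        assert ws.n_excluded == 0

    def test_nearest_rank_two_percent_each_tail(self):
        n = 1000
        rng = np.random.default_rng(0)
        w = pd.Series(rng.permutation(np.linspace(0.1, 10, n)))
        ws = combine_and_trim(w, pd.Series(np.ones(n)), self._keys(n))
        assert ws.n_excluded == 40
        dropped = ws.table.loc[ws.table.trimmed, "combined"]
        assert (dropped < ws.lower_cut).sum() == 20
        assert (dropped > ws.upper_cut).sum() == 20

    def test_full_range_trim_is_identity(self):
        n = 200
        w = pd.Series(np.random.default_rng(1).lognormal(size=n))
        ws = combine_and_trim(w, pd.Series(np.ones(n)), self._keys(n), 0, 100)
        assert ws.n_excluded == 0
        assert np.allclose(ws.table.combined, w)

    def test_cap_mode_preserves_rows_and_bounds(self):
        n = 300
        w = pd.Series(np.random.default_rng(2).lognormal(sigma=2, size=n))
        ws = combine_and_trim(w, pd.Series(np.ones(n)), self._keys(n), mode="cap")
        assert len(ws.table) == n and ws.n_excluded == 0
        assert ws.table.combined.max() <= ws.upper_cut + 1e-12
        assert ws.table.combined.min() >= ws.lower_cut - 1e-12

    def test_combined_is_product(self):
        a = pd.Series([1.0, 2.0, 3.0])
        b = pd.Series([2.0, 2.0, 2.0])
        ws = combine_and_trim(a, b, self._keys(3), 0, 100)
        assert list(ws.table.combined) == [2.0, 4.0, 6.0]


class TestSMD:
    def test_identical_groups_zero(self):
        x = np.r_[np.ones(10), np.ones(10)]
        g = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        assert standardized_mean_difference(x, g) == 0.0

    def test_hand_computed_value(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 1.0, 50_000)
        b = rng.normal(0.0, 1.0, 50_000)
        x = np.r_[a, b]
        g = np.r_[np.ones(len(a), bool), np.zeros(len(b), bool)]
        assert standardized_mean_difference(x, g) == pytest.approx(1.0, abs=0.02)

    def test_binary_uses_proportion_variance(self):
        x = np.r_[np.repeat([1.0, 0.0], [30, 70]), np.repeat([1.0, 0.0], [50, 50])]
        g = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        expected = (0.3 - 0.5) / np.sqrt((0.3 * 0.7 + 0.5 * 0.5) / 2)
        assert standardized_mean_difference(x, g) == pytest.approx(expected)

    def test_weights_that_equalize_means_drive_smd_below_rule(self):
        # group 1: 75% ones, group 2: 25% ones; down-weighting the majority
        # value by 1/3 equalizes both weighted means at 0.5
        x = np.r_[np.ones(75), np.zeros(25), np.ones(25), np.zeros(75)]
        g = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        w = np.r_[np.full(75, 1 / 3), np.ones(25), np.ones(25), np.full(75, 1 / 3)]
        assert abs(standardized_mean_difference(x, g)) > 0.10
        assert abs(standardized_mean_difference(x, g, w)) < 0.10

    def test_zero_variance_unequal_means_raises(self):
        x = np.r_[np.zeros(5), np.ones(5)]
        g = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        with pytest.raises(ValueError):
            standardized_mean_difference(x, g, binary=False)


class TestBalanceReport:
    def test_confounded_cohort_flagged_then_balanced(self, cohort10k, probs10k):
        """The time-varying confounder is imbalanced before weighting and
        within the 0.10 rule after (untrimmed weights)."""
        df = cohort10k.data
        iptw = compute_iptw(probs10k, df, stabilized=True, cumulative=True,
                            numerator="transition")
        ret = fit_censoring_model(cohort10k, ["L", "age", "female"])
        ret["ipcw"] = compute_ipcw(ret)
        merged = df[["participant_id", "wave"]].merge(ret, on=["participant_id", "wave"])
        ws = combine_and_trim(iptw, merged["ipcw"], df, 0, 100)
        rep = balance_report(df, ws, ["L", "age", "female"])
        assert rep.table.loc[rep.table.covariate == "L", "flag_unweighted"].any()
        assert not rep.any_flagged_weighted

    def test_report_symmetry_and_finiteness(self, cohort10k, probs10k):
        df = cohort10k.data
        iptw = compute_iptw(probs10k, df, cumulative=False)
        ws = combine_and_trim(iptw, pd.Series(np.ones(len(df))), df, 0, 100)
        rep = balance_report(df, ws, ["L", "female"])
        assert np.isfinite(rep.table.smd_unweighted).all()
        assert np.isfinite(rep.table.smd_weighted).all()
        md = rep.to_markdown()
        assert "covariate" in md and "L" in md
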