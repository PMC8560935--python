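"""Estimation stages: noise-free identifiability, invariances, errors."""

import numpy as np
import pandas as pd
import pytest

from marshres import (
    AssociationModel,
    FactorialModel,
    RecoveryRateModel,
    SurveyCountModel,
    fit_association,
    fit_factorial,
    fit_recovery_rates,
    fit_survey_counts,
)
from marshres import synthetic as syn
from marshres.stats import DesignError


@pytest.fixture(scope="module")
def noise_free_recovery():
    return syn.gen_patch_recovery(sd_plot=0.0, sd_resid=0.0, seed=0)


class TestRecoveryRateModel:
    def test_noise_free_identifiability(self, noise_free_recovery):
        d, t = noise_free_recovery
        fit = fit_recovery_rates(d)
        assert fit["rate_exclusion"] == pytest.approx(17.85, abs=1e-8)
        assert fit["rate_control"] == pytest.approx(6.85, abs=1e-8)

    def test_plotwise_cross_check_agrees_on_balanced_data(self, noise_free_recovery):
        d, _ = noise_free_recovery
        model = RecoveryRateModel.from_dataframe(d)
        fit = model.fit()
        plotwise = model.plotwise_rates()
        assert plotwise["exclusion"] == pytest.approx(fit["rate_exclusion"], abs=1e-8)
        assert plotwise["control"] == pytest.approx(fit["rate_control"], abs=1e-8)

    def test_mixed_and_plotwise_agree_with_noise(self):
        """On a balanced design the LMM arm slopes equal the mean of
        per-plot OLS slopes even with noise."""
        d, _ = syn.gen_patch_recovery(seed=33)
        model = RecoveryRateModel(d)
        fit = model.fit()
        plotwise = model.plotwise_rates()
        assert fit["rate_exclusion"] == pytest.approx(plotwise["exclusion"], abs=1e-6)

    def test_identical_arms_null_case(self):
        d, _ = syn.gen_patch_recovery(
            rate_exclusion=10.0, rate_control=10.0, seed=4
        )
        fit = fit_recovery_rates(d)
        assert fit.contrasts["rate_difference"][0] == pytest.approx(0.0, abs=1.0)
        assert fit.interaction_stat["p"] > 0.01

    def test_row_order_invariance(self):
        d, _ = syn.gen_patch_recovery(seed=9)
        shuffled = d.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a, b = fit_recovery_rates(d), fit_recovery_rates(shuffled)
        assert a["rate_exclusion"] == pytest.approx(b["rate_exclusion"], abs=1e-8)

    def test_design_errors(self):
        d, _ = syn.gen_patch_recovery(seed=0)
        with pytest.raises(DesignError, match="both arms"):
            fit_recovery_rates(d[d["treatment"] == "control"])
        single_visit = d[d["time"] == 0.0]
        with pytest.raises(DesignError, match="time points"):
            fit_recovery_rates(single_visit)
        with pytest.raises(DesignError, match="missing columns"):
            fit_recovery_rates(d.drop(columns=["percent_cover"]))


@pytest.fixture(scope="module")
def noise_free_factorial():
    return syn.gen_factorial(
        sd_vector={k: 0.0 for k in syn.DEFAULT_FACTORIAL_SD}, seed=0
    )


class TestFactorialModel:
    def test_noise_free_biomass_contrasts(self, noise_free_factorial):
        d, _ = noise_free_factorial
        fit = fit_factorial(d, "biomass")
        assert fit.contrasts["uncaged_added_minus_caged_added"][0] == (
            pytest.approx(-298.7, abs=1e-8)
        )
        assert fit.contrasts["caged_mussel_ratio"][0] == pytest.approx(1.5, abs=1e-8)

    def test_noise_free_crab_means(self, noise_free_factorial):
        d, _ = noise_free_factorial
        fit = fit_factorial(d, "crab_burrows")
        assert fit.arm_summaries["caged:added"] == pytest.approx(32.6)
        assert fit.arm_summaries["uncaged:added"] == pytest.approx(13.3)

    def test_arm_means_match_raw_means(self):
        d, _ = syn.gen_factorial(seed=6)
        fit = fit_factorial(d, "biomass")
        raw = d.groupby(["hog", "mussels"])["biomass"].mean()
        for (h, m), v in raw.items():
            assert fit.arm_summaries[f"{h}:{m}"] == pytest.approx(v, abs=1e-9)

    def test_equal_arms_no_interaction(self):
        d, _ = syn.gen_factorial(
            arm_means={
                "biomass": {arm: 400.0 for arm in syn.FACTORIAL_ARMS},
            },
            sd_vector={k: 0.0 for k in syn.DEFAULT_FACTORIAL_SD},
        )
        fit = fit_factorial(d, "biomass")
        assert fit.interaction_stat["stat"] == pytest.approx(0.0, abs=1e-8)

    def test_missing_arm_rejected(self):
        d, _ = syn.gen_factorial(seed=0)
        with pytest.raises(DesignError, match="arms"):
            FactorialModel(d[d["hog"] == "caged"], "biomass")


class TestSurveyCountModel:
    def test_stratum_means_equal_sample_means(self):
        """NB2 with a saturated stratum structure fits the stratum
        sample means exactly (score equations)."""
        d, _ = syn.gen_mussel_survey(n_sites=30, seed=2)
        fit = fit_survey_counts(d)
        raw = d.groupby(["hog_access", "marsh_area"])["mussel_count"].mean()
        for (a, m), v in raw.items():
            assert fit[f"mean_{a}:{m}"] == pytest.approx(v, rel=1e-6)

    def test_poisson_limit_agreement(self, rng):
        """Near-Poisson data: NB mean structure matches a Poisson fit
        within 1%."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d, _ = syn.gen_mussel_survey(n_sites=30, dispersion=1e5, seed=3)
        fit = fit_survey_counts(d)
        pois = smf.glm(
            "mussel_count ~ C(hog_access) * C(marsh_area)",
            d,
            family=sm.families.Poisson(),
        ).fit()
        pred = pois.predict(
            pd.DataFrame(
                {"hog_access": ["no", "yes"], "marsh_area": ["creekhead"] * 2}
            )
        )
        assert fit["mean_no:creekhead"] == pytest.approx(pred.iloc[0], rel=0.01)
        assert fit["mean_yes:creekhead"] == pytest.approx(pred.iloc[1], rel=0.01)

    def test_equal_strata_no_access_effect(self):
        d, _ = syn.gen_mussel_survey(
            marsh_means={"no": 500.0, "yes": 500.0}, n_sites=40, seed=5
        )
        fit = fit_survey_counts(d)
        no, yes = fit["marsh_total_no_hog"], fit["marsh_total_hog"]
        assert abs(no - yes) / no < 0.15

    def test_tukey_contrasts_cover_all_stratum_pairs(self):
        d, _ = syn.gen_mussel_survey(n_sites=10, seed=1)
        fit = fit_survey_counts(d)
        assert len(fit.contrasts) == 6  # C(4,2) stratum pairs
        assert len(fit.meta["tukey_p"]) == 6
        assert all(0 <= p <= 1 for p in fit.meta["tukey_p"].values())

    def test_zero_stratum_safeguard_flagged(self):
        d, _ = syn.gen_mussel_survey(n_sites=4, seed=1)
        d.loc[
            (d["hog_access"] == "yes") & (d["marsh_area"] == "platform"),
            "mussel_count",
        ] = 0
        fit = fit_survey_counts(d)
        assert "zero_stratum_adjusted" in fit.meta
        assert np.isfinite(fit["marsh_total_hog"])

    def test_design_validation(self):
        d, _ = syn.gen_mussel_survey(n_sites=3, seed=0)
        with pytest.raises(DesignError, match="access"):
            SurveyCountModel(d[d["hog_access"] == "no"])


class TestAssociationModel:
    def test_full_association_estimated_as_one(self):
        d, _ = syn.gen_mussel_survey(
            assoc_probs={"no": 1.0, "yes": 1.0}, n_sites=3, seed=0
        )
        fit = fit_association(d)
        assert fit["prop_assoc_no"] == 1.0
        assert fit["prop_assoc_yes"] == 1.0

    def test_recovers_configured_probabilities_at_scale(self):
        d, t = syn.gen_mussel_survey(n_sites=60, seed=12)
        fit = fit_association(d)
        for access in ("no", "yes"):
            p, se = fit.estimates[f"prop_assoc_{access}"]
            assert abs(p - t["assoc_probs"][access]) < max(3 * se, 0.01)

    def test_hog_contrast_sign(self):
        d, _ = syn.gen_mussel_survey(n_sites=20, seed=7)
        fit = fit_association(d)
        assert fit.contrasts["hog_minus_no_hog"][0] < 0

    def test_zero_mussel_stratum_excluded_with_warning(self):
        d, _ = syn.gen_mussel_survey(n_sites=3, seed=0)
        d.loc[d["hog_access"] == "yes", ["mussel_count", "n_associated"]] = 0
        with pytest.warns(UserWarning, match="zero mussels"):
            fit = fit_association(d)
        assert "prop_assoc_yes" not in fit.estimates
        assert fit.meta["excluded"] == ["yes"]

    def test_scat_survey_point_estimate_and_exact_interval(self):
        d, _ = syn.gen_scat_survey(seed=17)
        fit = fit_association(d)
        pos = int(d["contains_shell"].sum())
        assert fit["prop_shell"] == pytest.approx(pos / 190)
        lo, hi = fit.meta["ci_95_exact"]
        assert lo < pos / 190 < hi

    def test_overfull_association_rejected(self):
        d, _ = syn.gen_mussel_survey(n_sites=2, seed=0)
        d.loc[0, "n_associated"] = d.loc[0, "mussel_count"] + 5
        with pytest.raises(DesignError, match="exceed"):
            AssociationModel(d)


class TestFitResultSurface:
    def test_summary_renders(self):
        d, _ = syn.gen_patch_recovery(seed=0)
        text = fit_recovery_rates(d).summary()
        assert "rate_exclusion" in text and "interaction" in text

    def test_site_relabeling_invariance(self):
        d, _ = syn.gen_factorial(seed=11)
        renamed = d.assign(site=d["site"].map({"site1": "B", "site2": "A"}))
        a = fit_factorial(d, "crab_burrows")
        b = fit_factorial(renamed, "crab_burrows")
        assert a.contrasts["uncaged_added_minus_caged_added"][0] == pytest.approx(
            b.contrasts["uncaged_added_minus_caged_added"][0], abs=1e-9
        )
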