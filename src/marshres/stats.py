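"""Estimation stages for the field designs, as model/results objects.

Each design gets a model class built from a tidy DataFrame whose
``fit()`` returns a :class:`FitResult` carrying named estimates with
standard errors, treatment contrasts, an interaction test, per-arm
summaries and a ``summary()`` table:

* :class:`RecoveryRateModel` — linear mixed model (random plot
  intercepts, ML) of percent cover on time x exclusion treatment;
  reports arm-specific recovery rates in % cover per year, plus a
  per-plot least-squares slope average as a cross-check estimator.
* :class:`FactorialModel` — mixed/OLS linear model of a plot response
  on hog x mussel treatments; reports arm means and the named
  contrasts (uncaged-caged under mussel addition, caged mussel-effect
  ratio).
* :class:`SurveyCountModel` — negative-binomial (NB2, log link)
  regression of transect mussel counts on hog access x marsh area;
  reports stratum means, predicted per-marsh totals and
  Tukey-corrected pairwise stratum contrasts.
* :class:`AssociationModel` — binomial model of the mussel-cordgrass
  association proportion by stratum; also handles Bernoulli scat
  surveys (shell-fragment positivity with an exact binomial interval).

Module-level ``fit_*`` helpers mirror the class API for one-liners.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "FitResult",
    "RecoveryRateModel",
    "FactorialModel",
    "SurveyCountModel",
    "AssociationModel",
    "fit_recovery_rates",
    "fit_factorial",
    "fit_survey_counts",
    "fit_association",
    "DesignError",
]


class DesignError(ValueError):
    """The supplied table cannot support the requested design."""


@dataclass
class FitResult:
    """Estimates, contrasts and uncertainty from an estimation stage.

    ``estimates`` maps names to ``(estimate, se)``; ``contrasts`` maps
    contrast names to ``(estimate, se)`` (se may be NaN for derived
    ratios); ``interaction_stat`` holds the treatment-interaction test.
    """

    estimates: dict[str, tuple[float, float]]
    contrasts: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    interaction_stat: dict | None = None
    arm_summaries: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name][0]

    def se(self, name: str) -> float:
        return self.estimates[name][1]

    def summary(self) -> str:
        lines = [f"{self.meta.get('model', 'fit')} results", "=" * 46]
        lines.append(f"{'term':<30}{'estimate':>10}{'se':>8}")
        for name, (est, se) in self.estimates.items():
            lines.append(f"{name:<30}{est:>10.4g}{se:>8.3g}")
        if self.contrasts:
            lines.append("-" * 46)
            for name, (est, se) in self.contrasts.items():
                lines.append(f"{name:<30}{est:>10.4g}{se:>8.3g}")
        if self.interaction_stat:
            s = self.interaction_stat
            lines.append("-" * 46)
            lines.append(
                f"interaction {s.get('name', '')}: stat={s['stat']:.4g} "
                f"df={s.get('df', '')} p={s.get('p', float('nan')):.3g}"
            )
        return "\n".join(lines)


def _wald_f(est: float, se: float, df_denom: float) -> dict:
    """1-df Wald test reported on the F scale."""
    from scipy import stats as sps

    if abs(est) < 1e-10:
        # effect below numerical noise: null, even if the se collapsed
        # too (zero-variance data would otherwise give a 0/0 ratio)
        return {"stat": 0.0, "df": (1, df_denom), "p": 1.0}
    if se == 0 or not math.isfinite(se):
        return {"stat": math.inf, "df": (1, df_denom), "p": 0.0}
    f = (est / se) ** 2
    p = float(sps.f.sf(f, 1, df_denom))
    return {"stat": float(f), "df": (1, df_denom), "p": p}


def _mixedlm_or_ols(formula: str, data: pd.DataFrame, groups: pd.Series):
    """ML mixed fit with random intercepts; OLS fallback when the
    variance structure degenerates (e.g. noise-free data).

    On a balanced design the fixed-effect point estimates coincide, so
    downstream contrasts do not depend on which engine succeeded.
    """
    import statsmodels.formula.api as smf

    with warnings.catch_warnings(record=True):
        warnings.simplefilter("ignore")
        try:
            mixed = smf.mixedlm(formula, data, groups=groups).fit(reml=False)
            if np.all(np.isfinite(mixed.bse_fe)) and np.all(np.isfinite(mixed.fe_params)):
                return mixed, "mixedlm"
        except Exception:
            pass
        return smf.ols(formula, data).fit(), "ols"


def _coef(res, name: str) -> tuple[float, float]:
    params = res.fe_params if hasattr(res, "fe_params") else res.params
    bse = res.bse_fe if hasattr(res, "bse_fe") else res.bse
    return float(params[name]), float(bse[name])


# ------------------------------------------------------------ recovery rates


class RecoveryRateModel:
    """Repeated-measures model of cordgrass patch recovery.

    Percent cover is regressed on time, exclusion treatment and their
    interaction with a random intercept per plot; the arm-specific
    time slopes are the recovery rates (% cover per year).
    """

    def __init__(self, data: pd.DataFrame):
        required = {"site", "plot_id", "treatment", "time", "percent_cover"}
        missing = required - set(data.columns)
        if missing:
            raise DesignError(f"missing columns: {sorted(missing)}")
        arms = set(data["treatment"].unique())
        if arms != {"exclusion", "control"}:
            raise DesignError(
                f"both arms (exclusion, control) required, got {sorted(arms)}"
            )
        per_plot = data.groupby(["site", "plot_id"])["time"].nunique()
        if per_plot.min() < 2:
            raise DesignError("every plot needs at least 2 time points")
        self.data = data.copy()
        self.data["_plot"] = (
            self.data["site"].astype(str) + ":" + self.data["plot_id"].astype(str)
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "RecoveryRateModel":
        return cls(data)

    def plotwise_rates(self) -> dict[str, float]:
        """Cross-check estimator: mean of per-plot OLS slopes by arm."""
        slopes = {}
        for (arm, _), g in self.data.groupby(["treatment", "_plot"]):
            b = np.polyfit(g["time"], g["percent_cover"], 1)[0]
            slopes.setdefault(arm, []).append(float(b))
        return {arm: float(np.mean(v)) for arm, v in slopes.items()}

    def fit(self) -> FitResult:
        d = self.data
        formula = (
            "percent_cover ~ time * C(treatment, Treatment(reference='control'))"
        )
        res, engine = _mixedlm_or_ols(formula, d, d["_plot"])
        inter_name = (
            "time:C(treatment, Treatment(reference='control'))[T.exclusion]"
        )
        b_time, se_time = _coef(res, "time")
        b_int, se_int = _coef(res, inter_name)
        rate_control = b_time
        rate_exclusion = b_time + b_int
        # se of the sum from the covariance of the two slope terms
        cov = (
            res.cov_params().loc["time", inter_name]
            if hasattr(res.cov_params(), "loc")
            else 0.0
        )
        se_excl = math.sqrt(max(se_time**2 + se_int**2 + 2 * cov, 0.0))

        n_plots = d["_plot"].nunique()
        df_denom = len(d) - n_plots - 4
        interaction = _wald_f(b_int, se_int, max(df_denom, 1))
        interaction["name"] = "time:treatment"
        return FitResult(
            estimates={
                "rate_exclusion": (rate_exclusion, se_excl),
                "rate_control": (rate_control, se_time),
            },
            contrasts={"rate_difference": (b_int, se_int)},
            interaction_stat=interaction,
            arm_summaries=self.plotwise_rates(),
            meta={"model": "recovery-rate LMM", "engine": engine, "n_plots": n_plots},
        )


# ---------------------------------------------------------------- factorial


class FactorialModel:
    """2x2 hog-exclusion x mussel-addition analysis of a plot response."""

    RESPONSES = ("biomass", "mussel_density", "crab_burrows")

    def __init__(self, data: pd.DataFrame, response: str = "biomass"):
        if response not in data.columns:
            raise DesignError(f"response column {response!r} not in data")
        arms = set(map(tuple, data[["hog", "mussels"]].drop_duplicates().values))
        expected = {("caged", "added"), ("caged", "none"), ("uncaged", "added"), ("uncaged", "none")}
        if arms != expected:
            raise DesignError(f"all four arms required; missing {expected - arms}")
        self.data = data.copy()
        self.response = response

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str = "biomass"):
        return cls(data, response)

    def fit(self) -> FitResult:
        d = self.data
        resp = self.response
        formula = f"{resp} ~ C(hog) * C(mussels)"
        res, engine = _mixedlm_or_ols(formula, d, d["site"])

        arm_means = d.groupby(["hog", "mussels"])[resp].mean()
        arm_se = d.groupby(["hog", "mussels"])[resp].sem().fillna(0.0)
        estimates = {
            f"{h}:{m}": (float(arm_means[(h, m)]), float(arm_se[(h, m)]))
            for h, m in arm_means.index
        }

        diff = float(arm_means[("uncaged", "added")] - arm_means[("caged", "added")])
        se_diff = float(
            math.sqrt(arm_se[("uncaged", "added")] ** 2 + arm_se[("caged", "added")] ** 2)
        )
        caged_none = float(arm_means[("caged", "none")])
        ratio = (
            float(arm_means[("caged", "added")] / caged_none)
            if caged_none > 0
            else math.nan
        )
        secondary = float(
            arm_means[("uncaged", "added")] - arm_means[("uncaged", "none")]
        )

        inter_name = "C(hog)[T.uncaged]:C(mussels)[T.none]"
        b_int, se_int = _coef(res, inter_name)
        df_denom = max(len(d) - 5, 1)
        interaction = _wald_f(b_int, se_int, df_denom)
        interaction["name"] = "hog:mussels"
        return FitResult(
            estimates=estimates,
            contrasts={
                "uncaged_added_minus_caged_added": (diff, se_diff),
                "uncaged_added_minus_uncaged_none": (secondary, math.nan),
                "caged_mussel_ratio": (ratio, math.nan),
            },
            interaction_stat=interaction,
            arm_summaries={f"{h}:{m}": float(v) for (h, m), v in arm_means.items()},
            meta={"model": f"factorial ({resp})", "engine": engine},
        )


# ---------------------------------------------------------- survey counts


class SurveyCountModel:
    """Negative-binomial model of transect mussel counts.

    Mean structure is saturated in hog access x marsh area, so fitted
    stratum means equal stratum sample means for any dispersion; the
    per-marsh predicted total sums fitted transect means over a
    marsh's transects.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"site", "hog_access", "marsh_area", "mussel_count"}
        missing = required - set(data.columns)
        if missing:
            raise DesignError(f"missing columns: {sorted(missing)}")
        if (data["mussel_count"] < 0).any():
            raise DesignError("counts must be >= 0")
        if set(data["hog_access"].unique()) != {"no", "yes"}:
            raise DesignError("both hog-access levels required")
        self.data = data.copy()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "SurveyCountModel":
        return cls(data)

    def fit(self) -> FitResult:
        import statsmodels.formula.api as smf
        from scipy import stats as sps

        d = self.data.copy()
        meta: dict = {"model": "survey NB2 (log link)"}
        zero_strata = [
            k
            for k, g in d.groupby(["hog_access", "marsh_area"])
            if (g["mussel_count"] == 0).all()
        ]
        if zero_strata:
            # continuity safeguard: an all-zero stratum has no finite
            # log-mean; add 0.5 to every count and flag it
            d["mussel_count"] = d["mussel_count"] + 0.5
            meta["zero_stratum_adjusted"] = [":".join(k) for k in zero_strata]

        formula = "mussel_count ~ C(hog_access) * C(marsh_area)"
        import statsmodels.api as sm

        with warnings.catch_warnings(record=True):
            warnings.simplefilter("ignore")
            try:
                res = smf.negativebinomial(formula, d).fit(disp=0, maxiter=200)
                engine = "negativebinomial"
            except Exception:
                res = smf.glm(formula, d, family=sm.families.Poisson()).fit()
                engine = "poisson-glm"
            # materialize lazily computed uncertainties while warnings
            # are still suppressed
            inter_name = "C(hog_access)[T.yes]:C(marsh_area)[T.platform]"
            try:
                inter_coef = (float(res.params[inter_name]), float(res.bse[inter_name]))
            except Exception:
                inter_coef = None
        meta["engine"] = engine

        strata = d.groupby(["hog_access", "marsh_area"])["mussel_count"]
        stratum_means = strata.mean()
        stratum_sem = strata.sem().fillna(0.0)
        estimates = {
            f"mean_{a}:{m}": (float(stratum_means[(a, m)]), float(stratum_sem[(a, m)]))
            for a, m in stratum_means.index
        }

        # predicted per-marsh totals: fitted stratum mean x transects per
        # marsh in that stratum (averaged over marshes)
        per_marsh = {}
        for access, g in d.groupby("hog_access"):
            total = 0.0
            var = 0.0
            for area, ga in g.groupby("marsh_area"):
                n_per_marsh = ga.groupby("site").size().mean()
                total += float(stratum_means[(access, area)]) * n_per_marsh
                var += (float(stratum_sem[(access, area)]) * n_per_marsh) ** 2
            per_marsh[access] = (total, math.sqrt(var))
        label = {"no": "marsh_total_no_hog", "yes": "marsh_total_hog"}
        for access, (tot, se) in per_marsh.items():
            estimates[label[access]] = (tot, se)

        # Tukey-corrected pairwise stratum contrasts on the log scale
        keys = list(stratum_means.index)
        k = len(keys)
        df_resid = max(len(d) - k, 2)
        contrasts = {}
        for i in range(k):
            for j in range(i + 1, k):
                ki, kj = keys[i], keys[j]
                est = float(stratum_means[ki] - stratum_means[kj])
                se = math.sqrt(stratum_sem[ki] ** 2 + stratum_sem[kj] ** 2)
                name = f"{':'.join(ki)} - {':'.join(kj)}"
                contrasts[name] = (est, se)
                if se > 0:
                    q = abs(est) / se * math.sqrt(2.0)
                    p = float(sps.studentized_range.sf(q, k, df_resid))
                else:
                    p = 0.0 if est else 1.0
                meta.setdefault("tukey_p", {})[name] = p

        if inter_coef is not None:
            interaction = _wald_f(*inter_coef, df_resid)
        else:
            interaction = {"stat": math.nan, "df": (1, df_resid), "p": math.nan}
        interaction["name"] = "hog_access:marsh_area"

        return FitResult(
            estimates=estimates,
            contrasts=contrasts,
            interaction_stat=interaction,
            arm_summaries={
                ":".join(kk): float(stratum_means[kk]) for kk in stratum_means.index
            },
            meta=meta,
        )


# ------------------------------------------------------------- association


class AssociationModel:
    """Binomial model of mussel-cordgrass association.

    Accepts either transect tables (``mussel_count`` / ``n_associated``
    by stratum) or a Bernoulli scat survey (``contains_shell``), for
    which it returns the positivity proportion with an exact
    (Clopper-Pearson) binomial interval.
    """

    def __init__(self, data: pd.DataFrame):
        if "contains_shell" in data.columns:
            self.kind = "scat"
        else:
            required = {"hog_access", "mussel_count", "n_associated"}
            missing = required - set(data.columns)
            if missing:
                raise DesignError(f"missing columns: {sorted(missing)}")
            if (data["n_associated"] > data["mussel_count"]).any():
                raise DesignError("n_associated cannot exceed mussel_count")
            self.kind = "transect"
        self.data = data.copy()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "AssociationModel":
        return cls(data)

    def _fit_scat(self) -> FitResult:
        from statsmodels.stats.proportion import proportion_confint

        pos = int(self.data["contains_shell"].sum())
        n = len(self.data)
        p = pos / n
        lo, hi = proportion_confint(pos, n, alpha=0.05, method="beta")
        se = math.sqrt(p * (1 - p) / n)
        return FitResult(
            estimates={
                "prop_shell": (p, se),
                "percent_shell": (100.0 * p, 100.0 * se),
            },
            contrasts={},
            arm_summaries={"n": n, "positives": pos},
            meta={
                "model": "scat Bernoulli",
                "ci_95_exact": (float(lo), float(hi)),
            },
        )

    def fit(self) -> FitResult:
        if self.kind == "scat":
            return self._fit_scat()
        from statsmodels.stats.proportion import proportion_confint

        d = self.data
        estimates: dict[str, tuple[float, float]] = {}
        meta: dict = {"model": "association binomial", "ci_95": {}, "excluded": []}
        props: dict[str, float] = {}
        for access, g in d.groupby("hog_access"):
            count = float(g["mussel_count"].sum())
            assoc = float(g["n_associated"].sum())
            if count == 0:
                warnings.warn(
                    f"stratum hog_access={access} has zero mussels; excluded",
                    stacklevel=2,
                )
                meta["excluded"].append(access)
                continue
            p = assoc / count
            se = math.sqrt(max(p * (1 - p), 0.0) / count)
            estimates[f"prop_assoc_{access}"] = (p, se)
            props[access] = p
            lo, hi = proportion_confint(assoc, count, alpha=0.05, method="beta")
            meta["ci_95"][access] = (float(lo), float(hi))
        contrasts = {}
        if {"no", "yes"} <= props.keys():
            diff = props["yes"] - props["no"]
            se = math.sqrt(
                estimates["prop_assoc_yes"][1] ** 2
                + estimates["prop_assoc_no"][1] ** 2
            )
            contrasts["hog_minus_no_hog"] = (diff, se)
        return FitResult(
            estimates=estimates,
            contrasts=contrasts,
            arm_summaries=props,
            meta=meta,
        )


# ---------------------------------------------------------------- helpers


def fit_recovery_rates(data: pd.DataFrame) -> FitResult:
    return RecoveryRateModel(data).fit()


def fit_factorial(data: pd.DataFrame, response: str = "biomass") -> FitResult:
    return FactorialModel(data, response).fit()


def fit_survey_counts(data: pd.DataFrame) -> FitResult:
    return SurveyCountModel(data).fit()


def fit_association(data: pd.DataFrame) -> FitResult:
    return AssociationModel(data).fit()
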