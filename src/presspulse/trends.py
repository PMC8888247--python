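"""Cycle-level aggregation and effect estimation.

Three questions are answered here:

1. How does microbial biovolume build up across perturbation periods?
   (`cycle_average_biovolume`: per-replicate means over Baseline/P1/P2/P3.)
2. How is chlorophyll-a related to biovolume, and does enrichment change
   that relation?  (`fit_chl_biovolume`: linear model with a treatment
   interaction, optional log10 transform driven by a residual-normality
   screen.)
3. How do the perturbation metrics respond to the number of pulses and to
   enrichment?  (`fit_metric_trends`: linear mixed models with pulse count
   and treatment as fixed effects — control as the reference level — a
   random intercept per replicate, and the pulse intensity level as a
   variance component; the same linear structure stands in for smooth
   terms, which three cycle levels cannot support.)

Fixed-effect p-values use Wald t/F statistics with residual degrees of
freedom n - k; a seeded permutation fallback is available for small
designs.  Variance explained is reported as marginal (fixed effects only)
and conditional (fixed + random) proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object

DEFAULT_METRICS = ("c0", "d0", "rs_scaled", "rc_scaled")


# ---------------------------------------------------------------------------
# biovolume aggregation

def cycle_average_biovolume(
    timeseries: pd.DataFrame, pulse_days
) -> pd.DataFrame:
    """Mean biovolume per replicate x period (Baseline, P1, ..., Pn).

    Periods follow the perturbation schedule: Baseline runs from the series
    start to the first pulse, each Pk from its pulse to the next (the last
    to the series end).  With the full design this yields
    treatments x replicates x (n_pulses + 1) rows.
    """
    if "biovolume" not in timeseries.columns:
        raise ValueError("timeseries table missing column 'biovolume'")
    pulse_days = sorted(pulse_days)
    edges = [-np.inf] + list(pulse_days) + [np.inf]
    labels = ["Baseline"] + [f"P{i + 1}" for i in range(len(pulse_days))]
    rows = []
    for (trt, rep), grp in timeseries.groupby(["treatment", "replicate"], sort=True):
        for i, label in enumerate(labels):
            sel = (grp["day"] >= edges[i]) & (grp["day"] < edges[i + 1])
            if not sel.any():
                raise ValueError(
                    f"empty period {label} for replicate {rep!r}"
                )
            rows.append(
                (trt, rep, label, float(grp.loc[sel, "biovolume"].mean()))
            )
    return pd.DataFrame(rows, columns=["treatment", "replicate", "period", "biovolume_mean"])


def total_biovolume(bin_counts) -> float:
    """Total biovolume from per-bin counts: technical counts averaged, bins summed.

    ``bin_counts`` is either one vector of per-bin biovolumes or a
    (n_technical_counts, n_bins) array whose replicate counts are averaged
    bin-wise before summation.
    """
    arr = np.atleast_2d(np.asarray(bin_counts, dtype=float))
    if np.any(arr < 0):
        raise ValueError("bin biovolumes must be non-negative")
    return float(arr.mean(axis=0).sum())


# ---------------------------------------------------------------------------
# chlorophyll ~ biovolume regression

@dataclass
class ChlBiovolumeFit:
    slopes: dict          # treatment -> slope
    intercepts: dict      # treatment -> intercept
    interaction: dict     # treatment -> (slope contrast vs control, p-value)
    r_squared: float
    log10_applied: bool
    result: object = field(repr=False, default=None)


def _pick_reference(labels, reference: str | None) -> str:
    labels = list(dict.fromkeys(labels))
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference treatment {reference!r} not present")
        return reference
    return "control" if "control" in labels else labels[0]


def fit_chl_biovolume(
    records: pd.DataFrame,
    log10: bool | str = "auto",
    reference: str | None = None,
) -> ChlBiovolumeFit:
    """Linear model chl_total ~ biovolume x treatment (interaction included).

    ``log10='auto'`` fits untransformed first and refits both variables on
    log10 scale when a D'Agostino normality screen rejects the residuals at
    alpha = 0.05.
    """
    df = records[["chl_total", "biovolume", "treatment"]].dropna().copy()
    ref = _pick_reference(df["treatment"], reference)
    counts = df.groupby("treatment").size()
    if (counts < 3).any():
        raise ValueError("need at least 3 points per treatment")

    def _fit(frame):
        formula = (
            f"chl_total ~ biovolume * C(treatment, Treatment(reference='{ref}'))"
        )
        return smf.ols(formula, data=frame).fit()

    res = _fit(df)
    applied = False
    if log10 is True or (
        log10 == "auto"
        and len(res.resid) >= 8
        and scipy.stats.normaltest(res.resid)[1] < 0.05
    ):
        if (df[["chl_total", "biovolume"]] <= 0).any().any():
            raise ValueError("log10 transform requires positive values")
        tdf = df.copy()
        tdf["chl_total"] = np.log10(tdf["chl_total"])
        tdf["biovolume"] = np.log10(tdf["biovolume"])
        res = _fit(tdf)
        applied = True

    base_slope = res.params["biovolume"]
    base_int = res.params["Intercept"]
    slopes, intercepts, interaction = {ref: base_slope}, {ref: base_int}, {}
    for name, val in res.params.items():
        if name.startswith("biovolume:"):
            label = name.split("[T.")[-1].rstrip("]")
            slopes[label] = base_slope + val
            interaction[label] = (val, float(res.pvalues[name]))
        elif name.startswith("C(treatment"):
            label = name.split("[T.")[-1].rstrip("]")
            intercepts[label] = base_int + val
    return ChlBiovolumeFit(
        slopes=slopes, intercepts=intercepts, interaction=interaction,
        r_squared=float(res.rsquared), log10_applied=applied, result=res,
    )


# ---------------------------------------------------------------------------
# metric trend mixed models

@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect term of one metric's trend model."""

    metric_name: str
    term: str                 # eutrophication | n_perturbations | interaction
    estimate: float
    se: float
    statistic: float
    p_value: float
    var_marginal: float       # proportion explained by fixed effects
    var_conditional: float    # proportion explained by fixed + random

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class TrendFit:
    metric_name: str
    effects: list
    model_kind: str           # "mixed" | "mixed-intercept" | "ols"
    coefficients: dict
    var_marginal: float
    var_conditional: float
    log10_applied: bool = False
    result: object = field(repr=False, default=None)

    def effect(self, term: str) -> EffectEstimate:
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(term)


def _prepare_metrics(metrics: pd.DataFrame, reference: str | None) -> tuple[pd.DataFrame, str]:
    df = metrics.copy()
    required = {"cycle_id", "replicate_id", "treatment_label", "pulse_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    if df["cycle_id"].nunique() < 2:
        raise ValueError("metric trends need at least 2 perturbation cycles")
    df["n_perturbations"] = df["cycle_id"].astype(float)
    ref = _pick_reference(df["treatment_label"], reference)
    return df, ref


def _wald_joint(res, names: list[str], df_resid: float) -> tuple[float, float]:
    """Joint Wald F for a set of coefficients, p from F(q, df_resid)."""
    params = res.params if isinstance(res.params, pd.Series) else pd.Series(res.params)
    idx = [list(params.index).index(n) for n in names]
    beta = params.to_numpy()[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    q = len(idx)
    fstat = float(beta @ np.linalg.solve(cov, beta)) / q
    return fstat, float(scipy.stats.f.sf(fstat, q, df_resid))


def _contrast(res, names: list[str]) -> tuple[float, float]:
    """Average of coefficients and its standard error."""
    params = res.params if isinstance(res.params, pd.Series) else pd.Series(res.params)
    idx = [list(params.index).index(n) for n in names]
    w = np.zeros(len(params))
    w[idx] = 1.0 / len(idx)
    est = float(w @ params.to_numpy())
    se = float(np.sqrt(w @ np.asarray(res.cov_params()) @ w))
    return est, se


def _fit_one_metric(
    df: pd.DataFrame,
    response: str,
    ref: str,
    include_interaction: bool,
    random_intensity: bool,
) -> tuple[object, str]:
    trt = f"C(treatment_label, Treatment(reference='{ref}'))"
    fixed = f"{response} ~ n_perturbations + {trt}"
    if include_interaction:
        fixed += f" + n_perturbations:{trt}"
    df = df.assign(_one=1)
    vc = {"replicate": "0 + C(replicate_id)"}
    if random_intensity and df["pulse_intensity"].nunique() > 1:
        vc["intensity"] = "0 + C(pulse_intensity)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for vcf, kind in ((vc, "mixed"), ({"replicate": vc["replicate"]}, "mixed-intercept")):
            try:
                model = smf.mixedlm(
                    fixed, data=df, groups="_one", re_formula="0", vc_formula=vcf
                )
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
                if np.all(np.isfinite(res.bse_fe)) and res.scale > 0:
                    return res, kind
            except (np.linalg.LinAlgError, ValueError):
                continue
        return smf.ols(fixed, data=df).fit(), "ols"


def _variance_explained(res, kind: str) -> tuple[float, float]:
    if kind == "ols":
        total = np.var(res.model.endog)
        vf = np.var(res.fittedvalues)
        frac = float(min(1.0, vf / total)) if total > 0 else 0.0
        return frac, frac
    exog = res.model.exog
    fe = np.asarray(res.fe_params)
    var_f = float(np.var(exog @ fe))
    var_r = float(np.nansum(np.asarray(res.vcomp)))
    var_e = float(res.scale)
    denom = var_f + var_r + var_e
    if denom <= 0:
        return 0.0, 0.0
    return var_f / denom, (var_f + var_r) / denom


def fit_metric_trends(
    metrics: pd.DataFrame,
    responses=DEFAULT_METRICS,
    include_interaction: bool = False,
    random_intensity: bool = True,
    reference: str | None = None,
    log10: bool = False,
) -> dict[str, TrendFit]:
    """Fit one mixed trend model per metric; see module docstring.

    Returns ``{metric: TrendFit}``; each fit carries EffectEstimates for the
    pulse-count trend, the enrichment (treatment) effect and, when
    requested, their interaction.
    """
    df, ref = _prepare_metrics(metrics, reference)
    out: dict[str, TrendFit] = {}
    for response in responses:
        if response not in df.columns:
            raise ValueError(f"metrics table missing response column {response!r}")
        work = df.copy()
        applied = False
        if log10:
            if (work[response] <= 0).any():
                raise ValueError(f"log10 requires positive {response}")
            work[response] = np.log10(work[response])
            applied = True
        res, kind = _fit_one_metric(
            work, response, ref, include_interaction, random_intensity
        )
        params = res.params if kind == "ols" else res.fe_params
        k = len(params)
        df_resid = max(1.0, len(work) - k)
        var_m, var_c = _variance_explained(res, kind)

        trt_names = [n for n in params.index if n.startswith("C(treatment") and ":" not in n]
        int_names = [n for n in params.index if n.startswith("n_perturbations:")]
        effects = []

        est, se = float(params["n_perturbations"]), None
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[: k, : k], index=params.index, columns=params.index
        )
        se = float(np.sqrt(cov.loc["n_perturbations", "n_perturbations"]))
        tstat = est / se if se > 0 else np.nan
        p = 2 * scipy.stats.t.sf(abs(tstat), df_resid)
        effects.append(EffectEstimate(response, "n_perturbations", est, se,
                                      tstat, float(p), var_m, var_c))

        if trt_names:
            fstat, p = _wald_joint(res, trt_names, df_resid)
            est, se = _contrast(res, trt_names)
            effects.append(EffectEstimate(response, "eutrophication", est, se,
                                          fstat, p, var_m, var_c))
        if int_names:
            fstat, p = _wald_joint(res, int_names, df_resid)
            est, se = _contrast(res, int_names)
            effects.append(EffectEstimate(response, "interaction", est, se,
                                          fstat, p, var_m, var_c))
        out[response] = TrendFit(
            metric_name=response, effects=effects, model_kind=kind,
            coefficients={str(n): float(v) for n, v in params.items()},
            var_marginal=var_m, var_conditional=var_c,
            log10_applied=applied, result=res,
        )
    return out


def estimate_displacement_ratio(
    metrics: pd.DataFrame, reference: str | None = None
) -> float:
    """Enriched:control ratio of model-estimated marginal mean displacement.

    Fits the raw-scale mixed trend model for D0 and compares the marginal
    mean of the enriched arms (averaged) with the control at the average
    pulse count — the fold-change enrichment confers on absolute response.
    """
    df, ref = _prepare_metrics(metrics, reference)
    fit = fit_metric_trends(df, responses=("d0",), reference=ref)["d0"]
    coefs = fit.coefficients
    mean_n = float(df["n_perturbations"].mean())
    mu_control = coefs["Intercept"] + coefs["n_perturbations"] * mean_n
    trt_coefs = [v for n, v in coefs.items() if n.startswith("C(treatment")]
    if not trt_coefs:
        raise ValueError("no enriched treatments present")
    mu_enriched = mu_control + float(np.mean(trt_coefs))
    if mu_control <= 0:
        raise ValueError("non-positive control displacement estimate")
    return mu_enriched / mu_control


def permutation_pvalue(
    metrics: pd.DataFrame,
    response: str,
    term: str = "eutrophication",
    n_permutations: int = 5000,
    seed: int = 0,
    reference: str | None = None,
) -> float:
    """Permutation p-value for one term of the trend model (OLS statistic).

    Treatment labels are permuted across replicates (keeping each
    replicate's cycles together); for the pulse-count trend, cycle order is
    permuted within replicates.  Suitable fallback when the mixed-model
    F approximation is doubtful at small n.
    """
    df, ref = _prepare_metrics(metrics, reference)
    rng = np.random.default_rng(seed)

    def stat(frame: pd.DataFrame) -> float:
        trt = f"C(treatment_label, Treatment(reference='{ref}'))"
        res = smf.ols(f"{response} ~ n_perturbations + {trt}", data=frame).fit()
        if term == "n_perturbations":
            return float(res.tvalues["n_perturbations"] ** 2)
        names = [n for n in res.params.index if n.startswith("C(treatment")]
        f, _ = _wald_joint(res, names, res.df_resid)
        return f

    observed = stat(df)
    reps = df[["replicate_id", "treatment_label"]].drop_duplicates()
    count = 0
    for _ in range(n_permutations):
        perm = df.copy()
        if term == "n_perturbations":
            perm["n_perturbations"] = (
                perm.groupby("replicate_id")["n_perturbations"]
                .transform(lambda s: rng.permutation(s.to_numpy()))
            )
        else:
            shuffled = rng.permutation(reps["treatment_label"].to_numpy())
            mapping = dict(zip(reps["replicate_id"], shuffled))
            perm["treatment_label"] = perm["replicate_id"].map(mapping)
        if stat(perm) >= observed:
            count += 1
    return (count + 1) / (n_permutations + 1)


def null_metrics_table(
    n_treatments: int = 3,
    n_replicates: int = 6,
    n_cycles: int = 3,
    pulse_intensities=(0.5, 0.15, 0.3),
    baseline: float = 5.0,
    replicate_sd: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Metrics table with zero treatment effect and zero trend.

    Calibration utility: values are baseline + a replicate offset + iid
    noise, so any detected trend or treatment effect is a false positive.
    """
    rng = np.random.default_rng(seed)
    labels = ["control"] + [f"enriched_{i}" for i in range(1, n_treatments)]
    rows = []
    for trt in labels:
        for r in range(1, n_replicates + 1):
            rep = f"{trt}_{r}"
            offsets = rng.normal(0.0, replicate_sd, size=len(DEFAULT_METRICS))
            for c in range(1, n_cycles + 1):
                values = baseline + offsets + rng.normal(
                    0.0, noise_sd, size=len(DEFAULT_METRICS)
                )
                rows.append((
                    c, rep, trt,
                    pulse_intensities[(c - 1) % len(pulse_intensities)],
                    *values,
                ))
    return pd.DataFrame(
        rows, columns=["cycle_id", "replicate_id", "treatment_label",
                       "pulse_intensity", *DEFAULT_METRICS]
    )


class MetricTrendModel(BaseEstimator):
    """Estimator facade over :func:`fit_metric_trends` for one metric.

    After ``fit(metrics_df)``: ``effects_`` (list of EffectEstimate),
    ``coefficients_``, ``var_marginal_``, ``var_conditional_``,
    ``model_kind_``.
    """

    def __init__(
        self,
        response: str = "rs_scaled",
        include_interaction: bool = False,
        random_intensity: bool = True,
        reference: str | None = None,
        log10: bool = False,
    ):
        self.response = response
        self.include_interaction = include_interaction
        self.random_intensity = random_intensity
        self.reference = reference
        self.log10 = log10

    def fit(self, X: pd.DataFrame, y=None) -> "MetricTrendModel":
        fit = fit_metric_trends(
            X, responses=(self.response,),
            include_interaction=self.include_interaction,
            random_intensity=self.random_intensity,
            reference=self.reference, log10=self.log10,
        )[self.response]
        self.effects_ = fit.effects
        self.coefficients_ = fit.coefficients
        self.var_marginal_ = fit.var_marginal
        self.var_conditional_ = fit.var_conditional
        self.model_kind_ = fit.model_kind
        self.trend_fit_ = fit
        self.n_features_in_ = X.shape[1]
        return self

    def effect(self, term: str) -> EffectEstimate:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "effects_")
        return self.trend_fit_.effect(term)


class ChlBiovolumeModel(BaseEstimator):
    """Estimator facade over :func:`fit_chl_biovolume`.

    After ``fit``: ``slopes_``, ``intercepts_``, ``interaction_``,
    ``r_squared_``, ``log10_applied_``; ``predict(X)`` evaluates the
    per-treatment lines.
    """

    def __init__(self, log10: bool | str = "auto", reference: str | None = None):
        self.log10 = log10
        self.reference = reference

    def fit(self, X: pd.DataFrame, y=None) -> "ChlBiovolumeModel":
        fit = fit_chl_biovolume(X, log10=self.log10, reference=self.reference)
        self.slopes_ = fit.slopes
        self.intercepts_ = fit.intercepts
        self.interaction_ = fit.interaction
        self.r_squared_ = fit.r_squared
        self.log10_applied_ = fit.log10_applied
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "slopes_")
        bv = X["biovolume"].to_numpy(dtype=float)
        if self.log10_applied_:
            bv = np.log10(bv)
        out = np.empty(len(X))
        for i, (b, trt) in enumerate(zip(bv, X["treatment"])):
            out[i] = self.intercepts_[trt] + self.slopes_[trt] * b
        if self.log10_applied_:
            out = 10 ** out
        return out
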