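"""Per-layer community metrics and the trend / status models.

Three model families are fitted:

* penalized-spline GAM trends of community metrics (mean wingspan, mean
  total specialization, proportion of open-habitat species, FDis) on the
  midpoint year of each time layer;
* a linear mixed-effect model of species body size (log wingspan) on
  occurrence status with taxonomic family as a random intercept, summarized
  with Nakagawa-Schielzeth marginal and conditional R^2;
* Poisson mixed models of the specialization scores on status, with the same
  reporting contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

from .funcdiv import Embedding, fdis_per_layer
from .records import STATUS_LOST, STATUS_PREVIOUSLY_UNRECORDED, TimeLayerScheme

logger = logging.getLogger(__name__)


@dataclass
class TrendFit:
    response_name: str
    smooth_edf: float
    coefficient: float          # standardized slope of the fitted smooth on year
    test_statistic: float       # signed sqrt of the approximate F statistic
    p_value: float
    adjusted_r2: float
    n_points: int
    alpha: float = np.nan       # penalty weight chosen by GCV

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "smooth_edf": self.smooth_edf,
            "coefficient": self.coefficient,
            "statistic": self.test_statistic,
            "p_value": self.p_value,
            "adjusted_r2": self.adjusted_r2,
            "n_points": self.n_points,
        }


@dataclass
class StatusModelFit:
    response_name: str
    model: str                  # "lmm", "poisson_glmm" or a fallback label
    contrasts: dict[str, float]  # status -> coefficient vs the reference level
    reference_level: str
    primary_contrast: str
    coefficient: float          # primary contrast (lost vs previously unrecorded)
    test_statistic: float
    p_value: float
    marginal_r2: float
    conditional_r2: float
    random_intercept_variance: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "model": self.model,
            "contrasts": self.contrasts,
            "reference_level": self.reference_level,
            "coefficient": self.coefficient,
            "statistic": self.test_statistic,
            "p_value": self.p_value,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
            "random_intercept_variance": self.random_intercept_variance,
            "warnings": self.warnings,
        }


def logit(p: float, epsilon: float = 1e-3) -> float:
    """Logit with boundary clamping: ln(p'/(1-p')), p' = clamp(p, eps, 1-eps)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion {p} outside [0, 1]")
    q = min(max(p, epsilon), 1.0 - epsilon)
    return float(np.log(q / (1.0 - q)))


def layer_metrics(
    incidence: pd.DataFrame,
    trait_table: pd.DataFrame,
    scores: pd.DataFrame,
    fdis_values: pd.Series | Embedding | None,
    scheme: TimeLayerScheme,
) -> pd.DataFrame:
    """Community metrics per time layer.

    For each layer: species richness, arithmetic mean wingspan over the
    present species and its log, mean total specialization score, proportion
    of open-habitat species with an empirical-logit transform (epsilon
    0.5/n), and FDis. Layers with zero species are dropped with a warning.

    ``fdis_values`` may be a precomputed per-layer Series, an
    :class:`~mothdrift.funcdiv.Embedding` (FDis computed here), or None.
    """
    traits = trait_table.set_index("species_id") if "species_id" in trait_table.columns else trait_table
    sc = scores.set_index("species_id") if "species_id" in scores.columns else scores
    if isinstance(fdis_values, Embedding):
        fdis_values = fdis_per_layer(fdis_values, incidence)

    midpoints = scheme.midpoints()
    rows = []
    for layer in incidence.columns:
        present = incidence.index[incidence[layer] > 0]
        n = len(present)
        if n == 0:
            logger.warning("layer %r has zero species; dropped", layer)
            continue
        wings = traits.loc[present, "wingspan_mm"].astype(float)
        open_prop = float(traits.loc[present, "open_habitat"].astype(bool).mean())
        eps = 0.5 / n
        rows.append({
            "layer": layer,
            "layer_midpoint_year": midpoints[layer],
            "n_species": n,
            "mean_wingspan_mm": float(wings.mean()),
            "log_mean_wingspan": float(np.log(wings.mean())),
            "mean_total_specialization": float(sc.loc[present, "total_specialization"].mean()),
            "prop_open_habitat": open_prop,
            "logit_prop_open": logit(open_prop, eps),
            "fdis": float(fdis_values[layer]) if fdis_values is not None else np.nan,
        })
    return pd.DataFrame(rows)


def fit_trend_gam(
    series: pd.DataFrame,
    response: str,
    basis_dim: int = 4,
    year_column: str = "layer_midpoint_year",
) -> TrendFit:
    """Penalized-spline trend of a community metric over layer midpoint years.

    A cubic B-spline smooth of the response on year is fitted with the
    penalty weight chosen by generalized cross-validation. Reported are the
    effective degrees of freedom of the smooth, an adjusted R^2, an
    approximate F-test of the smooth against the intercept-only model (the
    signed square root of F is the test statistic, carrying the trend's
    sign), and a standardized trend coefficient: the slope of the fitted
    smooth regressed on year, scaled by sd(year)/sd(response). For a smooth
    that is effectively linear this equals the Pearson correlation.
    """
    df = series.dropna(subset=[response, year_column]).sort_values(year_column)
    x = df[year_column].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError(f"need at least 6 time points, got {n}")
    if n < basis_dim + 2:
        basis_dim = max(3, n - 2)
        logger.warning("basis_dim reduced to %d for %d points", basis_dim, n)

    sd_y = y.std(ddof=1)
    if sd_y <= 1e-12 * max(1.0, abs(y.mean())):  # constant response: null fit
        return TrendFit(response, 0.0, 0.0, 0.0, 1.0, 0.0, n)

    xs = (x - x.mean()) / x.std(ddof=1)  # scale years for basis conditioning
    bs = BSplines(xs[:, None], df=[basis_dim], degree=[3])
    exog = np.ones((n, 1))
    # deterministic GCV grid search for the penalty weight:
    # GCV(alpha) = n * RSS / (n - EDF)^2
    perfect = False
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for alpha in np.logspace(-3, 8, 23):
            try:
                res_a = GLMGam(y, exog=exog, smoother=bs, alpha=[alpha]).fit()
            except PerfectSeparationError:
                # residual-free fit (e.g. exactly linear response): the
                # smooth interpolates the data and IRLS refuses to continue
                perfect = True
                continue
            rss_a = float(((y - res_a.fittedvalues) ** 2).sum())
            edf_a = float(np.asarray(res_a.edf).sum())
            gcv = n * rss_a / max(n - edf_a, 1e-6) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, alpha, res_a)
    if best is not None:
        _, alpha, res = best
        perfect = False
    else:
        alpha = 0.0

    if perfect:
        fitted = y.copy()
        edf_smooth = float(basis_dim - 1)
        edf_total = float(basis_dim)
    else:
        fitted = np.asarray(res.fittedvalues)
        edf = np.asarray(res.edf)
        edf_smooth = float(edf[1:].sum())     # column 0 is the intercept
        edf_total = float(edf.sum())
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    denom_df = max(n - edf_total, 1e-6)
    adj_r2 = 1.0 - (rss / denom_df) / (tss / (n - 1))

    slope = float(np.cov(x, fitted, ddof=1)[0, 1] / np.var(x, ddof=1))
    coefficient = slope * x.std(ddof=1) / sd_y

    num_df = max(edf_smooth, 1e-6)
    f_stat = max((tss - rss) / num_df, 0.0) / (rss / denom_df) if rss > 0 else np.inf
    p = float(stats.f.sf(f_stat, num_df, denom_df)) if np.isfinite(f_stat) else 0.0
    statistic = float(np.sign(coefficient) * np.sqrt(f_stat)) if np.isfinite(f_stat) else np.inf

    return TrendFit(response, edf_smooth, float(coefficient), statistic, p, float(adj_r2), n, alpha)


def _nakagawa_r2(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    total = var_fixed + var_random + var_resid
    if total <= 0:
        return 0.0, 0.0
    return var_fixed / total, (var_fixed + var_random) / total


def fit_wingspan_status_model(
    trait_table: pd.DataFrame,
    statuses: pd.DataFrame,
    reference: str = STATUS_PREVIOUSLY_UNRECORDED,
) -> StatusModelFit:
    """Body size (log wingspan) vs occurrence status, family as random intercept.

    Fits log(wingspan) ~ status with a taxonomic-family random intercept and
    reports the lost vs previously-unrecorded contrast (Wald test) together
    with Nakagawa-Schielzeth marginal and conditional R^2. A singular
    random-effect fit falls back to ordinary least squares with a warning.
    """
    df = trait_table.merge(statuses[["species_id", "status"]], on="species_id")
    df = df.assign(log_wingspan=np.log(df["wingspan_mm"].astype(float)))
    if df["status"].nunique() < 2:
        raise ValueError("need at least two status groups")
    if df["family"].nunique() < 2:
        raise ValueError("need at least two taxonomic families")

    formula = f"log_wingspan ~ C(status, Treatment({reference!r}))"
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, df, groups=df["family"]).fit(reml=True)
            singular = not np.isfinite(fit.cov_re.iloc[0, 0]) or fit.cov_re.iloc[0, 0] < 1e-10
        except Exception as exc:
            singular, fit = True, None
            notes.append(f"mixed model failed: {exc}")

    if fit is not None and not singular:
        var_random = float(fit.cov_re.iloc[0, 0])
        var_resid = float(fit.scale)
        fe_names = [p for p in fit.params.index if p.startswith("C(status")]
        design = df.copy()
        fixed_pred = fit.predict(design)  # fixed-effects-only prediction
        var_fixed = float(np.var(fixed_pred, ddof=0))
        contrasts = {_status_from_term(t): float(fit.params[t]) for t in fe_names}
        primary = STATUS_LOST
        term = next(t for t in fe_names if _status_from_term(t) == primary)
        stat = float(fit.tvalues[term])
        p = float(fit.pvalues[term])
        model = "lmm"
    else:
        notes.append("singular random-effect fit; ordinary least squares fallback")
        logger.warning("wingspan status model: %s", "; ".join(notes))
        ols = smf.ols(formula, df).fit()
        fe_names = [p for p in ols.params.index if p.startswith("C(status")]
        contrasts = {_status_from_term(t): float(ols.params[t]) for t in fe_names}
        var_random = 0.0
        var_resid = float(ols.mse_resid)
        var_fixed = float(np.var(ols.fittedvalues, ddof=0))
        primary = STATUS_LOST
        term = next(t for t in fe_names if _status_from_term(t) == primary)
        stat = float(ols.tvalues[term])
        p = float(ols.pvalues[term])
        model = "ols_fallback"

    marg, cond = _nakagawa_r2(var_fixed, var_random, var_resid)
    return StatusModelFit(
        response_name="log_wingspan",
        model=model,
        contrasts=contrasts,
        reference_level=reference,
        primary_contrast=f"{STATUS_LOST} - {reference}",
        coefficient=contrasts.get(STATUS_LOST, np.nan),
        test_statistic=stat,
        p_value=p,
        marginal_r2=marg,
        conditional_r2=cond,
        random_intercept_variance=var_random,
        warnings=notes,
    )


def _status_from_term(term: str) -> str:
    return term.split("[T.")[-1].rstrip("]")


def fit_specialization_status_model(
    scores: pd.DataFrame,
    statuses: pd.DataFrame,
    trait_table: pd.DataFrame,
    response: str = "total_specialization",
    reference: str = STATUS_PREVIOUSLY_UNRECORDED,
) -> StatusModelFit:
    """Poisson mixed model of a specialization score on occurrence status.

    The response is a bounded ordinal score, not a count; the Poisson error
    family follows the analysis design this package reproduces, and a note
    flags that dispersion diagnostics are advisable. The family random
    intercept is fitted by variational Bayes; the primary contrast is again
    lost vs previously unrecorded, tested with the posterior mean / sd ratio
    as an approximate z statistic. Nakagawa R^2 uses the lognormal
    approximation ln(1 + 1/lambda-bar) for the Poisson residual variance on
    the link scale.
    """
    df = scores.merge(statuses[["species_id", "status"]], on="species_id")
    df = df.merge(
        trait_table[["species_id", "family"]]
        if "species_id" in trait_table.columns
        else trait_table.reset_index()[["species_id", "family"]],
        on="species_id",
    )
    y = df[response].astype(int)
    if (y < 1).any():
        raise ValueError("Poisson status model requires integer responses >= 1")
    df = df.assign(_y=y)

    notes = ["Poisson family on a bounded score; check over/under-dispersion"]
    formula = f"_y ~ C(status, Treatment({reference!r}))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = PoissonBayesMixedGLM.from_formula(formula, {"family": "0 + C(family)"}, df)
            state = np.random.get_state()
            np.random.seed(20_07)  # the VB optimizer draws from the global RNG
            try:
                fit = model.fit_vb()
            finally:
                np.random.set_state(state)
            fe = pd.Series(fit.fe_mean, index=model.exog_names)
            fe_sd = pd.Series(fit.fe_sd, index=model.exog_names)
            var_random = float(np.exp(2 * fit.vcp_mean[0]))
            engine = "poisson_glmm"
        except Exception as exc:
            notes.append(f"mixed Poisson fit failed ({exc}); fixed-effects GLM fallback")
            logger.warning(notes[-1])
            glm = smf.glm(formula, df, family=sm.families.Poisson()).fit()
            fe, fe_sd = glm.params, glm.bse
            var_random = 0.0
            engine = "poisson_glm_fallback"

    terms = [t for t in fe.index if t.startswith("C(status")]
    contrasts = {_status_from_term(t): float(fe[t]) for t in terms}
    term = next(t for t in terms if _status_from_term(t) == STATUS_LOST)
    z = float(fe[term] / fe_sd[term])
    p = float(2 * stats.norm.sf(abs(z)))

    x = pd.get_dummies(df["status"], dtype=float)
    eta_fixed = fe[f"{'Intercept' if 'Intercept' in fe.index else fe.index[0]}"] + sum(
        contrasts.get(s, 0.0) * x[s] for s in x.columns if s in contrasts
    )
    var_fixed = float(np.var(eta_fixed, ddof=0))
    lam_bar = float(df["_y"].mean())
    var_resid = float(np.log1p(1.0 / lam_bar))
    marg, cond = _nakagawa_r2(var_fixed, var_random, var_resid)

    return StatusModelFit(
        response_name=response,
        model=engine,
        contrasts=contrasts,
        reference_level=reference,
        primary_contrast=f"{STATUS_LOST} - {reference}",
        coefficient=contrasts.get(STATUS_LOST, np.nan),
        test_statistic=z,
        p_value=p,
        marginal_r2=marg,
        conditional_r2=cond,
        random_intercept_variance=var_random,
        warnings=notes,
    )
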