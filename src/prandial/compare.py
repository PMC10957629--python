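"""Mixed-model comparison of test interventions against a reference.

Per analyte and per PoI, a linear mixed model

    PoI ~ Intervention + Period + (1 | Participant)

is fitted by REML (Period is a categorical fixed effect, included by
default; Participant is a random intercept). Contrasts of each test
intervention against the reference are reported either as differences on
the response scale (default for Height and Time2Max) or as ratios (default
for AUC): for ratio-type PoIs the response is log-transformed before
fitting, so the back-transformed contrast and its confidence interval are
exact exponentials of the log-scale estimate.

Inference on the contrasts uses t-tests with Satterthwaite
degrees of freedom computed from the REML information matrix; for balanced
complete crossover designs these coincide with the classical residual
degrees of freedom (and with the Kenward-Roger values, since the
random-intercept covariance structure makes the two approximations agree).
p-values are corrected for multiplicity within each PoI family (Holm by
default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

POI_NAMES = ["auc", "height", "time2max"]

DEFAULT_CONTRAST_TYPES = {"auc": "ratio", "height": "difference", "time2max": "difference"}


@dataclass
class ModelSpec:
    """Configuration of the comparison model.

    contrast_types maps each PoI to "ratio" or "difference"; ratio is the
    convention for AUC (relative uptake), difference for peak height and
    time to maximum. adjust is one of "holm", "bonferroni", "none".
    """

    include_period: bool = True
    contrast_types: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST_TYPES))
    level: float = 0.95
    adjust: str = "holm"

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ConfigurationError(f"confidence level must be in (0,1), got {self.level}")
        if self.adjust not in ("holm", "bonferroni", "none"):
            raise ConfigurationError(f"unknown adjustment {self.adjust!r}")
        for poi, ctype in self.contrast_types.items():
            if ctype not in ("ratio", "difference"):
                raise ConfigurationError(f"contrast type for {poi}: {ctype!r}")


@dataclass
class PoIModelFit:
    """One fitted mixed model (one analyte x one PoI) plus everything
    needed for small-sample inference on its contrasts."""

    analyte: str
    poi: str
    reference: str
    test_levels: list[str]
    response_scale: str            # "log" for ratio contrasts, else "identity"
    coef: pd.Series                # fixed effects, index = design column names
    X: np.ndarray                  # fixed-effects design
    groups: np.ndarray             # participant codes per row
    y: np.ndarray
    sigma2_participant: float
    sigma2_residual: float
    n_used: int
    colnames: list[str]


def _build_design(df: pd.DataFrame, reference: str, include_period: bool):
    """Intercept + treatment-coded intervention (reference base) + period dummies."""
    levels = sorted(df["intervention"].unique())
    if reference not in levels:
        raise ConfigurationError(f"reference {reference!r} absent from data")
    test_levels = [l for l in levels if l != reference]
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for lev in test_levels:
        cols.append((df["intervention"] == lev).to_numpy(float))
        names.append(f"intervention[{lev}]")
    if include_period:
        periods = sorted(df["period"].unique())
        for per in periods[1:]:
            cols.append((df["period"] == per).to_numpy(float))
            names.append(f"period[{per}]")
    X = np.column_stack(cols)
    return X, names, test_levels


def fit_poi_model(pois: pd.DataFrame, poi: str, analyte: str, reference: str,
                  spec: ModelSpec | None = None) -> PoIModelFit | None:
    """Fit the random-intercept model for one analyte x PoI.

    Returns None (with a logged reason) when there are fewer than two
    interventions with at least three non-missing values each. For
    ratio-type PoIs non-positive values cannot enter the log transform and
    are dropped with a warning — curation should already have removed them.
    """
    spec = spec or ModelSpec()
    sub = pois[(pois["analyte"] == analyte) & pois[poi].notna()].copy()
    ctype = spec.contrast_types.get(poi, "difference")
    if ctype == "ratio":
        nonpos = sub[poi] <= 0
        if nonpos.any():
            warnings.warn(
                f"{analyte}/{poi}: dropping {int(nonpos.sum())} non-positive "
                "values before log transform", stacklevel=2)
            sub = sub[~nonpos]
    counts = sub.groupby("intervention")[poi].count()
    if (counts >= 3).sum() < 2:
        logger.warning("%s/%s: insufficient data (%s), model skipped",
                       analyte, poi, counts.to_dict())
        return None

    y = sub[poi].to_numpy(float)
    scale = "identity"
    if ctype == "ratio":
        y = np.log(y)
        scale = "log"
    include_period = (spec.include_period and "period" in sub.columns
                      and sub["period"].notna().all())
    X, names, test_levels = _build_design(sub, reference, include_period)
    groups, _ = pd.factorize(sub["participant"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=True, method=["lbfgs", "powell"])
            sigma2_p = float(np.asarray(res.cov_re)[0, 0])
            sigma2_e = float(res.scale)
            coef = pd.Series(np.asarray(res.fe_params), index=names)
        except Exception as exc:  # degenerate data (e.g. zero variance)
            logger.info("%s/%s: mixed model failed (%s); falling back to "
                        "fixed-participant least squares", analyte, poi, exc)
            dummies = pd.get_dummies(groups, drop_first=True).to_numpy(float)
            Xf = np.column_stack([X, dummies])
            beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
            resid = y - Xf @ beta
            dof = max(len(y) - np.linalg.matrix_rank(Xf), 1)
            sigma2_p, sigma2_e = 0.0, float(resid @ resid / dof)
            coef = pd.Series(beta[: X.shape[1]], index=names)

    return PoIModelFit(
        analyte=analyte, poi=poi, reference=reference, test_levels=test_levels,
        response_scale=scale, coef=coef, X=X, groups=groups, y=y,
        sigma2_participant=max(sigma2_p, 0.0), sigma2_residual=max(sigma2_e, 0.0),
        n_used=len(y), colnames=names,
    )


def _gls_inference(fit: PoIModelFit, ell: np.ndarray):
    """GLS estimate, standard error and Satterthwaite df for contrast ell'beta.

    V = sigma2_e I + sigma2_p Z Z' (Z the participant indicator). The df
    follow Satterthwaite: df = 2 f^2 / (g' A g) with f = ell' C ell,
    C = (X'V^-1 X)^-1, g the gradient of f in the variance components and A
    the inverse REML information matrix I_jk = tr(P V_j P V_k)/2,
    P = V^-1 - V^-1 X C X' V^-1.
    """
    X, y, groups = fit.X, fit.y, fit.groups
    n = len(y)
    Z = np.zeros((n, groups.max() + 1))
    Z[np.arange(n), groups] = 1.0
    V1 = Z @ Z.T
    s2p, s2e = fit.sigma2_participant, max(fit.sigma2_residual, 1e-300)
    V = s2e * np.eye(n) + s2p * V1
    Vinv = np.linalg.inv(V)
    XtVi = X.T @ Vinv
    C = np.linalg.inv(XtVi @ X)
    beta = C @ (XtVi @ y)
    est = float(ell @ beta)
    var = float(ell @ C @ ell)
    se = np.sqrt(max(var, 0.0))

    # Satterthwaite df
    P = Vinv - XtVi.T @ C @ XtVi
    info = 0.5 * np.array([
        [np.trace(P @ V1 @ P @ V1), np.trace(P @ V1 @ P)],
        [np.trace(P @ V1 @ P), np.trace(P @ P)],
    ])
    u = X @ (C @ ell)
    h = Vinv @ u
    g = np.array([float(h @ V1 @ h), float(h @ h)])
    try:
        A = np.linalg.pinv(info)
        denom = float(g @ A @ g)
        df = 2.0 * var**2 / denom if denom > 0 else np.nan
    except np.linalg.LinAlgError:
        df = np.nan
    if not np.isfinite(df) or df <= 0:
        # classical fallback: residual df of the fixed-participant model
        df = max(n - X.shape[1] - (Z.shape[1] - 1), 1)
    return est, se, float(df)


def contrasts_vs_reference(model_fits, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Build the test-vs-reference comparison table from fitted models.

    One row per (analyte, poi, test intervention). Ratio contrasts are
    exponentiated back from the log scale, so ``estimate`` is the geometric
    ratio and the CI bounds are exact back-transforms. p_adjusted applies
    the configured multiplicity correction within each PoI family.
    """
    spec = spec or ModelSpec()
    alpha = 1.0 - spec.level
    rows = []
    for fit in model_fits:
        if fit is None:
            continue
        ctype = "ratio" if fit.response_scale == "log" else "difference"
        for lev in fit.test_levels:
            name = f"intervention[{lev}]"
            ell = np.array([1.0 if c == name else 0.0 for c in fit.colnames])
            est, se, df = _gls_inference(fit, ell)
            tcrit = stats.t.ppf(1 - alpha / 2, df)
            lo, hi = est - tcrit * se, est + tcrit * se
            if se > 0:
                tstat = est / se
                p = 2 * stats.t.sf(abs(tstat), df)
            else:  # degenerate noiseless case: width-0 interval
                p = 1.0 if est == 0 else 0.0
            if ctype == "ratio":
                est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
            rows.append({
                "analyte": fit.analyte, "poi": fit.poi,
                "contrast": f"{lev} vs {fit.reference}", "type": ctype,
                "estimate": est, "ci_low": lo, "ci_high": hi,
                "p_raw": p, "n_used": fit.n_used, "df": df,
                "df_method": "satterthwaite",
            })
    out = pd.DataFrame(rows, columns=["analyte", "poi", "contrast", "type",
                                      "estimate", "ci_low", "ci_high", "p_raw",
                                      "n_used", "df", "df_method"])
    if len(out):
        out["p_adjusted"] = out["p_raw"]
        for poi, idx in out.groupby("poi").groups.items():
            p = out.loc[idx, "p_raw"].to_numpy()
            adj = p if spec.adjust == "none" else multipletests(p, method=spec.adjust)[1]
            out.loc[idx, "p_adjusted"] = adj
    else:
        out["p_adjusted"] = []
    return out


def compare_pois(pois: pd.DataFrame, reference: str,
                 spec: ModelSpec | None = None,
                 poi_names: tuple[str, ...] = ("auc", "height", "time2max"),
                 ) -> pd.DataFrame:
    """Full comparison driver: fit every analyte x PoI model, contrast, adjust."""
    spec = spec or ModelSpec()
    fits = []
    for analyte in sorted(pois["analyte"].unique()):
        for poi in poi_names:
            fits.append(fit_poi_model(pois, poi, analyte, reference, spec))
    return contrasts_vs_reference(fits, spec)


def summarize_pois(pois: pd.DataFrame) -> pd.DataFrame:
    """Count / mean / sd of each PoI per (analyte, poi, intervention)."""
    rows = []
    for (analyte, intervention), grp in pois.groupby(["analyte", "intervention"],
                                                     sort=True):
        for poi in POI_NAMES:
            if poi not in grp.columns:
                continue
            vals = grp[poi].dropna()
            rows.append({
                "analyte": analyte, "poi": poi, "intervention": intervention,
                "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows, columns=["analyte", "poi", "intervention",
                                       "n", "mean", "sd"])
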