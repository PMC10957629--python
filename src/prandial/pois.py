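"""Parameters of interest (PoIs) from Wood fits, and their curation.

The three PoIs summarizing one fitted curve y(t) = d + a*t^b*e^(-ct),
b = m*c, all relative to the baseline d:

* ``Time2Max`` — time of the peak maximum; equals m exactly.
* ``Height``   — peak height above baseline; a*(b/c)^b*e^(-b).
* ``AUC``      — area under the curve above baseline up to an endpoint t_f:

      AUC(t_f) = integral_0^{t_f} a t^b e^{-ct} dt
               = a * gammainc_lower(b+1, c*t_f) / c^(b+1),

  where gammainc_lower(q, x) = integral_0^x z^{q-1} e^{-z} dz is the
  (unregularized) lower incomplete gamma function with shape q and upper
  limit x.

Curation replaces values outside configured plausible ranges by missing,
with a full audit report. A curve-parameter violation discredits the whole
fit, so all three PoIs of that series are removed; a single-PoI violation
removes only that PoI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .woodcurve import WoodParams

POI_NAMES = ["auc", "height", "time2max"]
PARAM_NAMES = ["a", "m", "c", "d"]


def poi_time2max(params: WoodParams) -> float:
    """Time to the peak maximum in minutes: the parameter m, exactly."""
    return float(params.m)


def poi_height(params: WoodParams) -> float:
    """Peak height above baseline: a*(b/c)^b*e^(-b), b = m*c.

    Equals wood_eval(m) - d; computed in log space since b/c = m can make
    (b/c)^b overflow for slow-decay fits. An overflowing height comes back
    as inf (and is removed by curation) rather than raising.
    """
    b = params.b
    with np.errstate(over="ignore"):
        return float(params.a * np.exp(b * (math.log(params.m) - 1.0)))


def poi_auc(params: WoodParams, t_f: float) -> float:
    """Area under the curve above baseline on [0, t_f] minutes.

    Uses the closed form a * gammainc_lower(b+1, c*t_f) / c^(b+1), evaluated
    via the regularized incomplete gamma P and log-gamma for numerical range:
    gammainc_lower(q, x) = P(q, x) * Gamma(q).
    """
    if not t_f > 0:
        raise ValueError(f"t_f must be positive, got {t_f}")
    b, c = params.b, params.c
    q = b + 1.0
    log_scale = special.gammaln(q) - q * math.log(c)
    with np.errstate(over="ignore"):
        return float(params.a * special.gammainc(q, c * t_f) * np.exp(log_scale))


def poi_auc_infinite(params: WoodParams) -> float:
    """Limit of the AUC as t_f -> infinity: a*Gamma(b+1)/c^(b+1)."""
    q = params.b + 1.0
    return float(params.a * math.exp(special.gammaln(q) - q * math.log(params.c)))


def extract_pois(fits: pd.DataFrame, t_f: float | None = None) -> pd.DataFrame:
    """Compute the PoI table from a fit table (one row per series).

    Failed fits yield all-missing PoIs. ``t_f`` defaults per series to the
    largest observed sampling time (column ``t_max`` of the fit table), so
    the AUC never extrapolates beyond the data unless explicitly asked to.
    """
    rows = []
    for rec in fits.itertuples(index=False):
        row = {"participant": rec.participant, "intervention": rec.intervention,
               "analyte": rec.analyte, "period": getattr(rec, "period", np.nan)}
        tf_series = t_f if t_f is not None else getattr(rec, "t_max", np.nan)
        row["t_f"] = float(tf_series)
        if getattr(rec, "converged", False) and np.isfinite(rec.a):
            p = WoodParams(a=rec.a, m=rec.m, c=rec.c, d=rec.d)
            row.update(auc=poi_auc(p, tf_series), height=poi_height(p),
                       time2max=poi_time2max(p))
        else:
            row.update(auc=np.nan, height=np.nan, time2max=np.nan)
        rows.append(row)
    cols = ["participant", "intervention", "analyte", "period",
            "auc", "height", "time2max", "t_f"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class CurationRules:
    """Plausible ranges for PoIs and curve parameters.

    Open intervals (lo, hi); a value outside becomes missing. PoI defaults:
    AUC strictly positive, peak height in (0, 1000) concentration units,
    time to maximum in (15, 200) minutes. Curve-parameter rules default to
    bare positivity (narrow parameter limits belong to curation, not to the
    optimizer, but even here the defaults stay liberal). Note that totals of
    aggregated analytes may need wider height/AUC ranges than individual
    amino acids; set them per study.
    """

    poi_limits: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "auc": (0.0, math.inf),
        "height": (0.0, 1000.0),
        "time2max": (15.0, 200.0),
    })
    param_limits: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "a": (0.0, math.inf),
        "m": (0.0, math.inf),
        "c": (0.0, math.inf),
        "d": (-math.inf, math.inf),   # zero baseline is legitimate
    })

    def __post_init__(self):
        for name, (lo, hi) in {**self.poi_limits, **self.param_limits}.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")


def curate(pois: pd.DataFrame, fits: pd.DataFrame | None = None,
           rules: CurationRules | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace implausible values by missing and report every removal.

    Ranges are open: a value equal to a bound is out of range. Values inside
    their ranges are returned bit-identical. Idempotent.

    Returns
    -------
    (curated PoI table with an added ``curated_flags`` column,
     report frame with one row per removal: keys, quantity, value, bound).
    """
    rules = rules or CurationRules()
    out = pois.copy()
    report_rows = []
    if "curated_flags" in out.columns:  # re-curation: keep earlier flags
        flags = [set(f.split(";")) if f else set()
                 for f in out["curated_flags"].fillna("")]
    else:
        flags = [set() for _ in range(len(out))]
    keys = out[["participant", "intervention", "analyte"]]

    def _flag(i, quantity, value, lo, hi):
        flags[i].add(quantity)
        report_rows.append({
            **keys.iloc[i].to_dict(), "quantity": quantity,
            "value": value, "lower": lo, "upper": hi,
        })

    if fits is not None and len(fits):
        fit_idx = fits.set_index(["participant", "intervention", "analyte"])
        for i, key in enumerate(keys.itertuples(index=False)):
            try:
                frow = fit_idx.loc[tuple(key)]
            except KeyError:
                continue
            bad_param = False
            for pname in PARAM_NAMES:
                val = frow.get(pname, np.nan)
                if not np.isfinite(val):
                    continue
                lo, hi = rules.param_limits.get(pname, (-math.inf, math.inf))
                if not lo < val < hi:
                    _flag(i, f"param_{pname}", float(val), lo, hi)
                    bad_param = True
            if bad_param:  # a broken fit discredits every PoI of the series
                for poi in POI_NAMES:
                    if np.isfinite(out.at[out.index[i], poi]):
                        out.at[out.index[i], poi] = np.nan
                        flags[i].add(poi)

    for poi in POI_NAMES:
        lo, hi = rules.poi_limits.get(poi, (-math.inf, math.inf))
        col = out[poi].to_numpy(float)
        bad = np.isfinite(col) & ~((col > lo) & (col < hi))
        for i in np.flatnonzero(bad):
            _flag(i, poi, float(col[i]), lo, hi)
            out.iloc[i, out.columns.get_loc(poi)] = np.nan

    out["curated_flags"] = [";".join(sorted(f)) for f in flags]
    report = pd.DataFrame(
        report_rows,
        columns=["participant", "intervention", "analyte", "quantity",
                 "value", "lower", "upper"],
    )
    return out, report
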