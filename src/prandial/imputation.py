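"""Non-responder imputation of AUC and Height from the raw-data spread.

A series whose curve fit failed (or was curated away) because the
participant showed no measurable uptake is informative: its true AUC and
peak height are close to zero, not unknown. Leaving such series missing
biases the intervention comparison toward responders only.

The spread between the 0.2 and 0.8 quantiles of the raw time-course values
is a robust measure of how much the series moves. Per analyte, a simple
least-squares line of the observed PoI on this spread is trained on
responders and used to predict the PoI of non-responder series; predictions
are floored at 0. Time to maximum is never imputed — a series without a
peak has no maximum to locate.

Only series classified as non-response are imputed: fit failures whose
spread is small compared to the responders' (below a configurable fraction
of the median responder spread). Missingness with a normal-sized spread is
treated as a data-quality problem and left missing. It is advisable to run
the downstream comparison both with and without imputed values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dataio import StudyTable

logger = logging.getLogger(__name__)

_KEYS = ["participant", "intervention", "analyte"]

#: fixed quantile rule for the whole package: linear interpolation between
#: order statistics (numpy's default), for reproducibility across tools
QUANTILE_METHOD = "linear"


def spread_features(table: StudyTable) -> pd.DataFrame:
    """Per-series 0.2/0.8 quantiles of the raw values and their spread.

    Missing raw values are ignored. A series with fewer than 2 observed
    values gets NaN features and ``available=False``.

    Returns
    -------
    DataFrame: participant, intervention, analyte, q20, q80, spread, available.
    """
    rows = []
    for (participant, intervention, analyte), grp in table.series():
        vals = grp["value"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if vals.size >= 2:
            q20, q80 = np.quantile(vals, [0.2, 0.8], method=QUANTILE_METHOD)
            rows.append(dict(participant=participant, intervention=intervention,
                             analyte=analyte, q20=q20, q80=q80,
                             spread=q80 - q20, available=True))
        else:
            rows.append(dict(participant=participant, intervention=intervention,
                             analyte=analyte, q20=np.nan, q80=np.nan,
                             spread=np.nan, available=False))
    return pd.DataFrame(rows, columns=_KEYS + ["q20", "q80", "spread", "available"])


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x; flat line if x is constant."""
    if np.ptp(x) == 0:
        return 0.0, float(np.mean(y))
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def impute_pois(pois: pd.DataFrame, features: pd.DataFrame,
                targets: tuple[str, ...] = ("auc", "height"),
                min_responders: int = 3,
                nonresponse_spread_fraction: float = 0.5,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing AUC/Height for non-responder series.

    Parameters
    ----------
    pois
        PoI table (possibly curated); observed entries are never touched.
    features
        Output of :func:`spread_features` for the same study.
    targets
        Subset of {"auc", "height"}; time2max is never imputable.
    min_responders
        Minimum responder series per analyte to train the regression;
        analytes below it are skipped with a warning.
    nonresponse_spread_fraction
        A missing series counts as non-response only when its spread is
        below this fraction of the median responder spread for the analyte.

    Returns
    -------
    (PoI table with imputed values and an ``imputed`` flag column,
     report with one row per imputed value: keys, target, spread,
     imputed value, slope, intercept, n_responders).
    """
    bad = set(targets) - {"auc", "height"}
    if bad:
        raise ValueError(f"only auc and height can be imputed, got {sorted(bad)}")
    out = pois.reset_index(drop=True).copy()
    out["imputed"] = ""
    # left merge is 1:1 and order-preserving, so merged rows align with out
    merged = out.merge(features[_KEYS + ["spread"]], on=_KEYS, how="left")
    report_rows = []

    for analyte, grp in merged.groupby("analyte", sort=True):
        for target in targets:
            responders = grp[grp[target].notna() & grp["spread"].notna()]
            if len(responders) < min_responders:
                logger.warning(
                    "analyte %s: only %d responders for %s, imputation skipped",
                    analyte, len(responders), target)
                continue
            median_spread = float(responders["spread"].median())
            slope, intercept = _ols_line(responders["spread"].to_numpy(float),
                                         responders[target].to_numpy(float))
            candidates = grp[grp[target].isna() & grp["spread"].notna()]
            for idx, row in candidates.iterrows():
                if row["spread"] >= nonresponse_spread_fraction * median_spread:
                    continue  # data-quality missingness, not non-response
                pred = max(0.0, slope * row["spread"] + intercept)
                out.loc[idx, target] = pred
                prev = out.loc[idx, "imputed"]
                out.loc[idx, "imputed"] = f"{prev};{target}" if prev else target
                report_rows.append({
                    "participant": row["participant"],
                    "intervention": row["intervention"], "analyte": analyte,
                    "target": target, "spread": row["spread"],
                    "imputed_value": pred, "slope": slope,
                    "intercept": intercept, "n_responders": len(responders),
                })
    report = pd.DataFrame(
        report_rows,
        columns=_KEYS + ["target", "spread", "imputed_value", "slope",
                         "intercept", "n_responders"],
    )
    return out, report
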