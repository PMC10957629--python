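"""Static visualization: time-course panels, PCA score plots, PoI dot
plots and forest plots of intervention contrasts.

All plotting functions are side-effect-free on their input tables and
return the matplotlib Figure; pass ``path`` to also write an image file
(PNG/PDF/SVG by extension).
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dataio import StudyTable
from .errors import ConfigurationError
from .woodcurve import WoodParams, wood_eval

_COLORS = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def _intervention_colors(levels):
    return {lev: _COLORS[i % len(_COLORS)] for i, lev in enumerate(sorted(levels))}


def plot_timecourses(table: StudyTable, participants=None, analytes=None,
                     fits: pd.DataFrame | None = None, path=None):
    """Panel grid of raw time courses: rows = analytes, columns =
    participants, one colored line per intervention; fitted Wood curves
    overlaid when a fit table is supplied."""
    participants = list(participants) if participants is not None else table.participants
    analytes = list(analytes) if analytes is not None else table.analyte_roster
    known_p, known_a = set(table.participants), set(table.analyte_roster)
    unknown = [p for p in participants if p not in known_p] + \
              [a for a in analytes if a not in known_a]
    if unknown:
        raise ConfigurationError(f"unknown participants/analytes: {unknown}")
    if not participants or not analytes:
        raise ConfigurationError("empty participant or analyte selection")

    colors = _intervention_colors(table.interventions)
    fit_idx = (fits.set_index(["participant", "intervention", "analyte"])
               if fits is not None and len(fits) else None)
    nrows, ncols = len(analytes), len(participants)
    fig, axes = plt.subplots(nrows, ncols, squeeze=False, sharex=True,
                             figsize=(2.6 * ncols + 1, 1.8 * nrows + 1))
    for i, analyte in enumerate(analytes):
        for j, pid in enumerate(participants):
            ax = axes[i][j]
            sub = table.data[(table.data["participant"] == pid)
                             & (table.data["analyte"] == analyte)]
            for intervention, grp in sub.groupby("intervention"):
                grp = grp.sort_values("time")
                ax.plot(grp["time"], grp["value"], "o", ms=3,
                        color=colors[intervention], label=intervention)
                if fit_idx is not None:
                    try:
                        frow = fit_idx.loc[(pid, intervention, analyte)]
                    except KeyError:
                        continue
                    if bool(frow.get("converged", False)) and np.isfinite(frow["a"]):
                        tt = np.linspace(0, float(grp["time"].max()), 120)
                        p = WoodParams(a=frow["a"], m=frow["m"], c=frow["c"],
                                       d=frow["d"])
                        ax.plot(tt, wood_eval(p, tt), "-", lw=1,
                                color=colors[intervention])
            if i == 0:
                ax.set_title(str(pid), fontsize=9)
            if j == 0:
                ax.set_ylabel(analyte, fontsize=9)
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper right", fontsize=8)
    fig.supxlabel("time (min)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def pca_scores(table: StudyTable, arrangement: str = "per-participant-intervention",
               centering: str = "per-row", n_components: int = 2, path=None):
    """PCA of concatenated time courses.

    Rows are built per the arrangement: ``per-participant`` concatenates
    every (intervention, analyte) course of a participant into one row;
    ``per-participant-intervention`` one row per participant x intervention
    (courses of all analytes side by side); ``per-series`` one row per
    single time course. ``per-row`` centering subtracts each row's own mean
    first, largely removing baseline differences; columns are then
    mean-centered as usual and scores come from the singular value
    decomposition. Missing cells are column-mean-filled with a warning.

    Returns (scores DataFrame with key columns + PC1..PCk + explained
    variance ratios in ``.attrs``, Figure or None).
    """
    index_keys = {
        "per-participant": ["participant"],
        "per-participant-intervention": ["participant", "intervention"],
        "per-series": ["participant", "intervention", "analyte"],
    }.get(arrangement)
    if index_keys is None:
        raise ConfigurationError(f"unknown arrangement {arrangement!r}")
    if centering not in ("per-row", "none"):
        raise ConfigurationError(f"unknown centering {centering!r}")

    wide_cols = [c for c in ["intervention", "analyte", "time"] if c not in index_keys]
    mat = table.data.pivot_table(index=index_keys, columns=wide_cols,
                                 values="value", aggfunc="first",
                                 dropna=False, observed=True)
    if mat.shape[0] < 3:
        raise ConfigurationError("PCA needs at least 3 rows")
    X = mat.to_numpy(float)
    if np.isnan(X).any():
        warnings.warn("missing cells column-mean-filled before PCA", stacklevel=2)
        col_mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(col_mean, inds[1])
    if centering == "per-row":
        X = X - X.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    scores = U[:, :k] * S[:k]
    out = mat.index.to_frame(index=False)
    for i in range(k):
        out[f"PC{i+1}"] = scores[:, i]
    with np.errstate(invalid="ignore"):
        out.attrs["explained_variance_ratio"] = (S[:k] ** 2 / (S**2).sum()).tolist()

    fig = None
    if k >= 2:
        fig, ax = plt.subplots(figsize=(5, 4.5))
        if "intervention" in out.columns:
            colors = _intervention_colors(out["intervention"].unique())
            for lev, grp in out.groupby("intervention"):
                ax.scatter(grp["PC1"], grp["PC2"], color=colors[lev], label=lev, s=25)
            ax.legend(fontsize=8)
        else:
            ax.scatter(out["PC1"], out["PC2"], s=25)
        evr = out.attrs["explained_variance_ratio"]
        ax.set_xlabel(f"PC1 ({evr[0]*100:.1f}%)")
        ax.set_ylabel(f"PC2 ({evr[1]*100:.1f}%)")
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
    return out, fig


def plot_poi_dotplot(pois: pd.DataFrame, curated: pd.DataFrame, path=None):
    """Uncurated (left) vs curated (right) PoI values, per PoI x analyte.

    Participants on the vertical axis, colored by intervention; values
    removed by curation are simply absent from the right-hand panel.
    """
    poi_names = [p for p in ("auc", "height", "time2max") if p in pois.columns]
    if not len(pois):
        warnings.warn("empty PoI table, producing empty plot", stacklevel=2)
        fig, _ = plt.subplots()
        if path:
            fig.savefig(path, dpi=120)
        return fig
    analytes = sorted(pois["analyte"].unique())
    participants = sorted(pois["participant"].unique(), key=str)
    ypos = {p: i for i, p in enumerate(participants)}
    colors = _intervention_colors(pois["intervention"].unique())
    fig, axes = plt.subplots(len(analytes), 2 * len(poi_names), squeeze=False,
                             sharey=True,
                             figsize=(2.2 * 2 * len(poi_names), 1.5 * len(analytes) + 1))
    for i, analyte in enumerate(analytes):
        for j, poi in enumerate(poi_names):
            for side, frame in ((0, pois), (1, curated)):
                ax = axes[i][2 * j + side]
                sub = frame[(frame["analyte"] == analyte) & frame[poi].notna()]
                for lev, grp in sub.groupby("intervention"):
                    ax.plot(grp[poi], [ypos[p] for p in grp["participant"]],
                            "o", ms=3, color=colors[lev])
                if i == 0:
                    ax.set_title(f"{poi} ({'raw' if side == 0 else 'curated'})",
                                 fontsize=8)
            axes[i][0].set_ylabel(analyte, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def plot_forest(results: pd.DataFrame, path=None, highlight_color="red"):
    """Forest plot of intervention contrasts, one panel per PoI.

    The dashed no-effect line sits at 1 for ratio-type and 0 for
    difference-type results; intervals excluding it are highlighted.
    """
    if not len(results):
        raise ConfigurationError("empty results table")
    poi_names = list(pd.unique(results["poi"]))
    fig, axes = plt.subplots(1, len(poi_names), squeeze=False,
                             figsize=(4.2 * len(poi_names), 0.28 * len(results) + 2))
    for j, poi in enumerate(poi_names):
        ax = axes[0][j]
        sub = results[results["poi"] == poi].reset_index(drop=True)
        null_vals = sub["type"].map({"ratio": 1.0, "difference": 0.0})
        for i, row in sub.iterrows():
            null = null_vals[i]
            significant = row["ci_low"] > null or row["ci_high"] < null
            color = highlight_color if significant else "black"
            ax.plot([row["ci_low"], row["ci_high"]], [i, i], "-", color=color)
            ax.plot(row["estimate"], i, "o", ms=4, color=color)
        for null in sorted(null_vals.unique()):
            ax.axvline(null, ls="--", color="grey", lw=1)
        ax.set_yticks(range(len(sub)))
        ax.set_yticklabels(sub["analyte"] + " " + sub["contrast"], fontsize=7)
        ax.set_title(poi, fontsize=10)
        ax.invert_yaxis()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig
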