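"""Baseline-extended Wood curve: evaluation and multi-start nonlinear fitting.

The model for one postprandial time course is

    y(t) = d + a * t**(m*c) * exp(-c*t)

where ``d`` is the baseline concentration, ``a`` an amplitude scale, ``m``
the time of the peak maximum (minutes) and ``c`` the decay rate (1/min).
The shape exponent ``b = m*c`` is derived, never a free parameter, so that
``m`` is directly the time-to-maximum summary of the curve.

Fitting is multi-start bounded nonlinear least squares. Internally the
optimizer works in the equivalent parameterization (h, m, c, d) with h the
peak height above baseline,

    y(t) = d + h * (t/m)**(m*c) * exp(-c*(t - m)),

because h is on the scale of the data whereas a = h * exp(b*(1 - ln m))
spans hundreds of orders of magnitude over a liberal (m, c) box. Random
starts are screened cheaply — for fixed (m, c) the model is linear in
(h, d), so every start's best (h, d) and residual sum of squares come from
a closed-form 2x2 solve, vectorized over starts — and the most promising
candidates are polished with a full four-parameter bounded trust-region
optimization. Implausible parameter values are left to the downstream
curation step rather than excluded by narrow bounds, which can make the
optimizer fail to converge.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .dataio import StudyTable
from .errors import ConfigurationError, UnfittableSeriesError

MIN_POINTS = 5  # four parameters need at least five points

_TINY = 5e-324  # smallest positive float, used to keep a > 0 after underflow


@dataclass(frozen=True)
class WoodParams:
    """The four Wood-curve parameters; ``b = m*c`` is derived."""

    a: float
    m: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a > 0 and self.m > 0 and self.c > 0):
            raise ValueError(f"a, m, c must be strictly positive, got {self}")
        if self.d < 0:
            raise ValueError(f"baseline d must be non-negative, got {self.d}")

    @property
    def b(self) -> float:
        return self.m * self.c

    @property
    def height(self) -> float:
        """Peak height above baseline, a*(b/c)^b*e^-b, computed in log space."""
        return float(np.exp(np.log(self.a) + self.b * (np.log(self.m) - 1.0)))


@dataclass(frozen=True)
class WoodFit:
    """Outcome of fitting one time series."""

    params: WoodParams | None
    rss: float
    n_points: int
    n_starts: int
    converged: bool
    seed: int
    failure_reason: str | None = None


@dataclass
class FitSettings:
    """Tuning knobs for multi-start fitting.

    ``n_starts`` random starts are screened; the best ``n_refine`` get a
    full four-parameter polish. Bounds default to a liberal box derived
    from the data (see :func:`default_bounds`).
    """

    n_starts: int = 500
    n_refine: int = 10
    seed: int = 0
    bounds: dict | None = None
    ftol: float = 1e-10


def wood_eval(params: WoodParams, t) -> np.ndarray | float:
    """Evaluate the Wood curve d + a*t^(m*c)*exp(-c*t) at times t (minutes).

    At t = 0 with b > 0 the power term vanishes and the value is exactly d.
    Computed via the unit-peak form to avoid overflow for large b.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    h = params.height
    out = params.d + h * _unit_shape(t_arr, params.m, params.c)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _unit_shape(t, m, c):
    """(t/m)^(mc) * exp(-c(t-m)): the Wood shape normalized to peak value 1 at t=m.

    Never exceeds 1, so no overflow anywhere in the parameter box; t=0
    maps to exactly 0 (for b > 0).
    """
    t = np.asarray(t, float)
    b = m * c
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.log(t, out=np.full(np.shape(t), -np.inf), where=t > 0)
        logphi = b * (logt - np.log(m)) - c * (t - m)
    return np.exp(logphi)


def default_bounds(times: np.ndarray, values: np.ndarray) -> dict:
    """Liberal parameter box derived from the data.

    d spans [0, max(value)]; m from 5 min to 1.5x the last sampling time;
    c log-ranges over [1e-4, 1] per minute; the peak height h spans 0.01x
    to 10x the observed data range (the equivalent range for the raw
    amplitude a follows from a = h * exp(b*(1 - ln m))).
    """
    vmax = float(np.max(values))
    vrange = float(np.max(values) - np.min(values))
    if vrange <= 0:
        vrange = max(vmax, 1.0)
    tmax = float(np.max(times))
    return {
        "h": (0.01 * vrange, 10.0 * vrange),
        "m": (5.0, 1.5 * tmax),
        "c": (1e-4, 1.0),
        "d": (0.0, vmax),
    }


def _a_from_height(h, m, c):
    """Invert h = a*exp(b(ln m - 1)); clamps underflow away from zero."""
    b = m * c
    with np.errstate(over="ignore", under="ignore"):
        a = h * np.exp(b * (1.0 - np.log(m)))
    return float(np.clip(a, _TINY, 1e308))


def series_seed(global_seed: int, participant, intervention, analyte) -> int:
    """Stable per-series seed derived from the study seed and the series keys.

    Uses CRC-32 of the key string so single-series refits reproduce pipeline
    results across platforms and processes.
    """
    key = f"{global_seed}|{participant}|{intervention}|{analyte}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _draw_starts(box: dict, n_starts: int, seed: int):
    """Random (h, m, c, d) start arrays over the box: m and d uniform,
    c and the peak height h log-uniform. Deterministic given the seed."""
    if n_starts < 1:
        raise ConfigurationError(f"n_starts must be >= 1, got {n_starts}")
    rng = np.random.default_rng(seed)
    m = rng.uniform(*box["m"], n_starts)
    c = np.exp(rng.uniform(np.log(box["c"][0]), np.log(box["c"][1]), n_starts))
    d = rng.uniform(*box["d"], n_starts)
    h = np.exp(rng.uniform(np.log(box["h"][0]), np.log(box["h"][1]), n_starts))
    return h, m, c, d


def make_starts(times, values, n_starts: int = 500, seed: int = 0,
                bounds: dict | None = None) -> list[WoodParams]:
    """Draw random starting parameter sets over the bound box.

    The amplitude a follows from the sampled peak height via
    a = h * exp(b*(1 - ln m)). Deterministic given the seed; the same draw
    underlies :func:`fit_wood` with the same seed.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    box = bounds or default_bounds(times, values)
    h, m, c, d = _draw_starts(box, n_starts, seed)
    return [WoodParams(a=_a_from_height(hi, mi, ci), m=float(mi), c=float(ci),
                       d=float(di))
            for hi, mi, ci, di in zip(h, m, c, d)]


def _screen_starts(times, values, m, c, box):
    """Profile out (h, d) for every (m, c) start; return (rss, h, d) arrays.

    For fixed (m, c) the model is linear in (h, d): y = d + h*phi(t). The
    normal equations are solved in closed form for all starts at once;
    solutions violating the box are projected onto its boundary.
    """
    t = times[None, :]
    g = _unit_shape(t, m[:, None], c[:, None])   # (S, T), values in [0, 1]
    y = values[None, :]
    T = times.size
    sg = g.sum(axis=1)
    sgg = (g * g).sum(axis=1)
    sy = float(values.sum())
    sgy = (g * y).sum(axis=1)
    det = T * sgg - sg**2
    with np.errstate(divide="ignore", invalid="ignore"):
        h_hat = (T * sgy - sg * sy) / det
        d_hat = (sy - h_hat * sg) / T
    h_hat = np.where(np.isfinite(h_hat), h_hat, box["h"][0])
    d_hat = np.where(np.isfinite(d_hat), d_hat, sy / T)
    # flat-or-decreasing data can push h below its floor; refit d alone there
    low_h = h_hat < box["h"][0]
    if low_h.any():
        h_hat[low_h] = box["h"][0]
        d_hat[low_h] = (sy - box["h"][0] * sg[low_h]) / T
    neg_d = d_hat < 0
    if neg_d.any():
        d_hat[neg_d] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            h_d0 = np.where(sgg > 0, sgy / np.maximum(sgg, 1e-300), box["h"][0])
        h_hat[neg_d] = h_d0[neg_d]
    h_hat = np.clip(h_hat, box["h"][0], box["h"][1])
    d_hat = np.clip(d_hat, box["d"][0], box["d"][1])
    resid = y - (d_hat[:, None] + h_hat[:, None] * g)
    rss = (resid**2).sum(axis=1)
    return np.where(np.isfinite(rss), rss, np.inf), h_hat, d_hat


def _batch_model(times, X):
    """Model values for a batch: X is (B, 4) = (h, m, c, d); times (T,)."""
    h, m, c, d = X[:, 0:1], X[:, 1:2], X[:, 2:3], X[:, 3:4]
    return d + h * _unit_shape(times[None, :], m, c)


def _batch_jac(times, X):
    """Analytic Jacobian (B, T, 4) of the (h, m, c, d) parameterization."""
    h, m, c = X[:, 0:1], X[:, 1:2], X[:, 2:3]
    t = times[None, :]
    phi = _unit_shape(t, m, c)
    with np.errstate(divide="ignore"):
        log_ratio = np.where(t > 0, np.log(np.maximum(t, 1e-300)), 0.0) - np.log(m)
    J = np.empty(X.shape[:1] + times.shape + (4,))
    J[..., 0] = phi
    J[..., 1] = h * phi * c * log_ratio
    J[..., 2] = h * phi * (m * log_ratio + m - t)
    J[..., 3] = 1.0
    return J


def _box_arrays(box) -> tuple[np.ndarray, np.ndarray]:
    """(lo, hi) 4-vectors in (h, m, c, d) order for one parameter box."""
    lo = np.array([box["h"][0] * 1e-3, box["m"][0], box["c"][0], box["d"][0]])
    hi = np.array([box["h"][1], box["m"][1], box["c"][1], box["d"][1]])
    return lo, hi


def _lm_refine(times, Y, X0, lo, hi, ftol=1e-10, max_iter=120):
    """Bounded Levenberg-Marquardt over a batch of problems, vectorized.

    times is the shared grid (T,), Y the data (B, T), X0 the starts (B, 4)
    in (h, m, c, d); lo and hi broadcast against X0. Steps solve the
    Marquardt-scaled normal equations and are projected onto the box; a
    problem stops once an accepted step improves its residual sum of
    squares by less than ``ftol`` relative. Each problem's trajectory is
    independent of the rest of the batch, so results do not depend on how
    problems are batched together.

    Returns (X, rss) with X (B, 4) and rss (B,).
    """
    lo = np.broadcast_to(lo, X0.shape)
    hi = np.broadcast_to(hi, X0.shape)
    X = np.clip(np.asarray(X0, float), lo, hi)
    B = X.shape[0]
    resid = _batch_model(times, X) - Y
    rss = (resid**2).sum(axis=1)
    lam = np.full(B, 1e-3)
    active = np.ones(B, bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Xa, Ra = X[idx], resid[idx]
        J = _batch_jac(times, Xa)
        A = np.einsum("bti,btj->bij", J, J)
        g = np.einsum("bti,bt->bi", J, Ra)
        D = A[:, np.arange(4), np.arange(4)]
        Ad = A + lam[idx, None, None] * D[:, None, :] * np.eye(4)
        Ad[:, np.arange(4), np.arange(4)] += 1e-12
        try:
            step = np.linalg.solve(Ad, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(
                Ad.reshape(-1, 4), -g.reshape(-1), rcond=None)[0].reshape(-1, 4)
        Xn = np.clip(Xa + step, lo[idx], hi[idx])
        rn = _batch_model(times, Xn) - Y[idx]
        rss_n = (rn**2).sum(axis=1)
        rss_n = np.where(np.isfinite(rss_n), rss_n, np.inf)
        improved = rss_n < rss[idx]
        gain = rss[idx] - rss_n
        # accept improving steps, shrink damping; otherwise raise damping
        acc = idx[improved]
        X[acc] = Xn[improved]
        resid[acc] = rn[improved]
        converged = improved & (gain <= ftol * np.maximum(rss_n, 1e-300))
        rss[acc] = rss_n[improved]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-12)
        rej = idx[~improved]
        lam[rej] = lam[rej] * 5.0
        active[idx[converged]] = False
        active[rej[lam[rej] > 1e10]] = False
    return X, rss


def _clean_series(times, values):
    """Pairwise-delete missing values and sort by time."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    keep = np.isfinite(values) & np.isfinite(times)
    times, values = times[keep], values[keep]
    order = np.argsort(times)
    return times[order], values[order]


def _candidate_starts(times, values, n_starts, seed, box, n_refine):
    """Screen the random starts and return the top candidates as (k, 4)
    (h, m, c, d) rows, ranked by screened rss with start index breaking ties."""
    _, m, c, _ = _draw_starts(box, n_starts, seed)
    # the drawn h and d are superseded by their profiled optima given (m, c)
    rss_screen, h_hat, d_hat = _screen_starts(times, values, m, c, box)
    ranked = np.lexsort((np.arange(n_starts), rss_screen))
    top = ranked[np.isfinite(rss_screen[ranked])][:n_refine]
    return np.column_stack([h_hat[top], m[top], c[top], d_hat[top]])


def fit_wood(times, values, n_starts: int = 500, seed: int = 0,
             bounds: dict | None = None, n_refine: int = 10,
             ftol: float = 1e-10) -> WoodFit:
    """Fit the Wood curve to one series by multi-start least squares.

    Missing values are deleted pairwise first; at least five usable points
    are required (:class:`UnfittableSeriesError` otherwise). Among all
    candidate solutions the one with minimal residual sum of squares is
    returned; ties break toward the earliest start. A solution sitting on a
    bound still counts as converged — curation filters implausible values
    downstream.
    """
    times, values = _clean_series(times, values)
    n_points = times.size
    if n_points < MIN_POINTS:
        raise UnfittableSeriesError(
            f"need at least {MIN_POINTS} non-missing points, got {n_points}"
        )
    box = bounds or default_bounds(times, values)
    X0 = _candidate_starts(times, values, n_starts, seed, box, n_refine)
    if X0.shape[0] == 0:
        return WoodFit(params=None, rss=np.inf, n_points=n_points,
                       n_starts=n_starts, converged=False, seed=seed,
                       failure_reason="no start converged")
    lo, hi = _box_arrays(box)
    Y = np.broadcast_to(values, (X0.shape[0], n_points))
    X, rss = _lm_refine(times, Y, X0, lo, hi, ftol=ftol)
    rss = np.where(np.isfinite(rss), rss, np.inf)
    best = int(np.argmin(rss))  # first minimum wins: earliest-ranked start
    if not np.isfinite(rss[best]):
        return WoodFit(params=None, rss=np.inf, n_points=n_points,
                       n_starts=n_starts, converged=False, seed=seed,
                       failure_reason="no start converged")
    h, m, c, d = X[best]
    params = WoodParams(a=_a_from_height(h, m, c), m=float(m), c=float(c),
                        d=float(max(d, 0.0)))
    return WoodFit(params=params, rss=float(rss[best]), n_points=n_points,
                   n_starts=n_starts, converged=True, seed=seed)


def fit_all(table: StudyTable, settings: FitSettings | None = None) -> pd.DataFrame:
    """Fit every (participant, intervention, analyte) series of a study.

    Per-series seeds derive deterministically from the study seed and the
    series keys, so a single-series refit reproduces the pipeline result.
    Failures are recorded as rows with ``converged=False``, never raised.

    Returns
    -------
    DataFrame with one row per series: the keys, a, m, c, d, b, rss,
    n_points, converged, failure_reason, t_max (largest observed time).
    """
    settings = settings or FitSettings()
    prepared = []
    for (participant, intervention, analyte), grp in table.series():
        t_raw = grp["time"].to_numpy(float)
        v_raw = grp["value"].to_numpy(float)
        t, v = _clean_series(t_raw, v_raw)
        prepared.append({
            "participant": participant, "intervention": intervention,
            "analyte": analyte, "period": grp["period"].iloc[0],
            "t_max": float(np.nanmax(t_raw)) if t_raw.size else np.nan,
            "t": t, "v": v, "n_points": int(t.size),
        })

    # series sharing a sampling grid are refined together in one LM batch;
    # per-problem trajectories are batch-independent, so results equal a
    # series-by-series fit_wood with the same per-series seed
    by_grid: dict[tuple, list[int]] = {}
    for i, s in enumerate(prepared):
        if s["n_points"] >= MIN_POINTS:
            by_grid.setdefault(tuple(s["t"]), []).append(i)

    outcome: dict[int, tuple[WoodParams | None, float]] = {}
    for grid, idxs in by_grid.items():
        times = np.asarray(grid)
        X0s, Ys, los, his, owner = [], [], [], [], []
        for i in idxs:
            s = prepared[i]
            box = settings.bounds or default_bounds(times, s["v"])
            sseed = series_seed(settings.seed, s["participant"],
                                s["intervention"], s["analyte"])
            X0 = _candidate_starts(times, s["v"], settings.n_starts, sseed,
                                   box, settings.n_refine)
            if X0.shape[0] == 0:
                outcome[i] = (None, np.inf)
                continue
            k = X0.shape[0]
            lo, hi = _box_arrays(box)
            X0s.append(X0)
            Ys.append(np.broadcast_to(s["v"], (k, times.size)))
            los.append(np.broadcast_to(lo, (k, 4)))
            his.append(np.broadcast_to(hi, (k, 4)))
            owner.extend([i] * k)
        if not X0s:
            continue
        X, rss = _lm_refine(times, np.vstack(Ys), np.vstack(X0s),
                            np.vstack(los), np.vstack(his), ftol=settings.ftol)
        rss = np.where(np.isfinite(rss), rss, np.inf)
        owner_arr = np.asarray(owner)
        for i in np.unique(owner_arr):
            mask = owner_arr == i
            sub_rss = rss[mask]
            best = int(np.argmin(sub_rss))  # first minimum: earliest start
            if not np.isfinite(sub_rss[best]):
                outcome[i] = (None, np.inf)
                continue
            h, m, c, d = X[mask][best]
            outcome[i] = (WoodParams(a=_a_from_height(h, m, c), m=float(m),
                                     c=float(c), d=float(max(d, 0.0))),
                          float(sub_rss[best]))

    rows = []
    for i, s in enumerate(prepared):
        row = {k: s[k] for k in ("participant", "intervention", "analyte",
                                 "period", "t_max")}
        row["n_points"] = s["n_points"]
        if s["n_points"] < MIN_POINTS:
            row.update(a=np.nan, m=np.nan, c=np.nan, d=np.nan, b=np.nan,
                       rss=np.nan, converged=False,
                       failure_reason=f"need at least {MIN_POINTS} non-missing "
                                      f"points, got {s['n_points']}")
        else:
            params, rss_i = outcome.get(i, (None, np.inf))
            if params is None:
                row.update(a=np.nan, m=np.nan, c=np.nan, d=np.nan, b=np.nan,
                           rss=np.nan, converged=False,
                           failure_reason="no start converged")
            else:
                row.update(a=params.a, m=params.m, c=params.c, d=params.d,
                           b=params.b, rss=rss_i, converged=True,
                           failure_reason=None)
        rows.append(row)
    cols = ["participant", "intervention", "analyte", "period", "a", "m", "c",
            "d", "b", "rss", "n_points", "converged", "failure_reason", "t_max"]
    return pd.DataFrame(rows, columns=cols)
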