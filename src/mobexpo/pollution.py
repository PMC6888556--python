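"""Hourly 1-km pollution surfaces: ordinary kriging of meteorology + per-hour GWR.

The concentration model is a local linear regression of PM2.5 on three
meteorological covariates,

    PM(s) = b0(s) + b1(s)*VIS(s) + b2(s)*WS(s) + b3(s)*TEM(s) + eps,

with coefficients varying over space (geographically weighted regression).
Because pollution monitors and weather stations sit at different sites, each
meteorological variable is first interpolated to the 1-km grid by ordinary
kriging, then averaged over the cells within 1 km of each pollution monitor.
One GWR model is fitted per hour; its local coefficients, re-evaluated at
every cell center, turn the kriged covariate grids into an hourly
concentration surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin

MET_VARIABLES = ("visibility", "wind_speed", "temperature")  # beta1, beta2, beta3 order


@dataclass(frozen=True)
class Grid1km:
    """Regular square grid; cell (0,0) at the origin corner, row-major indexing."""

    x0: float
    y0: float
    n_rows: int
    n_cols: int
    cell_m: float = 1000.0

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of centers, row-major (row varies slowest)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        cx = self.x0 + (cols + 0.5) * self.cell_m
        cy = self.y0 + (rows + 0.5) * self.cell_m
        xx, yy = np.meshgrid(cx, cy)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def locate(self, x: float, y: float) -> tuple[int, int, bool]:
        """Half-open cell assignment; outside points clamp to the nearest edge cell.

        Returns (row, col, clamped).
        """
        col = math.floor((x - self.x0) / self.cell_m)
        row = math.floor((y - self.y0) / self.cell_m)
        clamped = not (0 <= row < self.n_rows and 0 <= col < self.n_cols)
        row = min(max(row, 0), self.n_rows - 1)
        col = min(max(col, 0), self.n_cols - 1)
        return row, col, clamped

    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col


# ---------------------------------------------------------------------------
# Ordinary kriging


def empirical_semivariogram(
    coords: np.ndarray, values: np.ndarray, n_bins: int = 15, hmax_frac: float = 0.25
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram: (bin centers, gamma, pair counts).

    Only lags up to ``hmax_frac`` of the maximum pairwise distance enter the
    fit: interpolation accuracy is governed by short-lag behaviour, and long
    lags are dominated by any large-scale trend.
    """
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    g = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    hmax = h.max() * hmax_frac
    edges = np.linspace(0, hmax, n_bins + 1)
    centers, gamma, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (h > lo) & (h <= hi)
        if m.sum() > 0:
            centers.append(0.5 * (lo + hi))
            gamma.append(g[m].mean())
            counts.append(m.sum())
    return np.array(centers), np.array(gamma), np.array(counts)


class OrdinaryKriging(BaseEstimator, RegressorMixin):
    """Exact geostatistical interpolator with a fitted exponential variogram.

    Parameters
    ----------
    variogram_model : {"exponential", "gaussian", "spherical"}
        Shape of the semivariogram; the exponential model
        ``gamma(h) = nugget + psill * (1 - exp(-3h/range))`` is the default.
        The Gaussian kernel reproduces smooth short-wavelength structure more
        faithfully at stations but its near-singular system propagates
        structured interpolation artifacts into downstream regressions.
    nugget : float
        Micro-scale variance; 0 keeps the interpolator exact at stations.
    n_bins, hmax_frac :
        Empirical-semivariogram binning for the weighted-least-squares
        variogram fit (weights = sqrt of pair counts per bin).

    A tiny diagonal regularization (1e-6 of the partial sill) conditions the
    kriging system at the cost of station-prediction errors of the same
    relative order.

    Fitted attributes: ``psill_``, ``range_``, ``coords_``, ``values_``.
    """

    def __init__(self, variogram_model: str = "exponential", nugget: float = 0.0,
                 n_bins: int = 15, hmax_frac: float = 0.25):
        self.variogram_model = variogram_model
        self.nugget = nugget
        self.n_bins = n_bins
        self.hmax_frac = hmax_frac

    def _gamma(self, h: np.ndarray, psill: float, rng: float) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.variogram_model == "exponential":
            return self.nugget + psill * (1.0 - np.exp(-3.0 * h / rng))
        if self.variogram_model == "gaussian":
            return self.nugget + psill * (1.0 - np.exp(-3.0 * (h / rng) ** 2))
        if self.variogram_model == "spherical":
            hr = np.minimum(h / rng, 1.0)
            return self.nugget + psill * (1.5 * hr - 0.5 * hr**3)
        raise ValueError(f"unknown variogram model {self.variogram_model!r}")

    def fit(self, X, y):
        coords = np.asarray(X, dtype=float)
        values = np.asarray(y, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("X must be (n_stations, 2) planar coordinates")
        if len(values) != len(coords):
            raise ValueError("X and y length mismatch")
        if len(coords) < 3:
            raise ValueError(f"ordinary kriging needs >= 3 stations, got {len(coords)}")
        uniq, inv = np.unique(coords, axis=0, return_inverse=True)
        if len(uniq) < len(coords):
            for k in range(len(uniq)):
                vals_here = values[inv == k]
                if np.ptp(vals_here) > 0:
                    raise ValueError(
                        f"duplicate station coordinates {tuple(uniq[k])} with conflicting values"
                    )
            # exact duplicates: keep first occurrence
            _, first = np.unique(inv, return_index=True)
            coords, values = coords[np.sort(first)], values[np.sort(first)]
        if len(coords) < 3:
            raise ValueError("fewer than 3 distinct stations after de-duplication")

        self.coords_ = coords
        self.values_ = values
        self.constant_ = bool(np.ptp(values) == 0)
        if self.constant_:
            self.psill_, self.range_ = 0.0, 1.0
            return self

        hc, gamma, counts = empirical_semivariogram(coords, values, self.n_bins,
                                                    self.hmax_frac)
        d_all = cdist(coords, coords)
        hmax_all = float(d_all.max())
        p0 = np.array([max(values.var(), 1e-12), max(hc.max() / 2.0, 1e-6)])
        w = np.sqrt(counts.astype(float))

        def resid(p):
            return w * (self._gamma(hc, p[0], p[1]) - gamma)

        sol = least_squares(resid, p0,
                            bounds=([1e-12, 1e-6], [np.inf, 1.5 * hmax_all]))
        self.psill_, self.range_ = float(sol.x[0]), float(sol.x[1])

        n = len(coords)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = self._gamma(d_all, self.psill_, self.range_)
        np.fill_diagonal(A[:n, :n], 0.0)  # gamma(0)=0: exactness at stations
        A[:n, :n] += 1e-6 * self.psill_ * np.eye(n)  # conditioning guard
        A[n, :n] = 1.0
        A[:n, n] = 1.0
        A[n, n] = 0.0
        self._A_inv = np.linalg.inv(A)
        return self

    def predict(self, X) -> np.ndarray:
        pts = np.asarray(X, dtype=float)
        if self.constant_:
            return np.full(len(pts), self.values_[0])
        n = len(self.coords_)
        b = np.empty((n + 1, len(pts)))
        b[:n] = self._gamma(cdist(self.coords_, pts), self.psill_, self.range_)
        b[n] = 1.0
        lam = self._A_inv @ b
        return lam[:n].T @ self.values_


def krige_meteorology(
    obs: pd.DataFrame, grid: Grid1km, variogram_model: str = "exponential",
    nugget: float = 0.0,
) -> np.ndarray:
    """Ordinary-kriging prediction of one variable/hour at every cell center.

    ``obs`` needs columns x, y, value (one row per station).
    """
    ok = OrdinaryKriging(variogram_model=variogram_model, nugget=nugget)
    ok.fit(obs[["x", "y"]].to_numpy(), obs["value"].to_numpy())
    return ok.predict(grid.cell_centers())


def attach_covariates(
    station_coords: np.ndarray,
    grid: Grid1km,
    surfaces: dict[str, np.ndarray],
    radius_m: float = 1000.0,
) -> tuple[pd.DataFrame, int]:
    """Average kriged cell values within ``radius_m`` of each pollution station.

    Stations with no cell center in radius take the nearest cell's value
    (counted in the returned flag). Returns (covariate table, n_fallback).
    """
    centers = grid.cell_centers()
    station_coords = np.asarray(station_coords, dtype=float)
    d = cdist(station_coords, centers)
    out = {}
    n_fallback = 0
    in_radius = d <= radius_m
    nearest = d.argmin(axis=1)
    fallback_rows = ~in_radius.any(axis=1)
    n_fallback = int(fallback_rows.sum())
    for var, vals in surfaces.items():
        col = np.empty(len(station_coords))
        for i in range(len(station_coords)):
            if fallback_rows[i]:
                col[i] = vals[nearest[i]]
            else:
                col[i] = vals[in_radius[i]].mean()
        out[var] = col
    return pd.DataFrame(out), n_fallback


# ---------------------------------------------------------------------------
# Geographically weighted regression


class GWRegressor(BaseEstimator, RegressorMixin):
    """Geographically weighted linear regression with kernel-distance weights.

    A separate weighted least-squares fit is performed at every calibration
    location, with weights decaying with distance under the chosen kernel, so
    the regression coefficients form smooth spatial fields.

    Parameters
    ----------
    kernel : {"bisquare", "gaussian"}
    bandwidth : float, int or "select"
        With ``adaptive=True`` an integer neighbor count (the kernel reaches
        zero at the k-th nearest station); with ``adaptive=False`` a fixed
        distance in meters. "select" searches the neighbor count minimizing
        the corrected AIC by golden section.
    adaptive : bool

    Fitted attributes: ``coef_`` (n, p+1) local coefficients including the
    intercept, ``fitted_``, ``residuals_``, ``r2_``, ``aic_``, ``aicc_``,
    ``rmse_``, ``bandwidth_``, ``tr_S_``.
    """

    def __init__(self, kernel: str = "bisquare", bandwidth="select", adaptive: bool = True):
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.adaptive = adaptive

    # -- weights ------------------------------------------------------------
    def _weights(self, d: np.ndarray, coords_train: np.ndarray, bw) -> np.ndarray:
        """Weight matrix for target-to-station distances d (m, n)."""
        if self.adaptive:
            k = int(bw)
            k = min(max(k, 1), coords_train.shape[0])
            # bandwidth at each target = distance to its k-th nearest station
            h = np.partition(d, k - 1, axis=1)[:, k - 1]
            h = np.maximum(h, 1e-12)[:, None]
        else:
            h = float(bw)
            if not np.isfinite(h) or h <= 0:
                raise ValueError("fixed bandwidth must be positive")
        u = d / h
        if self.kernel == "bisquare":
            w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
        elif self.kernel == "gaussian":
            w = np.exp(-0.5 * u**2)
        else:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        return w

    @staticmethod
    def _local_fit(Xd: np.ndarray, y: np.ndarray, W: np.ndarray) -> np.ndarray:
        """Batched local WLS: beta (m, p+1) solving (X'W X) b = X'W y per target."""
        XtWX = np.einsum("ms,sp,sq->mpq", W, Xd, Xd)
        XtWy = np.einsum("ms,sp,s->mp", W, Xd, y)
        try:
            return np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular local design in GWR fit: {exc}") from exc

    def _fit_at_train(self, bw) -> tuple[np.ndarray, np.ndarray, float]:
        """Local coefficients at training points + hat diagonal + trace(S)."""
        Xd, y, coords = self._Xd, self._y, self.coords_
        d = cdist(coords, coords)
        W = self._weights(d, coords, bw)
        XtWX = np.einsum("ms,sp,sq->mpq", W, Xd, Xd)
        XtWy = np.einsum("ms,sp,s->mp", W, Xd, y)
        try:
            beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
            inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular local design in GWR fit: {exc}") from exc
        # hat diagonal s_ii = x_i (X'W_iX)^-1 x_i * w_i(i), with X'W_i e_i = w_i(i) x_i
        s_ii = np.einsum("ip,ipq,iq->i", Xd, inv, Xd) * W.diagonal()
        return beta, s_ii, float(s_ii.sum())

    def _aicc(self, bw) -> float:
        try:
            beta, s_ii, trS = self._fit_at_train(bw)
        except ValueError:
            return np.inf  # singular local design at this bandwidth: not a candidate
        fitted = np.einsum("ip,ip->i", self._Xd, beta)
        n = len(self._y)
        rss = float(np.sum((self._y - fitted) ** 2))
        if n - 2.0 - trS <= 0:
            return np.inf
        sigma2 = rss / n
        if sigma2 <= 0:
            return -np.inf
        return n * np.log(sigma2) + n * np.log(2 * np.pi) + n * (n + trS) / (n - 2.0 - trS)

    def fit(self, X, y, coords=None):
        """Fit local regressions at every station.

        X : (n, p) covariates (no intercept column; one is added).
        y : (n,) response.
        coords : (n, 2) planar station coordinates, required.
        """
        if coords is None:
            raise ValueError("coords (n, 2) is required")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        coords = np.asarray(coords, dtype=float)
        n, p = X.shape
        if n < p + 2:
            raise ValueError(f"GWR needs at least p+2={p + 2} stations, got {n}")
        self.coords_ = coords
        self._Xd = np.column_stack([np.ones(n), X])
        self._y = y

        if isinstance(self.bandwidth, str) and self.bandwidth == "select":
            if not self.adaptive:
                raise ValueError("bandwidth='select' requires adaptive=True")
            lo, hi = max(p + 3, 8), n
            bw = self._golden_section(lo, hi)
        else:
            bw = self.bandwidth
        self.bandwidth_ = bw

        beta, s_ii, trS = self._fit_at_train(bw)
        self.coef_ = beta
        self.fitted_ = np.einsum("ip,ip->i", self._Xd, beta)
        self.residuals_ = y - self.fitted_
        rss = float(np.sum(self.residuals_**2))
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - rss / tss if tss > 0 else 1.0
        self.rmse_ = float(np.sqrt(rss / n))
        self.tr_S_ = trS
        sigma2 = max(rss / n, 1e-300)
        self.aic_ = n * np.log(sigma2) + n * np.log(2 * np.pi) + n + trS
        denom = n - 2.0 - trS
        self.aicc_ = (
            n * np.log(sigma2) + n * np.log(2 * np.pi) + n * (n + trS) / denom
            if denom > 0
            else np.inf
        )
        return self

    def _golden_section(self, lo: int, hi: int, tol: float = 0.9) -> int:
        """Integer golden-section search of neighbor count minimizing AICc."""
        phi = (math.sqrt(5) - 1) / 2
        a, b = float(lo), float(hi)
        cache: dict[int, float] = {}

        def f(x: float) -> float:
            k = int(round(x))
            if k not in cache:
                cache[k] = self._aicc(k)
            return cache[k]

        c = b - phi * (b - a)
        d = a + phi * (b - a)
        while b - a > tol:
            if f(c) < f(d):
                b, d = d, c
                c = b - phi * (b - a)
            else:
                a, c = c, d
                d = a + phi * (b - a)
        candidates = {int(round(a)), int(round(b)), int(round((a + b) / 2))} | set(cache)
        return min(candidates, key=lambda k: cache.get(k, f(float(k))))

    def predict_coefficients(self, coords_new) -> np.ndarray:
        """Local coefficients (m, p+1) re-fitted at arbitrary target locations."""
        coords_new = np.asarray(coords_new, dtype=float)
        d = cdist(coords_new, self.coords_)
        W = self._weights(d, self.coords_, self.bandwidth_)
        return self._local_fit(self._Xd, self._y, W)

    def predict(self, X, coords=None) -> np.ndarray:
        if coords is None:
            raise ValueError("coords (m, 2) is required")
        beta = self.predict_coefficients(coords)
        Xd = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        return np.einsum("ip,ip->i", Xd, beta)


@dataclass
class GWRModelHour:
    day: int
    hour: int
    model: GWRegressor
    r2: float
    aic: float
    aicc: float
    rmse: float
    residuals: np.ndarray
    station_coords: np.ndarray
    n_stations: int


def fit_gwr_hour(
    rows: pd.DataFrame, kernel: str = "bisquare", bandwidth="select",
    adaptive: bool = True, day: int = 0, hour: int = 0,
) -> GWRModelHour:
    """Fit one hour's GWR of PM2.5 on (visibility, wind_speed, temperature).

    ``rows``: one row per pollution station with columns pm, visibility,
    wind_speed, temperature, x, y.
    """
    needed = ["pm", "visibility", "wind_speed", "temperature", "x", "y"]
    missing = [c for c in needed if c not in rows.columns]
    if missing:
        raise ValueError(f"missing columns {missing}")
    X = rows[list(MET_VARIABLES)].to_numpy()
    y = rows["pm"].to_numpy()
    coords = rows[["x", "y"]].to_numpy()
    gwr = GWRegressor(kernel=kernel, bandwidth=bandwidth, adaptive=adaptive)
    try:
        gwr.fit(X, y, coords=coords)
    except ValueError as exc:
        raise ValueError(f"GWR fit failed for day {day} hour {hour}: {exc}") from exc
    return GWRModelHour(
        day=day, hour=hour, model=gwr, r2=gwr.r2_, aic=gwr.aic_, aicc=gwr.aicc_,
        rmse=gwr.rmse_, residuals=gwr.residuals_.copy(), station_coords=coords,
        n_stations=len(rows),
    )


def predict_surface(
    model: GWRModelHour, met_surfaces: dict[str, np.ndarray], grid: Grid1km
) -> tuple[np.ndarray, int]:
    """Hourly concentration at every cell: local coefficients x kriged covariates.

    Negative predictions are floored at 0 (concentrations are physical);
    returns (values, n_floored).
    """
    for var in MET_VARIABLES:
        if var not in met_surfaces:
            raise ValueError(f"missing covariate surface {var!r}")
    centers = grid.cell_centers()
    Xc = np.column_stack([met_surfaces[v] for v in MET_VARIABLES])
    vals = model.model.predict(Xc, coords=centers)
    n_floored = int((vals < 0).sum())
    return np.maximum(vals, 0.0), n_floored


@dataclass
class PollutionSurface:
    """Hour-indexed gridded concentration field (ug/m3 per 1-km cell)."""

    grid: Grid1km
    data: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)  # (day,hour)->flat
    floored: dict[tuple[int, int], int] = field(default_factory=dict)

    def value_at(self, day: int, hour: int, x: float, y: float) -> tuple[float, bool]:
        if (day, hour) not in self.data:
            raise KeyError(f"no surface for day {day} hour {hour}")
        row, col, clamped = self.grid.locate(x, y)
        return float(self.data[(day, hour)][self.grid.cell_id(row, col)]), clamped

    def hours(self) -> list[tuple[int, int]]:
        return sorted(self.data)

    def to_long_frame(self) -> pd.DataFrame:
        centers = self.grid.cell_centers()
        frames = []
        for (day, hour), vals in sorted(self.data.items()):
            rows, cols = np.divmod(np.arange(self.grid.n_cells), self.grid.n_cols)
            frames.append(pd.DataFrame({
                "day": day, "hour": hour, "row": rows, "col": cols,
                "x": centers[:, 0], "y": centers[:, 1], "value": vals,
            }))
        return pd.concat(frames, ignore_index=True)


def fit_all_hours(
    pm_obs: pd.DataFrame,
    met_obs: pd.DataFrame,
    grid: Grid1km,
    kernel: str = "bisquare",
    bandwidth="select",
    adaptive: bool = True,
    variogram_model: str = "exponential",
    nugget: float = 0.0,
    radius_m: float = 1000.0,
    allow_missing: bool = False,
) -> tuple[PollutionSurface, pd.DataFrame]:
    """Loop krige -> attach -> GWR -> predict over every (day, hour).

    pm_obs: station_id, day, hour, x, y, pm
    met_obs: station_id, day, hour, x, y, visibility, wind_speed, temperature

    Returns the full PollutionSurface and a diagnostics table with per-hour
    R2, AIC, AICc, RMSE, bandwidth and a trailing mean-summary row.
    """
    surface = PollutionSurface(grid=grid)
    diag_rows = []
    hours = sorted(set(map(tuple, met_obs[["day", "hour"]].drop_duplicates().to_numpy())))
    for day, hour in hours:
        pm_h = pm_obs[(pm_obs["day"] == day) & (pm_obs["hour"] == hour)]
        met_h = met_obs[(met_obs["day"] == day) & (met_obs["hour"] == hour)]
        if pm_h.empty:
            if allow_missing:
                continue
            raise ValueError(f"no pollution observations for day {day} hour {hour}")
        met_surfaces = {}
        for var in MET_VARIABLES:
            obs_v = met_h[["x", "y", var]].rename(columns={var: "value"})
            met_surfaces[var] = krige_meteorology(
                obs_v, grid, variogram_model=variogram_model, nugget=nugget
            )
        station_coords = pm_h[["x", "y"]].to_numpy()
        cov, n_fallback = attach_covariates(station_coords, grid, met_surfaces, radius_m)
        rows = pd.concat([pm_h[["pm", "x", "y"]].reset_index(drop=True), cov], axis=1)
        model = fit_gwr_hour(rows, kernel=kernel, bandwidth=bandwidth, adaptive=adaptive,
                             day=int(day), hour=int(hour))
        vals, n_floored = predict_surface(model, met_surfaces, grid)
        surface.data[(int(day), int(hour))] = vals
        surface.floored[(int(day), int(hour))] = n_floored
        diag_rows.append({
            "day": int(day), "hour": int(hour), "r2": model.r2, "aic": model.aic,
            "aicc": model.aicc, "rmse": model.rmse, "bandwidth": model.model.bandwidth_,
            "n_stations": model.n_stations, "n_floored": n_floored,
            "n_cov_fallback": n_fallback,
        })
    diag = pd.DataFrame(diag_rows)
    if not diag.empty:
        summary = diag[["r2", "aic", "aicc", "rmse"]].mean().to_dict()
        summary.update({"day": -1, "hour": -1, "bandwidth": np.nan,
                        "n_stations": np.nan, "n_floored": np.nan, "n_cov_fallback": np.nan})
        diag = pd.concat([diag, pd.DataFrame([summary])], ignore_index=True)
    return surface, diag


def read_pollution_csv(path) -> pd.DataFrame:
    """Station PM2.5 CSV: station_id,day,time,x,y,pm25 (time HH:MM) -> tidy frame."""
    df = pd.read_csv(path)
    df["hour"] = df["time"].astype(str).str.split(":").str[0].astype(int)
    return df.rename(columns={"pm25": "pm"})[["station_id", "day", "hour", "x", "y", "pm"]]


def read_meteorology_csv(path) -> pd.DataFrame:
    """Station meteorology CSV: station_id,day,time,x,y,wind_speed,visibility,temperature."""
    df = pd.read_csv(path)
    df["hour"] = df["time"].astype(str).str.split(":").str[0].astype(int)
    return df[["station_id", "day", "hour", "x", "y", "visibility", "wind_speed", "temperature"]]
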