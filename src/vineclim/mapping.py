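"""Per-day spatial temperature models and their phenological coupling.

Each day and variable gets its own Gaussian-kernel support-vector regression
of the sensor values on six terrain covariates (elevation, slope %,
northness, eastness, x, y), standardized with the training sensors'
statistics.  Daily predicted grids are aggregated into seasonal means and
pixel-wise Winkler sums, and coupled pixel-by-pixel to the GFV thermal-time
rule (after bias correction) to map stage dates.  Gap-filled sensor values
are never used for training.

Kernel hyperparameters default to C = 10, epsilon = 0.1 degC and a kernel
width set by the median pairwise distance heuristic in standardized
covariate space; all are overridable and a leave-one-sensor-out CV helper
exists for tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .bias import CorrectionModel
from .bioclim import WINKLER_BASE_C
from .errors import (ConfigurationError, InsufficientDataError,
                     InvalidParameterError, OutOfBoundsError)
from .gfv import GFVParams, STAGES
from .grids import COVARIATE_NAMES, CovariateGrid

MIN_TRAIN_SENSORS = 10


def extract_at_points(grid: CovariateGrid, meta: pd.DataFrame) -> pd.DataFrame:
    """Nearest-pixel covariate vectors at each sensor location.

    Uses (x, y) when present (pixel-boundary ties break toward the lower
    index), else the stored (row, col).  Returns sensor_id, row, col and the
    six covariates; raises naming the sensor if one falls outside the grid.
    """
    rows, cols = [], []
    for r in meta.itertuples(index=False):
        if hasattr(r, "x") and hasattr(r, "y") and np.isfinite(r.x) and np.isfinite(r.y):
            try:
                row, col = grid.to_index(r.x, r.y)
            except OutOfBoundsError as e:
                raise OutOfBoundsError(f"sensor {r.sensor_id} outside grid") from e
        else:
            row, col = int(r.row), int(r.col)
            if not (0 <= row < grid.ny and 0 <= col < grid.nx):
                raise OutOfBoundsError(f"sensor {r.sensor_id} outside grid")
        rows.append(row)
        cols.append(col)
    out = pd.DataFrame({"sensor_id": meta["sensor_id"].to_numpy(),
                        "row": rows, "col": cols})
    cov = grid.covariates_at(np.array(rows), np.array(cols))
    for j, name in enumerate(COVARIATE_NAMES):
        out[name] = cov[:, j]
    return out


@dataclass
class DailyModel:
    """One fitted day/variable SVR plus its training diagnostics."""

    variable: str
    date: pd.Timestamp
    scaler: StandardScaler
    svr: SVR
    n_train: int
    train_residual_sd: float
    epsilon: float
    feature_names: tuple[str, ...] = COVARIATE_NAMES
    meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svr.predict(self.scaler.transform(X))


def _median_heuristic_gamma(Xs: np.ndarray) -> float:
    """RBF gamma from the median pairwise distance in standardized space."""
    d = np.sqrt(((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(-1))
    med = np.median(d[np.triu_indices(len(Xs), k=1)])
    if not np.isfinite(med) or med <= 0:
        return 1.0 / Xs.shape[1]
    return 1.0 / (2 * med ** 2)


def fit_daily_model(values: pd.Series, covariates: pd.DataFrame,
                    variable: str = "", date: pd.Timestamp | None = None,
                    C: float = 10.0, epsilon: float = 0.1,
                    gamma: float | str = "median",
                    min_sensors: int = MIN_TRAIN_SENSORS) -> DailyModel:
    """Fit one day's SVR of sensor values on the six covariates.

    ``values`` is indexed by sensor_id; ``covariates`` must carry the same
    sensors (from :func:`extract_at_points`).  Requires at least 10 sensors
    with finite values.
    """
    cov = covariates.set_index("sensor_id").loc[values.index, list(COVARIATE_NAMES)]
    keep = values.notna().to_numpy()
    if keep.sum() < min_sensors:
        raise InsufficientDataError(
            f"{variable} {date}: {int(keep.sum())} sensors, need >= {min_sensors}")
    X = cov.to_numpy()[keep]
    y = values.to_numpy(dtype=float)[keep]
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    g = _median_heuristic_gamma(Xs) if gamma == "median" else float(gamma)
    svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=g).fit(Xs, y)
    resid = y - svr.predict(Xs)
    return DailyModel(variable=variable, date=date, scaler=scaler, svr=svr,
                      n_train=int(keep.sum()),
                      train_residual_sd=float(resid.std()), epsilon=epsilon,
                      meta={"C": C, "gamma": g})


def loso_cv_rmse(values: pd.Series, covariates: pd.DataFrame, **svr_kwargs) -> float:
    """Leave-one-sensor-out CV RMSE for one day (hyperparameter tuning aid)."""
    errs = []
    sensors = values.dropna().index
    for s in sensors:
        train = values.drop(s)
        model = fit_daily_model(train, covariates, **svr_kwargs)
        xrow = covariates.set_index("sensor_id").loc[[s], list(COVARIATE_NAMES)]
        errs.append(float(values[s] - model.predict(xrow.to_numpy())[0]))
    return float(np.sqrt(np.mean(np.square(errs))))


def predict_grid(model: DailyModel, grid: CovariateGrid) -> np.ndarray:
    """Predict the model over every pixel; full-coverage (ny, nx) array."""
    if tuple(model.feature_names) != COVARIATE_NAMES:
        raise ConfigurationError("model covariate schema does not match the grid")
    return model.predict(grid.covariate_matrix()).reshape(grid.shape)


def fit_predict_daily_maps(daily: pd.DataFrame, covariates: pd.DataFrame,
                           grid: CovariateGrid,
                           dates: pd.DatetimeIndex | None = None,
                           variables: tuple[str, ...] = ("tn", "tx"),
                           exclude_filled: bool = True,
                           **svr_kwargs) -> tuple[dict, list]:
    """Fit per-day models and predict grids for a clean daily long table.

    Returns ``(maps, skipped)`` where ``maps[(variable, date)]`` is a (ny,
    nx) array and ``skipped`` logs (variable, date, reason) for days with too
    few training sensors.  Filled values are excluded from training.
    """
    ok = daily[(daily["qc"] == "pass") & daily["value"].notna()]
    if exclude_filled:
        ok = ok[ok["source"] != "filled"]
    if dates is not None:
        ok = ok[ok["date"].isin(dates)]
    maps: dict[tuple[str, pd.Timestamp], np.ndarray] = {}
    skipped: list[tuple[str, pd.Timestamp, str]] = []
    for (var, date), g in ok.groupby(["variable", "date"]):
        if var not in variables:
            continue
        values = g.groupby("sensor_id")["value"].mean()
        try:
            model = fit_daily_model(values, covariates, variable=var, date=date,
                                    **svr_kwargs)
        except InsufficientDataError as e:
            skipped.append((var, date, str(e)))
            continue
        maps[(var, date)] = predict_grid(model, grid)
    return maps, skipped


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_maps(maps: dict, window: pd.DatetimeIndex, op: str = "mean",
                   variable: str = "tn", max_missing_frac: float = 0.05
                   ) -> np.ndarray:
    """Pixel-wise aggregate of daily maps over a date window.

    ``op = "mean"`` averages one variable's maps; ``op = "winkler_sum"``
    forms Tm = (tn_map + tx_map)/2 per day and accumulates degree-days above
    10 degC (the pixel-wise CWI).  Missing days beyond ``max_missing_frac``
    raise, listing the missing dates.
    """
    if op not in ("mean", "winkler_sum"):
        raise InvalidParameterError(f"unknown op '{op}'")
    need = (("tn", "tx") if op == "winkler_sum" else (variable,))
    missing = [d for d in window if any((v, d) not in maps for v in need)]
    if len(missing) > max_missing_frac * len(window):
        shown = ", ".join(str(d.date()) for d in missing[:10])
        raise InvalidParameterError(
            f"{len(missing)}/{len(window)} days missing from maps: {shown} ...")
    days = [d for d in window if d not in missing]
    if op == "mean":
        return np.mean([maps[(variable, d)] for d in days], axis=0)
    total = None
    for d in days:
        tm = (maps[("tn", d)] + maps[("tx", d)]) / 2
        dd = np.clip(tm - WINKLER_BASE_C, 0.0, None)
        total = dd if total is None else total + dd
    return total


# ---------------------------------------------------------------------------
# phenology maps
# ---------------------------------------------------------------------------

def pheno_map(maps: dict, dates: pd.DatetimeIndex,
              correction: dict[str, CorrectionModel],
              gfv: GFVParams = GFVParams.merlot(),
              max_missing_frac: float = 0.05) -> dict[str, np.ndarray]:
    """Pixel-wise GFV stage dates from one year of daily Tn/Tx maps.

    Daily maps are bias-corrected to station scale, Tm formed, and the
    thermal sum accumulated per pixel from DOY 60.  Returns a float DOY grid
    per stage with NaN where the threshold is never reached.  ``dates`` must
    cover accumulation (Mar-Dec); days missing beyond tolerance raise.
    """
    if correction is None or any(v not in correction for v in ("tn", "tx")):
        raise ConfigurationError("correction models for tn and tx are required")
    missing = [d for d in dates if ("tn", d) not in maps or ("tx", d) not in maps]
    if len(missing) > max_missing_frac * len(dates):
        raise InvalidParameterError(
            f"{len(missing)}/{len(dates)} days missing from daily maps")
    days = pd.DatetimeIndex([d for d in dates if d not in missing])

    shape = next(iter(maps.values())).shape
    tm_stack = np.empty((len(days), shape[0] * shape[1]))
    for i, d in enumerate(days):
        tn = correction["tn"].apply(maps[("tn", d)])
        tx = correction["tx"].apply(maps[("tx", d)])
        tm_stack[i] = ((tn + tx) / 2).ravel()

    doys = days.dayofyear.to_numpy()
    inc = np.clip(tm_stack - gfv.base_C, 0.0, None)
    inc[doys < gfv.start_doy] = 0.0
    cum = np.cumsum(inc, axis=0)

    out = {}
    for stage in STAGES:
        thr = gfv.threshold(stage)
        reached = cum >= thr
        any_hit = reached.any(axis=0)
        first = np.argmax(reached, axis=0)
        doy_map = np.where(any_hit, doys[first], np.nan)
        out[stage] = doy_map.reshape(shape)
    return out


def average_pheno_maps(yearly: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Multi-year mean DOY per stage; NaN where any year is undefined."""
    out = {}
    for stage in STAGES:
        out[stage] = np.mean([y[stage] for y in yearly], axis=0)
    return out


def map_validate(pheno_maps: dict[str, np.ndarray], obs: pd.DataFrame,
                 covariates: pd.DataFrame, year: int,
                 point_rmse: pd.DataFrame | None = None) -> pd.DataFrame:
    """RMSE of pixel-extracted stage dates against observations.

    ``covariates`` provides the sensor -> pixel mapping (row/col from
    :func:`extract_at_points`); ``obs`` has sensor_id, year, stage, doy.
    When a point-prediction validation table is supplied, the accuracy-loss
    statistic (map RMSE minus point RMSE per stage) is attached.
    """
    from .gfv import validate_rmse

    pix = covariates.set_index("sensor_id")
    rows = []
    for stage in STAGES:
        grid_doy = pheno_maps[stage]
        for sensor, r in pix.iterrows():
            v = grid_doy[int(r["row"]), int(r["col"])]
            if np.isfinite(v):
                rows.append((sensor, year, stage, float(v)))
    pred = pd.DataFrame(rows, columns=["sensor_id", "year", "stage", "doy"])
    table = validate_rmse(pred, obs[obs["year"] == year])
    if point_rmse is not None:
        ref = point_rmse.set_index(["year", "stage"])["rmse_days"]
        table["accuracy_loss_days"] = [
            row.rmse_days - ref.get((row.year, row.stage), np.nan)
            for row in table.itertuples()]
    return table


# ---------------------------------------------------------------------------
# per-day driver attribution
# ---------------------------------------------------------------------------

def drivers_ols(values: pd.Series, covariates: pd.DataFrame,
                order: tuple[str, ...] = COVARIATE_NAMES) -> pd.DataFrame:
    """Sequential-sum-of-squares variance shares of one day's sensor values.

    An ordinary least-squares fit on the standardized covariates, entered in
    the fixed documented order; each covariate's share is the incremental
    reduction in residual sum of squares over the total sum of squares, so
    the shares add up to the full-model R^2.  Signed coefficients come from
    the full model.  Raises on rank-deficient designs, listing the columns.
    """
    values = values.dropna()
    if len(values) < MIN_TRAIN_SENSORS:
        raise InsufficientDataError(f"{len(values)} sensors, need >= {MIN_TRAIN_SENSORS}")
    cov = covariates.set_index("sensor_id").loc[values.index, list(order)]
    X = cov.to_numpy(dtype=float)
    sd = X.std(axis=0)
    bad = [order[j] for j in range(len(order)) if sd[j] == 0]
    X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    y = values.to_numpy(dtype=float)
    n = len(y)

    full = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        # identify which columns are collinear with the ones before them
        for j in range(1, full.shape[1]):
            if np.linalg.matrix_rank(full[:, :j + 1]) < j + 1:
                bad.append(order[j - 1])
        raise InvalidParameterError(f"rank-deficient design, collinear: {sorted(set(bad))}")

    tss = float(((y - y.mean()) ** 2).sum())
    rss_prev = tss
    shares = []
    for j in range(1, full.shape[1]):
        beta, res, *_ = np.linalg.lstsq(full[:, :j + 1], y, rcond=None)
        rss = float(res[0]) if len(res) else float(
            ((y - full[:, :j + 1] @ beta) ** 2).sum())
        shares.append((rss_prev - rss) / tss if tss > 0 else 0.0)
        rss_prev = rss
    beta_full, *_ = np.linalg.lstsq(full, y, rcond=None)

    out = pd.DataFrame({"covariate": list(order),
                        "coefficient": beta_full[1:],
                        "variance_share": shares})
    out.attrs["r2"] = float(sum(shares))
    return out
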