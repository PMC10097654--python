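"""Climatological baseline, degree-heating-week accumulation and DHW-grid
alignment of fragment health surveys.

Degree heating weeks (DHW) accumulate daily temperature anomalies exceeding
1 degC above the adjusted climatological baseline (MMM_adj) over a trailing
84-day (12-week) window, divided by 7 to express the result in degC-weeks.
The anomaly rule is strict (``> 1``) by default, matching the experiment's
definition; the operational ``>= 1`` variant is available via
``hotspot_rule=">=1"``.

Because tanks accumulate heat at slightly different rates, fragment health
is compared on a fixed grid of DHW levels shared across tanks rather than
on calendar dates: for each tank and grid level the first date at which the
tank reached that DHW is found, and each fragment's most recent surveyed
category at or before that date is carried forward (step interpolation on
the DHW axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CATEGORY_WEIGHT, HEALTH_CATEGORIES
from .errors import DegenerateFitError, GapError, InsufficientDataError

DHW_WINDOW_DAYS = 84


@dataclass(frozen=True)
class ClimatologyBaseline:
    """Satellite MMM calibrated to in-situ conditions via a daily OLS fit."""

    mmm: float
    intercept: float
    slope: float
    mmm_adj: float


def fit_baseline_adjustment(satellite_daily: pd.Series, insitu_daily: pd.Series,
                            mmm: float) -> ClimatologyBaseline:
    """Regress daily in-situ temperature on satellite SST and adjust the MMM.

    Both series must be indexed by date; only overlapping dates are used and
    at least 30 are required. ``mmm_adj = intercept + slope * mmm``.
    """
    joined = pd.concat({"sat": satellite_daily, "situ": insitu_daily},
                       axis=1, join="inner").dropna()
    if len(joined) < 30:
        raise InsufficientDataError(
            f"only {len(joined)} overlapping days; need >= 30")
    x = joined["sat"].to_numpy(float)
    y = joined["situ"].to_numpy(float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("satellite series has zero variance")
    res = stats.linregress(x, y)
    mmm_adj = res.intercept + res.slope * mmm
    return ClimatologyBaseline(mmm=float(mmm), intercept=float(res.intercept),
                               slope=float(res.slope), mmm_adj=float(mmm_adj))


def _daily_means(tank: pd.DataFrame) -> pd.Series:
    """Calendar-day means from intra-day samples; partial edge days dropped."""
    ts = tank["timestamp"]
    gaps = ts.diff()
    too_long = gaps > pd.Timedelta(hours=24)
    if too_long.any():
        raise GapError(tank["tank_id"].iloc[0],
                       ts[too_long].dt.date.unique())
    by_day = tank.groupby(ts.dt.normalize())["temp_c"]
    means, counts = by_day.mean(), by_day.size()
    if len(counts) > 2:
        full = counts.iloc[1:-1].max()
        keep = means.index[(counts >= full) | ~means.index.isin(
            [means.index[0], means.index[-1]])]
        means = means.loc[keep]
    return means


def compute_dhw(temperature_log: pd.DataFrame, baseline: ClimatologyBaseline,
                hotspot_rule: str = ">1") -> pd.DataFrame:
    """Daily hotspot and DHW trajectory for every tank in a temperature log.

    Returns a long table with columns ``tank_id, date, daily_mean_c,
    hotspot_c, dhw_c_weeks``. The hotspot is the full anomaly
    ``daily_mean - mmm_adj`` retained only when it exceeds 1 degC (strict by
    default); DHW is the trailing 84-day sum of hotspots divided by 7.
    """
    if hotspot_rule not in {">1", ">=1"}:
        raise ValueError(f"unknown hotspot rule {hotspot_rule!r}")
    out = []
    for tank, grp in temperature_log.groupby("tank_id", sort=True):
        means = _daily_means(grp)
        anom = means - baseline.mmm_adj
        if hotspot_rule == ">1":
            hotspot = anom.where(anom > 1.0, 0.0)
        else:
            hotspot = anom.where(anom >= 1.0, 0.0)
        dhw = hotspot.rolling(window=DHW_WINDOW_DAYS, min_periods=1).sum() / 7.0
        out.append(pd.DataFrame({
            "tank_id": tank,
            "date": means.index,
            "daily_mean_c": means.to_numpy(),
            "hotspot_c": hotspot.to_numpy(),
            "dhw_c_weeks": dhw.to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class DhwGrid:
    """Evenly spaced DHW levels shared across tanks."""

    levels: np.ndarray = field(repr=False)

    def __post_init__(self):
        lv = np.asarray(self.levels, float)
        if lv.ndim != 1 or len(lv) < 2:
            raise ValueError("grid needs >= 2 levels")
        d = np.diff(lv)
        if not (d > 0).all() or not np.allclose(d, d[0]):
            raise ValueError("grid levels must be strictly increasing and evenly spaced")
        object.__setattr__(self, "levels", lv)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def from_stress(cls, stress: pd.DataFrame, n_levels: int = 21,
                    heat_tanks: list[str] | None = None) -> "DhwGrid":
        """Grid from 0 to the minimum across heat tanks of the final DHW.

        Heat tanks default to those whose final DHW exceeds 0.
        """
        finals = stress.sort_values("date").groupby("tank_id")["dhw_c_weeks"].last()
        if heat_tanks is None:
            finals = finals[finals > 0]
        else:
            finals = finals.loc[heat_tanks]
        if len(finals) == 0:
            raise ValueError("no heat tanks with nonzero final DHW")
        return cls(np.linspace(0.0, float(finals.min()), n_levels))


def _dhw_curve(tank_stress: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear DHW accumulation curve for one tank.

    The daily DHW value describes heat accumulated through the end of that
    calendar day, so it is stamped at day end and joined linearly; a zero
    anchor one day before the first value lets level 0 resolve to the
    series start.
    """
    s = tank_stress.sort_values("date")
    # running max guards against any non-monotone stretch once the window rolls
    vals = np.maximum.accumulate(s["dhw_c_weeks"].to_numpy(float))
    ends = s["date"].to_numpy("datetime64[ns]") + np.timedelta64(1, "D")
    times = np.concatenate([[ends[0] - np.timedelta64(2, "D")], ends])
    vals = np.concatenate([[0.0], vals])
    return times, vals


def _reach_times(times: np.ndarray, vals: np.ndarray,
                 levels: np.ndarray) -> np.ndarray | None:
    """First instant the linearly interpolated DHW curve reaches each level."""
    out = np.empty(len(levels), dtype="datetime64[ns]")
    for i, x in enumerate(levels):
        idx = np.flatnonzero(vals >= x - 1e-12)
        if len(idx) == 0:
            return None
        k = idx[0]
        if k == 0 or vals[k] <= vals[k - 1]:
            out[i] = times[k]
        else:
            frac = (x - vals[k - 1]) / (vals[k] - vals[k - 1])
            frac = min(max(frac, 0.0), 1.0)
            step = (times[k] - times[k - 1]) / np.timedelta64(1, "s")
            out[i] = times[k - 1] + np.timedelta64(int(round(frac * step)), "s")
    return out


def interpolate_health_at_grid(records: pd.DataFrame, stress: pd.DataFrame,
                               grid: DhwGrid,
                               method: str = "step") -> pd.DataFrame:
    """Align fragment health onto the fixed DHW grid.

    Parameters
    ----------
    records
        Health records of heat-tank fragments (``health`` schema).
    stress
        Per-tank daily DHW from :func:`compute_dhw`.
    grid
        Shared :class:`DhwGrid`; every fragment's tank must reach its
        maximum level.
    method
        ``"step"`` (default) carries the most recent surveyed ordinal
        category forward; ``"linear"`` linearly interpolates the fragment's
        numeric ordinal weight between surveys on the DHW axis and reports
        it in a ``score`` column alongside the rounded category.

    Returns a long table ``colony_id, fragment_id, tank_id, dhw_level,
    category`` (plus ``score`` for the linear method).
    """
    if method not in {"step", "linear"}:
        raise ValueError(f"unknown interpolation method {method!r}")
    rows = []
    for tank, frag_grp in records.groupby("tank_id", sort=True):
        tank_stress = stress[stress["tank_id"] == tank]
        if tank_stress.empty:
            raise InsufficientDataError(f"no heat-stress series for tank {tank}")
        times, vals = _dhw_curve(tank_stress)
        reach = _reach_times(times, vals, grid.levels)
        if reach is None:
            raise InsufficientDataError(
                f"tank {tank} never reaches the grid maximum "
                f"({grid.levels[-1]:.2f} degC-weeks)")
        for (colony, fragment), surveys in frag_grp.groupby(
                ["colony_id", "fragment_id"], sort=True):
            surveys = surveys.sort_values("survey_time")
            stimes = surveys["survey_time"].to_numpy("datetime64[ns]")
            cats = surveys["category"].to_numpy()
            weights = np.array([CATEGORY_WEIGHT[c] for c in cats], float)
            if method == "step":
                # index of last survey at or before each reach time
                idx = np.searchsorted(stimes, reach, side="right") - 1
                idx = np.clip(idx, 0, len(stimes) - 1)
                for x, i in zip(grid.levels, idx):
                    rows.append((colony, fragment, tank, float(x), cats[i]))
            else:
                survey_dhw = np.interp(
                    stimes.astype("int64"), times.astype("int64"), vals)
                score = np.interp(grid.levels, survey_dhw, weights)
                for x, sc in zip(grid.levels, score):
                    cat = HEALTH_CATEGORIES[int(round(sc))]
                    rows.append((colony, fragment, tank, float(x), cat, float(sc)))
    cols = ["colony_id", "fragment_id", "tank_id", "dhw_level", "category"]
    if method == "linear":
        cols.append("score")
    return pd.DataFrame(rows, columns=cols)
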