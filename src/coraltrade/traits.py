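"""Size-corrected colony growth and whole-colony fecundity.

Raw areal/volumetric growth scales with colony size (for identical linear
extension a large hemisphere adds more area per year than a small one), so
growth rates are multiplied by a dimensionless adjustment factor (AF) — the
ratio of the population-mean initial size to the colony's initial size, one
dimension below the growth metric::

    areal_AF_i      = mean(D) / D_i
    volumetric_AF_i = mean(A) / A_i,   A_i = D_i * (D_i / 2)

Whole-colony fecundity scales dissection counts up to the colony::

    EV  = 4/3 * pi * (GMD / 2)^3          [mm^3, GMD in mm]
    TEP = EC * PD * LiveSA                [eggs per colony]
    TEV = EV * TEP / 1000                 [cm^3 per colony]

where EC is mean eggs per dissected polyp, PD polyp density per cm^2,
LiveSA live surface area in cm^2 and GMD the geometric mean of an egg's
two measured perpendicular diameters.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import decode_egg_diameters
from .errors import DegenerateFitError, InsufficientDataError, ValidationError

DAYS_PER_YEAR = 365.25
MIN_INTERVAL_DAYS = 30

# log-log regression of in-situ maximum diameter on initial 3D-model surface
# area, used only for colonies whose diameter was never taped in the field
D_FROM_SA_INTERCEPT = -0.738
D_FROM_SA_SLOPE = 0.537


def annual_growth(surveys: pd.DataFrame) -> pd.DataFrame:
    """Raw annual growth rates from repeated colony size surveys.

    Per colony and consecutive survey pair, the rate is the size change
    divided by the interval in years, for live surface area and volume;
    with two usable intervals the arithmetic mean of both is taken.
    Shrinkage (negative rates) is preserved. Intervals of <= 30 days are
    rejected; colonies with fewer than two surveys are omitted with a
    warning.

    Returns ``colony_id, raw_livesa_growth, raw_vol_growth, n_intervals``.
    """
    rows, skipped = [], []
    for colony, grp in surveys.sort_values("survey_date").groupby(
            "colony_id", sort=True):
        if len(grp) < 2:
            skipped.append(colony)
            continue
        dates = grp["survey_date"].to_numpy()
        livesa = grp["livesa_cm2"].to_numpy(float)
        vol = grp["volume_cm3"].to_numpy(float)
        rates_a, rates_v = [], []
        for i in range(len(grp) - 1):
            dt_days = (dates[i + 1] - dates[i]) / np.timedelta64(1, "D")
            if dt_days <= MIN_INTERVAL_DAYS:
                continue
            dt_years = dt_days / DAYS_PER_YEAR
            rates_a.append((livesa[i + 1] - livesa[i]) / dt_years)
            rates_v.append((vol[i + 1] - vol[i]) / dt_years)
        if not rates_a:
            skipped.append(colony)
            continue
        rows.append((colony, float(np.mean(rates_a)), float(np.mean(rates_v)),
                     len(rates_a)))
    if skipped:
        warnings.warn(f"colonies without two usable size surveys omitted: "
                      f"{len(skipped)}", stacklevel=2)
    return pd.DataFrame(rows, columns=["colony_id", "raw_livesa_growth",
                                       "raw_vol_growth", "n_intervals"])


def predict_diameter_from_sa(initial_sa: float, log_base: str = "e") -> float:
    """Predict maximum diameter (cm) from initial total surface area (cm^2).

    Uses the printed log-log calibration ``log(D) = -0.738 + 0.537 *
    log(SA)``; natural logs by default, ``log_base="10"`` for the base-10
    reading.
    """
    if initial_sa <= 0:
        raise ValidationError(f"initial SA must be > 0, got {initial_sa}")
    if log_base == "e":
        return math.exp(D_FROM_SA_INTERCEPT + D_FROM_SA_SLOPE * math.log(initial_sa))
    if log_base == "10":
        return 10 ** (D_FROM_SA_INTERCEPT + D_FROM_SA_SLOPE * math.log10(initial_sa))
    raise ValueError(f"log_base must be 'e' or '10', got {log_base!r}")


def initial_sizes(surveys: pd.DataFrame) -> pd.DataFrame:
    """First-survey diameter/SA/LiveSA per colony, predicting missing D.

    Colonies lacking a taped diameter get one from
    :func:`predict_diameter_from_sa` on their initial total SA; the
    ``diameter_predicted`` flag records which.
    """
    first = (surveys.sort_values("survey_date")
             .groupby("colony_id", sort=True).first().reset_index())
    predicted = first["diameter_cm"].isna()
    first.loc[predicted, "diameter_cm"] = [
        predict_diameter_from_sa(sa) for sa in first.loc[predicted, "sa_cm2"]]
    first["diameter_predicted"] = predicted
    return first[["colony_id", "diameter_cm", "sa_cm2", "livesa_cm2",
                  "partial_mortality", "diameter_predicted"]]


def adjustment_factors(initial: pd.DataFrame) -> pd.DataFrame:
    """Per-colony areal and volumetric size-adjustment factors.

    ``initial`` needs ``colony_id`` and ``diameter_cm`` (every colony must
    have one, measured or predicted). The proxy area for the volumetric AF
    is ``A = D * (D / 2)``, diameter times an assumed height of half the
    diameter.
    """
    d = initial["diameter_cm"].to_numpy(float)
    if (d <= 0).any() or np.isnan(d).any():
        raise ValidationError("all colonies need a positive diameter for AFs")
    a = d * d / 2.0
    return pd.DataFrame({
        "colony_id": initial["colony_id"].to_numpy(),
        "areal_af": d.mean() / d,
        "volumetric_af": a.mean() / a,
    })


def corrected_growth(surveys: pd.DataFrame) -> pd.DataFrame:
    """Raw and AF-corrected growth for every colony with >= 2 surveys."""
    raw = annual_growth(surveys)
    init = initial_sizes(surveys[surveys["colony_id"].isin(raw["colony_id"])])
    afs = adjustment_factors(init)
    out = raw.merge(afs, on="colony_id")
    out["corrected_livesa_growth"] = out["raw_livesa_growth"] * out["areal_af"]
    out["corrected_vol_growth"] = out["raw_vol_growth"] * out["volumetric_af"]
    return out


def egg_volume(gmd_mm: float) -> float:
    """Spherical egg volume (mm^3) from geometric mean diameter (mm)."""
    if gmd_mm < 0:
        raise ValidationError(f"GMD must be >= 0, got {gmd_mm}")
    return (4.0 / 3.0) * math.pi * (gmd_mm / 2.0) ** 3


def colony_fecundity(dissections: pd.DataFrame, polyp_density: float,
                     livesa: float) -> dict:
    """Whole-colony fecundity from one colony's polyp dissections.

    ``dissections`` holds that colony's dissection records (nominally 20
    polyps from two fragments). EC is the mean egg count over polyps, the
    per-egg GMD the geometric mean of its two axis measurements, EV the
    mean spherical volume over all eggs. If no polyp contains eggs, EV and
    GMD are undefined (NaN) and TEP is 0.
    """
    if len(dissections) == 0:
        raise InsufficientDataError("no dissected polyps")
    if polyp_density <= 0 or livesa <= 0:
        raise ValidationError("polyp density and LiveSA must be > 0")
    ec_mean = float(dissections["egg_count"].mean())
    gmds = []
    for cell in dissections["egg_diameters_mm"]:
        for d1, d2 in decode_egg_diameters(cell):
            gmds.append(math.sqrt(d1 * d2))
    if gmds:
        gmd_mean = float(np.mean(gmds))
        ev_mean = float(np.mean([egg_volume(g) for g in gmds]))
    else:
        gmd_mean = ev_mean = float("nan")
    tep = ec_mean * polyp_density * livesa
    tev = (ev_mean / 1000.0) * tep if gmds else 0.0  # mm^3 -> cm^3
    return {"ec_mean": ec_mean, "gmd_mean": gmd_mean, "ev_mean": ev_mean,
            "pd": float(polyp_density), "livesa": float(livesa),
            "tep": float(tep), "tev": float(tev)}


def fecundity_table(dissections: pd.DataFrame, densities: pd.DataFrame,
                    initial: pd.DataFrame) -> pd.DataFrame:
    """Per-colony :func:`colony_fecundity` for every colony with all inputs."""
    dens = densities.set_index("colony_id")["polyps_per_cm2"]
    live = initial.set_index("colony_id")["livesa_cm2"]
    rows = []
    for colony, grp in dissections.groupby("colony_id", sort=True):
        if colony not in dens.index or colony not in live.index:
            continue
        rec = colony_fecundity(grp, float(dens[colony]), float(live[colony]))
        rows.append({"colony_id": colony, **rec})
    return pd.DataFrame(rows)


def size_dependence_test(values: pd.Series, sizes: pd.Series) -> dict:
    """OLS of a (corrected) growth metric on initial colony size.

    Returns slope, its standard error and the two-sided p-value; used to
    check that the AF correction removed the size bias.
    """
    df = pd.concat({"y": values, "x": sizes}, axis=1, join="inner").dropna()
    if len(df) < 10:
        raise InsufficientDataError(f"need >= 10 colonies, got {len(df)}")
    if df["x"].nunique() < 2 or np.ptp(df["x"].to_numpy()) == 0:
        raise DegenerateFitError("initial sizes have zero variance")
    fit = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
    return {"slope": float(fit.params["x"]), "se": float(fit.bse["x"]),
            "p_value": float(fit.pvalues["x"]), "n": int(len(df))}
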