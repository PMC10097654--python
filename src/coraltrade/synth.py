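"""Synthetic study-data generator.

Emulates a complete colony trade-off study: tank temperature logs from a
marine-heatwave emulation profile (ambient acclimatisation, a ~0.8 degC
per week ramp to +3.5 degC above baseline held to day 35, diel cycle and
logger noise), repeated 3D-model colony size surveys, polyp dissections,
polyp densities, ITS2 symbiont profiles, and ordinal fragment health
surveys driven by DHW-threshold crossings.

The generator embodies the energetic-continuum hypothesis: a latent
per-colony energy budget couples heat tolerance (critical DHW) to growth
and fecundity with configurable correlations, so the downstream inference
can be checked against known ground truth.

Calibration note: a fragment enters ordinal category ``k+1`` when its tank
DHW crosses ``h_f + (k - 1/2) * delta`` where ``h_f`` is the colony's
latent critical DHW plus fragment-level noise and ``delta`` the category
spacing. Centering the first transition half a spacing *before* ``h_f``
makes the colony's expected BSI equal exactly 0.75 (the onset definition)
when tank DHW reaches the colony's latent critical DHW, by symmetry of the
fragment noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import thermal
from .data_io import HEALTH_CATEGORIES, encode_egg_diameters
from .errors import ConfigError, InsufficientDataError

HEAT_TANKS = ("T2", "T3", "T5", "T6")
CONTROL_TANKS = ("T1", "T4")
MODAL_PROFILE = "C40-C3-C115-C40h"
MINOR_PROFILES = ("C40-C3-C40h", "C3-C40-C3b", "C40-C115-C3")
MIXED_SECONDARIES = ("C15h-C15hf-C15hg", "D1/D4-D4c-D1c-D1h-D2")

#: survey-day offsets within the 35-day assay (16 timepoints, 2-3 d apart)
SURVEY_DAY_OFFSETS = (0, 3, 6, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27, 29, 32, 35)

_SUBSTREAMS = ("temperature", "calibration", "population", "health")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults match the real design."""

    n_colonies: int = 66
    n_heat_fragments: int = 4
    n_control_fragments: int = 2
    mean_diameter_cm: float = 24.0
    sd_diameter_cm: float = 8.0
    mean_eggs_per_polyp: float = 4.9
    sd_eggs_per_polyp: float = 1.4
    sd_eggs_between_colonies: float = 1.0
    mean_egg_volume_mm3: float = 0.11
    tolerance_growth_coupling: float = 0.35
    tolerance_fecundity_coupling: float = 0.0

    # heatwave profile
    baseline_c: float = 29.5           # adjusted climatological baseline
    acclim_days: int = 7
    assay_days: int = 35
    ramp_rate_c_per_week: float = 0.8
    peak_anomaly_c: float = 3.5
    diel_amplitude_c: float = 0.3
    noise_sd_c: float = 0.1
    n_surveys: int = 16

    # latent tolerance distribution and bleaching mechanics
    mean_critical_dhw: float = 6.7
    sd_critical_dhw: float = 1.1
    fragment_threshold_sd: float = 0.4
    category_spacing_dhw: float = 1.0
    handling_death_prob: float = 2.0 / 66.0

    # trait distributions (population means and SDs)
    mean_livesa_growth: float = 216.0
    sd_livesa_growth: float = 722.0
    mean_vol_growth: float = 404.0
    sd_vol_growth: float = 647.0
    mean_polyp_density: float = 60.0
    sd_polyp_density: float = 8.0
    partial_mortality_prob: float = 0.3

    # availability of each trait table (matches the real study's attrition)
    growth_fraction: float = 45.0 / 66.0
    three_survey_fraction: float = 24.0 / 45.0
    fecundity_fraction: float = 47.0 / 66.0
    symbiont_fraction: float = 51.0 / 66.0
    missing_diameter_n: int = 3
    modal_profile_fraction: float = 0.70
    single_profile_fraction: float = 0.96

    polyps_per_fragment: int = 10
    dissected_fragments: int = 2
    start_date: str = "2018-08-01"
    size_survey_dates: tuple = ("2017-11-15", "2018-05-15", "2019-02-15")
    seed: int = 0

    def __post_init__(self):
        for name in ("n_colonies", "n_heat_fragments", "n_control_fragments",
                     "assay_days", "n_surveys", "polyps_per_fragment"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("tolerance_growth_coupling", "tolerance_fecundity_coupling"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ConfigError(f"{name} must lie in [-1, 1], got {r}")
        if not 0.0 <= self.handling_death_prob <= 1.0:
            raise ConfigError("handling_death_prob must lie in [0, 1]")

    def rng(self, substream: str) -> np.random.Generator:
        """Named, reproducible pseudo-random substream."""
        idx = _SUBSTREAMS.index(substream)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,)))


def colony_ids(config: SyntheticConfig) -> list[str]:
    return [f"A{i + 1:02d}" for i in range(config.n_colonies)]


def generate_tank_temperatures(config: SyntheticConfig) -> pd.DataFrame:
    """10-minute tank logger series for 4 heat and 2 control tanks.

    Heat tanks sit at ambient for the acclimatisation period, ramp linearly
    at ``ramp_rate_c_per_week`` to ``baseline + peak_anomaly`` and hold to
    the end of the assay; a diel sinusoid (peak mid-afternoon), a small
    per-tank offset/ramp-start jitter and Gaussian logger noise are added.
    Control tanks stay at ambient throughout.
    """
    rng = config.rng("temperature")
    total_days = config.acclim_days + config.assay_days
    times = pd.date_range(config.start_date, periods=total_days * 144,
                          freq="10min")
    t_days = (times - times[0]) / pd.Timedelta(days=1)
    hours = times.hour + times.minute / 60.0
    diel = config.diel_amplitude_c * np.sin(2 * np.pi * (hours - 9.0) / 24.0)

    frames = []
    for tank in HEAT_TANKS + CONTROL_TANKS:
        offset = rng.normal(0.0, 0.05)
        jitter = rng.uniform(-0.5, 0.5)
        if tank in HEAT_TANKS:
            anomaly = np.clip(
                (t_days - (config.acclim_days + jitter))
                * config.ramp_rate_c_per_week / 7.0,
                0.0, config.peak_anomaly_c)
        else:
            anomaly = 0.0
        temp = (config.baseline_c + anomaly + offset + diel
                + rng.normal(0.0, config.noise_sd_c, len(times)))
        frames.append(pd.DataFrame({"tank_id": tank, "timestamp": times,
                                    "temp_c": np.clip(temp, 20.0, 40.0)}))
    return pd.concat(frames, ignore_index=True)


def generate_calibration_series(config: SyntheticConfig, n_days: int = 365
                                ) -> tuple[pd.Series, pd.Series, float]:
    """Daily satellite SST, in-situ logger series and satellite MMM.

    The in-situ series is the satellite series shifted by a fixed +0.7 degC
    offset plus noise, and the satellite MMM is set so the adjusted
    baseline recovers ``config.baseline_c``.
    """
    rng = config.rng("calibration")
    offset = 0.7
    dates = pd.date_range("2017-06-01", periods=n_days, freq="D")
    t = np.arange(n_days)
    sat = (config.baseline_c - offset - 1.0
           + 1.2 * np.sin(2 * np.pi * t / 365.25)
           + rng.normal(0.0, 0.3, n_days))
    situ = sat + offset + rng.normal(0.0, 0.2, n_days)
    mmm = config.baseline_c - offset
    return (pd.Series(sat, index=dates), pd.Series(situ, index=dates),
            float(mmm))


def _truncated_normal(rng, mean, sd, lower, size):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(out, lower)


def generate_population(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Latent colony states plus every static trait table.

    Returns a dict with keys ``truth, size, dissection, symbiont,
    polyp_density``. The latent standard-normal energy score drives the
    colony's critical DHW exactly and its growth/fecundity with the
    configured couplings, so sample correlations between ground-truth
    critical DHW and the traits recover the couplings at large n.
    """
    rng = config.rng("population")
    n = config.n_colonies
    ids = np.array(colony_ids(config))

    z = rng.standard_normal(n)                      # latent energy score
    energy = np.exp(0.4 * z)
    critical = np.maximum(
        config.mean_critical_dhw + config.sd_critical_dhw * z, 0.3)

    rg = config.tolerance_growth_coupling
    e1 = rng.standard_normal(n)
    e3 = rng.standard_normal(n)
    e2 = 0.7 * e1 + np.sqrt(1 - 0.7 ** 2) * e3      # growth metrics co-vary
    g_live = (config.mean_livesa_growth + config.sd_livesa_growth
              * (rg * z + np.sqrt(1 - rg ** 2) * e1))
    g_vol = (config.mean_vol_growth + config.sd_vol_growth
             * (rg * z + np.sqrt(1 - rg ** 2) * e2))

    rf = config.tolerance_fecundity_coupling
    e4 = rng.standard_normal(n)
    ec_colony = np.maximum(
        config.mean_eggs_per_polyp + config.sd_eggs_between_colonies
        * (rf * z + np.sqrt(1 - rf ** 2) * e4), 0.2)

    diam = _truncated_normal(rng, config.mean_diameter_cm,
                             config.sd_diameter_cm, 5.0, n)
    pm_flag = rng.random(n) < config.partial_mortality_prob
    pm_frac = np.where(pm_flag, rng.uniform(0.05, 0.30, n), 0.0)
    r0 = diam / 2.0
    sa0 = 2 * np.pi * r0 ** 2                      # hemispherical geometry
    livesa0 = sa0 * (1 - pm_frac)
    vol0 = (2.0 / 3.0) * np.pi * r0 ** 3
    pdens = _truncated_normal(rng, config.mean_polyp_density,
                              config.sd_polyp_density, 10.0, n)

    # --- size surveys -----------------------------------------------------
    n_growth = int(round(config.growth_fraction * n))
    growth_idx = np.sort(rng.choice(n, n_growth, replace=False))
    n_three = int(round(config.three_survey_fraction * n_growth))
    three = set(growth_idx[np.sort(rng.choice(n_growth, n_three,
                                              replace=False))])
    missing_d = set(rng.choice(growth_idx, min(config.missing_diameter_n,
                                               n_growth), replace=False))
    dates = [pd.Timestamp(d) for d in config.size_survey_dates]
    size_rows = []
    for i in growth_idx:
        if i in three:
            use = dates
        else:
            first = rng.integers(0, len(dates) - 1)
            use = dates[first:first + 2]
        for d in use:
            dt_years = (d - use[0]) / pd.Timedelta(days=365.25)
            livesa = max(livesa0[i] + g_live[i] * dt_years, 1.0)
            sa = max(livesa / (1 - pm_frac[i]) if pm_frac[i] < 1 else livesa,
                     livesa)
            vol = max(vol0[i] + g_vol[i] * dt_years, 1.0)
            size_rows.append((ids[i], d,
                              np.nan if i in missing_d else diam[i],
                              sa, livesa, vol, bool(pm_flag[i])))
    size = pd.DataFrame(size_rows, columns=[
        "colony_id", "survey_date", "diameter_cm", "sa_cm2", "livesa_cm2",
        "volume_cm3", "partial_mortality"])

    # --- polyp dissections ------------------------------------------------
    sig_w, sig_c = 0.08, 0.09      # within/between-colony lognormal GMD SDs
    mu0 = (np.log(6.0 * config.mean_egg_volume_mm3 / np.pi)
           - 4.5 * (sig_w ** 2 + sig_c ** 2)) / 3.0
    n_fec = int(round(config.fecundity_fraction * n))
    fec_idx = np.sort(rng.choice(n, n_fec, replace=False))
    mu_colony = mu0 + sig_c * rng.standard_normal(n)
    diss_rows = []
    for i in fec_idx:
        for frag in range(config.dissected_fragments):
            for polyp in range(config.polyps_per_fragment):
                count = int(max(round(rng.normal(ec_colony[i],
                                                 config.sd_eggs_per_polyp)), 0))
                gmd = np.exp(rng.normal(mu_colony[i], sig_w, count))
                u = rng.normal(0.0, 0.05, count)
                pairs = np.clip(
                    np.column_stack([gmd * np.exp(u), gmd * np.exp(-u)]),
                    0.05, 1.95)
                diss_rows.append((ids[i], f"{ids[i]}-D{frag + 1}", polyp + 1,
                                  count, encode_egg_diameters(map(tuple, pairs))))
    dissection = pd.DataFrame(diss_rows, columns=[
        "colony_id", "fragment_id", "polyp_index", "egg_count",
        "egg_diameters_mm"])

    # --- symbiont profiles ------------------------------------------------
    n_sym = int(round(config.symbiont_fraction * n))
    sym_idx = np.sort(rng.choice(n, n_sym, replace=False))
    n_mixed = int(round((1 - config.single_profile_fraction) * n_sym))
    mixed = set(rng.choice(sym_idx, n_mixed, replace=False))
    sym_rows = []
    for i in sym_idx:
        if rng.random() < config.modal_profile_fraction:
            main = MODAL_PROFILE
        else:
            main = MINOR_PROFILES[rng.integers(len(MINOR_PROFILES))]
        if i in mixed:
            secondary = MIXED_SECONDARIES[rng.integers(len(MIXED_SECONDARIES))]
            frac = rng.uniform(0.25, 0.35)
            sym_rows.append((ids[i], main, 1.0 - frac))
            sym_rows.append((ids[i], secondary, frac))
        else:
            sym_rows.append((ids[i], main, 1.0))
    symbiont = pd.DataFrame(sym_rows, columns=["colony_id", "its2_profile",
                                               "relative_abundance"])

    density = pd.DataFrame({"colony_id": ids, "polyps_per_cm2": pdens})
    truth = pd.DataFrame({
        "colony_id": ids,
        "energy_budget": energy,
        "true_critical_dhw": critical,
        "true_growth_livesa": g_live,
        "true_growth_vol": g_vol,
        "true_ec": ec_colony,
        "true_tep": ec_colony * pdens * livesa0,
    })
    return {"truth": truth, "size": size, "dissection": dissection,
            "symbiont": symbiont, "polyp_density": density}


def generate_health_trajectories(truth: pd.DataFrame, stress: pd.DataFrame,
                                 config: SyntheticConfig) -> pd.DataFrame:
    """Ordinal fragment health surveys driven by tank DHW-threshold crossings.

    Each colony gets one fragment per heat tank and one per control tank.
    A fragment's state at a survey is 1 + the number of its four category
    thresholds the tank DHW has crossed; states never improve. Control
    fragments stay healthy except for a configurable handling-death rate
    (one control fragment of an affected colony dies mid-assay), which
    exercises the procedural-control exclusion rule downstream.
    """
    rng = config.rng("health")
    have = set(stress["tank_id"])
    needed = set(HEAT_TANKS[:config.n_heat_fragments]
                 + CONTROL_TANKS[:config.n_control_fragments])
    if not needed <= have:
        raise InsufficientDataError(
            f"missing heat-stress series for tanks: {sorted(needed - have)}")

    assay_start = (pd.Timestamp(config.start_date)
                   + pd.Timedelta(days=config.acclim_days))
    offsets = SURVEY_DAY_OFFSETS[:config.n_surveys]
    survey_times = [assay_start + pd.Timedelta(days=int(d), hours=10)
                    for d in offsets]

    dhw_at = {}
    for tank in needed:
        s = stress[stress["tank_id"] == tank].sort_values("date")
        series = pd.Series(np.maximum.accumulate(s["dhw_c_weeks"].to_numpy()),
                           index=s["date"])
        days = pd.DatetimeIndex([t.normalize() for t in survey_times])
        dhw_at[tank] = series.reindex(
            series.index.union(days)).ffill().fillna(0.0).loc[days].to_numpy()

    delta = config.category_spacing_dhw
    rows = []
    for rec in truth.itertuples(index=False):
        for k in range(config.n_heat_fragments):
            tank = HEAT_TANKS[k % len(HEAT_TANKS)]
            h_f = rec.true_critical_dhw + rng.normal(
                0.0, config.fragment_threshold_sd)
            thresholds = h_f + (np.arange(4) - 0.5) * delta
            states = 1 + (dhw_at[tank][:, None] >= thresholds[None, :]).sum(axis=1)
            states = np.maximum.accumulate(states)
            for t, st in zip(survey_times, states):
                rows.append((rec.colony_id, f"{rec.colony_id}-H{k + 1}",
                             tank, t, HEALTH_CATEGORIES[st - 1]))
        dead_from = None
        if rng.random() < config.handling_death_prob:
            dead_from = int(rng.integers(4, max(5, config.n_surveys - 3)))
            dead_frag = int(rng.integers(config.n_control_fragments))
        for k in range(config.n_control_fragments):
            tank = CONTROL_TANKS[k % len(CONTROL_TANKS)]
            for s_idx, t in enumerate(survey_times):
                cat = ("dead" if dead_from is not None and k == dead_frag
                       and s_idx >= dead_from else "healthy")
                rows.append((rec.colony_id, f"{rec.colony_id}-C{k + 1}",
                             tank, t, cat))
    return pd.DataFrame(rows, columns=["colony_id", "fragment_id", "tank_id",
                                       "survey_time", "category"])


def generate_dataset(config: SyntheticConfig) -> dict:
    """Full synthetic study: all six input tables plus latent ground truth.

    Tank DHW used to drive bleaching is computed with the package's own
    DHW accumulator from the generated logger series and the generator's
    true baseline.
    """
    temps = generate_tank_temperatures(config)
    sat, situ, mmm = generate_calibration_series(config)
    baseline = thermal.ClimatologyBaseline(
        mmm=mmm, intercept=config.baseline_c - mmm, slope=1.0,
        mmm_adj=config.baseline_c)
    stress = thermal.compute_dhw(temps, baseline)
    pop = generate_population(config)
    health = generate_health_trajectories(pop["truth"], stress, config)
    return {
        "temperature": temps,
        "health": health,
        "size": pop["size"],
        "dissection": pop["dissection"],
        "symbiont": pop["symbiont"],
        "polyp_density": pop["polyp_density"],
        "truth": pop["truth"],
        "stress": stress,
        "calibration": {"satellite": sat, "insitu": situ, "mmm": mmm},
    }
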