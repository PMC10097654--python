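"""Colony-level bleaching survival index (BSI) trajectories and
heat-tolerance summaries.

The BSI scores a colony from the proportions ``c1..c5`` of its replicate
fragments in the five ordinal health categories (healthy, half bleached,
bleached, partial mortality, dead)::

    BMI = (0*c1 + 1*c2 + 2*c3 + 3*c4 + 4*c5) / (N - 1),   N = 5
    BSI = 1 - BMI

so an all-healthy colony scores 1, an all-dead colony 0, and an
all-half-bleached colony 0.75 — the onset threshold. A colony's overall
heat tolerance is its average BSI across the fixed DHW grid, and its
critical DHW is the first grid level at which BSI falls to <= 0.75.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_io import CATEGORY_WEIGHT, HEALTH_CATEGORIES, N_CATEGORIES
from .errors import ValidationError

ONSET_BSI = 0.75
#: average-BSI tolerance categories: high >= 0.8 > medium >= 0.7 > low
CATEGORY_BOUNDS = {"high": 0.8, "medium": 0.7}

_WEIGHTS = np.arange(N_CATEGORIES, dtype=float)


def compute_bsi(proportions) -> float:
    """BSI from the five category proportions of one colony.

    ``proportions`` is ``(c1, c2, c3, c4, c5)``; they must lie in [0, 1]
    and sum to 1 (tolerance 1e-9 on the sum).
    """
    c = np.asarray(proportions, dtype=float)
    if c.shape != (N_CATEGORIES,):
        raise ValidationError(f"expected {N_CATEGORIES} proportions, got {c.shape}")
    if (c < -1e-12).any() or (c > 1 + 1e-12).any():
        raise ValidationError("category proportions must lie in [0, 1]")
    if abs(c.sum() - 1.0) > 1e-9:
        raise ValidationError(f"category proportions sum to {c.sum()!r}, not 1")
    bmi = float(c @ _WEIGHTS) / (N_CATEGORIES - 1)
    return 1.0 - bmi


def apply_control_exclusion(records: pd.DataFrame, control_tanks) -> tuple[pd.DataFrame, list[str]]:
    """Drop every record of colonies that lost a fragment in a control tank.

    Death in an unheated procedural-control tank indicates a handling
    artefact, so the whole colony is removed from the experiment and never
    assigned a tolerance score. Returns the filtered records and the sorted
    list of excluded colonies. Colonies with no control fragments at all
    are retained with a warning.
    """
    control_tanks = set(control_tanks)
    in_control = records["tank_id"].isin(control_tanks)
    with_controls = set(records.loc[in_control, "colony_id"])
    orphans = sorted(set(records["colony_id"]) - with_controls)
    if orphans:
        warnings.warn(
            f"{len(orphans)} colony(ies) have no procedural-control fragments "
            f"and are retained unchecked: {', '.join(orphans[:5])}...",
            stacklevel=2)
    dead_in_control = records.loc[in_control & (records["category"] == "dead"),
                                  "colony_id"]
    excluded = sorted(set(dead_in_control))
    kept = records[~records["colony_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def colony_trajectories(grid_categories: pd.DataFrame) -> pd.DataFrame:
    """Per-colony BSI trajectory on the DHW grid.

    ``grid_categories`` is the output of
    :func:`~coraltrade.thermal.interpolate_health_at_grid` restricted to
    heat-tank fragments. Death is absorbing: a fragment's ordinal state is
    made non-improving across grid levels before proportions are formed.

    Returns a long table ``colony_id, dhw_level, c1..c5, n_fragments, bsi``.
    """
    df = grid_categories.copy()
    df["weight"] = df["category"].map(CATEGORY_WEIGHT).astype(float)
    df = df.sort_values(["colony_id", "fragment_id", "dhw_level"])
    df["weight"] = df.groupby(["colony_id", "fragment_id"])["weight"].cummax()

    rows = []
    for (colony, x), grp in df.groupby(["colony_id", "dhw_level"], sort=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            continue
        counts = np.bincount(grp["weight"].astype(int), minlength=N_CATEGORIES)
        props = counts / n
        rows.append((colony, float(x), *props, n, compute_bsi(props)))
    cols = (["colony_id", "dhw_level"]
            + [f"c{i + 1}" for i in range(N_CATEGORIES)]
            + ["n_fragments", "bsi"])
    out = pd.DataFrame(rows, columns=cols)
    empty = set(grid_categories["colony_id"]) - set(out["colony_id"])
    if empty:
        warnings.warn(f"colonies without heat-tank fragments skipped: {sorted(empty)}",
                      stacklevel=2)
    return out


def summarize_tolerance(trajectories: pd.DataFrame,
                        onset_bsi: float = ONSET_BSI) -> pd.DataFrame:
    """Average BSI, critical DHW and tolerance category per colony.

    The average is an unweighted mean over grid levels; the critical DHW is
    the smallest grid level with ``bsi <= onset_bsi`` (a tie at exactly the
    threshold counts as onset), NaN if never reached. Categories:
    high (>= 0.8), medium (>= 0.7), low.
    """
    rows = []
    for colony, grp in trajectories.sort_values("dhw_level").groupby(
            "colony_id", sort=True):
        bsi = grp["bsi"].to_numpy()
        avg = float(bsi.mean())
        onset = np.flatnonzero(bsi <= onset_bsi + 1e-12)
        critical = float(grp["dhw_level"].to_numpy()[onset[0]]) if len(onset) else np.nan
        if avg >= CATEGORY_BOUNDS["high"]:
            cat = "high"
        elif avg >= CATEGORY_BOUNDS["medium"]:
            cat = "medium"
        else:
            cat = "low"
        rows.append((colony, avg, critical, cat))
    return pd.DataFrame(rows, columns=["colony_id", "average_bsi",
                                       "critical_dhw", "tolerance_category"])
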