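#!/usr/bin/env python
"""Bayesian trade-off inference: overall, per-DHW-level, and covariate tests.

Regresses colony heat tolerance (average BSI) on each trait and reports
P(slope > 0) — the posterior odds that no trade-off exists; repeats the
regression independently at all 21 DHW levels (slope progression); tests
the symbiont ITS2 effect and partial-mortality confounding; and draws the
slope-progression figure with 50/75/95% credible bands.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from coraltrade import data_io, tradeoff


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    summaries = pd.read_csv(args.out / "tolerance_summaries.csv")
    traj = pd.read_csv(args.out / "bsi_trajectories.csv")
    growth = pd.read_csv(args.out / "growth.csv")
    fec = pd.read_csv(args.out / "fecundity.csv")
    trait_table = growth.merge(fec, on="colony_id", how="outer")

    overall = tradeoff.overall_tradeoff_analysis(summaries, trait_table)
    print("overall trade-off regressions (tolerance ~ trait):")
    for r in overall.itertuples():
        print(f"  {r.trait_name:>24s} [{r.variant:>16s}]  "
              f"slope {r.beta1_median:+.2e}  P(slope>0) = {r.p_positive:.2f} "
              f"(n = {r.n_colonies})")
    print("  -> P(slope>0) well above 0.5 indicates growth and tolerance act"
          " in concert; near 0.5 means the data cannot resolve a direction.")

    progression = []
    for trait in tradeoff.OVERALL_TRAITS:
        series = trait_table.set_index("colony_id")[trait]
        progression.append(tradeoff.slope_progression(traj, series,
                                                      trait_name=trait))
    progression = pd.concat(progression, ignore_index=True)
    g = progression[progression["trait_name"] == "corrected_livesa_growth"]
    peak = g.loc[g["p_positive"].idxmax()]
    print(f"slope progression (LiveSA growth): P(slope>0) peaks at "
          f"{peak['p_positive']:.2f} at DHW {peak['dhw_level']:.1f} degC-weeks")

    sym = data_io.read_table(args.data / "symbiont.csv", "symbiont")
    sym_tests = tradeoff.symbiont_effect_test(traj, sym)
    tested = sym_tests[sym_tests["adjusted_p"].notna()]
    if len(tested):
        print(f"symbiont ITS2 contrasts: min adjusted p = "
              f"{tested['adjusted_p'].min():.2f} "
              f"({(tested['adjusted_p'] < 0.05).sum()} significant of "
              f"{len(tested)})")
    flagged = sym_tests[sym_tests["flag"] != ""]
    for r in flagged.itertuples():
        print(f"  note: {r.group_a}: {r.flag}")

    size = data_io.read_table(args.data / "size.csv", "size")
    pm = (size.sort_values("survey_date").groupby("colony_id")
          .first().reset_index()[["colony_id", "partial_mortality"]])
    conf = tradeoff.confounder_tests(
        summaries.merge(trait_table, on="colony_id", how="left")
        .merge(pm, on="colony_id"),
        "partial_mortality",
        ["average_bsi", "corrected_livesa_growth", "corrected_vol_growth",
         "tep", "tev"])
    omni = conf[conf["group_a"] == "omnibus"]
    print("partial-mortality confounder tests (omnibus p):")
    for r in omni.itertuples():
        print(f"  {r.test_name:>32s}: p = {r.raw_p:.3f}")

    data_io.write_results(overall, args.out / "tradeoff_overall.csv")
    data_io.write_results(progression, args.out / "tradeoff_progression.csv")
    if len(sym_tests):
        data_io.write_results(sym_tests, args.out / "symbiont_tests.csv")
    data_io.write_results(conf, args.out / "confounder_tests.csv")

    _plot_progression(g, args.out / "slope_progression.png")
    print(f"figure written to {args.out / 'slope_progression.png'}")


def _plot_progression(g, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = g.sort_values("dhw_level")
    fig, ax = plt.subplots(figsize=(7, 4))
    for pct, alpha in ((95, 0.15), (75, 0.25), (50, 0.35)):
        ax.fill_between(g["dhw_level"], g[f"beta1_lower_{pct}"],
                        g[f"beta1_upper_{pct}"], color="grey", alpha=alpha,
                        label=f"{pct}% CI")
    ax.plot(g["dhw_level"], g["beta1_median"], color="tab:blue", lw=2,
            label="median slope")
    ax.axhline(0, color="red", ls="--", lw=1)
    ax.set_xlabel("DHW level (degC-weeks)")
    ax.set_ylabel("BSI ~ LiveSA-growth slope")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


if __name__ == "__main__":
    main()
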