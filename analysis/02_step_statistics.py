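"""Per-step time and visit statistics with operative-time correlations.

Loads the cohort written by ``01_simulate_cohort.py``, computes each
step's cumulative/mean time and visit frequency plus Spearman
correlations with console and total operative time, and writes the table
to ``results/summary.csv``.  Prints the steps that dominate operative
time and the strongest correlations.

Run from the repository root:  python analysis/02_step_statistics.py
"""

from pathlib import Path

import pandas as pd

from procflow.catalog import StepCatalog
from procflow.io import load_annotations
from procflow.stats import summarize_steps, summary_frame

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    catalog = StepCatalog.load(DATA / "catalog.csv")
    cohort = load_annotations(DATA / "events.csv", DATA / "metadata.csv", catalog)
    summary = summarize_steps(cohort)
    frame = summary_frame(summary, catalog)
    frame.to_csv(OUT / "summary.csv", index=False, na_rep="NA")

    print(f"wrote {OUT / 'summary.csv'} ({len(frame)} steps, "
          f"{summary.n_procedures} procedures)")
    print(f"  mean occurrences/procedure: {summary.mean_occurrences_per_procedure:.1f} "
          f"(sd {summary.sd_occurrences_per_procedure:.1f})")
    print(f"  console time {summary.mean_ct_min:.0f} min (sd {summary.sd_ct_min:.0f}); "
          f"total {summary.mean_tot_min:.0f} min (sd {summary.sd_tot_min:.0f})")

    with pd.option_context("display.width", 120):
        top_time = frame.nlargest(3, "mean_time_min")[["step_name", "mean_time_min"]]
        top_visits = frame.nlargest(3, "mean_visits")[["step_name", "mean_visits"]]
        print("\nlongest steps (mean min):")
        print(top_time.to_string(index=False))
        print("\nmost revisited steps (mean visits):")
        print(top_visits.to_string(index=False))
        strong = frame[(frame["rho_time_ct"].abs() >= 0.6) | (frame["rho_visits_ct"].abs() >= 0.6)]
        if not strong.empty:
            print("\nsteps strongly rank-correlated with console time (|rho| >= 0.6):")
            print(strong[["step_name", "rho_time_ct", "rho_visits_ct"]]
                  .to_string(index=False, na_rep="NA"))


if __name__ == "__main__":
    main()
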