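"""Summarize the age-bias correction results from the pipeline run.

Age predictors overestimate the young and underestimate the old; the linear
correction removes that trend exactly on the data it was fit on, but a
correction fit on one cohort need not help another — which is what the
per-cohort before/after MAE table shows.
"""

from pathlib import Path

import pandas as pd

SRC = Path("results/pipeline/bias_correction.csv")


def main() -> None:
    if not SRC.exists():
        raise SystemExit(f"{SRC} not found - run analysis/02_run_pipeline.py first")
    b = pd.read_csv(SRC)
    b["delta"] = b["mae_after"] - b["mae_before"]
    print("Bias-correction effect on test MAE (negative delta = improvement):\n")
    print(
        b[["model", "cohort", "slope", "mae_before", "mae_after", "delta"]]
        .round(3)
        .to_string(index=False)
    )
    own = b[b.apply(lambda r: r["model"].endswith(r["cohort"]), axis=1)]
    if not own.empty:
        print(
            f"\nOn the cohorts they were fit on, corrections changed MAE by "
            f"{own['delta'].mean():+.3f} y on average; slopes below 1 confirm the "
            "regression-to-the-mean bias the correction removes."
        )


if __name__ == "__main__":
    main()
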