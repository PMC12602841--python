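"""Summarize the Cox survival profiling of the age-gap scores.

Prints the per-outcome coefficient tables (separate and pairwise fits of the
brain gap, the metabolic gap and the mortality score, age-only and fully
adjusted) and the predicted survival at end of follow-up for the four
quartile-combination profiles: individuals old-appearing on both scores fare
worst, young-appearing on both best, mixed profiles in between. Dementia risk
is carried by the brain gap only.
"""

from pathlib import Path

import pandas as pd

SRC = Path("results/pipeline")


def main() -> None:
    coef_files = sorted(SRC.glob("survival_coefficients_*.csv"))
    if not coef_files:
        raise SystemExit("no survival outputs found - run analysis/02_run_pipeline.py first")
    for path in coef_files:
        cohort = path.stem.split("_")[-1]
        c = pd.read_csv(path)
        scores = c[c["term"].isin(["bag", "mag", "metabohealth"])]
        print(f"\n=== cohort {cohort}: gap-score hazard ratios ===\n")
        print(
            scores[["outcome", "covariate_set", "model", "term", "hr", "p", "events"]]
            .round(4)
            .to_string(index=False)
        )
    for path in sorted(SRC.glob("survival_curves_*bag_mag*.csv")):
        curves = pd.read_csv(path, index_col=0)
        print(f"\n{path.name}: predicted survival at end of follow-up")
        print(curves.iloc[-1].round(3).to_string())


if __name__ == "__main__":
    main()
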