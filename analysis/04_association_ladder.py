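"""Summarize the federated association ladder for both responses.

Six covariate sets (M1: none ... M6: age, sex, DM, lag time, BMI, education)
relate the imaging-based age score to each metabolomics response. The key
contrast is M1 vs M2: the unadjusted association between the two age scores
is strong, and adding chronological age collapses it — the scores mostly
share the age signal. For the mortality-trained metabolite score the
association survives age adjustment, indicating shared information beyond age.
"""

from pathlib import Path

import pandas as pd

SRC = Path("results/pipeline")


def main() -> None:
    for response in ("metaboage", "metabohealth"):
        path = SRC / f"association_{response}_table.csv"
        if not path.exists():
            raise SystemExit(f"{path} not found - run analysis/02_run_pipeline.py first")
        wide = pd.read_csv(path, index_col="model")
        print(f"\n=== response: {response} (beta per term; ** p<=5e-10, * p<=0.05, = n.s.) ===\n")
        print(wide.to_string())
        tidy = pd.read_csv(SRC / f"association_{response}.csv")
        m1 = tidy.query("model == 'M1' and term == 'brainage'")["beta"].iloc[0]
        m2 = tidy.query("model == 'M2' and term == 'brainage'")["beta"].iloc[0]
        print(f"\nAge adjustment moves the score coefficient {m1:+.3f} -> {m2:+.3f} "
              f"({100 * (1 - abs(m2) / abs(m1)):.0f}% attenuation)." if abs(m1) > 0 else "")


if __name__ == "__main__":
    main()
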