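#!/usr/bin/env python
"""Run the 9-run three-optimizer conformance study for F1–F4.

For each generative function the study fits the two-parameter line with
SGD, RMSprop and Adam on nine fresh datasets, measures the pairwise
prediction distances d_SA (SGD vs Adam) and d_SR (SGD vs RMSprop), and
Welch-tests the two distance samples. Distance tables, summary JSONs
and figures go to results/conformance.
"""

from pathlib import Path

import pandas as pd

from conformnet import export_conformance_outputs, run_conformance_study
from conformnet.synthetic_data import TARGET_FUNCTION_IDS

OUT = Path(__file__).resolve().parents[1] / "results" / "conformance"
SEED = 0


def main() -> None:
    rows = []
    for k, fn_id in enumerate(TARGET_FUNCTION_IDS):
        study = run_conformance_study(fn_id, n_runs=9, m=100, base_seed=SEED + 1000 * k)
        export_conformance_outputs(study, OUT)
        rows.append(study.summary())
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "study_summaries.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    adam_closer = table[table.mean_d_sa < table.mean_d_sr].fn_id.tolist()
    print(
        f"\nAdam-fitted models sit closer to SGD than RMSprop-fitted models for: "
        f"{adam_closer or 'none'}. For the remaining functions all three optimizers "
        "converge into the same gradient-tolerance region (or, for F4, the "
        "adaptive methods fall short of the distant optimum at different rates), "
        "so the ordering is not systematic — see docs/methods.md."
    )


if __name__ == "__main__":
    main()
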