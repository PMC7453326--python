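"""Apply the data-sufficiency filter and preprocessing to the raw cohort.

Reads results/cohort/recordings.csv (from 01_simulate_cohort.py), applies
the 50%-of-4032 inclusion criterion, runs the preprocessing chain
(5-minute resampling with linear imputation, 3-SD clipping, 0-1 scaling)
and writes the inclusion report plus a per-subject preprocessing summary.

Usage: python analysis/02_preprocess_inclusion.py
"""

from pathlib import Path

import pandas as pd

from volsense import FeatureUndefinedError, preprocess, sufficiency_filter
from volsense.io_formats import read_recording_log

COHORT = Path("results/cohort")


def main():
    logs = read_recording_log(COHORT / "recordings.csv")
    inclusion, summary = [], []
    for sid in sorted(logs):
        log = logs[sid]
        included = sufficiency_filter(log)
        inclusion.append(
            {"subject_id": sid, "n_recordings": len(log), "expected": 4032,
             "included": int(included)}
        )
        try:
            s = preprocess(log)
        except FeatureUndefinedError:
            continue
        summary.append(
            {"subject_id": sid, "n_grid_points": len(s),
             "mean_normalized_volume": float(s.values.mean())}
        )
    inc = pd.DataFrame(inclusion)
    inc.to_csv(COHORT / "inclusion.csv", index=False)
    pd.DataFrame(summary).to_csv(COHORT / "preprocess_summary.csv", index=False)

    n_in = int(inc["included"].sum())
    print(f"{n_in} of {len(inc)} subjects meet the 50% sufficiency criterion "
          f"(median yield {inc['n_recordings'].median() / 4032:.0%} of protocol)")
    print(f"inclusion report -> {COHORT / 'inclusion.csv'}")


if __name__ == "__main__":
    main()
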