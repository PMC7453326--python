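"""Extract the four behavioural features for every subject.

Reads the raw cohort tables, computes daily similarity (24-h lag
autocorrelation), the two sleep-disturbance variants (pooled SD in the
00:00-06:00 window, all nights and weeknights) and the speech presence
ratio, and writes the per-subject feature table plus a descriptive
summary (mean, SD, min, quartiles, max over included subjects).

Usage: python analysis/03_extract_features.py
"""

from pathlib import Path

from volsense.io_formats import read_recording_log, write_feature_table
from volsense.pipeline import cohort_features, summarize_features

COHORT = Path("results/cohort")


def main():
    logs = read_recording_log(COHORT / "recordings.csv")
    rows = cohort_features(logs)
    write_feature_table(rows, COHORT / "features.csv")
    table = summarize_features(rows)
    table.to_csv(COHORT / "feature_summary.csv", index=False)

    print(f"features for {len(rows)} subjects "
          f"({sum(r.included for r in rows)} included) -> features.csv")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
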