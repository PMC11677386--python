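"""Evaluate every estimating equation for the working cohort.

Reads results/cohort.csv, writes results/derived.csv, and prints whole-sample
mean/median for the key derived biomarkers — the synthetic analogue of the
whole-sample biomarker tables.
"""

from pathlib import Path

from musclecompare.biomarkers import derived_frame
from musclecompare.pipeline import read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"

KEY = ["l3_sma", "l3_smd", "smi_ct", "smg", "shen_mm", "mourtzakis_ffm",
       "janssen_mm", "kanellakis_ffm", "kotler_ffm", "theta",
       "rf_mt", "quad_mt", "rf_csa", "hgs"]


def main() -> None:
    records = read_cohort(RESULTS / "cohort.csv")
    frame = derived_frame(records)
    frame.to_csv(RESULTS / "derived.csv", index=False)
    print(f"derived {frame.shape[1]} columns for {len(frame)} subjects")
    print(f"{'biomarker':<16}{'mean':>9}{'sd':>8}{'median':>9}")
    for var in KEY:
        s = frame[var]
        print(f"{var:<16}{s.mean():>9.1f}{s.std():>8.1f}{s.median():>9.1f}")
    print(f"wrote {RESULTS / 'derived.csv'}")


if __name__ == "__main__":
    main()
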