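"""Intra- and inter-technique correlation matrices.

Matrix 1 relates BIA (raw and estimated), CT (measured and estimated),
anthropometry and handgrip; matrix 2 relates ultrasound to CT, anthropometry
and handgrip.  Written to results/corr_matrix[12].csv; the headline signs are
printed (resistance anti-correlates with CT muscle area; phase angle tracks
handgrip strength).
"""

from pathlib import Path

from musclecompare.biomarkers import derived_frame
from musclecompare.pipeline import correlation_matrix, read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"

MATRIX1 = ["rz", "xc", "theta", "janssen_mm", "kanellakis_ffm", "kotler_ffm",
           "l3_sma", "l3_smd", "smg", "shen_mm", "mourtzakis_ffm",
           "height", "weight", "hgs"]
MATRIX2 = ["quad_mt", "rf_mt", "rf_csa", "l3_sma", "l3_smd", "shen_mm",
           "mourtzakis_ffm", "height", "weight", "hgs"]


def main() -> None:
    frame = derived_frame(read_cohort(RESULTS / "cohort.csv"))
    for name, variables in (("corr_matrix1", MATRIX1), ("corr_matrix2", MATRIX2)):
        corr, pvals = correlation_matrix(frame, variables, method="pearson")
        corr.round(3).to_csv(RESULTS / f"{name}.csv")
        pvals.to_csv(RESULTS / f"{name}_p.csv")
        print(f"wrote {name}.csv ({len(variables)} variables)")
    corr1, _ = correlation_matrix(frame, MATRIX1)
    corr2, _ = correlation_matrix(frame, MATRIX2)
    print(f"  corr(R_z, L3-SMA)   = {corr1.loc['rz', 'l3_sma']:+.2f} (expected negative)")
    print(f"  corr(theta, HGS)    = {corr1.loc['theta', 'hgs']:+.2f} (expected positive)")
    print(f"  corr(RF-MT, L3-SMA) = {corr2.loc['rf_mt', 'l3_sma']:+.2f} (expected positive)")


if __name__ == "__main__":
    main()
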