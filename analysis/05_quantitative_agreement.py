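"""Inter-technique quantitative agreement and the US→L3-SMA refit.

For each (reference, index) pair of whole-body estimates — CT-based Shen MM
vs the BIA Janssen MM, CT-based Mourtzakis FFM vs the BIA Kanellakis/Kotler
FFM, and measured L3-SMA vs its ultrasound-based estimates — reports Pearson
r, Lin's CCC with category, Bland–Altman bias/LoA and the paired location
test; also refits the US→L3-SMA regression on the synthetic cohort.  Writes
results/agreement.json and Bland–Altman panels under scratch/.
"""

import json
from pathlib import Path

import matplotlib.pyplot as plt

from musclecompare.biomarkers import derived_frame, fit_sma_regression
from musclecompare.pipeline import agreement_report, read_cohort
from musclecompare.plots import bland_altman_plot, scatter_identity

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

PAIRS = [
    ("shen_mm", "janssen_mm"),
    ("mourtzakis_ffm", "kanellakis_ffm"),
    ("mourtzakis_ffm", "kotler_ffm"),
    ("l3_sma", "fischer_sma"),
    ("l3_sma", "newmodel_sma"),
]


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    records = read_cohort(RESULTS / "cohort.csv")
    frame = derived_frame(records)

    reports = agreement_report(frame, PAIRS)
    (RESULTS / "agreement.json").write_text(json.dumps(reports, indent=2))
    for rep in reports:
        ba, ccc = rep["bland_altman"], rep["ccc"]
        print(f"{rep['reference']} vs {rep['index']}: r = {rep['pearson_r']:.3f}, "
              f"CCC = {ccc['rho_c']:.3f} [{ccc['category']}], "
              f"bias = {ba['bias']:.1f} ({ba['sd_diff']:.1f}), "
              f"LoA ({ba['loa_low']:.1f}, {ba['loa_high']:.1f}), "
              f"{ba['n_outside']}/{ba['n']} outside")
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        pair = frame[[rep["reference"], rep["index"]]].dropna()
        scatter_identity(pair.iloc[:, 0], pair.iloc[:, 1],
                         labels=(rep["reference"], rep["index"]), ax=axes[0])
        bland_altman_plot(pair.iloc[:, 0], pair.iloc[:, 1], ax=axes[1])
        fig.tight_layout()
        fig.savefig(SCRATCH / f"ba_{rep['reference']}_vs_{rep['index']}.png", dpi=90)
        plt.close(fig)

    fit = fit_sma_regression(records)
    print(f"US->L3-SMA refit (n = {fit.n}): "
          f"SMA = {fit.intercept:.2f} + {fit.coef_quad_mt:.2f}*Q "
          f"+ {fit.coef_weight:.2f}*W + {fit.coef_height:.2f}*H "
          f"+ {fit.coef_sex:.2f}*S, adj R² = {fit.adjusted_r2:.3f}")
    (RESULTS / "sma_refit.json").write_text(json.dumps({
        "intercept": fit.intercept, "quad_mt_cm": fit.coef_quad_mt,
        "weight": fit.coef_weight, "height_cm": fit.coef_height,
        "sex": fit.coef_sex, "adjusted_r2": fit.adjusted_r2, "n": fit.n,
    }, indent=2))


if __name__ == "__main__":
    main()
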