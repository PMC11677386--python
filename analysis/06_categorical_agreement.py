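"""Diagnostic prevalence under competing definitions and their kappa grid.

Applies every shipped cut-off set plus dynapenia, sarcopenia, GLIM and BMI
categories to the working cohort; writes results/flags.csv,
results/prevalence.csv and results/kappa_grid.csv, and prints how strongly
the competing muscle-atrophy definitions agree.
"""

from pathlib import Path

from musclecompare.pipeline import (diagnose_cohort, kappa_grid,
                                    prevalence_table, read_cohort)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_cohort(RESULTS / "cohort.csv")
    flags = diagnose_cohort(records)
    flags.to_csv(RESULTS / "flags.csv", index=False)

    prev = prevalence_table(flags)
    prev.to_csv(RESULTS / "prevalence.csv", index=False)
    print("prevalence by definition:")
    for _, row in prev.iterrows():
        print(f"  {row['definition']:<34}{row['positives']:>4}/{row['n']} "
              f"({row['percent']:.1f}%)")

    atrophy_cols = [c for c in flags.columns if c.startswith("atrophy_")]
    usable = [c for c in atrophy_cols if flags[c].notna().all()]
    grid = kappa_grid(flags[usable].astype(bool))
    grid.to_csv(RESULTS / "kappa_grid.csv", index=False)
    print("\nkappa between atrophy definitions:")
    for _, row in grid.iterrows():
        note = "" if row.get("kappa") == row.get("kappa") else " (undefined)"
        print(f"  {row['a']} vs {row['b']}: k = {row['kappa']:.3f}{note}"
              if note == "" else f"  {row['a']} vs {row['b']}:{note}")


if __name__ == "__main__":
    main()
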