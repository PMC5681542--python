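"""Simulate the study cohort and freeze it as the repository's fixture data.

Writes data/synthetic_cohort.csv (143 patients, 66 treated; Growth recorded
for untreated patients only, as in the clinical reporting convention) and
data/synthetic_truth.json (the generating network, for recovery scoring).
Deterministic: re-running reproduces the same files byte for byte.
"""

import pathlib

from cephbn import GeneratorConfig, compute_differences, simulate_cohort, study_truth, write_cohort

SEED = 2017
ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    truth = study_truth()
    config = GeneratorConfig(seed=SEED, truth=truth)
    cohort = simulate_cohort(config)

    data_dir = ROOT / "data"
    data_dir.mkdir(exist_ok=True)
    write_cohort(cohort, data_dir / "synthetic_cohort.csv")
    truth.to_json(data_dir / "synthetic_truth.json")

    table = compute_differences(cohort)
    n_treated = int(table.frame["Treatment"].sum())
    n_growth = int(table.frame["Growth"].notna().sum())
    print(f"cohort: {len(cohort)} patients ({n_treated} treated, "
          f"{len(cohort) - n_treated} untreated)")
    print(f"Growth recorded for {n_growth} patients")
    print(f"truth network: {len(truth.dag.arcs)} arcs")
    print("difference-variable summary:")
    print(table.frame.describe().loc[["mean", "std"]].round(2).to_string())
    print(f"wrote {data_dir / 'synthetic_cohort.csv'}")
    print(f"wrote {data_dir / 'synthetic_truth.json'}")


if __name__ == "__main__":
    main()
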