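"""Learn the bootstrap consensus Bayesian network from the fixture cohort.

200 bootstrap replicates of constrained BIC hill-climbing give an arc
strength (appearance frequency) per variable pair; the consensus DAG keeps
arcs above the data-driven threshold.  A sparse 0.85-strength view is also
written, as is the single-sample (non-averaged) network for comparison.

Outputs under results/: arc_strengths.tsv, consensus.dot, consensus_085.dot,
consensus_arcs.tsv, fitted_network.json.
"""

import pathlib

from cephbn import (
    bootstrap_strengths,
    compute_differences,
    consensus_network,
    consensus_to_dot,
    default_constraints,
    estimate_threshold,
    fit_ols,
    hill_climb,
    read_cohort,
)

ROOT = pathlib.Path(__file__).resolve().parents[1]
R = 200
SEED = 2017


def main() -> None:
    cohort = read_cohort(ROOT / "data" / "synthetic_cohort.csv")
    table = compute_differences(cohort)
    constraints = default_constraints(table.columns)

    strengths = bootstrap_strengths(table, constraints, R=R, seed=SEED)
    threshold = estimate_threshold(strengths)
    consensus = consensus_network(strengths, threshold)
    sparse = consensus_network(strengths, 0.85)
    single = hill_climb(table, constraints)
    fitted = fit_ols(consensus, table)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    strengths.to_tsv(results / "arc_strengths.tsv")
    consensus.to_tsv(results / "consensus_arcs.tsv")
    (results / "consensus.dot").write_text(
        consensus_to_dot(strengths, consensus, highlight=constraints.whitelist))
    (results / "consensus_085.dot").write_text(
        consensus_to_dot(strengths, sparse, highlight=constraints.whitelist))
    fitted.to_json(results / "fitted_network.json")

    print(f"bootstrap replicates: {R} (failures: {strengths.failures})")
    print(f"estimated strength threshold: {threshold:.3f}")
    print(f"consensus network: {len(consensus.arcs)} arcs "
          f"({len(sparse.arcs)} with strength >= 0.85)")
    print(f"single-sample hill-climb: {len(single.arcs)} arcs")
    strong = sum(1 for e in strengths.entries.values()
                 if e.strength >= threshold and e.strength >= 0.85)
    print(f"{strong} of {len(consensus.arcs)} consensus arcs have strength >= 0.85")
    print("consensus arcs (strength, direction frequency):")
    for (p, c) in sorted(consensus.arcs):
        e = strengths.entries[frozenset((p, c))]
        print(f"  {p:>10s} -> {c:<10s} {e.strength:.2f}  {e.direction:.2f}")


if __name__ == "__main__":
    main()
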