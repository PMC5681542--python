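"""Interrogate the fitted consensus network with the four clinical queries.

Uses logic sampling (10^4 draws) and do-style interventions on the network
fitted by 03_consensus_network.py.  Writes results/hypotheses.json and
prints the consolidated table.
"""

import json
import pathlib

from cephbn import FittedNetwork, format_report, run_hypotheses

ROOT = pathlib.Path(__file__).resolve().parents[1]
SEED = 2017


def main() -> None:
    net = FittedNetwork.from_json(ROOT / "results" / "fitted_network.json")
    report = run_hypotheses(net, n=10_000, seed=SEED)
    (ROOT / "results" / "hypotheses.json").write_text(json.dumps(report, indent=2))
    print(format_report(report))


if __name__ == "__main__":
    main()
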