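"""Bootstrap model averaging: arc strengths, data-driven significance
threshold, and consensus-DAG assembly.

Structure learning from a single sample understates model uncertainty, so the
data are resampled with replacement R times (200 by default), a constrained
hill-climb is run on each replicate, and each undirected pair's *strength* is
the fraction of replicates in which it appears in either direction; its
*direction* is the fraction, among those, pointing the majority way.  The
consensus DAG keeps every pair whose strength meets a threshold — either a
fixed value (0.85 gives the sparse, interpretable view) or one estimated from
the strength distribution itself.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .domain_data import RateTable
from .errors import CephbnError
from .gbn import ConstraintSet, Dag, hill_climb

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ArcStrength:
    strength: float      # frequency of the pair, either direction
    direction: float     # frequency of the majority direction, given presence
    orientation: tuple[str, str]  # the majority (parent, child)


@dataclasses.dataclass(frozen=True)
class StrengthTable:
    """Bootstrap arc/direction frequencies over unordered node pairs."""

    nodes: tuple[str, ...]
    entries: dict  # frozenset({a,b}) -> ArcStrength, pairs seen at least once
    replicates: int
    failures: int = 0

    def strength(self, a: str, b: str) -> float:
        e = self.entries.get(frozenset((a, b)))
        return e.strength if e else 0.0

    def strengths(self) -> list[float]:
        return [e.strength for e in self.entries.values()]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "from": e.orientation[0],
                "to": e.orientation[1],
                "strength": e.strength,
                "direction": e.direction,
            }
            for e in self.entries.values()
        ]
        return (
            pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
            .sort_values(["strength", "from", "to"], ascending=[False, True, True])
            .reset_index(drop=True)
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def bootstrap_strengths(table, constraints: Optional[ConstraintSet] = None,
                        R: int = 200, seed: int = 0) -> StrengthTable:
    """Arc strengths over R nonparametric bootstrap replicates.

    Each replicate draws n rows with replacement (resample size = original n)
    and runs :func:`hill_climb`; replicates that fail to learn are logged and
    excluded from the denominator.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    frame = table.frame if isinstance(table, RateTable) else pd.DataFrame(table)
    if frame.empty:
        raise ValueError("table is empty")
    rng = np.random.default_rng(seed)
    nodes = tuple(frame.columns)
    pair_counts: dict[frozenset, int] = {}
    dir_counts: dict[tuple[str, str], int] = {}
    failures = 0
    n = len(frame)
    for _ in range(R):
        idx = rng.integers(0, n, size=n)
        resample = frame.iloc[idx].reset_index(drop=True)
        try:
            dag = hill_climb(resample, constraints)
        except CephbnError as err:
            failures += 1
            logger.warning("bootstrap replicate failed to learn: %s", err)
            continue
        for arc in dag.arcs:
            pair = frozenset(arc)
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
            dir_counts[arc] = dir_counts.get(arc, 0) + 1
    denom = R - failures
    if denom == 0:
        raise CephbnError("every bootstrap replicate failed to learn")
    entries = {}
    for pair, count in pair_counts.items():
        a, b = sorted(pair)
        fwd = dir_counts.get((a, b), 0)
        rev = dir_counts.get((b, a), 0)
        orientation = (a, b) if fwd >= rev else (b, a)
        entries[pair] = ArcStrength(
            strength=count / denom,
            direction=max(fwd, rev) / count,
            orientation=orientation,
        )
    return StrengthTable(nodes, entries, replicates=R, failures=failures)


def estimate_threshold(strengths: StrengthTable) -> float:
    """Data-driven significance threshold for arc strengths.

    The observed strengths are compared with the ideal noiseless case, in
    which every arc has strength exactly 0 or exactly 1: the threshold is
    the candidate cut (midpoint between consecutive distinct observed
    strengths) minimising the L1 distance between the empirical strength CDF
    and the step CDF that declares everything below the cut noise and
    everything above it signal.  Ties resolve toward the smaller threshold;
    a fully uninformative table (all strengths identical) returns 0.5 with
    a warning.
    """
    values = sorted(strengths.strengths())
    if not values:
        raise ValueError("strength table has no entries")
    distinct = sorted(set(values))
    if len(distinct) == 1:
        warnings.warn("all arc strengths identical; returning threshold 0.5")
        return 0.5
    candidates = [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    m = len(values)
    # breakpoints of the empirical CDF on [0, 1]
    xs = [0.0] + distinct + [1.0]

    def l1(cut: float) -> float:
        noise = sum(v < cut for v in values) / m
        total = 0.0
        for left, right in zip(xs, xs[1:]):
            if right <= left:
                continue
            ecdf = sum(v <= left for v in values) / m
            total += abs(ecdf - noise) * (right - left)
        return total

    best = min(candidates, key=lambda c: (l1(c), c))
    return float(best)


def consensus_network(strengths: StrengthTable, threshold: float) -> Dag:
    """Assemble the consensus DAG from all pairs with strength >= threshold.

    Each retained pair is oriented along its majority direction.  Majority
    directions from different replicates can conflict and form cycles; in
    that case arcs are dropped weakest-first (by strength, then direction
    frequency, then lexicographic) until the graph is acyclic, each drop
    logged loudly.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept = [
        (e.orientation, e.strength, e.direction)
        for e in strengths.entries.values()
        if e.strength >= threshold
    ]
    arcs = {arc: (s, d) for arc, s, d in kept}
    g = nx.DiGraph()
    g.add_nodes_from(strengths.nodes)
    g.add_edges_from(arcs)
    while not nx.is_directed_acyclic_graph(g):
        comp_of = {}
        for cid, comp in enumerate(nx.strongly_connected_components(g)):
            if len(comp) > 1:
                for v in comp:
                    comp_of[v] = cid
        in_cycles = [
            arc for arc in arcs
            if g.has_edge(*arc)
            and comp_of.get(arc[0], -1) == comp_of.get(arc[1], -2)
        ]
        victim = min(in_cycles, key=lambda a: (arcs[a][0], arcs[a][1], a))
        logger.warning(
            "consensus assembly: dropping arc %s->%s (strength %.3f) to break a cycle",
            victim[0], victim[1], arcs[victim][0],
        )
        g.remove_edge(*victim)
        del arcs[victim]
    return Dag(strengths.nodes, frozenset(arcs))


def consensus_to_dot(strengths: StrengthTable, dag: Dag,
                     highlight=()) -> str:
    """DOT rendering with arc thickness proportional to bootstrap strength."""
    highlight = set(highlight)
    lines = ["digraph consensus {"]
    for v in dag.nodes:
        lines.append(f'  "{v}";')
    for p, c in sorted(dag.arcs):
        s = strengths.strength(p, c)
        attrs = [f"penwidth={max(0.5, 4 * s):.2f}", f'label="{s:.2f}"']
        if (p, c) in highlight:
            attrs.append('color="red"')
        lines.append(f'  "{p}" -> "{c}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines)
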