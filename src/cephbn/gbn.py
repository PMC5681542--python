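"""Linear-Gaussian Bayesian network core: BIC scoring, constrained
hill-climbing structure search, and ordinary-least-squares parameter fits.

Every node X_i carries a local linear-Gaussian model

    X_i = mu + beta_1 P_1 + ... + beta_k P_k + eps,   eps ~ N(0, sigma^2),

where P_1..P_k are the parents of X_i in the DAG, so the joint density
factorises as  p(X) = prod_i p(X_i | Pa(X_i)).  Structure search maximises
the decomposable network score

    score(G) = sum_i [ llik_i - (k_i / 2) * log n ],

the maximised Gaussian log-likelihood of each node's regression penalised
per the Bayesian Information Criterion, with k_i = |Pa(X_i)| + 2 free
parameters per node (intercept, slopes, variance).  Binary Treatment/Growth
columns are scored as Gaussian variables over their 0/1 codes, which keeps
the whitelist dT -> Growth expressible in a single unified likelihood.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .domain_data import (
    DELTA_COLUMNS,
    EXOGENOUS_COLUMNS,
    OUTCOME_COLUMNS,
    RateTable,
)
from .errors import ConstraintError, FittingError, ScoringError

#: Lower bound on residual standard deviations; guards logic sampling and
#: log-likelihoods against degenerate (noiseless) fits.
SD_FLOOR = 1e-6

#: Minimum score gain for a hill-climbing move to count as an improvement.
_SCORE_EPS = 1e-10

#: How far below the incumbent score a lookahead reversal sequence may dip.
_MAX_PLATEAU_DROP = 10.0


# ---------------------------------------------------------------------------
# Graph types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Dag:
    """Directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]]

    def __post_init__(self):
        node_set = set(self.nodes)
        for p, c in self.arcs:
            if p == c:
                raise ConstraintError(f"self-loop {p}->{c}")
            if p not in node_set or c not in node_set:
                raise ConstraintError(f"arc {p}->{c} references unknown node")
        self.topological_order()  # raises on cycles

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.arcs if c == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(c for p, c in self.arcs if p == node))

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; stable with respect to the node order."""
        indeg = {v: 0 for v in self.nodes}
        for _, c in self.arcs:
            indeg[c] += 1
        order, ready = [], [v for v in self.nodes if indeg[v] == 0]
        while ready:
            v = ready.pop(0)
            order.append(v)
            for c in self.children(v):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            raise ConstraintError("graph contains a cycle")
        return order

    def skeleton(self) -> frozenset[frozenset]:
        return frozenset(frozenset(a) for a in self.arcs)

    # -- text formats -------------------------------------------------------
    def to_dot(self, highlight: Iterable[tuple[str, str]] = ()) -> str:
        highlight = set(highlight)
        lines = ["digraph G {"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for p, c in sorted(self.arcs):
            attr = ' [color="red"]' if (p, c) in highlight else ""
            lines.append(f'  "{p}" -> "{c}"{attr};')
        lines.append("}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.arcs), columns=["parent", "child"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, nodes: Iterable[str]) -> "Dag":
        frame = pd.read_csv(path, sep="\t")
        arcs = frozenset(zip(frame["parent"], frame["child"]))
        return cls(tuple(nodes), arcs)


def skeleton_shd(a: Dag, b: Dag) -> int:
    """Structural Hamming distance between the skeletons of two DAGs."""
    return len(a.skeleton() ^ b.skeleton())


@dataclasses.dataclass(frozen=True)
class ConstraintSet:
    """Whitelisted (forced, directed) and blacklisted (forbidden, directed) arcs."""

    whitelist: frozenset[tuple[str, str]] = frozenset()
    blacklist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ConstraintError(f"arcs both whitelisted and blacklisted: {sorted(overlap)}")
        nodes = tuple(sorted({v for arc in self.whitelist for v in arc}))
        Dag(nodes, frozenset(self.whitelist))  # whitelist alone must be acyclic

    @classmethod
    def empty(cls) -> "ConstraintSet":
        return cls()


def default_constraints(columns: Iterable[str]) -> ConstraintSet:
    """The study's prior-knowledge tiers for a rate table's columns.

    * no arcs into dT or Treatment from anything (they are exogenous:
      patients are treated or not for the whole observation window);
    * no arcs from the feature deltas into Growth (the prognosis drives the
      features, not the reverse);
    * forced arcs dANB -> dIMPA <- dPPPM (dental compensation) and
      dT -> Growth (the prognosis may change over time).
    """
    columns = list(columns)
    feature_cols = [c for c in columns if c not in EXOGENOUS_COLUMNS + OUTCOME_COLUMNS]
    black = set()
    for sink in EXOGENOUS_COLUMNS:
        if sink in columns:
            black.update((src, sink) for src in columns if src != sink)
    if "Growth" in columns:
        black.update((f, "Growth") for f in feature_cols)
    white = set()
    for arc in (("dANB", "dIMPA"), ("dPPPM", "dIMPA"), ("dT", "Growth")):
        if arc[0] in columns and arc[1] in columns:
            white.add(arc)
    return ConstraintSet(frozenset(white), frozenset(black - white))


# ---------------------------------------------------------------------------
# Local models
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LocalModel:
    node: str
    parents: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    residual_sd: float

    def __post_init__(self):
        if len(self.coefficients) != len(self.parents):
            raise FittingError(f"{self.node}: coefficient/parent count mismatch")
        if self.residual_sd < SD_FLOOR:
            object.__setattr__(self, "residual_sd", SD_FLOOR)

    def mean(self, parent_values: Mapping[str, np.ndarray]) -> np.ndarray:
        mu = self.intercept
        for p, b in zip(self.parents, self.coefficients):
            mu = mu + b * np.asarray(parent_values[p])
        return np.asarray(mu, dtype=float)


@dataclasses.dataclass(frozen=True)
class FittedNetwork:
    """A DAG plus one linear-Gaussian local model per node."""

    dag: Dag
    locals: Mapping[str, LocalModel]
    sample_size: int

    def __post_init__(self):
        for v in self.dag.nodes:
            if v not in self.locals:
                raise FittingError(f"no local model for node {v}")
            if tuple(sorted(self.locals[v].parents)) != self.dag.parents(v):
                raise FittingError(f"local model for {v} disagrees with DAG parents")

    def to_json(self, path=None) -> str:
        payload = {
            "nodes": list(self.dag.nodes),
            "sample_size": self.sample_size,
            "locals": [
                {
                    "node": lm.node,
                    "parents": list(lm.parents),
                    "intercept": lm.intercept,
                    "coefficients": list(lm.coefficients),
                    "residual_sd": lm.residual_sd,
                }
                for lm in (self.locals[v] for v in self.dag.nodes)
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedNetwork":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        locals_ = {
            d["node"]: LocalModel(
                d["node"], tuple(d["parents"]), d["intercept"],
                tuple(d["coefficients"]), d["residual_sd"],
            )
            for d in payload["locals"]
        }
        arcs = frozenset(
            (p, lm.node) for lm in locals_.values() for p in lm.parents
        )
        dag = Dag(tuple(payload["nodes"]), arcs)
        return cls(dag, locals_, int(payload["sample_size"]))


def build_network(nodes: Iterable[str],
                  locals: Iterable[LocalModel],
                  sample_size: int = 0) -> FittedNetwork:
    """Assemble a FittedNetwork directly from local models (ground truths, tests)."""
    locals_ = {lm.node: lm for lm in locals}
    arcs = frozenset((p, lm.node) for lm in locals_.values() for p in lm.parents)
    return FittedNetwork(Dag(tuple(nodes), arcs), locals_, sample_size)


# ---------------------------------------------------------------------------
# BIC scoring (Gram-matrix backed, cached per dataset)
# ---------------------------------------------------------------------------

class Scorer:
    """Caches cross-product matrices and local BIC scores for one dataset.

    All local regressions over a given scope share the Gram matrix of
    [1, X]; any node-on-parents OLS then costs O(p^3) independent of n.
    Scopes touching a column with missing values (Growth) use the listwise-
    complete rows for that column set.
    """

    def __init__(self, frame: pd.DataFrame):
        self.columns = list(frame.columns)
        self._index = {c: i + 1 for i, c in enumerate(self.columns)}  # 0 = intercept
        X = np.column_stack([np.ones(len(frame)), frame.to_numpy(dtype=float)])
        self._nan_cols = frozenset(
            c for c in self.columns if np.isnan(frame[c].to_numpy(dtype=float)).any()
        )
        clean = X.copy()
        clean[np.isnan(clean)] = 0.0  # NaN columns never read from this gram
        self._gram_all = clean.T @ clean
        self._n_all = len(frame)
        complete = X[~np.isnan(X).any(axis=1)]
        self._gram_complete = complete.T @ complete
        self._n_complete = len(complete)
        self._cache: dict[tuple[str, frozenset], float] = {}
        self._warned_floor = False

    def _gram_for(self, scope: frozenset):
        if scope & self._nan_cols:
            return self._gram_complete, self._n_complete
        return self._gram_all, self._n_all

    def rss(self, node: str, parents: Iterable[str]) -> tuple[float, np.ndarray, int]:
        """Residual sum of squares, coefficient vector (intercept first), n."""
        parents = sorted(parents)
        gram, n = self._gram_for(frozenset([node, *parents]))
        idx = [0] + [self._index[p] for p in parents]
        yi = self._index[node]
        G = gram[np.ix_(idx, idx)]
        s = gram[idx, yi]
        syy = gram[yi, yi]
        try:
            L = np.linalg.cholesky(G)
        except np.linalg.LinAlgError as err:
            raise ScoringError(
                f"singular design for node {node} with parents {parents}"
            ) from err
        diag = np.diag(L)
        if diag.min() <= 1e-7 * np.sqrt(np.diag(G).max()):
            # numerically singular (e.g. duplicated or constant parent)
            raise ScoringError(
                f"singular design for node {node} with parents {parents}")
        beta = np.linalg.solve(L.T, np.linalg.solve(L, s))
        rss = max(float(syy - s @ beta), 0.0)
        return rss, beta, n

    def bic(self, node: str, parents: Iterable[str]) -> float:
        key = (node, frozenset(parents))
        if key in self._cache:
            return self._cache[key]
        rss, _, n = self.rss(node, key[1])
        if n < len(key[1]) + 2:
            raise ScoringError(f"too few rows ({n}) to score {node} | {sorted(key[1])}")
        sigma2 = rss / n
        if sigma2 < SD_FLOOR**2:
            if not self._warned_floor:
                warnings.warn(f"residual variance clamped at sd_floor^2 for node {node}")
                self._warned_floor = True
            sigma2 = SD_FLOOR**2
        llik = -0.5 * n * math.log(2 * math.pi * sigma2) - rss / (2 * sigma2)
        # scopes fitted on listwise-complete rows are rescaled to the full
        # sample size: log-likelihood magnitude grows with the row count, so
        # unrescaled scores would reward any parent set that shrinks the
        # complete-row set (every arc into the partially observed node would
        # look like a huge gain)
        llik *= self._n_all / n
        k = len(key[1]) + 2
        score = llik - 0.5 * k * math.log(self._n_all)
        self._cache[key] = score
        return score


def bic_local(node: str, parents: Iterable[str], table) -> float:
    """Local BIC score llik_hat - (k/2) log n of one node's regression."""
    frame = table.frame if isinstance(table, RateTable) else pd.DataFrame(table)
    return Scorer(frame).bic(node, parents)


def network_score(dag: Dag, table, scorer: Optional[Scorer] = None) -> float:
    """Total (decomposable) BIC score of a DAG on a dataset."""
    if scorer is None:
        frame = table.frame if isinstance(table, RateTable) else pd.DataFrame(table)
        scorer = Scorer(frame)
    return sum(scorer.bic(v, dag.parents(v)) for v in dag.nodes)


# ---------------------------------------------------------------------------
# Hill-climbing structure search
# ---------------------------------------------------------------------------

def _reachable(children: Mapping[str, set], src: str, dst: str) -> bool:
    stack, seen = [src], set()
    while stack:
        v = stack.pop()
        if v == dst:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(children[v])
    return False


class _Search:
    """Mutable hill-climbing state: parent/child sets plus cached local scores."""

    def __init__(self, nodes, cs: ConstraintSet, scorer: Scorer):
        self.nodes = nodes
        self.cs = cs
        self.scorer = scorer
        self.parents: dict[str, set] = {v: set() for v in nodes}
        self.children: dict[str, set] = {v: set() for v in nodes}
        for p, c in cs.whitelist:
            self.parents[c].add(p)
            self.children[p].add(c)
        self.local = {v: scorer.bic(v, self.parents[v]) for v in nodes}
        self.ordered_pairs = sorted((p, c) for p in nodes for c in nodes if p != c)

    def try_bic(self, node, pa):
        # moves whose family cannot be scored (e.g. a parent constant on the
        # listwise-complete rows) are simply unavailable
        try:
            return self.scorer.bic(node, pa)
        except ScoringError:
            return None

    def reversal_gain(self, p, c):
        """Score gain of reversing p->c, or None if illegal/unscorable."""
        if (p, c) in self.cs.whitelist or (c, p) in self.cs.blacklist:
            return None
        self.children[p].discard(c)
        cycle = _reachable(self.children, p, c)
        self.children[p].add(c)
        if cycle:
            return None
        s_c = self.try_bic(c, self.parents[c] - {p})
        s_p = self.try_bic(p, self.parents[p] | {c})
        if s_c is None or s_p is None:
            return None
        return s_c - self.local[c] + s_p - self.local[p]

    def best_move(self):
        """Best strictly-improving single move in lexicographic
        (parent, child, move-type) order; earlier candidates win ties."""
        best_gain, best_move = _SCORE_EPS, None
        for p, c in self.ordered_pairs:
            has_arc = c in self.children[p]
            # move types in lexicographic order: add < delete < reverse
            if not has_arc and (p, c) not in self.cs.blacklist:
                if not _reachable(self.children, c, p):  # no cycle
                    s = self.try_bic(c, self.parents[c] | {p})
                    if s is not None and s - self.local[c] > best_gain:
                        best_gain, best_move = s - self.local[c], ("add", p, c)
            if has_arc and (p, c) not in self.cs.whitelist:
                s = self.try_bic(c, self.parents[c] - {p})
                if s is not None and s - self.local[c] > best_gain:
                    best_gain, best_move = s - self.local[c], ("delete", p, c)
                g = self.reversal_gain(p, c)
                if g is not None and g > best_gain:
                    best_gain, best_move = g, ("reverse", p, c)
        return best_gain, best_move

    def apply(self, move):
        kind, p, c = move
        if kind == "add":
            self.parents[c].add(p)
            self.children[p].add(c)
        elif kind == "delete":
            self.parents[c].discard(p)
            self.children[p].discard(c)
        else:  # reverse p->c to c->p
            self.parents[c].discard(p)
            self.children[p].discard(c)
            self.parents[p].add(c)
            self.children[c].add(p)
            self.local[p] = self.scorer.bic(p, self.parents[p])
        self.local[c] = self.scorer.bic(c, self.parents[c])

    def arcset(self) -> frozenset:
        return frozenset((p, c) for c in self.nodes for p in self.parents[c])

    def set_arcs(self, arcs) -> None:
        for v in self.nodes:
            self.parents[v].clear()
            self.children[v].clear()
        for p, c in arcs:
            self.parents[c].add(p)
            self.children[p].add(c)
        self.local = {v: self.scorer.bic(v, self.parents[v]) for v in self.nodes}

    def neutral_reversals(self):
        """Legal reversals whose score gain is (numerically) zero —
        orientation changes within the same score-equivalence class."""
        out = []
        for p, c in self.ordered_pairs:
            if c not in self.children[p]:
                continue
            g = self.reversal_gain(p, c)
            if g is not None and abs(g) <= _SCORE_EPS:
                out.append((p, c))
        return out

    def dag(self) -> Dag:
        arcs = frozenset((p, c) for c in self.nodes for p in self.parents[c])
        return Dag(tuple(self.nodes), arcs)


def hill_climb(table, constraints: Optional[ConstraintSet] = None,
               seed: int = 0) -> Dag:
    """Greedy BIC maximisation over single-arc additions/deletions/reversals.

    Starts from the whitelist-only graph.  Candidate moves are evaluated in
    lexicographic (parent, child, move-type) order and the first move with
    the strictly largest score gain is applied.  At a local maximum the
    search additionally tries score-neutral ("sideways") arc reversals —
    Gaussian networks score identically across equivalent orientations, so
    greedy search otherwise stalls on plateaus around colliders — and
    commits one only when a strictly improving move follows, so the total
    score still increases strictly and the search terminates.  Whitelisted
    arcs are never deleted or reversed, blacklisted arcs never added.  The
    algorithm is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic stages.
    """
    del seed
    frame = table.frame if isinstance(table, RateTable) else pd.DataFrame(table)
    nodes = tuple(frame.columns)
    cs = constraints or ConstraintSet.empty()
    for p, c in cs.whitelist:
        if p not in nodes or c not in nodes:
            raise ConstraintError(f"whitelisted arc {p}->{c} references unknown column")

    state = _Search(nodes, cs, Scorer(frame))
    while True:
        _, move = state.best_move()
        if move is not None:
            state.apply(move)
            continue
        if not _plateau_escape(state):
            break
    return state.dag()


def _plateau_escape(state: _Search, max_states: int = 256) -> bool:
    """Bounded best-first lookahead over arc-reversal sequences from a local
    maximum.

    Gaussian networks score identically across equivalent arc orientations,
    so greedy search stalls on plateaus (e.g. a star oriented the wrong way
    around a collider) and in shallow dips where re-orienting several arcs
    must precede a profitable deletion.  This explores states reachable
    through reversal sequences whose cumulative score change stays above
    ``-_MAX_PLATEAU_DROP``, in deterministic best-first order capped at
    ``max_states`` visited states, and commits the first state from which a
    strictly improving single move makes the *total* gain positive.  Returns
    True if the state was advanced; the committed score strictly increases
    on every escape, so the outer climb still terminates.
    """
    import heapq

    origin = state.arcset()
    seen = {origin}
    counter = 0
    heap = [(-0.0, counter, 0.0, origin)]
    while heap and len(seen) <= max_states:
        _, _, cum, arcs = heapq.heappop(heap)
        state.set_arcs(arcs)
        if arcs != origin:
            gain, move = state.best_move()
            if move is not None and cum + gain > _SCORE_EPS:
                state.apply(move)
                return True
        for p, c in state.ordered_pairs:
            if c not in state.children[p]:
                continue
            g = state.reversal_gain(p, c)
            if g is None or cum + g < -_MAX_PLATEAU_DROP:
                continue
            nxt = (arcs - {(p, c)}) | {(c, p)}
            if nxt not in seen:
                seen.add(nxt)
                counter += 1
                heapq.heappush(heap, (-(cum + g), counter, cum + g, nxt))
    state.set_arcs(origin)
    return False


def exhaustive_search(table, constraints: Optional[ConstraintSet] = None) -> tuple[Dag, float]:
    """Best-scoring DAG by brute-force enumeration (small node sets only)."""
    frame = table.frame if isinstance(table, RateTable) else pd.DataFrame(table)
    nodes = tuple(frame.columns)
    if len(nodes) > 4:
        raise ValueError("exhaustive search supported for <= 4 nodes")
    cs = constraints or ConstraintSet.empty()
    scorer = Scorer(frame)
    pairs = [(p, c) for p in nodes for c in nodes
             if p != c and (p, c) not in cs.blacklist]
    best = None
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            arcs = frozenset(combo) | cs.whitelist
            try:
                dag = Dag(nodes, arcs)
                score = network_score(dag, None, scorer=scorer)
            except (ConstraintError, ScoringError):
                continue
            if best is None or score > best[1]:
                best = (dag, score)
    return best


# ---------------------------------------------------------------------------
# Parameter learning
# ---------------------------------------------------------------------------

def fit_ols(dag: Dag, table) -> FittedNetwork:
    """Ordinary-least-squares fit of every local model on the DAG.

    Residual standard deviations use the maximum-likelihood convention
    (denominator n), matching :func:`bic_local`, and are floored at
    :data:`SD_FLOOR`.  Local models whose scope includes a column with
    missing values are fitted on the listwise-complete rows.
    """
    frame = table.frame if isinstance(table, RateTable) else pd.DataFrame(table)
    locals_ = {}
    for node in dag.nodes:
        pa = dag.parents(node)
        sub = frame[[node, *pa]].dropna()
        n = len(sub)
        if n <= len(pa) + 1:
            raise FittingError(f"node {node}: {n} rows for {len(pa)} parents")
        X = np.column_stack([np.ones(n)] + [sub[p].to_numpy(dtype=float) for p in pa])
        y = sub[node].to_numpy(dtype=float)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise FittingError(f"singular design for node {node} (collinear parents)")
        resid = y - X @ beta
        sd = max(float(np.sqrt(resid @ resid / n)), SD_FLOOR)
        locals_[node] = LocalModel(node, pa, float(beta[0]), tuple(map(float, beta[1:])), sd)
    return FittedNetwork(dag, locals_, len(frame))
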