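"""Forward (logic) sampling, conditional-probability queries, the exact
Gaussian conditioning oracle, and do-style graph mutilation.

Logic sampling draws joint samples by visiting nodes in topological order and
sampling each from N(intercept + beta . parents, residual_sd^2).  Conditional
queries are answered by rejection: the estimate is n_{E,q} / n_E, the number
of draws matching both evidence and event over the number matching the
evidence, with a binomial Monte-Carlo standard error.  Because every node is
Gaussian, the network also implies a joint multivariate normal whose exact
conditional distributions serve as a deterministic oracle and as the
cross-validation predictor.

Evidence on continuous nodes is interval-valued (a point has probability zero
under forward sampling); a scalar constraint on a continuous node is widened
to value +/- half_width.  Binary nodes (Treatment, Growth) are sampled as
Gaussian and then thresholded at 0.5, and scalar constraints on them compare
against the thresholded 0/1 value.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import QueryError
from .gbn import SD_FLOOR, Dag, FittedNetwork, LocalModel

#: Columns treated as binary (thresholded at 0.5) when present in a network.
BINARY_NODES = ("Treatment", "Growth")

Constraint = Union[float, tuple]  # scalar (equality) or (low, high) interval


# ---------------------------------------------------------------------------
# Forward sampling
# ---------------------------------------------------------------------------

def logic_sample(net: FittedNetwork, n: int, seed: int,
                 given: Optional[Mapping[str, np.ndarray]] = None) -> pd.DataFrame:
    """Draw ``n`` joint samples by ancestral (logic) sampling.

    ``given`` optionally supplies fixed value arrays for a subset of nodes
    (used by the cohort simulator to impose non-Gaussian exogenous draws);
    those nodes are copied instead of sampled, all others are drawn from
    their local models as usual.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    given = given or {}
    values: dict[str, np.ndarray] = {}
    for node in net.dag.topological_order():
        if node in given:
            arr = np.broadcast_to(np.asarray(given[node], dtype=float), (n,))
            values[node] = np.array(arr)
            continue
        lm = net.locals[node]
        mu = lm.mean(values) if lm.parents else np.full(n, lm.intercept)
        values[node] = mu + rng.normal(0.0, lm.residual_sd, size=n)
    return pd.DataFrame({v: values[v] for v in net.dag.nodes})


# ---------------------------------------------------------------------------
# Query specification and rejection-sampling estimates
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class QuerySpec:
    """A conditional query: P(event | evidence) or E[target | evidence].

    ``event`` is either a mapping node -> constraint (conjunction of interval
    or equality constraints) for a probability query, or a node name for a
    posterior-mean query.  ``evidence`` is a mapping of the same constraint
    form (possibly empty).  Scalar constraints on continuous nodes become
    intervals of half-width ``half_width``.
    """

    event: Union[Mapping[str, Constraint], str]
    evidence: Mapping[str, Constraint] = dataclasses.field(default_factory=dict)
    n_samples: int = 10_000
    half_width: float = 0.1

    def __post_init__(self):
        if self.n_samples < 1:
            raise QueryError("n_samples must be >= 1")

    @classmethod
    def from_document(cls, doc: Mapping) -> "QuerySpec":
        """Build a query from a plain JSON-style document:
        {"event": ..., "evidence": ..., "n_samples": ..., "half_width": ...};
        interval constraints are 2-element lists (null = unbounded)."""

        def constraints(raw):
            if isinstance(raw, str):
                return raw
            return {node: tuple(v) if isinstance(v, (list, tuple)) else v
                    for node, v in raw.items()}

        return cls(
            event=constraints(doc["event"]),
            evidence=constraints(doc.get("evidence", {})),
            n_samples=int(doc.get("n_samples", 10_000)),
            half_width=float(doc.get("half_width", 0.1)),
        )


@dataclasses.dataclass(frozen=True)
class QueryResult:
    estimate: Optional[float]
    n_matched_evidence: int
    mc_se: Optional[float]
    n_samples: int

    @property
    def no_match(self) -> bool:
        return self.n_matched_evidence == 0

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "n_E": self.n_matched_evidence,
                "mc_se": self.mc_se, "n_samples": self.n_samples}


def _constraint_mask(samples: pd.DataFrame, node: str, constraint: Constraint,
                     binary: frozenset, half_width: float) -> np.ndarray:
    if node not in samples.columns:
        raise QueryError(f"constraint references unknown node {node!r}")
    x = samples[node].to_numpy()
    if node in binary:
        x = (x >= 0.5).astype(float)
    if isinstance(constraint, tuple):
        lo, hi = constraint
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        return (x >= lo) & (x <= hi)
    if node in binary:
        return x == float(constraint)
    v = float(constraint)
    return (x >= v - half_width) & (x <= v + half_width)


def _match(samples: pd.DataFrame, constraints: Mapping[str, Constraint],
           binary: frozenset, half_width: float) -> np.ndarray:
    mask = np.ones(len(samples), dtype=bool)
    for node, constraint in constraints.items():
        mask &= _constraint_mask(samples, node, constraint, binary, half_width)
    return mask


def conditional_query(net: FittedNetwork, query: QuerySpec, seed: int,
                      binary: Optional[Sequence[str]] = None) -> QueryResult:
    """Estimate a conditional probability (or posterior mean) by rejection.

    Returns an explicit no-match result (``estimate is None``) when no draw
    satisfies the evidence.
    """
    if binary is None:
        binary = [b for b in BINARY_NODES if b in net.dag.nodes]
    binary = frozenset(binary)
    samples = logic_sample(net, query.n_samples, seed)
    ev = _match(samples, query.evidence, binary, query.half_width)
    n_e = int(ev.sum())
    if n_e == 0:
        return QueryResult(None, 0, None, query.n_samples)
    if isinstance(query.event, str):  # posterior mean of a node
        x = samples.loc[ev, query.event].to_numpy()
        if query.event in binary:
            x = (x >= 0.5).astype(float)
        se = float(x.std(ddof=1) / np.sqrt(n_e)) if n_e > 1 else None
        return QueryResult(float(x.mean()), n_e, se, query.n_samples)
    both = ev & _match(samples, query.event, binary, query.half_width)
    p = both.sum() / n_e
    se = float(np.sqrt(p * (1 - p) / n_e))
    return QueryResult(float(p), n_e, se, query.n_samples)


# ---------------------------------------------------------------------------
# Exact Gaussian oracle
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GaussianSummary:
    """Means and covariances of a set of (possibly conditioned) nodes."""

    nodes: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def marginal(self, subset: Sequence[str]) -> "GaussianSummary":
        idx = [self.nodes.index(v) for v in subset]
        return GaussianSummary(tuple(subset), self.mean[idx], self.cov[np.ix_(idx, idx)])


def implied_moments(net: FittedNetwork) -> GaussianSummary:
    """The joint multivariate normal implied by the network.

    Computed by topological recursion over the local models:
    m_v = mu_v + beta . m_pa;  cov(v, u) = beta . cov(pa, u);
    var(v) = beta' cov(pa, pa) beta + sigma_v^2.
    """
    nodes = list(net.dag.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    p = len(nodes)
    mean = np.zeros(p)
    cov = np.zeros((p, p))
    for v in net.dag.topological_order():
        lm = net.locals[v]
        i = idx[v]
        pa = [idx[q] for q in lm.parents]
        beta = np.asarray(lm.coefficients)
        mean[i] = lm.intercept + beta @ mean[pa] if pa else lm.intercept
        if pa:
            cross = beta @ cov[np.ix_(pa, range(p))]
            cov[i, :] = cross
            cov[:, i] = cross
            cov[i, i] = float(beta @ cov[np.ix_(pa, pa)] @ beta) + lm.residual_sd**2
        else:
            cov[i, i] = lm.residual_sd**2
    return GaussianSummary(tuple(nodes), mean, cov)


def exact_conditional(net: FittedNetwork,
                      evidence: Mapping[str, float]) -> GaussianSummary:
    """Exact conditional normal of the remaining nodes given point evidence.

    With empty evidence this returns the implied joint unchanged.  The
    conditioning solve uses a pseudo-inverse so that (near-)deterministic
    networks — residual variances at the floor — remain well-defined.
    """
    joint = implied_moments(net)
    if not evidence:
        return joint
    nodes = list(joint.nodes)
    for v in evidence:
        if v not in nodes:
            raise QueryError(f"evidence references unknown node {v!r}")
    e_idx = [i for i, v in enumerate(nodes) if v in evidence]
    r_idx = [i for i, v in enumerate(nodes) if v not in evidence]
    x_e = np.array([float(evidence[nodes[i]]) for i in e_idx])
    S_ee = joint.cov[np.ix_(e_idx, e_idx)]
    S_re = joint.cov[np.ix_(r_idx, e_idx)]
    S_rr = joint.cov[np.ix_(r_idx, r_idx)]
    gain = S_re @ np.linalg.pinv(S_ee, hermitian=True, rcond=1e-12)
    mean = joint.mean[r_idx] + gain @ (x_e - joint.mean[e_idx])
    cov = S_rr - gain @ S_re.T
    d = np.diag(cov).copy()
    d[d < 0] = 0.0
    np.fill_diagonal(cov, d)
    return GaussianSummary(tuple(nodes[i] for i in r_idx), mean, cov)


# ---------------------------------------------------------------------------
# Interventions
# ---------------------------------------------------------------------------

def intervene_fix(net: FittedNetwork, node: str, value: float) -> FittedNetwork:
    """Graph mutilation do(node = value): remove all arcs into ``node`` and
    replace its local model by a point mass (intercept = value, sd at floor)."""
    if node not in net.dag.nodes:
        raise QueryError(f"unknown node {node!r}")
    arcs = frozenset(a for a in net.dag.arcs if a[1] != node)
    locals_ = dict(net.locals)
    locals_[node] = LocalModel(node, (), float(value), (), SD_FLOOR)
    return FittedNetwork(Dag(net.dag.nodes, arcs), locals_, net.sample_size)
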