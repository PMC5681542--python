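"""Clinical hypothesis queries over a fitted network, and treated/untreated
subgroup consensus networks.

The four scripted checks mirror common clinical expectations for Class III
malocclusion and are pure compositions of the inference primitives:

1. ramus growth vs palatal plane: the simulated-regression slope of dPPPM on
   dCoGo (expected negative in clinically plausible networks);
2. dental compensation: the slope of dANB on dIMPA (expected positive);
3. prognosis and treatment: P(Growth good | Treatment) for treated vs
   untreated draws, before and after the do-intervention dANB := 0;
4. mandibular proxy: with dGoPg held at 0 by intervention, the posterior
   mean of dANB for treated vs untreated draws.

Every output carries a Monte-Carlo standard error; no bare point estimates.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
from scipy import stats

from .averaging import StrengthTable, bootstrap_strengths, consensus_network, estimate_threshold
from .domain_data import RateTable
from .errors import CephbnError
from .gbn import SD_FLOOR, ConstraintSet, Dag, FittedNetwork, default_constraints
from .inference import QueryResult, QuerySpec, conditional_query, intervene_fix, logic_sample


@dataclasses.dataclass(frozen=True)
class SlopeResult:
    slope: float
    se: float
    sign: int
    n: int


def slope_query(net: FittedNetwork, x: str, y: str, n: int = 10_000,
                seed: int = 0) -> SlopeResult:
    """OLS slope of y on x over n logic samples (the simulated-regression check)."""
    for v in (x, y):
        if v not in net.dag.nodes:
            raise CephbnError(f"unknown node {v!r}")
    samples = logic_sample(net, n, seed)
    xv = samples[x].to_numpy()
    if xv.std() <= 10 * SD_FLOOR:  # e.g. a node held fixed by intervention
        raise CephbnError(f"degenerate variance for {x!r}")
    fit = stats.linregress(xv, samples[y].to_numpy())
    return SlopeResult(float(fit.slope), float(fit.stderr),
                       int(np.sign(fit.slope)), n)


@dataclasses.dataclass(frozen=True)
class PrognosisResult:
    treated: QueryResult
    untreated: QueryResult

    @property
    def combined_se(self) -> Optional[float]:
        if self.treated.mc_se is None or self.untreated.mc_se is None:
            return None
        return float(np.hypot(self.treated.mc_se, self.untreated.mc_se))


def prognosis_query(net: FittedNetwork,
                    intervention: Optional[tuple[str, float]] = None,
                    n: int = 10_000, seed: int = 0) -> PrognosisResult:
    """P(Growth = good | Treatment = 1) and P(Growth = good | Treatment = 0).

    ``intervention=(node, value)`` first applies the do-style mutilation
    (e.g. ``("dANB", 0.0)`` emulates a treatment that freezes the sagittal
    imbalance).
    """
    for v in ("Growth", "Treatment"):
        if v not in net.dag.nodes:
            raise CephbnError(f"network lacks node {v!r}")
    if intervention is not None:
        net = intervene_fix(net, *intervention)
    out = {}
    for label, t in (("treated", 1), ("untreated", 0)):
        q = QuerySpec(event={"Growth": 1}, evidence={"Treatment": t}, n_samples=n)
        out[label] = conditional_query(net, q, seed=seed + (0 if t else 1))
    return PrognosisResult(out["treated"], out["untreated"])


@dataclasses.dataclass(frozen=True)
class ContrastResult:
    treated: QueryResult
    untreated: QueryResult

    @property
    def difference(self) -> Optional[float]:
        if self.treated.estimate is None or self.untreated.estimate is None:
            return None
        return self.treated.estimate - self.untreated.estimate


def anb_contrast(net: FittedNetwork, n: int = 10_000, seed: int = 0,
                 fixed: tuple[str, float] = ("dGoPg", 0.0)) -> ContrastResult:
    """Posterior mean of dANB for treated vs untreated draws with dGoPg
    held at 0 by intervention (GoPg as a proxy for skeletal point B)."""
    mutilated = intervene_fix(net, *fixed)
    out = {}
    for label, t in (("treated", 1), ("untreated", 0)):
        q = QuerySpec(event="dANB", evidence={"Treatment": t}, n_samples=n)
        out[label] = conditional_query(mutilated, q, seed=seed + (0 if t else 1))
    return ContrastResult(out["treated"], out["untreated"])


def run_hypotheses(net: FittedNetwork, n: int = 10_000, seed: int = 0) -> dict:
    """Consolidated report of the four hypothesis queries (JSON-ready)."""
    h1 = slope_query(net, "dCoGo", "dPPPM", n=n, seed=seed)
    h2 = slope_query(net, "dIMPA", "dANB", n=n, seed=seed + 1)
    h3_pre = prognosis_query(net, n=n, seed=seed + 2)
    h3_post = prognosis_query(net, intervention=("dANB", 0.0), n=n, seed=seed + 4)
    h4 = anb_contrast(net, n=n, seed=seed + 6)

    def _q(r: QueryResult) -> dict:
        return {"estimate": r.estimate, "n_matched_evidence": r.n_matched_evidence,
                "mc_se": r.mc_se}

    return {
        "ramus_vs_palatal_plane": {"slope": h1.slope, "se": h1.se, "sign": h1.sign},
        "dental_compensation": {"slope": h2.slope, "se": h2.se, "sign": h2.sign},
        "prognosis": {
            "treated": _q(h3_pre.treated),
            "untreated": _q(h3_pre.untreated),
            "after_fixing_dANB": {
                "treated": _q(h3_post.treated),
                "untreated": _q(h3_post.untreated),
            },
        },
        "dANB_with_dGoPg_fixed": {
            "treated": _q(h4.treated),
            "untreated": _q(h4.untreated),
            "difference": h4.difference,
        },
        "n_samples": n,
    }


def format_report(report: dict) -> str:
    """Plain-text table of :func:`run_hypotheses` output."""
    lines = [
        f"{'query':<42}{'estimate':>12}{'mc se':>10}",
        "-" * 64,
        f"{'slope dPPPM ~ dCoGo':<42}{report['ramus_vs_palatal_plane']['slope']:>12.3f}"
        f"{report['ramus_vs_palatal_plane']['se']:>10.3f}",
        f"{'slope dANB ~ dIMPA':<42}{report['dental_compensation']['slope']:>12.3f}"
        f"{report['dental_compensation']['se']:>10.3f}",
    ]
    prog = report["prognosis"]
    for label in ("treated", "untreated"):
        q = prog[label]
        lines.append(f"{'P(good grower | ' + label + ')':<42}"
                     f"{q['estimate']:>12.3f}{q['mc_se']:>10.3f}")
    for label in ("treated", "untreated"):
        q = prog["after_fixing_dANB"][label]
        lines.append(f"{'  ... after do(dANB=0), ' + label:<42}"
                     f"{q['estimate']:>12.3f}{q['mc_se']:>10.3f}")
    for label in ("treated", "untreated"):
        q = report["dANB_with_dGoPg_fixed"][label]
        lines.append(f"{'E[dANB | do(dGoPg=0), ' + label + ']':<42}"
                     f"{q['estimate']:>12.3f}{q['mc_se']:>10.3f}")
    return "\n".join(lines)


def subgroup_networks(table, constraints: Optional[ConstraintSet] = None,
                      R: int = 200, seed: int = 0,
                      threshold: Optional[float] = None,
                      min_rows: int = 20) -> dict[str, tuple[Dag, StrengthTable, float]]:
    """Separate consensus networks for treated and untreated patients.

    Splits the rows by Treatment, drops the (now constant) Treatment column,
    and runs the full bootstrap-consensus pipeline within each subgroup.
    Returns {"treated" | "untreated": (consensus DAG, strengths, threshold)}.
    """
    frame = table.frame if isinstance(table, RateTable) else table
    out = {}
    for label, flag in (("treated", 1.0), ("untreated", 0.0)):
        sub = frame[frame["Treatment"] == flag].drop(columns=["Treatment"])
        if len(sub) < min_rows:
            raise CephbnError(
                f"{label} subgroup has {len(sub)} rows (< {min_rows} required)"
            )
        cs = constraints if constraints is not None else default_constraints(frame.columns)
        cs_sub = ConstraintSet(
            frozenset(a for a in cs.whitelist if "Treatment" not in a),
            frozenset(a for a in cs.blacklist if "Treatment" not in a),
        )
        st = bootstrap_strengths(sub, cs_sub, R=R, seed=seed + (0 if flag else 1))
        thr = estimate_threshold(st) if threshold is None else threshold
        out[label] = (consensus_network(st, thr), st, thr)
    return out
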