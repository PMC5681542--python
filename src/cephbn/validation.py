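"""10-fold cross-validation of the full learning pipeline.

For each fold, structure (optionally bootstrap-averaged) and parameters are
learned on the training rows; each variable of each test row is then
predicted from *all the other variables of that row* via the exact
conditional mean of the fitted network's implied multivariate normal.  The
pooled (observed, predicted) pairs give a predictive correlation per
continuous variable; Growth predictions are thresholded at 0.5 and summarised
as a misclassification fraction.  Rows with missing Growth are excluded from
Growth's metric but still contribute to the feature metrics (their prediction
conditions on one variable fewer).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
import pandas as pd

from .averaging import bootstrap_strengths, consensus_network, estimate_threshold
from .correlation import pearson
from .domain_data import RateTable
from .errors import CephbnError, FittingError, UndefinedCorrelationError
from .gbn import ConstraintSet, fit_ols, hill_climb
from .inference import implied_moments

_PREDICT_RCOND = 1e-12


def classification_error(observed, predicted) -> float:
    """Fraction of positions where observed != predicted (0/1 sequences)."""
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-d and equal length")
    if len(observed) < 1:
        raise ValueError("need at least one observation")
    return float(np.mean(observed != predicted))


@dataclasses.dataclass(frozen=True)
class CVReport:
    predictive_correlation: dict[str, float]
    classification_error: Optional[float]
    fold_assignments: dict[str, int]
    k: int
    pairs: pd.DataFrame  # columns: patient, variable, observed, predicted

    def to_json(self, path=None) -> str:
        payload = {
            "k": self.k,
            "predictive_correlation": self.predictive_correlation,
            "classification_error": self.classification_error,
            "fold_assignments": self.fold_assignments,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def pairs_to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)


def _assign_folds(frame: pd.DataFrame, k: int, seed: int,
                  stratify: bool) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.empty(len(frame), dtype=int)
    if stratify:
        for _, idx in frame.groupby("Treatment").indices.items():
            perm = rng.permutation(idx)
            folds[perm] = np.arange(len(perm)) % k
    else:
        perm = rng.permutation(len(frame))
        folds[perm] = np.arange(len(frame)) % k
    return folds


def _conditional_mean_rows(moments, target: str, evidence_nodes: list[str],
                           rows: pd.DataFrame) -> np.ndarray:
    """Exact conditional mean of ``target`` given the evidence columns, per row."""
    nodes = list(moments.nodes)
    t = nodes.index(target)
    e_idx = [nodes.index(v) for v in evidence_nodes]
    S_ee = moments.cov[np.ix_(e_idx, e_idx)]
    s_te = moments.cov[t, e_idx]
    gain = s_te @ np.linalg.pinv(S_ee, hermitian=True, rcond=_PREDICT_RCOND)
    X = rows[evidence_nodes].to_numpy(dtype=float)
    return moments.mean[t] + (X - moments.mean[e_idx]) @ gain


def cross_validate(table, constraints: Optional[ConstraintSet] = None,
                   k: int = 10, averaging: bool = False, R: int = 200,
                   threshold: Optional[float] = None, seed: int = 0,
                   stratify: bool = False) -> CVReport:
    """k-fold cross-validation with per-variable predictive correlation.

    With ``averaging=True`` each training fold runs the full bootstrap
    consensus (R replicates; ``threshold=None`` estimates it from the fold's
    strengths), otherwise a single hill-climb.  Fold assignment is a seeded
    uniform shuffle (optionally stratified by Treatment).
    """
    frame = (table.frame if isinstance(table, RateTable) else pd.DataFrame(table))
    n = len(frame)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} rows for {k}-fold CV, got {n}")
    folds = _assign_folds(frame, k, seed, stratify)
    continuous = [c for c in frame.columns if c not in ("Treatment", "Growth")]
    records = []
    for fold in range(k):
        test = frame.iloc[folds == fold]
        train = frame.iloc[folds != fold]
        try:
            if averaging:
                st = bootstrap_strengths(train, constraints, R=R,
                                         seed=int(seed) * k + fold)
                thr = estimate_threshold(st) if threshold is None else threshold
                dag = consensus_network(st, thr)
            else:
                dag = hill_climb(train, constraints)
            net = fit_ols(dag, train)
        except (CephbnError, FittingError) as err:
            raise CephbnError(f"fold {fold}: {err}") from err
        moments = implied_moments(net)
        # group test rows by missingness pattern (Growth present/absent)
        growth_missing = test["Growth"].isna() if "Growth" in test else pd.Series(False, index=test.index)
        for missing, rows in test.groupby(growth_missing):
            if rows.empty:
                continue
            available = [c for c in frame.columns if not (missing and c == "Growth")]
            for target in frame.columns:
                if missing and target == "Growth":
                    continue
                evidence = [c for c in available if c != target]
                pred = _conditional_mean_rows(moments, target, evidence, rows)
                for pid, obs, pr in zip(rows.index, rows[target], pred):
                    records.append((str(pid), fold, target, float(obs), float(pr)))
    pairs = pd.DataFrame(records, columns=["patient", "fold", "variable",
                                           "observed", "predicted"])
    predictive = {}
    for var in continuous:
        sub = pairs[pairs["variable"] == var]
        try:
            predictive[var] = pearson(sub["observed"], sub["predicted"])
        except UndefinedCorrelationError:
            predictive[var] = float("nan")  # constant predictions (isolated node)
    cls_err = None
    growth = pairs[pairs["variable"] == "Growth"]
    if len(growth):
        cls_err = classification_error(
            growth["observed"].to_numpy(),
            (growth["predicted"].to_numpy() >= 0.5).astype(float),
        )
    assignments = {str(pid): int(f) for pid, f in zip(frame.index, folds)}
    return CVReport(predictive, cls_err, assignments, k, pairs)
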