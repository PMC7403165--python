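"""Per-participant mixture weights over grapheme-phoneme rule types.

Each participant's per-condition response proportions are modeled as a convex
combination of the three rule types' corpus conditional distributions:

    P(category | condition) = sum_j beta_j * P(category | rule_j, condition)

The constrained fit minimises the sum of squared residuals over all
(condition, modeled category) cells subject to beta_j in [0, 1] and
sum_j beta_j = 1 (the weights are interpreted as the probability that the
reader relies on each rule type).  The relaxed variant drops the simplex
constraints entirely — both the sum-to-one equality and the box bounds — so
it reduces to ordinary linear least squares and can return negative weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .design import CorpusProbabilityTable, StudyDesign

log = logging.getLogger(__name__)

_RANK_TOL = 1e-10
_LOSS_TOL = 1e-8


@dataclass
class WeightFit:
    """Result of fitting one participant's rule-type weights."""

    participant_id: str
    beta: np.ndarray
    loss: float
    constrained: bool
    converged: bool
    identifiable: bool
    n_conditions_used: int
    rule_types: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        d = {"participant_id": self.participant_id}
        for name, b in zip(self.rule_types, self.beta):
            d[f"beta_{name}"] = float(b)
        d.update(
            loss=float(self.loss),
            constrained=self.constrained,
            converged=self.converged,
            identifiable=self.identifiable,
            n_conditions_used=self.n_conditions_used,
        )
        return d


def predict_probabilities(
    beta: np.ndarray,
    probs: CorpusProbabilityTable,
    condition: str,
    design: StudyDesign,
) -> dict[str, float]:
    """Predicted probability of each modeled category in *condition* under
    weight vector *beta* (ordered as ``design.rule_types``)."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (3,):
        raise ValueError("beta must be a length-3 vector")
    mat = probs.rule_matrix(design, condition)  # (n_categories, 3)
    pred = mat @ beta
    return dict(zip(design.response_categories, pred.tolist()))


def observed_proportions(
    df: pd.DataFrame,
    participant_id: str,
    design: StudyDesign,
    renormalize_modeled: bool = False,
) -> tuple[dict[tuple[str, str], float], list[str]]:
    """Per-condition observed proportions of the modeled categories for one
    participant, among their non-error trials.

    By default the denominator is all non-error trials in the condition, so
    unmodeled vowel responses dilute the modeled proportions without being
    fitted themselves; with ``renormalize_modeled=True`` the denominator is
    restricted to modeled-category trials.

    Returns ``(proportions, dropped_conditions)`` where ``proportions`` maps
    (condition, category) to a proportion and ``dropped_conditions`` lists
    conditions with no usable trials.
    """
    sub = df[(df["participant_id"] == participant_id) & ~df["is_error"]]
    out: dict[tuple[str, str], float] = {}
    dropped: list[str] = []
    for cond in design.conditions:
        cdf = sub[sub["condition"] == cond]
        if renormalize_modeled:
            cdf = cdf[cdf["response_category"].isin(design.response_categories)]
        n = len(cdf)
        if n == 0:
            dropped.append(cond)
            continue
        counts = cdf["response_category"].value_counts()
        for cat in design.response_categories:
            out[(cond, cat)] = float(counts.get(cat, 0)) / n
    if dropped:
        log.info(
            "participant %s: no usable trials in condition(s) %s; dropped from fit",
            participant_id, dropped,
        )
    return out, dropped


def _design_matrix(
    observed: dict[tuple[str, str], float],
    probs: CorpusProbabilityTable,
    design: StudyDesign,
) -> tuple[np.ndarray, np.ndarray, int]:
    conditions = [c for c in design.conditions if any(k[0] == c for k in observed)]
    if len(conditions) < 2:
        raise ValueError(
            f"need observed data in at least 2 conditions, got {len(conditions)}"
        )
    rows, y = [], []
    for cond in conditions:
        mat = probs.rule_matrix(design, cond)
        for i, cat in enumerate(design.response_categories):
            rows.append(mat[i])
            y.append(observed[(cond, cat)])
    return np.array(rows), np.array(y), len(conditions)


_N_RANDOM_STARTS = 6


def _simplex_starts(rng: np.random.Generator) -> np.ndarray:
    """10 multi-start points: the 3 simplex vertices, the barycentre, and 6
    seeded random interior points."""
    starts = [np.eye(3)[i] for i in range(3)]
    starts.append(np.full(3, 1.0 / 3.0))
    starts.extend(rng.dirichlet(np.ones(3)) for _ in range(_N_RANDOM_STARTS))
    return np.array(starts)


def fit_weights(
    observed: dict[tuple[str, str], float],
    probs: CorpusProbabilityTable,
    design: StudyDesign,
    constrained: bool = True,
    participant_id: str = "",
) -> WeightFit:
    """Least-squares fit of the rule-type weights to observed proportions.

    Constrained fits solve the quadratic program on the probability simplex
    with SLSQP from 10 starting points; relaxed fits use the closed-form
    normal equations.  ``identifiable`` is False when the three rule
    prediction vectors are linearly dependent (rank < 3 at tolerance 1e-10),
    in which case the returned beta is one of many equal-loss optima.
    """
    A, y, n_cond = _design_matrix(observed, probs, design)
    identifiable = np.linalg.matrix_rank(A, tol=_RANK_TOL) == 3

    def loss(b: np.ndarray) -> float:
        r = A @ b - y
        return float(r @ r)

    def grad(b: np.ndarray) -> np.ndarray:
        return 2.0 * A.T @ (A @ b - y)

    if not constrained:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return WeightFit(
            participant_id=participant_id,
            beta=beta,
            loss=loss(beta),
            constrained=False,
            converged=True,
            identifiable=identifiable,
            n_conditions_used=n_cond,
            rule_types=design.rule_types,
        )

    rng = np.random.default_rng(0)  # fixed: multi-starts are part of the algorithm
    best, best_loss, any_success = None, np.inf, False
    for x0 in _simplex_starts(rng):
        res = optimize.minimize(
            loss,
            x0,
            jac=grad,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * 3,
            constraints=[{"type": "eq", "fun": lambda b: b.sum() - 1.0,
                          "jac": lambda b: np.ones(3)}],
            options={"ftol": _LOSS_TOL * 1e-4, "maxiter": 200},
        )
        b = np.clip(res.x, 0.0, 1.0)
        b = b / b.sum()
        l = loss(b)
        any_success = any_success or res.success
        if l < best_loss - 0.0:
            best, best_loss = b, l
    if not any_success:
        log.warning("fit_weights: no SLSQP start converged for %s", participant_id)
    return WeightFit(
        participant_id=participant_id,
        beta=best,
        loss=best_loss,
        constrained=True,
        converged=any_success,
        identifiable=identifiable,
        n_conditions_used=n_cond,
        rule_types=design.rule_types,
    )


def fit_all_participants(
    df: pd.DataFrame,
    probs: CorpusProbabilityTable,
    design: StudyDesign,
    constrained: bool = True,
    renormalize_modeled: bool = False,
) -> list[WeightFit]:
    """Fit every participant in a validated, pre-filtered response table."""
    fits = []
    for pid in df["participant_id"].unique():
        obs, _ = observed_proportions(df, pid, design, renormalize_modeled)
        try:
            fits.append(
                fit_weights(
                    obs, probs, design, constrained=constrained, participant_id=pid
                )
            )
        except ValueError as exc:
            log.warning("skipping participant %s: %s", pid, exc)
    return fits


def model_fit_correlation(
    fits: list[WeightFit],
    df: pd.DataFrame,
    probs: CorpusProbabilityTable,
    design: StudyDesign,
    group_by: str | None = "grade",
    renormalize_modeled: bool = False,
) -> dict:
    """Pearson r between observed and model-predicted response percentages.

    Observed and predicted percentages for every participant x condition x
    modeled category cell are pooled within each group (e.g. grade) and a
    single r is computed per group.  Zero variance in either pooled vector
    makes r undefined and is reported as NaN, not 0.
    """
    if group_by is not None and group_by not in df.columns:
        raise ValueError(f"group_by column {group_by!r} not in table")
    groups_of = (
        df.groupby("participant_id")[group_by].first().to_dict()
        if group_by is not None
        else {pid: "all" for pid in df["participant_id"].unique()}
    )
    pooled: dict[object, tuple[list, list]] = {}
    for fit in fits:
        obs, _ = observed_proportions(df, fit.participant_id, design, renormalize_modeled)
        g = groups_of.get(fit.participant_id)
        if g is None:
            continue
        ob, pr = pooled.setdefault(g, ([], []))
        conds = {c for (c, _cat) in obs}
        for cond in conds:
            pred = predict_probabilities(fit.beta, probs, cond, design)
            for cat in design.response_categories:
                ob.append(100.0 * obs[(cond, cat)])
                pr.append(100.0 * pred[cat])
    out = {}
    for g, (ob, pr) in sorted(pooled.items(), key=lambda kv: str(kv[0])):
        ob, pr = np.asarray(ob), np.asarray(pr)
        # percentage scale: treat numerically-degenerate spread as undefined
        if len(ob) < 3 or ob.std() < 1e-9 or pr.std() < 1e-9:
            out[g] = float("nan")
            continue
        out[g] = float(np.corrcoef(ob, pr)[0, 1])
    return out


def aggregate_weights(
    fits: list[WeightFit],
    grades: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Mean (sample SD) beta per rule type per grade.

    Non-identifiable fits are excluded (their beta is arbitrary among
    equal-loss optima); the exclusion count is logged.  A single fit in a
    group reports SD as NaN.
    """
    usable = [f for f in fits if f.identifiable]
    n_excl = len(fits) - len(usable)
    if n_excl:
        log.info("aggregate_weights: excluded %d non-identifiable fit(s)", n_excl)
    if not usable:
        return pd.DataFrame()
    rule_types = usable[0].rule_types
    rows = []
    for f in usable:
        grade = grades.get(f.participant_id, "all") if grades else "all"
        rows.append({"grade": grade, **{r: b for r, b in zip(rule_types, f.beta)}})
    long = pd.DataFrame(rows)
    agg = long.groupby("grade").agg(["mean", lambda s: s.std(ddof=1)])
    agg.columns = [
        f"{rule}_{'sd' if name == '<lambda_0>' else name}" for rule, name in agg.columns
    ]
    agg["n_fits"] = long.groupby("grade").size()
    return agg.reset_index()
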