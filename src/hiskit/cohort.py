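"""Clinical response-prediction stack: RECIST calls, ROC/AUC, Youden
cutoffs, contingency-table reconstruction, grouped logistic regression,
and the DeLong paired-AUC test.

The central objects are 2x2 (response x biomarker) and 2x2x2 (BTV stratum
x TPS indicator x response) contingency tables. Published sensitivity /
specificity percentages plus marginal counts determine these tables up to
rounding, which makes the cohort's AUCs and logistic coefficients exactly
recomputable from summary statistics alone:

* a binary score's tie-corrected AUC is (sensitivity + specificity)/2;
* the 2x2x2 table has a single free cell, pinned by the combined model's
  published operating point;
* the maximum-likelihood logistic fit on the grouped table reproduces the
  published logit equations.

Indicator coding: the BTV indicator is 1 for BTV *below* the cutoff
(BTV-small), the TPS indicator is 1 for TPS >= the cut. This is the only
coding consistent with the published positive coefficients (BTV-small
patients respond more often) and it satisfies the maximum-likelihood score
equations on the reconstructed tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "JointTable2x2x2",
    "ROCCurve",
    "LogisticModel",
    "DeLongResult",
    "recist_classify",
    "empirical_roc",
    "youden_cutoff",
    "sens_spec_at",
    "reconstruct_tps_table",
    "reconstruct_joint_table",
    "fit_logistic",
    "fit_bivariate",
    "predict_probability",
    "delong_test",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Response x biomarker counts: (responder, non-responder) x (pos, neg)."""

    resp_pos: int
    resp_neg: int
    nonresp_pos: int
    nonresp_neg: int

    def __post_init__(self) -> None:
        for name in ("resp_pos", "resp_neg", "nonresp_pos", "nonresp_neg"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_resp(self) -> int:
        return self.resp_pos + self.resp_neg

    @property
    def n_nonresp(self) -> int:
        return self.nonresp_pos + self.nonresp_neg

    @property
    def n_pos(self) -> int:
        return self.resp_pos + self.nonresp_pos

    @property
    def n_total(self) -> int:
        return self.n_resp + self.n_nonresp

    @property
    def sensitivity(self) -> float:
        return self.resp_pos / self.n_resp

    @property
    def specificity(self) -> float:
        return self.nonresp_neg / self.n_nonresp

    @property
    def auc(self) -> float:
        """Tie-corrected AUC of the binary indicator: (sens + spec)/2."""
        return 0.5 * (self.sensitivity + self.specificity)

    def scores_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to per-patient binary scores (indicator) and labels."""
        scores = np.concatenate([
            np.ones(self.resp_pos), np.zeros(self.resp_neg),
            np.ones(self.nonresp_pos), np.zeros(self.nonresp_neg),
        ])
        labels = np.concatenate([
            np.ones(self.n_resp, dtype=int), np.zeros(self.n_nonresp, dtype=int),
        ])
        return scores, labels


#: cell key order of JointTable2x2x2: (btv_small, tps_pos)
_CELL_KEYS = ((True, True), (True, False), (False, True), (False, False))


@dataclass(frozen=True)
class JointTable2x2x2:
    """(BTV small/large) x (TPS pos/neg) x (responder/non) counts.

    ``cells`` maps (btv_small, tps_pos) -> (n_responders, n_nonresponders).
    """

    cells: dict[tuple[bool, bool], tuple[int, int]]

    def __post_init__(self) -> None:
        if set(self.cells) != set(_CELL_KEYS):
            raise ValueError(f"cells must be keyed by {_CELL_KEYS}")
        for k, (r, n) in self.cells.items():
            if r < 0 or n < 0 or int(r) != r or int(n) != n:
                raise ValueError(f"cell {k} has invalid counts ({r}, {n})")

    def cell(self, btv_small: bool, tps_pos: bool) -> tuple[int, int]:
        return self.cells[(btv_small, tps_pos)]

    @property
    def n_total(self) -> int:
        return sum(r + n for r, n in self.cells.values())

    def collapse_tps(self) -> ContingencyTable2x2:
        """Marginal response x TPS table (BTV summed out)."""
        rp = sum(self.cells[(b, True)][0] for b in (True, False))
        rn = sum(self.cells[(b, False)][0] for b in (True, False))
        np_ = sum(self.cells[(b, True)][1] for b in (True, False))
        nn = sum(self.cells[(b, False)][1] for b in (True, False))
        return ContingencyTable2x2(rp, rn, np_, nn)

    def collapse_btv(self) -> ContingencyTable2x2:
        """Marginal response x BTV-small table (TPS summed out)."""
        rp = sum(self.cells[(True, t)][0] for t in (True, False))
        rn = sum(self.cells[(False, t)][0] for t in (True, False))
        np_ = sum(self.cells[(True, t)][1] for t in (True, False))
        nn = sum(self.cells[(False, t)][1] for t in (True, False))
        return ContingencyTable2x2(rp, rn, np_, nn)

    def stratum(self, btv_small: bool) -> ContingencyTable2x2:
        """Response x TPS table within one BTV stratum."""
        rp, np_ = self.cells[(btv_small, True)]
        rn, nn = self.cells[(btv_small, False)]
        return ContingencyTable2x2(rp, rn, np_, nn)

    def patients(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Expand to per-patient arrays (btv_small, tps_pos, response)."""
        b, t, y = [], [], []
        for (bs, tp), (r, n) in sorted(self.cells.items(), reverse=True):
            b += [bs] * (r + n)
            t += [tp] * (r + n)
            y += [1] * r + [0] * n
        return (np.array(b, dtype=bool), np.array(t, dtype=bool),
                np.array(y, dtype=int))

    def scores(self, model: "LogisticModel") -> tuple[np.ndarray, np.ndarray]:
        """Per-patient logit scores under ``model`` plus response labels."""
        b, t, y = self.patients()
        return model.logit(b, t), y


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: one operating point per distinct threshold.

    At threshold t the positive call is score >= t; sensitivity is
    non-increasing as t rises. ``auc`` is the tie-corrected Mann-Whitney
    statistic P(score_resp > score_non) + 0.5 P(equal).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    @property
    def youden(self) -> np.ndarray:
        """Youden index J = sensitivity + specificity - 1 per point."""
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class LogisticModel:
    """logit(p) = intercept + coef_btv*[BTV small] + coef_tps*[TPS >= cut].

    Both predictors are binary indicators; ``coef_btv`` multiplies 1 when
    BTV is at or below the cutoff (BTV-small), ``coef_tps`` multiplies 1
    when TPS >= the cut.
    """

    intercept: float
    coef_btv: float
    coef_tps: float
    tps_cut: float | None = None

    def logit(self, btv_small, tps_positive) -> np.ndarray:
        b = np.asarray(btv_small, dtype=float)
        t = np.asarray(tps_positive, dtype=float)
        return self.intercept + self.coef_btv * b + self.coef_tps * t

    def predict_probability(self, btv_small, tps_positive):
        return _expit(self.logit(btv_small, tps_positive))


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float
    degenerate: bool = False


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# RECIST-style responder call


def recist_classify(
    baseline_burden: float,
    series: Sequence[tuple[float, float]],
    shrink_fraction: float = 0.30,
    control_weeks: float = 24.0,
    progression_factor: float = 1.2,
) -> bool:
    """Responder call from a (week, tumor burden) follow-up series.

    A patient responds when the burden shrinks by more than
    ``shrink_fraction`` (default 30%) of baseline at some visit and the
    shrinkage is not followed, before ``control_weeks`` (default 24),
    by progression — any measurement exceeding ``progression_factor``
    (default 1.2) times the running nadir. Patients who never shrink, or
    who enlarge within the control window after initial shrinking, are
    non-responders.
    """
    if baseline_burden < 0 or any(b < 0 for _, b in series):
        raise ValueError("tumor burden must be >= 0")
    if not series:
        raise ValueError("follow-up series must be non-empty")
    weeks = [w for w, _ in series]
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError("weeks must be strictly increasing")

    shrink_cut = (1.0 - shrink_fraction) * baseline_burden
    shrunk = False
    nadir = baseline_burden
    for week, burden in series:
        if burden <= shrink_cut:
            shrunk = True
        if shrunk and week < control_weeks and burden > progression_factor * nadir:
            return False
        nadir = min(nadir, burden)
    return shrunk


# ---------------------------------------------------------------------------
# ROC / Youden


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both responder and non-responder labels are required")


def empirical_roc(scores, labels) -> ROCCurve:
    """Empirical ROC curve with the tie-corrected Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be equal length")
    _check_two_classes(labels)

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # tie-corrected Mann-Whitney AUC via midranks
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0) / (
        len(pos) * len(neg)
    )

    thresholds = np.unique(scores)[::-1]  # descending: sens rises along array
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return ROCCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=float(auc))


def youden_cutoff(roc: ROCCurve) -> float:
    """Threshold maximizing J = sens + spec - 1; ties -> smallest threshold."""
    if len(roc.thresholds) < 2:
        raise ValueError("ROC curve must have >= 2 operating points")
    j = roc.youden
    best = j.max()
    candidates = roc.thresholds[j >= best - 1e-12]
    return float(candidates.min())


def sens_spec_at(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    return float((pos >= threshold).mean()), float((neg < threshold).mean())


# ---------------------------------------------------------------------------
# contingency-table reconstruction from published summaries


def reconstruct_tps_table(
    n_resp: int,
    n_nonresp: int,
    sensitivity: float,
    specificity: float,
    expected_positive_total: int | None = None,
) -> ContingencyTable2x2:
    """Rebuild a response x biomarker 2x2 table from published percentages.

    ``sensitivity`` and ``specificity`` are percentages in [0, 100].
    Responders-positive = round(sens * n_resp / 100) and non-responders-
    negative = round(spec * n_nonresp / 100); the remaining cells follow by
    subtraction. When ``expected_positive_total`` (an independently
    published margin, e.g. the count of biomarker-positive patients) is
    supplied, the reconstruction is validated against it.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
    resp_pos = round(sensitivity * n_resp / 100.0)
    nonresp_neg = round(specificity * n_nonresp / 100.0)
    resp_neg = n_resp - resp_pos
    nonresp_pos = n_nonresp - nonresp_neg
    if min(resp_neg, nonresp_pos) < 0:
        raise ValueError(
            "published percentages are infeasible for the stated group sizes "
            f"(cells {resp_pos=}, {resp_neg=}, {nonresp_pos=}, {nonresp_neg=})"
        )
    table = ContingencyTable2x2(resp_pos, resp_neg, nonresp_pos, nonresp_neg)
    if expected_positive_total is not None and table.n_pos != expected_positive_total:
        raise ValueError(
            f"reconstructed positive total {table.n_pos} does not match the "
            f"independent margin {expected_positive_total}"
        )
    return table


def reconstruct_joint_table(
    margins,
    tps_cut: int,
    tps_table: ContingencyTable2x2,
    combined_sensitivity: float,
    combined_specificity: float,
) -> JointTable2x2x2:
    """Rebuild the (BTV x TPS x response) 2x2x2 table from its margins.

    ``margins`` is a :class:`hiskit.presets.CohortMargins` (stratum sizes,
    responders per stratum, TPS-positive counts per stratum) and
    ``tps_table`` the marginal response x TPS table. These pin every cell
    except one degree of freedom — the responders in the (BTV-small,
    TPS-positive) cell. That free cell is resolved by requiring the
    combined model's positive region (every cell except BTV-large &
    TPS-negative, the lowest-logit cell) to reproduce the published
    combined sensitivity and specificity (percent, matched after rounding
    to their printed precision). The winning table is verified to collapse
    exactly to all supplied margins.
    """
    s_pos, l_pos = margins.tps_pos_by_size[tps_cut]
    if tps_table.n_pos != s_pos + l_pos:
        raise ValueError(
            f"TPS table positive total {tps_table.n_pos} conflicts with the "
            f"stratum margins {s_pos}+{l_pos}"
        )
    if tps_table.n_resp != margins.n_resp or tps_table.n_nonresp != margins.n_nonresp:
        raise ValueError("TPS table response margins conflict with the cohort margins")

    ndigits_sens = _printed_decimals(combined_sensitivity)
    ndigits_spec = _printed_decimals(combined_specificity)

    matches: list[tuple[int, JointTable2x2x2]] = []
    near_misses: list[tuple[int, float, float]] = []
    for a in range(0, min(s_pos, tps_table.resp_pos, margins.resp_small) + 1):
        cells = {
            (True, True): (a, s_pos - a),
            (True, False): (
                margins.resp_small - a,
                margins.nonresp_small - (s_pos - a),
            ),
            (False, True): (
                tps_table.resp_pos - a,
                tps_table.nonresp_pos - (s_pos - a),
            ),
        }
        r_large_neg = margins.resp_large - cells[(False, True)][0]
        n_large_neg = margins.nonresp_large - cells[(False, True)][1]
        cells[(False, False)] = (r_large_neg, n_large_neg)
        if any(min(c) < 0 for c in cells.values()):
            continue
        table = JointTable2x2x2(cells=cells)
        # positive region = all cells except (large, TPS-negative)
        sens = 100.0 * (margins.n_resp - r_large_neg) / margins.n_resp
        spec = 100.0 * n_large_neg / margins.n_nonresp
        if (round(sens, ndigits_sens) == combined_sensitivity
                and round(spec, ndigits_spec) == combined_specificity):
            matches.append((a, table))
        else:
            near_misses.append((a, round(sens, 1), round(spec, 1)))

    if not matches:
        raise ValueError(
            "no integer free cell reproduces the published combined "
            f"sensitivity {combined_sensitivity} / specificity "
            f"{combined_specificity}; candidates (free cell, sens, spec): "
            f"{near_misses}"
        )
    if len(matches) > 1:
        raise ValueError(
            f"free cell not unique: candidates {[a for a, _ in matches]} all "
            "reproduce the published operating point"
        )
    table = matches[0][1]
    _verify_collapse(table, margins, tps_cut, tps_table)
    return table


def _printed_decimals(x: float) -> int:
    """Number of decimals the value is printed with (e.g. 77.9 -> 1)."""
    s = f"{x!r}"
    return len(s.split(".")[1]) if "." in s else 0


def _verify_collapse(table: JointTable2x2x2, margins, tps_cut: int,
                     tps_table: ContingencyTable2x2) -> None:
    small = table.stratum(True)
    large = table.stratum(False)
    checks = [
        (small.n_total, margins.n_small, "BTV-small stratum size"),
        (large.n_total, margins.n_large, "BTV-large stratum size"),
        (small.n_resp, margins.resp_small, "BTV-small responders"),
        (large.n_resp, margins.resp_large, "BTV-large responders"),
        (small.n_pos, margins.tps_pos_by_size[tps_cut][0], "BTV-small TPS-positive"),
        (large.n_pos, margins.tps_pos_by_size[tps_cut][1], "BTV-large TPS-positive"),
        (table.collapse_tps().resp_pos, tps_table.resp_pos, "responders TPS-positive"),
        (table.collapse_tps().nonresp_pos, tps_table.nonresp_pos,
         "non-responders TPS-positive"),
    ]
    for got, want, what in checks:
        if got != want:
            raise AssertionError(f"joint table fails margin check {what}: {got} != {want}")


# ---------------------------------------------------------------------------
# grouped-binomial logistic regression by IRLS


class ConvergenceError(RuntimeError):
    pass


def fit_logistic(
    design: np.ndarray,
    successes: np.ndarray,
    totals: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Maximum-likelihood logistic fit to grouped binomial data by IRLS.

    ``design`` is cells x parameters (include the intercept column),
    ``successes``/``totals`` the per-cell responder counts and sizes.
    Iterates Newton / iteratively-reweighted-least-squares steps until the
    score equations X'(y - n p) = 0 hold with max residual < ``tol``.

    Returns (coefficients, standard errors, n_iterations). Raises
    :class:`ConvergenceError` after ``max_iter`` iterations — typically a
    symptom of complete or quasi-complete separation (a cell probability
    driven to 0 or 1).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(n) != X.shape[0]:
        raise ValueError("design, successes and totals have inconsistent shapes")
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("successes must lie in [0, totals]")

    beta = np.zeros(X.shape[1])
    for it in range(1, max_iter + 1):
        p = _expit(X @ beta)
        score = X.T @ (y - n * p)
        if np.max(np.abs(score)) < tol:
            W = n * p * (1.0 - p)
            info = X.T @ (X * W[:, None])
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return beta, se, it
        W = n * p * (1.0 - p)
        info = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix; the design is not identifiable "
                "on the supplied cells"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            raise ConvergenceError(
                "coefficients diverging (fitted cell probability at 0 or 1); "
                "the data are completely or quasi-completely separated"
            )
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations; the data may be "
        "completely or quasi-completely separated"
    )


def fit_bivariate(table: JointTable2x2x2, tps_cut: float | None = None) -> LogisticModel:
    """Fit the bivariate BTV+TPS logistic model to a 2x2x2 table by IRLS."""
    rows, succ, tot = [], [], []
    for (b, t), (r, n) in table.cells.items():
        rows.append([1.0, float(b), float(t)])
        succ.append(r)
        tot.append(r + n)
    beta, _, _ = fit_logistic(np.array(rows), np.array(succ), np.array(tot))
    return LogisticModel(intercept=float(beta[0]), coef_btv=float(beta[1]),
                         coef_tps=float(beta[2]), tps_cut=tps_cut)


def predict_probability(model: LogisticModel, btv_small: bool, tps_positive: bool) -> float:
    """Response probability = inverse-logit of the model's linear predictor."""
    return float(model.predict_probability(btv_small, tps_positive))


# ---------------------------------------------------------------------------
# DeLong paired-AUC test


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-subject structural components (placement values)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n          # per responder
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m    # per non-responder
    auc = v10.mean()
    return float(auc), v10, v01


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's paired comparison of two correlated AUCs.

    Both score vectors must be over the same patients (same ``labels``).
    The variance of the AUC difference is estimated from the empirical
    covariance of the structural components. When the two score vectors
    induce identical placements the variance degenerates; z = 0 and p = 1
    are returned with ``degenerate=True``.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if sa.shape != labels.shape or sb.shape != labels.shape:
        raise ValueError("paired scores must match the label vector length")
    _check_two_classes(labels)

    auc_a, v10_a, v01_a = _placements(sa, labels)
    auc_b, v10_b, v01_b = _placements(sb, labels)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n

    diff = auc_a - auc_b
    if var_diff <= 0 or not np.isfinite(var_diff) or (diff == 0 and var_diff < 1e-300):
        return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_diff=max(var_diff, 0.0),
                            z=0.0, p=1.0, degenerate=True)
    z = diff / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_diff=float(var_diff),
                        z=float(z), p=float(p))
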