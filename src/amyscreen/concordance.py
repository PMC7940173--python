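"""Concordance of plasma biomarkers with amyloid PET status.

Predictor scores (raw biomarkers, the mass-spectrometry composite, or fitted
probabilities from logistic models) are evaluated against binary PET status
with empirical ROC curves. AUCs use the midrank (Mann-Whitney) formula with
ties counting one half; correlated AUCs are compared with the DeLong
placement-value test; operating points are chosen by Youden's index.

Conventions
-----------
* ROC ``orientation`` declares which direction of the score indicates PET
  positivity: ``"higher"`` (default; probabilities, p-tau181) or ``"lower"``
  (amyloid-beta 42/40 ratios, which fall with cerebral amyloid).
* Candidate thresholds are midpoints between adjacent distinct scores plus
  the two infinite endpoints, and classification places the boundary on the
  positive side (score >= t positive for "higher", <= t for "lower"),
  mirroring the SUVR rule.
* Logistic fits are maximum likelihood through statsmodels; separation is
  reported as an unconverged model rather than an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata

from .errors import InvalidRecordError, UndefinedRocError

__all__ = [
    "LogisticModel",
    "RocCurve",
    "DeLongComparison",
    "CutpointResult",
    "lcms_composite",
    "fit_logistic",
    "roc_curve",
    "delong_test",
    "delong_auc_variance",
    "youden_cutpoint",
    "log_pearson_correlations",
]


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == object or y.dtype.kind in "US":
        y = np.asarray([v in ("positive", "True", "true", "1") for v in y])
    y = y.astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary (0/1, bool, or positive/negative)")
    return y.astype(int)


# ---------------------------------------------------------------------------
# Composite score


def lcms_composite(table: pd.DataFrame) -> pd.Series:
    """Mass-spectrometry amyloid-beta composite per participant.

    The composite is the average of the sample z-scores of the
    Abeta(-3-40)/Abeta(1-42) and Abeta(1-40)/Abeta(1-42) ratios; higher
    values indicate more cerebral amyloid. z-scores are taken over the rows
    of ``table`` (the analysis sample), so the composite has sample mean 0
    by construction.
    """
    for col in ("lcms_ab42", "lcms_ab40", "lcms_abm3_40"):
        if col not in table.columns:
            raise InvalidRecordError(f"table missing column {col!r}")
    ab42 = table["lcms_ab42"].to_numpy(dtype=float)
    bad = ~(ab42 > 0)
    if bad.any():
        rows = table.index[bad].tolist()
        raise InvalidRecordError(f"non-positive lcms_ab42 in rows {rows[:5]}")
    r1 = table["lcms_abm3_40"].to_numpy(dtype=float) / ab42
    r2 = table["lcms_ab40"].to_numpy(dtype=float) / ab42
    z1 = (r1 - r1.mean()) / r1.std(ddof=1)
    z2 = (r2 - r2.mean()) / r2.std(ddof=1)
    return pd.Series((z1 + z2) / 2.0, index=table.index, name="lcms_composite")


# ---------------------------------------------------------------------------
# Logistic models


@dataclass(frozen=True)
class LogisticModel:
    """A fitted binary logistic regression (intercept first)."""

    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept followed by one slope per predictor
    converged: bool
    n_obs: int
    separation: bool = False

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        """Fitted probability of the positive class for each row."""
        X = np.column_stack(
            [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in self.predictors]
        )
        eta = X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(outcome, predictors: pd.DataFrame) -> LogisticModel:
    """Maximum-likelihood logistic regression of a binary outcome.

    Parameters
    ----------
    outcome : array-like
        Binary status (bool/0-1/"positive"/"negative"); needs at least one
        event and one non-event.
    predictors : pandas.DataFrame
        Numeric predictor columns, no missing values. An empty frame fits an
        intercept-only model.

    Complete or quasi-complete separation is flagged (``separation=True``,
    ``converged=False``) with a warning; coefficients are then the last
    iterate and should not be interpreted.
    """
    y = _as_binary(outcome)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one event and one non-event")
    if predictors.isna().to_numpy().any():
        raise ValueError("missing predictor values; apply complete-case filter first")
    names = tuple(predictors.columns)
    X = np.column_stack(
        [np.ones(y.size)] + [predictors[p].to_numpy(dtype=float) for p in names]
    )
    separation = False
    converged = False
    params = np.full(X.shape[1], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
            # quasi-separation shows up as runaway coefficients
            if converged and np.abs(params).max() > 1e3:
                separation, converged = True, False
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ):
            separation = True
    if separation:
        warnings.warn(
            "complete or quasi-complete separation detected; model flagged unconverged",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticModel(
        predictors=names,
        coefficients=params,
        converged=converged,
        n_obs=int(y.size),
        separation=separation,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC over all distinct thresholds of a score.

    ``thresholds`` are on the original score scale (midpoints between
    adjacent distinct scores, bracketed by -inf/+inf); ``sensitivity[i]`` and
    ``specificity[i]`` are the operating point when classifying positive on
    the score's positive side of ``thresholds[i]`` (boundary positive).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    orientation: str = "higher"

    @property
    def prevalence(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)


def roc_curve(scores, labels, orientation: str = "higher") -> RocCurve:
    """Empirical ROC curve and midrank AUC of a score against binary labels.

    The AUC is the Mann-Whitney estimate: the proportion of
    (positive, negative) pairs the score orders correctly, ties counting
    one half — invariant under strictly monotone transforms of the score.
    """
    if orientation not in ("higher", "lower"):
        raise ValueError("orientation must be 'higher' or 'lower'")
    y = _as_binary(labels)
    x = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRocError("both outcome classes must be present")

    s = x if orientation == "higher" else -x
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    u = np.unique(s)
    inner = (u[:-1] + u[1:]) / 2.0
    thr_internal = np.concatenate(([-np.inf], inner, [np.inf]))
    # sensitivity/specificity for "internal score >= t" via cumulative counts
    pos_sorted = np.sort(s[y == 1])
    neg_sorted = np.sort(s[y == 0])
    sens = 1.0 - np.searchsorted(pos_sorted, thr_internal, side="left") / n_pos
    spec = np.searchsorted(neg_sorted, thr_internal, side="left") / n_neg
    thresholds = thr_internal if orientation == "higher" else -thr_internal
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        n_pos=n_pos,
        n_neg=n_neg,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# DeLong


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    variance: float
    z: float
    p_value: float
    degenerate: bool = False


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Midrank placement values (structural components) of one score.

    Returns (auc, V10 over positives, V01 over negatives).
    """
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """DeLong (placement-value) estimate of an AUC and its variance."""
    y = _as_binary(labels)
    auc, v10, v01 = _placements(np.asarray(scores, dtype=float), y)
    m, n = v10.size, v01.size
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def delong_test(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong test for the difference of two correlated (paired) AUCs.

    Both scores must be measured on the same participants. The covariance of
    the AUCs is estimated from placement values; ``z`` is the difference over
    its standard error and the p-value is two-sided normal. Identical
    rankings give zero variance; that degenerate case reports p = 1.
    """
    y = _as_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired scores and labels must share length")
    auc_a, v10_a, v01_a = _placements(a, y)
    auc_b, v10_b, v01_b = _placements(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var = max(float(var), 0.0)
    diff = auc_a - auc_b
    if var <= 1e-300 or (diff == 0.0 and var == 0.0):
        return DeLongComparison(auc_a, auc_b, 0.0, 0.0, 1.0, degenerate=True)
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, var, float(z), p)


# ---------------------------------------------------------------------------
# Youden cut-point


@dataclass(frozen=True)
class CutpointResult:
    """An operating point chosen on a ROC curve."""

    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden_j: float
    orientation: str = "higher"


def youden_cutpoint(roc: RocCurve, prevalence: float | None = None) -> CutpointResult:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties on J are broken toward the highest sensitivity, then the smallest
    threshold, so the result is deterministic. ``accuracy`` is
    ``sens * p + spec * (1 - p)`` at the sample prevalence unless an
    explicit ``prevalence`` is supplied.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j.max()
    cand = np.flatnonzero(j >= best_j - 1e-12)
    best_sens = roc.sensitivity[cand].max()
    cand = cand[roc.sensitivity[cand] >= best_sens - 1e-12]
    thr = roc.thresholds[cand]
    i = cand[int(np.argmin(thr))]
    p = roc.prevalence if prevalence is None else float(prevalence)
    sens, spec = float(roc.sensitivity[i]), float(roc.specificity[i])
    return CutpointResult(
        threshold=float(roc.thresholds[i]),
        sensitivity=sens,
        specificity=spec,
        accuracy=sens * p + spec * (1.0 - p),
        youden_j=sens + spec - 1.0,
        orientation=roc.orientation,
    )


# ---------------------------------------------------------------------------
# Correlations


def log_pearson_correlations(
    table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson correlations between log-transformed biomarkers.

    Each member of a pair is natural-log transformed before correlating,
    except the ``lcms_composite`` column which is used untransformed (it is
    a z-score average and can be negative). p-values are two-sided t-based,
    with a Bonferroni adjustment by the number of pairs tested.

    Returns a frame with columns ``var_a, var_b, r, p, p_bonferroni``.
    """
    rows = []
    k = len(pairs)
    for a, b in pairs:
        va = _maybe_log(table, a)
        vb = _maybe_log(table, b)
        ok = ~(np.isnan(va) | np.isnan(vb))
        if ok.sum() < 3:
            raise InvalidRecordError(f"fewer than 3 complete pairs for ({a}, {b})")
        r, p = stats.pearsonr(va[ok], vb[ok])
        rows.append(
            {"var_a": a, "var_b": b, "r": float(r), "p": float(p),
             "p_bonferroni": min(1.0, float(p) * k)}
        )
    return pd.DataFrame(rows)


def _maybe_log(table: pd.DataFrame, name: str) -> np.ndarray:
    v = table[name].to_numpy(dtype=float)
    if name == "lcms_composite":
        return v
    bad = np.isfinite(v) & (v <= 0)
    if bad.any():
        rows = table.index[bad].tolist()
        raise InvalidRecordError(f"non-positive {name} under log transform in rows {rows[:5]}")
    return np.log(v)
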