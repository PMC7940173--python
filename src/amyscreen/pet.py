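"""Amyloid PET positivity from SUVR via a two-component Gaussian mixture.

The cohort's SUVR distribution is bimodal: a large amyloid-negative mode and
a smaller, broader amyloid-positive mode. The positivity cut-point is
defined as the 99th percentile of the lower (PET-negative) component of a
two-Gaussian mixture fitted by EM, and SUVR at or above the cut-point is
classified PET-positive.

The EM fit is deliberately deterministic: initialisation splits the sample
at its median and takes component moments from the two halves, so the same
data always give the same fit. A seed only matters when optional random
restarts are requested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import DegenerateDataError

__all__ = ["MixtureFit", "PetCutpoint", "fit_gmm_1d", "gmm_cutpoint", "classify_pet"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixtureFit:
    """A fitted two-component 1-D Gaussian mixture, components sorted by mean.

    ``lower_index`` identifies the component with the smaller mean (always 0
    after sorting, but kept explicit so consumers never depend on labels).
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool
    lower_index: int = 0
    #: per-iteration log-likelihood trace; non-decreasing by construction of EM
    loglik_path: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if min(self.weights) < 0 or min(self.sds) <= 0:
            raise ValueError("weights must be >= 0 and sds positive")


@dataclass(frozen=True)
class PetCutpoint:
    """SUVR positivity threshold derived from a mixture fit."""

    suvr_threshold: float
    percentile: float
    source_fit: MixtureFit | None = None


def _em(x: np.ndarray, w, mu, sd, tol: float, max_iter: int, sd_floor: float):
    """Run EM from the given start; returns (w, mu, sd, loglik, n_iter, converged)."""
    w = np.asarray(w, float).copy()
    mu = np.asarray(mu, float).copy()
    sd = np.maximum(np.asarray(sd, float), sd_floor)
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    ll_path: list[float] = []
    for n_iter in range(1, max_iter + 1):
        # E-step in log space; responsibilities are a row-normalised soft partition
        log_comp = np.log(w)[None, :] + stats.norm.logpdf(
            x[:, None], mu[None, :], sd[None, :]
        )
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        ll_path.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / x.size
        mu = resp.T @ x / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
    return w, mu, sd, prev_ll, n_iter, converged, tuple(ll_path)


def fit_gmm_1d(
    values,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 0,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to 1-D data by EM.

    Parameters
    ----------
    values : array-like
        At least four finite values, not all identical.
    tol : float
        Absolute log-likelihood change declaring convergence.
    max_iter : int
        Maximum EM iterations; hitting it returns ``converged=False`` with a
        logged warning rather than raising.
    seed, n_restarts : int
        Optional random restarts from perturbed median-split starts; the
        best log-likelihood wins. The default (0 restarts) is fully
        deterministic given the data.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise DegenerateDataError("need at least 4 values to fit a two-Gaussian mixture")
    if not np.all(np.isfinite(x)):
        raise DegenerateDataError("non-finite values in SUVR input")
    data_range = float(np.ptp(x))
    if data_range == 0.0:
        raise DegenerateDataError("all values identical; mixture is undefined")
    sd_floor = 1e-6 * data_range

    # Median-split moment initialisation (deterministic)
    order = np.argsort(x, kind="stable")
    half = x.size // 2
    lo, hi = x[order[:half]], x[order[half:]]
    mu0 = np.array([lo.mean(), hi.mean()])
    sd0 = np.maximum(np.array([lo.std(), hi.std()]), sd_floor)
    w0 = np.array([lo.size, hi.size], float) / x.size

    best = _em(x, w0, mu0, sd0, tol, max_iter, sd_floor)
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            jitter_mu = mu0 + rng.normal(0, 0.5 * data_range, size=2)
            cand = _em(x, w0, jitter_mu, sd0, tol, max_iter, sd_floor)
            if cand[3] > best[3]:
                best = cand
    w, mu, sd, ll, n_iter, converged, ll_path = best
    if not converged:
        msg = f"EM did not converge within {max_iter} iterations (|dloglik| >= {tol})"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    order = np.argsort(mu)
    return MixtureFit(
        weights=tuple(float(v) for v in w[order]),
        means=tuple(float(v) for v in mu[order]),
        sds=tuple(float(v) for v in sd[order]),
        loglik=float(ll),
        n_iter=int(n_iter),
        converged=bool(converged),
        lower_index=0,
        loglik_path=ll_path,
    )


def gmm_cutpoint(fit: MixtureFit, percentile: float = 0.99) -> PetCutpoint:
    """Closed-form cut-point: the given percentile of the lower component.

    ``threshold = mean_lower + z(percentile) * sd_lower`` — no sampling.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must lie in (0, 1); got {percentile}")
    mean = fit.means[fit.lower_index]
    sd = fit.sds[fit.lower_index]
    threshold = float(mean + stats.norm.ppf(percentile) * sd)
    return PetCutpoint(suvr_threshold=threshold, percentile=percentile, source_fit=fit)


def classify_pet(suvr, cutpoint: PetCutpoint | float) -> np.ndarray:
    """Classify SUVR values against a cut-point.

    Positive iff ``suvr >= threshold`` (the boundary is positive). Accepts a
    scalar or array; returns a boolean array where ``True`` is PET-positive.
    """
    threshold = (
        cutpoint.suvr_threshold if isinstance(cutpoint, PetCutpoint) else float(cutpoint)
    )
    x = np.asarray(suvr, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite SUVR value")
    return x >= threshold
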