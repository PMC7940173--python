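"""Seeded synthetic cohorts of dementia-free ~70-year-olds with amyloid PET
and plasma biomarker data.

The generator emulates the joint structure the downstream screening analysis
assumes: a bimodal SUVR distribution (mixture of PET-negative and
PET-positive Gaussians), APOE e4 carriage enriched in the PET-positive
group, and log-normal plasma biomarker concentrations whose per-status
medians and interquartile ranges match published cohort summaries.
Skewed assay values are summarised in the field as ``median [IQR]``, so the
bridge from summary to generative model is the exact log-normal
median/IQR inversion :func:`lognormal_params_from_median_iqr`.

Ratios (e.g. amyloid-beta 42/40) are never drawn directly: they are always
computed from the generated peptide concentrations, so ratio consistency is
structural. Within each PET-status group, peptide log-concentrations may be
correlated through a Gaussian copula (a correlation matrix on the latent
normal scores); the default cohort uses moderate within-platform
correlations so that derived ratios have realistic dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InvalidRecordError, InvalidSummaryError

__all__ = [
    "BIOMARKERS",
    "COHORT_COLUMNS",
    "CohortSpec",
    "lognormal_params_from_median_iqr",
    "default_log_correlation",
    "default_cohort_spec",
    "generate_cohort",
    "validate_cohort",
    "complete_cases",
    "read_cohort",
    "write_cohort",
]

#: 75th percentile of the standard normal; half the IQR of N(0,1).
_Z75 = 0.6744897501960817

#: Biomarker column order; fixed so that correlation matrices and draws are
#: reproducible independent of dict ordering.
BIOMARKERS = (
    "simoa_ab40",
    "simoa_ab42",
    "simoa_ptau181",
    "lcms_ab38",
    "lcms_ab40",
    "lcms_ab42",
    "lcms_abm3_40",
)

#: Documented on-disk column order for cohort tables.
COHORT_COLUMNS = ("id", "age", "sex", "apoe4_carrier", "suvr") + BIOMARKERS + ("pet_status",)

# Published per-status biomarker summaries, median (q1, q3) in pg/ml, used by
# the default spec. Keyed by biomarker then PET status.
_MEDIAN_IQR: dict[str, dict[str, tuple[float, float, float]]] = {
    "simoa_ab40": {"negative": (289.0, 255.0, 319.0), "positive": (285.0, 257.0, 328.0)},
    "simoa_ab42": {"negative": (19.9, 17.1, 22.6), "positive": (18.1, 15.5, 22.9)},
    "simoa_ptau181": {"negative": (8.5, 6.1, 12.2), "positive": (12.8, 9.2, 16.0)},
    "lcms_ab38": {"negative": (24.8, 21.6, 27.9), "positive": (24.5, 21.6, 28.7)},
    "lcms_ab40": {"negative": (284.0, 255.0, 314.0), "positive": (285.0, 260.0, 311.0)},
    "lcms_ab42": {"negative": (29.6, 24.9, 34.2), "positive": (23.7, 20.3, 27.2)},
    "lcms_abm3_40": {"negative": (30.1, 24.4, 35.7), "positive": (29.9, 24.4, 34.9)},
}


def lognormal_params_from_median_iqr(
    median: float, q1: float, q3: float
) -> tuple[float, float]:
    """Invert a ``median [q1, q3]`` summary to log-normal parameters.

    A log-normal with location ``mu = ln(median)`` and scale
    ``sigma = (ln q3 - ln q1) / (2 * z_0.75)`` has exactly the given median
    and interquartile range.

    Parameters
    ----------
    median, q1, q3 : float
        Sample median and quartiles; must satisfy ``0 < q1 <= median <= q3``.

    Returns
    -------
    (location, scale) : tuple of float
        Parameters of the log of the variable, in log-units.
    """
    if not (0 < q1 <= median <= q3):
        raise InvalidSummaryError(
            f"quartile summary must satisfy 0 < q1 <= median <= q3; "
            f"got median={median}, q1={q1}, q3={q3}"
        )
    location = float(np.log(median))
    scale = float((np.log(q3) - np.log(q1)) / (2.0 * _Z75))
    return location, scale


@dataclass(frozen=True)
class CohortSpec:
    """Population quantities from which a synthetic cohort is drawn.

    ``biomarker_params`` maps biomarker name -> PET status
    (``"negative"``/``"positive"``) -> ``(location, scale)`` of the
    log-concentration. ``log_correlation`` is an optional correlation matrix
    on the latent normal scores of the biomarkers, ordered as
    :data:`BIOMARKERS`; ``None`` means independence (identity copula).
    """

    n_participants: int = 441
    prevalence: float = 0.186
    age_mean: float = 70.7
    age_sd: float = 0.7
    age_bounds: tuple[float, float] = (69.0, 72.0)
    frac_female: float = 0.506
    apoe4_prob_pos: float = 0.573
    apoe4_prob_neg: float = 0.220
    suvr_mix: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"negative": (0.54, 0.030), "positive": (0.70, 0.080)}
    )
    biomarker_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    log_correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError("prevalence must lie strictly in (0, 1)")
        for name, p in (
            ("frac_female", self.frac_female),
            ("apoe4_prob_pos", self.apoe4_prob_pos),
            ("apoe4_prob_neg", self.apoe4_prob_neg),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]; got {p}")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be positive")
        for status in ("negative", "positive"):
            if status not in self.suvr_mix:
                raise ConfigError(f"suvr_mix missing status {status!r}")
            if self.suvr_mix[status][1] <= 0:
                raise ConfigError("SUVR component scales must be positive")
        for name, per_status in self.biomarker_params.items():
            if name not in BIOMARKERS:
                raise ConfigError(f"unknown biomarker {name!r}")
            for status in ("negative", "positive"):
                if per_status[status][1] < 0:
                    raise ConfigError(f"negative scale for {name}/{status}")
        if self.log_correlation is not None:
            corr = np.asarray(self.log_correlation, dtype=float)
            k = len(BIOMARKERS)
            if corr.shape != (k, k):
                raise ConfigError(f"log_correlation must be {k}x{k}")
            if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
                raise ConfigError("log_correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ConfigError("log_correlation must be positive semidefinite")


def default_log_correlation(
    lcms_rho: float = 0.6, simoa_ab_rho: float = 0.5
) -> np.ndarray:
    """Latent-score correlation used by the default cohort.

    LC-MS peptides are moderately inter-correlated in real plasma panels
    (published pairwise r of roughly 0.55-0.70), which is what gives the
    derived 42/40 ratio its relatively tight spread; an exchangeable block
    with correlation ``lcms_rho`` reproduces both the peptide marginals and
    the published ratio IQR. The two immunoassay amyloid peptides get a
    modest ``simoa_ab_rho``; p-tau181 stays independent of everything.
    """
    idx = {name: i for i, name in enumerate(BIOMARKERS)}
    corr = np.eye(len(BIOMARKERS))
    lcms = ["lcms_ab38", "lcms_ab40", "lcms_ab42", "lcms_abm3_40"]
    for a in lcms:
        for b in lcms:
            if a != b:
                corr[idx[a], idx[b]] = lcms_rho
    corr[idx["simoa_ab40"], idx["simoa_ab42"]] = simoa_ab_rho
    corr[idx["simoa_ab42"], idx["simoa_ab40"]] = simoa_ab_rho
    return corr


def default_cohort_spec(seed: int = 0, n_participants: int = 441) -> CohortSpec:
    """Cohort spec matched to the published dementia-free sample.

    Biomarker log-normal parameters are inverted from the per-status
    ``median [IQR]`` summaries; prevalence, APOE e4 carriage, age and sex
    fractions are the published values. SUVR mixture locations are chosen so
    the 99th-percentile rule on the lower component lands near 0.61 (they
    are generator conventions, not measured values).
    """
    params = {
        name: {
            status: lognormal_params_from_median_iqr(*_MEDIAN_IQR[name][status])
            for status in ("negative", "positive")
        }
        for name in BIOMARKERS
    }
    return CohortSpec(
        n_participants=n_participants,
        biomarker_params=params,
        log_correlation=default_log_correlation(),
        seed=seed,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    # Inverse-CDF sampling keeps the draw reproducible from `rng` alone.
    a, b = stats.norm.cdf([(lo - mean) / sd, (hi - mean) / sd])
    u = rng.uniform(a, b, size=size)
    return mean + sd * stats.norm.ppf(u)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table from ``spec``.

    Per participant: PET status ~ Bernoulli(prevalence); SUVR from the
    status-specific Gaussian; APOE e4 carriage Bernoulli with the
    status-specific probability; the seven biomarkers jointly log-normal via
    the Gaussian copula in ``spec.log_correlation``. The same spec and seed
    give a bit-identical table.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`COHORT_COLUMNS`; ``pet_status`` holds the generative
        (true) status as ``"positive"``/``"negative"``.
    """
    if not spec.biomarker_params:
        raise ConfigError("spec.biomarker_params is empty; use default_cohort_spec()")
    missing = [b for b in BIOMARKERS if b not in spec.biomarker_params]
    if missing:
        raise ConfigError(f"biomarker_params missing entries for {missing}")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    positive = rng.random(n) < spec.prevalence
    status = np.where(positive, "positive", "negative")

    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_bounds, size=n)
    sex = np.where(rng.random(n) < spec.frac_female, "female", "male")
    p_apoe = np.where(positive, spec.apoe4_prob_pos, spec.apoe4_prob_neg)
    apoe4 = rng.random(n) < p_apoe

    suvr = np.empty(n)
    for st in ("negative", "positive"):
        mask = status == st
        mean, sd = spec.suvr_mix[st]
        suvr[mask] = rng.normal(mean, sd, size=mask.sum())

    corr = (
        np.eye(len(BIOMARKERS))
        if spec.log_correlation is None
        else np.asarray(spec.log_correlation, dtype=float)
    )
    # Cholesky of the copula correlation; tiny jitter guards exact-singular
    # but valid matrices (e.g. a perfectly correlated block).
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(BIOMARKERS)))
    z = rng.standard_normal((n, len(BIOMARKERS))) @ chol.T

    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(BIOMARKERS):
        loc = np.empty(n)
        scale = np.empty(n)
        for st in ("negative", "positive"):
            mask = status == st
            loc[mask], scale[mask] = spec.biomarker_params[name][st]
        data[name] = np.exp(loc + scale * z[:, j])

    table = pd.DataFrame(
        {
            "id": [f"P{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "apoe4_carrier": apoe4,
            "suvr": suvr,
            **data,
            "pet_status": status,
        },
        columns=list(COHORT_COLUMNS),
    )
    validate_cohort(table)
    return table


def validate_cohort(
    table: pd.DataFrame, require_status: bool = False, require_complete: bool = False
) -> None:
    """Check cohort-table invariants; raise :class:`InvalidRecordError` on the
    first violation, naming the offending rows.

    Missing values are permitted on disk (empty fields); an analysis-ready
    table additionally requires ``require_complete=True`` — the pipeline's
    complete-case rule.
    """
    required = [c for c in COHORT_COLUMNS if c != "pet_status"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise InvalidRecordError(f"cohort table missing columns {missing_cols}")
    if require_status and "pet_status" not in table.columns:
        raise InvalidRecordError("cohort table missing pet_status column")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise InvalidRecordError(f"duplicate participant ids: {dupes[:5]}")
    numeric = ["suvr", *BIOMARKERS]
    values = table[numeric].to_numpy(dtype=float)
    bad = np.isfinite(values) & (values <= 0)
    if bad.any():
        rows = table.index[bad.any(axis=1)].tolist()
        raise InvalidRecordError(f"non-positive SUVR/biomarker values in rows {rows[:5]}")
    if require_complete:
        with_na = table[required].isna().any(axis=1)
        if with_na.any():
            rows = table.index[with_na].tolist()
            raise InvalidRecordError(f"missing values in rows {rows[:5]}")


def complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    """Return the complete-case subset over all analysis columns (the
    pipeline's first step)."""
    required = [c for c in COHORT_COLUMNS if c != "pet_status" and c in table.columns]
    return table.dropna(subset=required).reset_index(drop=True)


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as comma-separated text with the documented
    header; missing values become empty fields."""
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort` (or any delimited
    text file with the documented columns) and validate it."""
    table = pd.read_csv(path)
    if "apoe4_carrier" in table.columns:
        table["apoe4_carrier"] = table["apoe4_carrier"].astype(bool)
    validate_cohort(table)
    return table
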