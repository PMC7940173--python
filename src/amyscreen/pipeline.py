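"""End-to-end analysis: cohort -> PET cut-point -> concordance -> economics.

`run_pipeline` reproduces the shape of a complete blood-screening analysis:
a per-status cohort summary, a concordance table (AUC with 95% CI per model
and DeLong p-values against the demographic base model), a screening table
(sensitivity/specificity/accuracy at the Youden cut-point, NNS, NPS, scans
saved), a prevalence sweep and a cost-ratio grid. Everything is
deterministic given the seed; every written file carries the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as _cohort
from . import concordance as _conc
from . import economics as _econ
from . import pet as _pet
from .errors import ConfigError, DegenerateDataError

__all__ = [
    "MODEL_ROSTER",
    "BIOMARKER_ORIENTATION",
    "AnalysisConfig",
    "AucCI",
    "ReportBundle",
    "prepare_analysis_table",
    "run_pipeline",
    "auc_ci",
    "sweep_pet_cutoff",
    "parse_flat_config",
]

logger = logging.getLogger(__name__)

#: The nine-model roster: one demographic base model, four single-biomarker
#: models, and the four biomarker models adjusted for age, sex and APOE e4.
_BASE_COVARIATES = ("age", "sex_female", "apoe4")
_BIOMARKER_MODELS = ("simoa_ab4240", "simoa_ptau181", "lcms_ab4240", "lcms_composite")
MODEL_ROSTER: dict[str, tuple[str, ...]] = {
    "base": _BASE_COVARIATES,
    **{name: (name,) for name in _BIOMARKER_MODELS},
    **{f"{name}_adj": (name,) + _BASE_COVARIATES for name in _BIOMARKER_MODELS},
}

#: Direction in which each raw biomarker score indicates PET positivity
#: (amyloid-beta ratios fall with cerebral amyloid; p-tau and the composite rise).
BIOMARKER_ORIENTATION = {
    "simoa_ab4240": "lower",
    "simoa_ptau181": "higher",
    "lcms_ab4240": "lower",
    "lcms_composite": "higher",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for one pipeline run.

    Exactly one input source: a cohort CSV at ``input_path``, or (when that
    is ``None``) a simulated default cohort of ``n_participants`` drawn with
    ``seed``.
    """

    input_path: str | None = None
    n_participants: int = 441
    cutpoint_mode: str = "gmm"  # "gmm" or "fixed"
    fixed_cutpoint: float | None = None
    percentile: float = 0.99
    n_target: float = 100
    sweep_min: float = 0.10
    sweep_max: float = 0.50
    sweep_step: float = 0.05
    cost_ratios: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.3, 0.5)
    roster: tuple[str, ...] = tuple(MODEL_ROSTER)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.cutpoint_mode not in ("gmm", "fixed"):
            raise ConfigError("cutpoint_mode must be 'gmm' or 'fixed'")
        if self.cutpoint_mode == "fixed":
            if self.fixed_cutpoint is None or self.fixed_cutpoint <= 0:
                raise ConfigError("fixed cutpoint mode requires fixed_cutpoint > 0")
        if not self.roster:
            raise ConfigError("model roster must be non-empty")
        unknown = [m for m in self.roster if m not in MODEL_ROSTER]
        if unknown:
            raise ConfigError(f"unknown roster models {unknown}")

    def config_hash(self) -> str:
        # outdir does not affect the analysis, so it is excluded: two runs of
        # the same analysis into different directories hash identically
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode())
        return digest.hexdigest()[:16]


@dataclass(frozen=True)
class AucCI:
    """An AUC with a DeLong-variance normal 95% interval, clamped to [0, 1]."""

    auc: float
    lower: float
    upper: float
    degenerate: bool = False


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus run metadata."""

    cohort_summary: pd.DataFrame
    concordance: pd.DataFrame
    screening: pd.DataFrame
    sweep: pd.DataFrame
    costs: pd.DataFrame
    metadata: dict

    def write(self, outdir) -> None:
        """Write each table as CSV plus a key-value twin; deterministic bytes
        for a fixed config and seed."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "cohort_summary": self.cohort_summary,
            "concordance": self.concordance,
            "screening": self.screening,
            "sweep": self.sweep,
            "costs": self.costs,
        }
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
            with open(out / f"{name}.kv", "w") as fh:
                fh.write(f"# config_hash = {self.metadata['config_hash']}\n")
                for i, row in df.iterrows():
                    for col in df.columns:
                        fh.write(f"{name}[{i}].{col} = {row[col]}\n")
        with open(out / "metadata.kv", "w") as fh:
            for k in sorted(self.metadata):
                fh.write(f"{k} = {self.metadata[k]}\n")


def prepare_analysis_table(table: pd.DataFrame) -> pd.DataFrame:
    """Complete-case filter plus derived analysis columns.

    Adds numeric ``sex_female``/``apoe4`` encodings, the two ratio scores
    and the mass-spectrometry composite (z-scored over the analysis sample).
    """
    t = _cohort.complete_cases(table).copy()
    if t.empty:
        raise DegenerateDataError("no complete cases after filtering")
    t["sex_female"] = (t["sex"].astype(str) == "female").astype(float)
    t["apoe4"] = t["apoe4_carrier"].astype(bool).astype(float)
    t["simoa_ab4240"] = t["simoa_ab42"] / t["simoa_ab40"]
    t["lcms_ab4240"] = t["lcms_ab42"] / t["lcms_ab40"]
    t["lcms_composite"] = _conc.lcms_composite(t)
    return t


def auc_ci(roc: _conc.RocCurve, scores=None, labels=None, level: float = 0.95) -> AucCI:
    """DeLong-variance normal confidence interval for an AUC.

    The variance needs the underlying scores; pass the same ``scores`` and
    ``labels`` the curve was built from. A degenerate (zero) variance
    collapses the interval to the point estimate with a flag.
    """
    if scores is None or labels is None:
        raise ValueError("auc_ci needs the scores and labels behind the curve")
    auc, var = _conc.delong_auc_variance(
        np.asarray(scores, float) if roc.orientation == "higher" else -np.asarray(scores, float),
        labels,
    )
    if var <= 0.0:
        return AucCI(auc=auc, lower=auc, upper=auc, degenerate=True)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return AucCI(auc=auc, lower=max(0.0, auc - half), upper=min(1.0, auc + half))


def _load_cohort(config: AnalysisConfig) -> pd.DataFrame:
    if config.input_path is not None:
        logger.info("stage=load reading cohort from %s", config.input_path)
        return _cohort.read_cohort(config.input_path)
    logger.info("stage=simulate drawing default cohort (n=%d, seed=%d)",
                config.n_participants, config.seed)
    spec = _cohort.default_cohort_spec(seed=config.seed, n_participants=config.n_participants)
    return _cohort.generate_cohort(spec)


def _pet_labels(t: pd.DataFrame, config: AnalysisConfig):
    """Classify PET status per the configured cut-point mode."""
    if config.cutpoint_mode == "fixed":
        logger.info("stage=cutpoint using fixed SUVR cut-point %.4f", config.fixed_cutpoint)
        cut = _pet.PetCutpoint(
            suvr_threshold=float(config.fixed_cutpoint), percentile=config.percentile
        )
    else:
        logger.info("stage=cutpoint fitting two-component SUVR mixture")
        fit = _pet.fit_gmm_1d(t["suvr"].to_numpy())
        cut = _pet.gmm_cutpoint(fit, config.percentile)
        logger.info("stage=cutpoint suvr_threshold=%.4f", cut.suvr_threshold)
    y = _pet.classify_pet(t["suvr"].to_numpy(), cut)
    if y.all() or not y.any():
        raise DegenerateDataError("cutpoint stage produced a single PET class")
    return y, cut


def _cohort_summary(t: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    rows = []
    groups = {"negative": t[~y], "positive": t[y], "all": t}
    rows.append({"characteristic": "n", **{g: len(df) for g, df in groups.items()}})
    rows.append(
        {"characteristic": "age_mean_sd",
         **{g: f"{df['age'].mean():.1f} ({df['age'].std(ddof=1):.1f})" for g, df in groups.items()}}
    )
    rows.append(
        {"characteristic": "pct_female",
         **{g: round(100.0 * (df["sex"] == "female").mean(), 1) for g, df in groups.items()}}
    )
    rows.append(
        {"characteristic": "pct_apoe4_carrier",
         **{g: round(100.0 * df["apoe4_carrier"].astype(bool).mean(), 1) for g, df in groups.items()}}
    )
    for b in list(_cohort.BIOMARKERS) + ["simoa_ab4240", "lcms_ab4240"]:
        rows.append(
            {"characteristic": f"{b}_median_iqr",
             **{g: f"{df[b].median():.3g} [{df[b].quantile(0.25):.3g}, {df[b].quantile(0.75):.3g}]"
                for g, df in groups.items()}}
        )
    rows.append(
        {"characteristic": "lcms_composite_mean_sd",
         **{g: f"{df['lcms_composite'].mean():.3f} ({df['lcms_composite'].std(ddof=1):.3f})"
            for g, df in groups.items()}}
    )
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Execute all analysis stages and return the report tables.

    Stages: load/simulate -> complete-case filter -> PET cut-point ->
    logistic/ROC/DeLong/Youden per roster model -> screening economics ->
    prevalence sweep and cost grid. Deterministic given ``config.seed``.
    """
    raw = _load_cohort(config)
    t = prepare_analysis_table(raw)
    logger.info("stage=filter complete cases: %d of %d", len(t), len(raw))
    y, cut = _pet_labels(t, config)
    prevalence = float(y.mean())

    # --- concordance stage ---------------------------------------------
    probs: dict[str, np.ndarray] = {}
    rows_conc, rows_screen = [], []
    base_probs = None
    for name in config.roster:
        preds = MODEL_ROSTER[name]
        model = _conc.fit_logistic(y, t[list(preds)])
        probs[name] = model.predict_proba(t)
        if name == "base":
            base_probs = probs[name]

    for name in config.roster:
        roc = _conc.roc_curve(probs[name], y, orientation="higher")
        ci = auc_ci(roc, probs[name], y)
        if base_probs is not None and name != "base":
            cmp_ = _conc.delong_test(probs[name], base_probs, y)
            p_vs_base = cmp_.p_value
        else:
            p_vs_base = np.nan
        cp = _conc.youden_cutpoint(roc)
        # biomarker-scale cut-off for unadjusted single-biomarker models
        if len(MODEL_ROSTER[name]) == 1:
            b = MODEL_ROSTER[name][0]
            broc = _conc.roc_curve(
                t[b].to_numpy(), y, orientation=BIOMARKER_ORIENTATION[b]
            )
            bcp = _conc.youden_cutpoint(broc)
            biomarker_cut = bcp.threshold
        else:
            biomarker_cut = np.nan
        rows_conc.append(
            {"model": name, "auc": roc.auc, "ci_lower": ci.lower, "ci_upper": ci.upper,
             "delong_p_vs_base": p_vs_base}
        )
        perf = _econ.TestPerformance(cp.sensitivity, cp.specificity, label=name)
        proj = _econ.solve_screening(perf, prevalence, config.n_target)
        rows_screen.append(
            {"model": name, "sensitivity_pct": 100 * cp.sensitivity,
             "specificity_pct": 100 * cp.specificity, "accuracy_pct": 100 * cp.accuracy,
             "youden_threshold_prob": cp.threshold, "biomarker_threshold": biomarker_cut,
             "nns": proj.rounded()["nns"], "nps": proj.rounded()["nps"],
             "scans_saved": proj.rounded()["scans_saved"],
             "pct_scans_saved": proj.pct_scans_saved}
        )

    concordance = pd.DataFrame(rows_conc)
    screening = pd.DataFrame(rows_screen)
    # percent scans saved relative to the base model (negative = worse)
    if "base" in config.roster:
        base_nps = float(
            screening.loc[screening["model"] == "base", "nps"].iloc[0]
        )
        screening["pct_vs_base"] = 100.0 * (base_nps - screening["nps"]) / base_nps
        screening.loc[screening["model"] == "base", "pct_vs_base"] = np.nan

    # --- economics stage ------------------------------------------------
    sweep_rows, cost_rows = [], []
    for _, row in screening.iterrows():
        perf = _econ.TestPerformance(
            row["sensitivity_pct"] / 100.0, row["specificity_pct"] / 100.0, row["model"]
        )
        sw = _econ.prevalence_sweep(
            perf, config.sweep_min, config.sweep_max, config.sweep_step, config.n_target
        )
        sw.insert(0, "model", row["model"])
        sweep_rows.append(sw)
        proj = _econ.solve_screening(perf, prevalence, config.n_target)
        for r in config.cost_ratios:
            sc = _econ.relative_cost(proj, pet_cost=1.0, blood_cost=float(r))
            cost_rows.append(
                {"model": row["model"], "blood_over_pet_cost": float(r),
                 "relative_cost": sc.relative_cost}
            )
    sweep = pd.concat(sweep_rows, ignore_index=True)
    costs = pd.DataFrame(cost_rows)

    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_analysis": int(len(t)),
        "n_pet_positive": int(y.sum()),
        "prevalence": prevalence,
        "suvr_cutpoint": cut.suvr_threshold,
        "cutpoint_mode": config.cutpoint_mode,
    }
    bundle = ReportBundle(
        cohort_summary=_cohort_summary(t, y),
        concordance=concordance,
        screening=screening,
        sweep=sweep,
        costs=costs,
        metadata=metadata,
    )
    if config.outdir is not None:
        bundle.write(config.outdir)
    return bundle


def sweep_pet_cutoff(
    config: AnalysisConfig,
    cut_min: float = 0.57,
    cut_max: float = 0.65,
    step: float = 0.01,
    biomarker: str = "lcms_ab4240",
) -> pd.DataFrame:
    """Sensitivity analysis over the SUVR positivity cut-point.

    For each cut-point in the range: reclassify PET status, recompute the
    Youden cut-point of the chosen plasma biomarker, and split the
    plasma-vs-PET discordance into plasma-positive/PET-negative and
    plasma-negative/PET-positive fractions. Cut-points yielding a single
    PET class are flagged and skipped.
    """
    if step <= 0 or cut_min > cut_max:
        raise ValueError("need cut_min <= cut_max and step > 0")
    if biomarker not in BIOMARKER_ORIENTATION:
        raise ConfigError(f"unknown biomarker {biomarker!r}")
    raw = _load_cohort(config)
    t = prepare_analysis_table(raw)
    scores = t[biomarker].to_numpy()
    orientation = BIOMARKER_ORIENTATION[biomarker]
    n_steps = int(round((cut_max - cut_min) / step))
    rows = []
    for k in range(n_steps + 1):
        c = cut_min + k * step
        y = _pet.classify_pet(t["suvr"].to_numpy(), float(c))
        if y.all() or not y.any():
            rows.append({"suvr_cutoff": c, "skipped": True})
            logger.warning("cut-off %.3f yields a single PET class; skipped", c)
            continue
        roc = _conc.roc_curve(scores, y, orientation=orientation)
        cp = _conc.youden_cutpoint(roc)
        if orientation == "higher":
            plasma_pos = scores >= cp.threshold
        else:
            plasma_pos = scores <= cp.threshold
        n = y.size
        rows.append(
            {
                "suvr_cutoff": float(c),
                "skipped": False,
                "pet_positive_frac": float(y.mean()),
                "plasma_threshold": cp.threshold,
                "sensitivity": cp.sensitivity,
                "specificity": cp.specificity,
                "youden_j": cp.youden_j,
                "frac_plasma_pos_pet_neg": float((plasma_pos & ~y).sum() / n),
                "frac_plasma_neg_pet_pos": float((~plasma_pos & y).sum() / n),
                "frac_discordant": float((plasma_pos != y).sum() / n),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flat key-value config files

_CONFIG_KEYS = {
    "input_path": str,
    "n_participants": int,
    "cutpoint_mode": str,
    "fixed_cutpoint": float,
    "percentile": float,
    "n_target": float,
    "sweep_min": float,
    "sweep_max": float,
    "sweep_step": float,
    "cost_ratios": str,
    "roster": str,
    "seed": int,
    "outdir": str,
}


def parse_flat_config(path) -> AnalysisConfig:
    """Parse a flat ``key = value`` config file into an AnalysisConfig.

    Blank lines and ``#`` comments are ignored; unknown keys are rejected.
    ``roster`` and ``cost_ratios`` take comma-separated values.
    """
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        kwargs[key] = _CONFIG_KEYS[key](value)
    if "roster" in kwargs:
        kwargs["roster"] = tuple(s.strip() for s in kwargs["roster"].split(",") if s.strip())
    if "cost_ratios" in kwargs:
        kwargs["cost_ratios"] = tuple(
            float(s) for s in kwargs["cost_ratios"].split(",") if s.strip()
        )
    return AnalysisConfig(**kwargs)
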