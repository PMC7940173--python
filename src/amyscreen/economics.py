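"""Screening-programme arithmetic: from a blood test's sensitivity and
specificity to the numbers and costs of a PET-confirmation workflow.

The design question: how many people must be pre-screened with a blood test
(NNS), and how many of those proceed to an amyloid PET scan (NPS), to obtain
a target number ``n`` of PET-positive individuals from a population with
positivity prevalence ``p``? The expected 2x2 table (A true positive,
B false positive, C false negative, D true negative) solves in closed form:

    A = n,    A + C = n / sens,    NNS = (n / sens) / p,
    B = (1 - spec) * (NNS - n/sens),    D = spec * (NNS - n/sens),
    NPS = A + B,  PPV = A / (A + B),  NPV = D / (C + D).

Without screening, ``n / p`` scans are needed; the scans saved are that
baseline minus NPS. All arithmetic is continuous-first; integers are
produced only at reporting time (rounded half away from zero), because
printed sensitivities/specificities rounded to one decimal shift the counts
by a couple of units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InfeasibleDesignError

__all__ = [
    "TestPerformance",
    "ScreeningProjection",
    "CostScenario",
    "round_half_away",
    "solve_screening",
    "scans_saved",
    "relative_cost",
    "prevalence_sweep",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class TestPerformance:
    """A screening test summarised by its sensitivity and specificity."""

    sensitivity: float
    specificity: float
    label: str = ""

    def __post_init__(self) -> None:
        for name, v in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")

    @property
    def informative(self) -> bool:
        """True when sensitivity + specificity > 1 (better than chance)."""
        return self.sensitivity + self.specificity > 1.0


@dataclass(frozen=True)
class ScreeningProjection:
    """The solved expected 2x2 screening design (continuous cells)."""

    performance: TestPerformance
    prevalence: float
    n_target: float
    a: float  # true positives (the target)
    b: float  # false positives
    c: float  # false negatives
    d: float  # true negatives
    nns: float
    nps: float
    ppv: float
    npv: float
    baseline_scans: float
    scans_saved: float
    pct_scans_saved: float  # percent, 0-100

    def rounded(self) -> dict[str, int]:
        """Reporting integers (half away from zero) for the count fields."""
        return {
            "nns": round_half_away(self.nns),
            "nps": round_half_away(self.nps),
            "baseline_scans": round_half_away(self.baseline_scans),
            "scans_saved": round_half_away(self.scans_saved),
        }


@dataclass(frozen=True)
class CostScenario:
    """Relative cost of a screened vs unscreened programme.

    ``relative_cost < 1`` means pre-screening with the blood test is cheaper
    than scanning everyone needed to reach the same number of PET-positive
    individuals. Per-unit costs are assumed to absorb setup costs.
    """

    pet_cost: float
    blood_cost: float
    relative_cost: float


def solve_screening(
    perf: TestPerformance, prevalence: float, n_target: float = 100
) -> ScreeningProjection:
    """Solve the expected screening 2x2 table in closed form.

    Parameters
    ----------
    perf : TestPerformance
        Sensitivity must be positive (a test that never flags positives
        cannot reach the target).
    prevalence : float
        Population PET-positivity prevalence, strictly in (0, 1).
    n_target : float
        Number of PET-positive individuals sought (default 100).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0, 1); got {prevalence}")
    if perf.sensitivity <= 0.0:
        raise InfeasibleDesignError("sensitivity must be positive to reach the target")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    sens, spec, p = perf.sensitivity, perf.specificity, prevalence
    a = float(n_target)
    apc = a / sens  # A + C: positives among those screened
    nns = apc / p
    bpd = nns - apc
    b = (1.0 - spec) * bpd
    d = spec * bpd
    c = apc - a
    nps = a + b
    baseline = a / p
    saved = baseline - nps
    return ScreeningProjection(
        performance=perf,
        prevalence=p,
        n_target=a,
        a=a,
        b=b,
        c=c,
        d=d,
        nns=nns,
        nps=nps,
        ppv=a / nps,
        npv=d / (c + d) if (c + d) > 0 else 1.0,
        baseline_scans=baseline,
        scans_saved=saved,
        pct_scans_saved=100.0 * saved / baseline,
    )


def scans_saved(
    projection: ScreeningProjection, reference: ScreeningProjection | None = None
) -> dict[str, float]:
    """Scan-saving summary of a projection, optionally against a reference.

    The percent saved has the closed form ``(1 - p) * (1 - (1 - spec)/sens)``
    (as a fraction of the no-screening baseline ``n/p``). When a reference
    projection is given, also reports the percent saved relative to the
    reference's NPS (negative when the test is worse than the reference).
    """
    out = {
        "scans_saved": projection.scans_saved,
        "baseline_scans": projection.baseline_scans,
        "pct_scans_saved": projection.pct_scans_saved,
    }
    if reference is not None:
        out["pct_vs_reference"] = (
            100.0 * (reference.nps - projection.nps) / reference.nps
        )
    return out


def relative_cost(
    projection: ScreeningProjection, pet_cost: float, blood_cost: float
) -> CostScenario:
    """Cost of the screened programme relative to scanning everyone.

    ``relative_cost = (NNS * y + NPS * x) / ((n/p) * x)`` with PET cost ``x``
    and blood-test cost ``y``; linear and increasing in ``y/x``.
    """
    if pet_cost <= 0:
        raise ValueError("pet_cost must be positive")
    if blood_cost < 0:
        raise ValueError("blood_cost must be non-negative")
    ratio = (projection.nns * blood_cost + projection.nps * pet_cost) / (
        projection.baseline_scans * pet_cost
    )
    return CostScenario(pet_cost=pet_cost, blood_cost=blood_cost, relative_cost=ratio)


def prevalence_sweep(
    perf: TestPerformance,
    p_min: float = 0.10,
    p_max: float = 0.50,
    step: float = 0.05,
    n_target: float = 100,
) -> pd.DataFrame:
    """Predictive values and scan reduction across a prevalence range.

    One row per prevalence from ``p_min`` to ``p_max`` inclusive in ``step``
    increments; each row is consistent with :func:`solve_screening` at that
    prevalence. Columns: ``prevalence, ppv, npv, pct_scans_saved, nns, nps``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0.0 < p_min <= p_max < 1.0:
        raise ValueError("need 0 < p_min <= p_max < 1")
    n_steps = int(round((p_max - p_min) / step))
    grid = p_min + step * np.arange(n_steps + 1)
    grid = grid[grid <= p_max + 1e-12]
    rows = []
    for p in grid:
        proj = solve_screening(perf, float(p), n_target)
        rows.append(
            {
                "prevalence": float(p),
                "ppv": proj.ppv,
                "npv": proj.npv,
                "pct_scans_saved": proj.pct_scans_saved,
                "nns": proj.nns,
                "nps": proj.nps,
            }
        )
    return pd.DataFrame(rows)
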