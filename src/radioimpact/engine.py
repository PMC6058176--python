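"""Simplified deaths-averted engine in the Lives Saved Tool (LiST) tradition.

The engine converts a change in intervention coverage into cause-specific
deaths averted against a fixed mortality envelope:

    impact fraction   phi = E * AF * (C1 - C0) / (1 - E * AF * C0)

where E is the intervention's effectiveness (proportional mortality
reduction among covered, affected cases), AF the affected fraction of the
cause's deaths, and C0 -> C1 the coverage change.  phi is algebraically the
relative drop in residual risk, 1 - (1 - E*AF*C1)/(1 - E*AF*C0), and is the
fraction of the cause's current deaths averted by the coverage change.
Several interventions acting on one cause combine through their residuals:

    phi_comb = 1 - prod_i (1 - phi_i)

Coverage changes are driven by the trial's utilisation effects: the
relative increase r in facility attendance for a diagnosis group, scaled by
the proportion q of attenders who actually receive the effective treatment
(``treatment_with_receipt``), applied directly where care-seeking is itself
the coverage proxy (``careseeking_proxy``, as for oral antibiotics for
pneumonia) or where the effect is already a coverage change (``direct``,
for antenatal-care and facility-delivery effects):

    C_y = min(1, C0 * (1 + r_y * q))        (q = 1 outside receipt mode)

The mortality envelope turns an under-five mortality rate (deaths per 1000
live births) and annual live births into total and cause-specific deaths in
the absence of the intervention; those are the denominators for the
percentage mortality reductions.  The same algebra applies unchanged to a
maternal envelope with ANC/delivery-linked causes.

Only interventions targeted by the campaign enter the engine, so lives
saved through any non-targeted channel are excluded by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .utils import round_half_away

logger = logging.getLogger(__name__)

COVERAGE_MODES = ("treatment_with_receipt", "careseeking_proxy", "direct")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MortalityEnvelope:
    """Per-year deaths implied by a mortality rate, live births and cause structure."""

    years: list[int]
    u5mr: dict[int, float]            # deaths per 1000 live births, by year
    live_births: dict[int, float]     # live births, by year
    cause_fractions: dict[str, float]  # cause -> fraction of deaths; sum <= 1

    def __post_init__(self):
        for y in self.years:
            if self.u5mr[y] <= 0:
                raise ValueError(f"u5mr must be positive (year {y})")
            if self.live_births[y] <= 0:
                raise ValueError(f"live births must be positive (year {y})")
        fr = np.array(list(self.cause_fractions.values()), dtype=float)
        if np.any((fr < 0) | (fr > 1)):
            raise ValueError("cause fractions must be in [0, 1]")
        if fr.sum() > 1 + 1e-9:
            raise ValueError("cause fractions must sum to <= 1")

    def deaths(self, year: int) -> float:
        """Total deaths in the absence of the intervention: u5mr * births / 1000."""
        return self.u5mr[year] * self.live_births[year] / 1000.0

    def cause_deaths(self, cause: str, year: int) -> float:
        return self.deaths(year) * self.cause_fractions[cause]

    def scaled(self, factor: float) -> "MortalityEnvelope":
        """Envelope for a population share (scales live births, not rates)."""
        return MortalityEnvelope(
            years=list(self.years),
            u5mr=dict(self.u5mr),
            live_births={y: v * factor for y, v in self.live_births.items()},
            cause_fractions=dict(self.cause_fractions),
        )


@dataclass
class InterventionSpec:
    """An intervention's effectiveness and the cause(s) of death it acts on."""

    name: str
    effectiveness: float
    causes: list[str]
    affected_fraction: float | dict[str, float] = 1.0
    coverage_mode: str = "treatment_with_receipt"

    def __post_init__(self):
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ValueError("effectiveness must be in [0, 1]")
        if self.coverage_mode not in COVERAGE_MODES:
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")
        for c in self.causes:
            af = self.af(c)
            if not 0.0 <= af <= 1.0:
                raise ValueError("affected fraction must be in [0, 1]")
            if self.effectiveness * af > 1.0:
                raise ValueError("E * AF must be <= 1")

    def af(self, cause: str) -> float:
        if isinstance(self.affected_fraction, dict):
            return float(self.affected_fraction[cause])
        return float(self.affected_fraction)


@dataclass
class CoveragePath:
    """Baseline and per-year coverage of one intervention."""

    name: str
    baseline: float
    per_year: dict[int, float]

    def __post_init__(self):
        for v in [self.baseline, *self.per_year.values()]:
            if not 0.0 <= v <= 1.0:
                raise ValueError("coverages must lie in [0, 1]")


@dataclass
class LivesSavedResult:
    """Deaths averted by year/intervention/cause, plus totals and % reductions."""

    detail: pd.DataFrame          # year, intervention, cause, averted (single-phi attribution)
    totals: dict[int, float]      # per-year deaths averted (residual-combined)
    envelope_deaths: dict[int, float]
    pct_reduction: dict[int, float]

    @property
    def total(self) -> float:
        return float(sum(self.totals.values()))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def coverage_from_utilisation(
    c0: float, r: float, q: float = 1.0, mode: str = "treatment_with_receipt"
) -> float:
    """Per-year coverage implied by a relative utilisation increase.

    Receipt scaling q applies only in ``treatment_with_receipt`` mode; in
    the care-seeking-proxy and direct modes the utilisation effect is the
    coverage change.  Coverage is capped at 1 with a saturation warning.
    """
    if not 0.0 <= c0 <= 1.0 or not 0.0 <= q <= 1.0:
        raise ValueError("C0 and q must lie in [0, 1]")
    if r <= -1.0:
        raise ValueError("relative effect r must be > -1")
    if mode not in COVERAGE_MODES:
        raise ValueError(f"unknown coverage mode {mode!r}")
    mult = 1.0 + r * q if mode == "treatment_with_receipt" else 1.0 + r
    c1 = c0 * mult
    if c1 > 1.0:
        logger.warning("coverage saturated at 1 (C0=%.3f, r=%.3f, q=%.3f)", c0, r, q)
        c1 = 1.0
    return float(c1)


def impact_fraction(e: float, af: float, c0: float, c1: float) -> float:
    """Fraction of current cause-specific deaths averted by coverage C0 -> C1."""
    for v, name in ((c0, "C0"), (c1, "C1")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    denom = 1.0 - e * af * c0
    if denom <= 0.0:
        raise ValueError("E * AF * C0 must be < 1")
    return e * af * (c1 - c0) / denom


def combine_interventions(phis) -> float:
    """Residual combination of impact fractions acting on one cause."""
    phis = np.asarray(list(phis), dtype=float)
    return float(1.0 - np.prod(1.0 - phis))


def lives_saved(
    envelope: MortalityEnvelope,
    coverage_paths: dict[str, CoveragePath],
    specs: list[InterventionSpec],
) -> LivesSavedResult:
    """Per-year deaths averted for a set of interventions against one envelope.

    Per-year totals use the residual combination of all impact fractions
    acting on each cause; the ``detail`` table attributes deaths by each
    intervention's own impact fraction, so the detail rows for a shared
    cause can sum to slightly more than the combined total.
    """
    for spec in specs:
        if spec.name not in coverage_paths:
            raise ValueError(f"no coverage path for intervention {spec.name!r}")
        for c in spec.causes:
            if c not in envelope.cause_fractions:
                raise ValueError(f"cause {c!r} of {spec.name!r} missing from envelope")
    years = list(envelope.years)
    for spec in specs:
        missing = [y for y in years if y not in coverage_paths[spec.name].per_year]
        if missing:
            raise ValueError(f"coverage path for {spec.name!r} missing years {missing}")

    rows = []
    totals: dict[int, float] = {}
    for y in years:
        by_cause: dict[str, list[float]] = {}
        for spec in specs:
            path = coverage_paths[spec.name]
            for cause in spec.causes:
                phi = impact_fraction(
                    spec.effectiveness, spec.af(cause), path.baseline, path.per_year[y]
                )
                by_cause.setdefault(cause, []).append(phi)
                rows.append(
                    {
                        "year": y,
                        "intervention": spec.name,
                        "cause": cause,
                        "averted": envelope.cause_deaths(cause, y) * phi,
                    }
                )
        totals[y] = float(
            sum(
                envelope.cause_deaths(cause, y) * combine_interventions(phis)
                for cause, phis in by_cause.items()
            )
        )
    env_deaths = {y: envelope.deaths(y) for y in years}
    pct = {y: 100.0 * totals[y] / env_deaths[y] for y in years}
    return LivesSavedResult(
        detail=pd.DataFrame(rows),
        totals=totals,
        envelope_deaths=env_deaths,
        pct_reduction=pct,
    )


def weighted_average_reduction(result: LivesSavedResult) -> float:
    """Deaths-weighted average % mortality reduction across years (unrounded).

    Display rounds to one decimal, half away from zero.
    """
    total_deaths = sum(result.envelope_deaths.values())
    if total_deaths <= 0:
        raise ValueError("zero total deaths in envelope")
    return 100.0 * sum(result.totals.values()) / total_deaths


def display_average_reduction(result: LivesSavedResult) -> float:
    return float(round_half_away(weighted_average_reduction(result), 1))
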