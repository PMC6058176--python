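"""Scenario algebra on top of the deaths-averted engine.

A scenario bundles a mortality envelope, intervention definitions (with
baseline coverage and treatment-receipt proportions), and the trial's
utilisation effects (point and 95% CI bounds per campaign year).  The
scenario layer then applies, in order:

* population scaling — either on the envelope's live births, or post hoc on
  the final lives-saved totals (the route used when national projections
  are rescaled to the trial-zone population share);
* a media-penetration index — lives saved scale linearly with the exposed
  proportion, so totals are multiplied by ``p_target / p_reference``;
* campaign-format discounting — a fixed 0/10/20% reduction in lives saved
  representing a spots-only campaign without long-format programmes;
* sensitivity bounds — the whole engine rerun with every utilisation effect
  at its lower (resp. upper) 95% bound.

Percentage reductions under discounting re-divide the discounted lives
saved by the unchanged deaths envelope, i.e. the percentage scales by the
same (1 - d) factor.  Displayed lives saved are rounded to the nearest
integer and percentages to one decimal, half away from zero; all internal
arithmetic is double precision and rounding happens once, at display.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .engine import (
    CoveragePath,
    InterventionSpec,
    LivesSavedResult,
    MortalityEnvelope,
    coverage_from_utilisation,
    lives_saved,
    weighted_average_reduction,
)
from .utils import round_half_away

logger = logging.getLogger(__name__)

BOUNDS = ("point", "low", "high")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class InterventionConfig:
    """Engine intervention plus its coverage baseline and effect linkage."""

    spec: InterventionSpec
    baseline_coverage: float
    receipt: float = 1.0            # proportion of attenders receiving effective treatment
    effect: str | None = None       # key into the scenario's utilisation effects

    def __post_init__(self):
        if not 0.0 <= self.receipt <= 1.0:
            raise ValueError("receipt proportion must be in [0, 1]")
        if not 0.0 <= self.baseline_coverage <= 1.0:
            raise ValueError("baseline coverage must be in [0, 1]")


@dataclass
class Scenario:
    """One complete scenario configuration."""

    name: str
    years: list[int]
    envelope: MortalityEnvelope
    interventions: list[InterventionConfig]
    effects: dict[str, dict[str, list[float]]]   # effect key -> bound -> per-year r
    penetration_reference: float = 0.52
    penetration_target: float = 0.52
    discounts: list[float] = field(default_factory=lambda: [0.0, 0.10, 0.20])
    population_scale: float = 1.0
    population_scale_mode: str = "post"          # 'post' (on lives saved) or 'envelope'
    rural_adjustment: float = 1.0                # multiplier on baseline coverages

    def __post_init__(self):
        if not 0.0 < self.penetration_reference <= 1.0:
            raise ValueError("penetration_reference must be in (0, 1]")
        if not 0.0 < self.penetration_target <= 1.0:
            raise ValueError("penetration_target must be in (0, 1]")
        if not 0.0 < self.population_scale <= 1.0:
            raise ValueError("population_scale must be in (0, 1]")
        for d in self.discounts:
            if not 0.0 <= d < 1.0:
                raise ValueError("discounts must lie in [0, 1)")
        if self.population_scale_mode not in ("post", "envelope"):
            raise ValueError("population_scale_mode must be 'post' or 'envelope'")
        for ic in self.interventions:
            if ic.effect is not None and ic.effect not in self.effects:
                raise ValueError(f"no utilisation effect {ic.effect!r} in scenario")
            if ic.effect is not None:
                for bound, vals in self.effects[ic.effect].items():
                    if len(vals) != len(self.years):
                        raise ValueError(
                            f"effect {ic.effect!r}/{bound} must have one value per year"
                        )

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        env = d["envelope"]
        years = [int(y) for y in d["years"]]
        envelope = MortalityEnvelope(
            years=years,
            u5mr={int(k): float(v) for k, v in env["u5mr"].items()},
            live_births={int(k): float(v) for k, v in env["live_births"].items()},
            cause_fractions={k: float(v) for k, v in env["cause_fractions"].items()},
        )
        interventions = []
        for it in d["interventions"]:
            spec = InterventionSpec(
                name=it["name"],
                effectiveness=float(it["effectiveness"]),
                causes=list(it["causes"]),
                affected_fraction=it.get("affected_fraction", 1.0),
                coverage_mode=it.get("coverage_mode", "treatment_with_receipt"),
            )
            interventions.append(
                InterventionConfig(
                    spec=spec,
                    baseline_coverage=float(it["baseline_coverage"]),
                    receipt=float(it.get("receipt", 1.0)),
                    effect=it.get("effect"),
                )
            )
        effects = {
            k: {b: [float(x) for x in v] for b, v in bounds.items()}
            for k, bounds in d.get("utilisation_effects", {}).items()
        }
        pen = d.get("penetration", {})
        return cls(
            name=d.get("name", "scenario"),
            years=years,
            envelope=envelope,
            interventions=interventions,
            effects=effects,
            penetration_reference=float(pen.get("reference", 0.52)),
            penetration_target=float(pen.get("target", 0.52)),
            discounts=[float(x) for x in d.get("discounts", [0.0, 0.10, 0.20])],
            population_scale=float(d.get("population_scale", 1.0)),
            population_scale_mode=d.get("population_scale_mode", "post"),
            rural_adjustment=float(d.get("rural_adjustment", 1.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# elementary scenario operations
# ---------------------------------------------------------------------------

def apply_penetration(lives, p_target: float, p_ref: float):
    """Scale lives saved by relative media penetration.

    Returns ``(scaled lives, implied % reduction)`` where the reduction is
    ``100 * (1 - p_target / p_ref)`` rounded to one decimal (13.1 for the
    52% -> 45.2% national-listenership adjustment).  Scale-up to a
    higher-penetration medium (p_target > p_ref) is allowed with a note.
    """
    if p_ref <= 0:
        raise ValueError("reference penetration must be positive")
    factor = p_target / p_ref
    if factor > 1.0:
        logger.info("scale-up to higher penetration (factor %.3f)", factor)
    reduction_pct = float(round_half_away(100.0 * (1.0 - factor), 1))
    return np.asarray(lives, dtype=float) * factor, reduction_pct


def apply_discount(lives, d: float):
    """Campaign-format discount: lives * (1 - d); rounding happens at display."""
    if not 0.0 <= d < 1.0:
        raise ValueError("discount must lie in [0, 1)")
    return np.asarray(lives, dtype=float) * (1.0 - d)


def average_reduction_from_table(averted, pct_reductions) -> float:
    """Deaths-weighted average % reduction from per-year (averted, %) pairs.

    The per-year deaths denominators are implied as averted / (pct / 100);
    the average is total averted over total implied deaths, to one decimal.
    """
    averted = np.asarray(averted, dtype=float)
    pct = np.asarray(pct_reductions, dtype=float)
    if np.any(pct <= 0):
        raise ValueError("percentage reductions must be positive to imply denominators")
    implied_deaths = averted / (pct / 100.0)
    return float(round_half_away(100.0 * averted.sum() / implied_deaths.sum(), 1))


# ---------------------------------------------------------------------------
# scenario runs
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Lives saved and % mortality reductions for one scenario.

    ``grid`` holds one row per year x discount with point/low/high lives
    saved and percentage reductions (unrounded); ``display_grid()`` applies
    the table rounding.
    """

    name: str
    grid: pd.DataFrame
    avg_reduction: dict[str, dict[float, float]]   # bound -> discount -> weighted avg %
    totals: dict[str, dict[float, float]]          # bound -> discount -> total lives
    penetration_factor: float
    penetration_reduction_pct: float
    engine_results: dict[str, LivesSavedResult]

    def display_grid(self) -> pd.DataFrame:
        out = self.grid.copy()
        for c in out.columns:
            if c.startswith("lives_"):
                out[c] = [int(round_half_away(v)) for v in out[c]]
            elif c.startswith("pct_"):
                out[c] = [float(round_half_away(v, 1)) for v in out[c]]
        return out


def _effect_for(scn: Scenario, ic: InterventionConfig, bound: str) -> list[float]:
    if ic.effect is None:
        return [0.0] * len(scn.years)
    eff = scn.effects[ic.effect]
    if bound not in eff:
        raise ValueError(f"effect {ic.effect!r} has no {bound!r} bound")
    return eff[bound]


def run_engine_for_bound(scn: Scenario, bound: str) -> LivesSavedResult:
    """One full engine run with every utilisation effect at the given bound."""
    envelope = scn.envelope
    if scn.population_scale_mode == "envelope" and scn.population_scale != 1.0:
        envelope = envelope.scaled(scn.population_scale)
    paths: dict[str, CoveragePath] = {}
    specs: list[InterventionSpec] = []
    for ic in scn.interventions:
        r_years = _effect_for(scn, ic, bound)
        c0 = min(1.0, ic.baseline_coverage * scn.rural_adjustment)
        q = ic.receipt if ic.spec.coverage_mode == "treatment_with_receipt" else 1.0
        per_year = {
            y: coverage_from_utilisation(c0, r, q, ic.spec.coverage_mode)
            for y, r in zip(scn.years, r_years)
        }
        paths[ic.spec.name] = CoveragePath(name=ic.spec.name, baseline=c0, per_year=per_year)
        specs.append(ic.spec)
    return lives_saved(envelope, paths, specs)


def run_scenario(scn: Scenario, bounds: tuple[str, ...] = BOUNDS) -> ScenarioResult:
    """Run a scenario across sensitivity bounds and the discount grid."""
    have_bounds = [
        b
        for b in bounds
        if b == "point" or all(b in scn.effects[k] for k in scn.effects)
    ]
    engine_results = {b: run_engine_for_bound(scn, b) for b in have_bounds}

    factor, reduction_pct = 1.0, 0.0
    if scn.penetration_target != scn.penetration_reference:
        _, reduction_pct = apply_penetration(
            [1.0], scn.penetration_target, scn.penetration_reference
        )
        factor = scn.penetration_target / scn.penetration_reference
    post = factor * (scn.population_scale if scn.population_scale_mode == "post" else 1.0)

    rows = []
    totals: dict[str, dict[float, float]] = {b: {} for b in have_bounds}
    avg: dict[str, dict[float, float]] = {b: {} for b in have_bounds}
    for d in scn.discounts:
        for y in scn.years:
            row = {"year": y, "discount": d}
            for b in have_bounds:
                res = engine_results[b]
                lives = res.totals[y] * post * (1.0 - d)
                row[f"lives_{b}"] = lives
                row[f"pct_{b}"] = 100.0 * lives / res.envelope_deaths[y]
            rows.append(row)
        for b in have_bounds:
            res = engine_results[b]
            tot = sum(res.totals.values()) * post * (1.0 - d)
            totals[b][d] = tot
            avg[b][d] = 100.0 * tot / sum(res.envelope_deaths.values())
    grid = pd.DataFrame(rows)
    return ScenarioResult(
        name=scn.name,
        grid=grid,
        avg_reduction=avg,
        totals=totals,
        penetration_factor=factor,
        penetration_reduction_pct=reduction_pct,
        engine_results=engine_results,
    )


def sensitivity_bounds(scn: Scenario) -> ScenarioResult:
    """Scenario run including the low/high utilisation-effect bounds.

    Requires every effect to carry both 95% CI bounds; the low bound may be
    negative (coverage below baseline), in which case a year's contribution
    from that intervention is negative.
    """
    for k, eff in scn.effects.items():
        for b in ("low", "high"):
            if b not in eff:
                raise ValueError(f"effect {k!r} is missing its {b!r} bound")
    return run_scenario(scn, bounds=BOUNDS)


def country_scaleup(
    countries: list[Scenario] | dict, years: list[int] | None = None
) -> tuple[dict[str, ScenarioResult], pd.DataFrame]:
    """Multi-country scale-up grid: engine + penetration + discount per country.

    ``countries`` may be parsed Scenario objects or a raw config mapping
    with a ``countries:`` list (each entry a full scenario, typically
    sharing the trial's utilisation effects).  Returns per-country results
    and a tidy display grid (country, discount, year, lives saved, %
    reduction) shaped like a multi-country projection table.
    """
    if isinstance(countries, dict):
        shared = countries.get("utilisation_effects", {})
        scns = []
        for c in countries["countries"]:
            c = dict(c)
            c.setdefault("utilisation_effects", shared)
            scns.append(Scenario.from_dict(c))
        countries = scns
    results: dict[str, ScenarioResult] = {}
    rows = []
    for scn in countries:
        if years is not None and list(scn.years) != list(years):
            raise ValueError(f"country {scn.name!r} years {scn.years} != {years}")
        res = run_scenario(scn, bounds=("point",))
        results[scn.name] = res
        disp = res.display_grid()
        for _, r in disp.iterrows():
            rows.append(
                {
                    "country": scn.name,
                    "discount": r["discount"],
                    "year": int(r["year"]),
                    "lives_saved": int(r["lives_point"]),
                    "pct_reduction": float(r["pct_point"]),
                }
            )
    grid = pd.DataFrame(rows).sort_values(["discount", "year", "country"]).reset_index(drop=True)
    return results, grid
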