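"""Synthetic facility-utilisation data with the structure the ITS analysis assumes.

The generator emulates a pair-matched cluster randomised trial of a mass
radio campaign: 14 rural clusters in 7 matched pairs, monthly under-five
consultation counts by clinical diagnosis category over a 48-month window
(Jan 2011 - Dec 2014), with seasonality, a secular trend, a systematic
between-arm baseline offset, a continuous cluster-level confounder score,
cluster random intercepts, and step intervention effects by campaign year in
the intervention arm only.

Counts are Poisson conditional on the cluster intercept, mirroring the
mixed-effects Poisson model fitted downstream (so counts are marginally
over-dispersed when ``cluster_sd > 0``).  Diagnosis counts exceed
consultations because health workers record multiple diagnoses per visit;
the per-arm "multiplicity" (diagnoses per consultation) drifts linearly from
a start to an end value over the study window.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .compress import apportion, category_columns

logger = logging.getLogger(__name__)

ARMS = ("control", "intervention")
PERIODS = ("baseline", "year1", "year2", "year3")

DEFAULT_CATEGORIES = ("malaria", "pneumonia", "diarrhoea", "urti", "malnutrition", "other")

#: category shares of all-cause consultations: malaria ~55%, pneumonia ~18%,
#: diarrhoea ~3% as reported for the trial area; remainder spread over
#: non-targeted categories.
DEFAULT_CATEGORY_MIX = {
    "malaria": 0.55,
    "pneumonia": 0.18,
    "diarrhoea": 0.03,
    "urti": 0.10,
    "malnutrition": 0.05,
    "other": 0.09,
}

#: true intervention-arm rate ratios by (category, campaign year), matching
#: the trial's reported effect sizes for the targeted illnesses; non-targeted
#: categories carry no effect.
DEFAULT_TRUE_EFFECTS = {
    ("malaria", "year1"): 1.56,
    ("malaria", "year2"): 1.37,
    ("malaria", "year3"): 1.35,
    ("pneumonia", "year1"): 1.39,
    ("pneumonia", "year2"): 1.25,
    ("pneumonia", "year3"): 1.11,
    ("diarrhoea", "year1"): 1.73,
    ("diarrhoea", "year2"): 1.60,
    ("diarrhoea", "year3"): 2.07,
}

#: diagnoses-per-consultation drift, start -> end of window, by arm.
DEFAULT_MULTIPLICITY_PATH = {"control": (1.23, 2.17), "intervention": (1.51, 2.29)}

# log-scale month-of-year multipliers (Jan..Dec); single rainy-season peak
# around September, as for malaria transmission in the Sahel.
DEFAULT_SEASON = (-0.20, -0.25, -0.15, -0.05, 0.05, 0.15, 0.30, 0.40, 0.35, 0.20, -0.10, -0.30)


def month_range(start: tuple[int, int] = (2011, 1), n_months: int = 48) -> list[tuple[int, int]]:
    """Ordered (year, month-of-year) pairs for a study window."""
    y, m = start
    out = []
    for _ in range(n_months):
        out.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def default_period_breaks(
    months: list[tuple[int, int]], campaign_start: tuple[int, int] = (2012, 3)
) -> dict[tuple[int, int], str]:
    """Label calendar months: pre-campaign baseline, then 12-month campaign years.

    The third campaign year is truncated wherever the window ends; months
    more than 36 from campaign start would also be labelled year3.
    """
    start_idx = None
    for i, ym in enumerate(months):
        if ym == campaign_start:
            start_idx = i
            break
    if start_idx is None:
        raise ValueError(f"campaign start {campaign_start} not inside the study window")
    breaks = {}
    for i, ym in enumerate(months):
        if i < start_idx:
            breaks[ym] = "baseline"
        else:
            k = (i - start_idx) // 12
            breaks[ym] = f"year{min(k + 1, 3)}"
    return breaks


@dataclass
class TrialDesignConfig:
    """Design of the emulated trial and the generator's data-generating process.

    Defaults reproduce the study conditions: 7 matched pairs, 48 months
    from January 2011, campaign years starting March 2012, six diagnosis
    categories, and the reported effect sizes as true rate ratios.
    """

    n_pairs: int = 7
    months: list = field(default_factory=lambda: month_range((2011, 1), 48))
    period_breaks: dict = None  # filled in __post_init__ if None
    categories: tuple = DEFAULT_CATEGORIES
    baseline_rate: float = 800.0  # expected monthly all-cause consultations per cluster at start
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    trend: float = 0.005  # log-scale secular trend per month
    season: tuple = DEFAULT_SEASON
    arm_offset: float = -0.10  # log-scale baseline difference, intervention vs control
    confounder_effect: float = 0.20  # log-scale coefficient per unit confounder score
    cluster_sd: float = 0.25  # SD of cluster random intercepts (log scale)
    true_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS))
    multiplicity_path: dict = field(default_factory=lambda: dict(DEFAULT_MULTIPLICITY_PATH))
    seed: int = 0

    def __post_init__(self):
        self.months = [tuple(m) for m in self.months]
        if self.period_breaks is None:
            self.period_breaks = default_period_breaks(self.months)
        else:
            self.period_breaks = {tuple(k): v for k, v in self.period_breaks.items()}

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least 2 matched pairs")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        missing_mix = [c for c in self.categories if c not in self.category_mix]
        if missing_mix:
            raise ValueError(f"category_mix missing categories: {missing_mix}")
        mix_sum = sum(self.category_mix[c] for c in self.categories)
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1 (got {mix_sum})")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be >= 0")
        if len(self.season) != 12:
            raise ValueError("season must have 12 month-of-year values")
        for (cat, per), rr in self.true_effects.items():
            if rr <= 0:
                raise ValueError(f"rate ratio for {(cat, per)} must be > 0")
            if cat not in self.categories or per not in PERIODS:
                raise ValueError(f"unknown (category, period) in true_effects: {(cat, per)}")
        for arm, (m0, m1) in self.multiplicity_path.items():
            if m0 < 1 or m1 < 1:
                raise ValueError("multiplicity values must be >= 1")
        missing = [m for m in self.months if m not in self.period_breaks]
        if missing:
            raise ValueError(f"period_breaks does not cover months: {missing[:3]}...")

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["months"] = [list(m) for m in self.months]
        d["period_breaks"] = {f"{y}-{m:02d}": v for (y, m), v in self.period_breaks.items()}
        d["true_effects"] = {f"{c}/{p}": v for (c, p), v in self.true_effects.items()}
        d["categories"] = list(self.categories)
        d["season"] = list(self.season)
        d["multiplicity_path"] = {a: list(v) for a, v in self.multiplicity_path.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialDesignConfig":
        d = dict(d)
        if "months" in d:
            d["months"] = [tuple(m) for m in d["months"]]
        if "period_breaks" in d and d["period_breaks"] is not None:
            pb = {}
            for k, v in d["period_breaks"].items():
                if isinstance(k, str):
                    y, m = k.split("-")
                    pb[(int(y), int(m))] = v
                else:
                    pb[tuple(k)] = v
            d["period_breaks"] = pb
        if "true_effects" in d:
            te = {}
            for k, v in d["true_effects"].items():
                if isinstance(k, str):
                    c, p = k.split("/")
                    te[(c, p)] = float(v)
                else:
                    te[tuple(k)] = float(v)
            d["true_effects"] = te
        if "categories" in d:
            d["categories"] = tuple(d["categories"])
        if "season" in d:
            d["season"] = tuple(d["season"])
        if "multiplicity_path" in d:
            d["multiplicity_path"] = {a: tuple(v) for a, v in d["multiplicity_path"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TrialDesignConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def multiplicity_at(path: tuple[float, float], month_index: int, n_months: int) -> float:
    """Linear interpolation of diagnoses-per-consultation over the window."""
    m0, m1 = path
    if n_months <= 1:
        return float(m0)
    frac = month_index / (n_months - 1)
    return float(m0 + (m1 - m0) * frac)


def generate_dataset(config: TrialDesignConfig) -> pd.DataFrame:
    """Draw one synthetic records table (one row per cluster per calendar month).

    Category diagnosis counts are Poisson with log-mean

        log(baseline_rate * category share) + trend * t + season[month-of-year]
        + arm_offset * 1[intervention] + confounder_effect * score
        + cluster intercept + log(true RR)   (intervention arm, affected periods)

    and ``all_cause`` is the category-count total divided by the arm's
    interpolated multiplicity for that month, rounded to the nearest integer.
    Fully reproducible for a given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    months = config.months
    T = len(months)
    cats = list(config.categories)
    C = len(cats)
    season = np.asarray(config.season)
    base_log = np.log(config.baseline_rate) + np.log(
        np.array([config.category_mix[c] for c in cats])
    )
    periods = [config.period_breaks[m] for m in months]
    moy = np.array([m for (_, m) in months])
    t_idx = np.arange(T)

    # log RR lookup: (T, C) for the intervention arm
    log_rr = np.zeros((T, C))
    for j, c in enumerate(cats):
        for i, per in enumerate(periods):
            rr = config.true_effects.get((c, per), 1.0)
            log_rr[i, j] = np.log(rr)

    rows = []
    cluster_no = 0
    for pair in range(config.n_pairs):
        for arm in ARMS:
            cluster_no += 1
            cid = f"c{cluster_no:02d}"
            score = float(rng.normal())
            b = float(rng.normal(0.0, config.cluster_sd)) if config.cluster_sd > 0 else 0.0
            eta = (
                base_log[None, :]
                + config.trend * t_idx[:, None]
                + season[moy - 1][:, None]
                + (config.arm_offset if arm == "intervention" else 0.0)
                + config.confounder_effect * score
                + b
            )
            if arm == "intervention":
                eta = eta + log_rr
            counts = rng.poisson(np.exp(eta))  # (T, C)
            mult = np.array(
                [multiplicity_at(config.multiplicity_path[arm], t, T) for t in range(T)]
            )
            all_cause = np.rint(counts.sum(axis=1) / mult).astype(np.int64)
            for i, (yy, mm) in enumerate(months):
                row = {
                    "cluster_id": cid,
                    "pair_id": pair,
                    "arm": arm,
                    "confounder_score": score,
                    "year": yy,
                    "month": mm,
                    "month_index": i,
                    "month_of_year": mm,
                    "period": periods[i],
                }
                for j, c in enumerate(cats):
                    row[c] = int(counts[i, j])
                row["all_cause"] = int(all_cause[i])
                rows.append(row)
    df = pd.DataFrame(rows)
    return df


def inject_multiplicity(df: pd.DataFrame, multiplicity_path: dict) -> pd.DataFrame:
    """Inflate category counts so diagnoses/consultation follow the arm's path.

    The per-record target total is ``round(all_cause * m(t))`` with ``m`` the
    linear start->end interpolation for the record's arm; the inflation is
    allocated proportionally to the existing counts by largest-remainder
    apportionment.  Records with ``all_cause == 0`` (or no recorded
    diagnoses) pass through unchanged.
    """
    for arm, (m0, m1) in multiplicity_path.items():
        if m0 < 1 or m1 < 1:
            raise ValueError("multiplicity values must be >= 1")
    cats = category_columns(df)
    out = df.copy()
    T = int(df["month_index"].max()) + 1
    counts = df[cats].to_numpy(dtype=np.int64).copy()
    for i, (_, row) in enumerate(df.iterrows()):
        ac = int(row["all_cause"])
        if ac == 0 or counts[i].sum() == 0:
            continue
        m = multiplicity_at(tuple(multiplicity_path[row["arm"]]), int(row["month_index"]), T)
        target = int(np.rint(ac * m))
        counts[i] = apportion(counts[i], target)
    out[cats] = counts
    return out


# -- flat-file interface -----------------------------------------------------

CSV_META = ["cluster_id", "pair_id", "arm", "confounder_score", "year", "month", "period"]


def write_records(df: pd.DataFrame, path) -> None:
    """Write records as a flat CSV (meta columns, one column per category, all_cause)."""
    cats = category_columns(df)
    cols = CSV_META + cats + ["all_cause"]
    df.to_csv(path, index=False, columns=cols, float_format="%.10g")


def read_records(path) -> pd.DataFrame:
    """Read a records CSV, reconstructing month_index / month_of_year / ordering."""
    df = pd.read_csv(path)
    key = df["year"] * 12 + (df["month"] - 1)
    order = np.sort(key.unique())
    lookup = {k: i for i, k in enumerate(order)}
    df["month_index"] = key.map(lookup)
    df["month_of_year"] = df["month"]
    cats = [c for c in df.columns if c not in set(CSV_META) | {"month_index", "month_of_year", "all_cause"}]
    return df[CSV_META[:4] + ["year", "month", "month_index", "month_of_year", "period"] + cats + ["all_cause"]]
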