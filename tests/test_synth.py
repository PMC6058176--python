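"""Synthetic-data generator: reproducibility, calibration, multiplicity."""
import io

import numpy as np
import pandas as pd
import pytest

from radioimpact import (
    TrialDesignConfig,
    generate_dataset,
    inject_multiplicity,
    read_records,
    write_records,
)
from radioimpact.synth import default_period_breaks, month_range, multiplicity_at


def _flat_config(**kw):
    base = dict(
        n_pairs=7,
        baseline_rate=800.0,
        trend=0.0,
        season=(0.0,) * 12,
        arm_offset=0.0,
        confounder_effect=0.0,
        cluster_sd=0.0,
        true_effects={},
        multiplicity_path={"control": (1.0, 1.0), "intervention": (1.0, 1.0)},
        seed=0,
    )
    base.update(kw)
    return TrialDesignConfig(**base)


def test_same_seed_byte_identical():
    cfg = TrialDesignConfig(seed=42)
    bufs = []
    for _ in range(2):
        df = generate_dataset(TrialDesignConfig(seed=42))
        buf = io.StringIO()
        write_records(df, buf)
        bufs.append(buf.getvalue())
    assert bufs[0] == bufs[1]
    assert generate_dataset(cfg).equals(generate_dataset(TrialDesignConfig(seed=42)))


def test_csv_round_trip(tmp_path, trial_df):
    path = tmp_path / "records.csv"
    write_records(trial_df, path)
    back = read_records(path)
    for col in ("cluster_id", "period", "malaria", "all_cause", "month_index"):
        assert (back[col].to_numpy() == trial_df[col].to_numpy()).all()


def test_null_config_rate_ratio_near_one():
    """With no true effects and no arm offset, arms have equal rates."""
    df = generate_dataset(_flat_config(seed=3))
    for cat in ("malaria", "pneumonia", "diarrhoea"):
        a = df.loc[df.arm == "intervention", cat].sum()
        b = df.loc[df.arm == "control", cat].sum()
        se_log = np.sqrt(1.0 / a + 1.0 / b)
        assert abs(np.log(a / b)) < 4.0 * se_log


def test_all_cause_mean_matches_poisson_mean():
    """Large-sample check: mean all_cause ~= baseline_rate / multiplicity."""
    cfg = _flat_config(
        n_pairs=100,
        months=month_range((2011, 1), 1),
        period_breaks={(2011, 1): "baseline"},
        baseline_rate=1000.0,
        multiplicity_path={"control": (1.51, 1.51), "intervention": (1.51, 1.51)},
        seed=5,
    )
    df = generate_dataset(cfg)
    expected = 1000.0 / 1.51
    se = np.sqrt(1000.0) / 1.51 / np.sqrt(len(df))
    assert abs(df["all_cause"].mean() - expected) < 3.0 * se + 0.5  # 0.5 = rounding slack


def test_seasonal_profile_recovered():
    cfg = _flat_config(baseline_rate=20000.0, season=TrialDesignConfig().season, seed=9)
    df = generate_dataset(cfg)
    prof = np.log(df.groupby("month_of_year")["malaria"].mean()).to_numpy()
    season = np.asarray(cfg.season)
    corr = np.corrcoef(prof, season)[0, 1]
    assert corr > 0.9


def test_intervention_effect_visible_in_period_means(trial_df):
    """Year-1 malaria counts rise more in the intervention arm than control."""
    base = trial_df[trial_df.period == "baseline"].groupby("arm")["malaria"].mean()
    y1 = trial_df[trial_df.period == "year1"].groupby("arm")["malaria"].mean()
    rel = (y1 / base)["intervention"] / (y1 / base)["control"]
    assert 1.3 < rel < 1.9  # true year-1 rate ratio is 1.56


def test_period_breaks_default_layout():
    months = month_range((2011, 1), 48)
    breaks = default_period_breaks(months)
    assert breaks[(2011, 1)] == "baseline"
    assert breaks[(2012, 2)] == "baseline"   # pre-campaign months stay baseline
    assert breaks[(2012, 3)] == "year1"
    assert breaks[(2013, 3)] == "year2"
    assert breaks[(2014, 3)] == "year3"
    assert breaks[(2014, 12)] == "year3"     # truncated third campaign year


def test_config_validation_errors():
    with pytest.raises(ValueError):
        _flat_config(baseline_rate=0.0).validate()
    with pytest.raises(ValueError):
        _flat_config(category_mix={"malaria": 1.0}).validate()
    cfg = _flat_config()
    cfg.period_breaks = {m: "baseline" for m in cfg.months[:-1]}  # one month uncovered
    with pytest.raises(ValueError):
        generate_dataset(cfg)


def test_config_yaml_round_trip(tmp_path):
    cfg = TrialDesignConfig(seed=17)
    path = tmp_path / "design.yaml"
    cfg.to_yaml(path)
    back = TrialDesignConfig.from_yaml(path)
    assert back.true_effects == cfg.true_effects
    assert back.months == cfg.months
    assert back.period_breaks == cfg.period_breaks
    assert generate_dataset(back).equals(generate_dataset(cfg))


def test_inject_multiplicity_identity_and_proportional():
    df = pd.DataFrame(
        {
            "cluster_id": ["a", "a"],
            "pair_id": [0, 0],
            "arm": ["control", "control"],
            "confounder_score": [0.0, 0.0],
            "year": [2011, 2011],
            "month": [1, 2],
            "month_index": [0, 1],
            "month_of_year": [1, 2],
            "period": ["baseline", "baseline"],
            "malaria": [50, 0],
            "pneumonia": [30, 0],
            "diarrhoea": [20, 0],
            "all_cause": [100, 0],
        }
    )
    same = inject_multiplicity(df, {"control": (1.0, 1.0), "intervention": (1.0, 1.0)})
    assert same.equals(df)
    doubled = inject_multiplicity(df, {"control": (2.0, 2.0), "intervention": (2.0, 2.0)})
    assert tuple(doubled.loc[0, ["malaria", "pneumonia", "diarrhoea"]]) == (100, 60, 40)
    # all_cause == 0 passes through unchanged
    assert tuple(doubled.loc[1, ["malaria", "pneumonia", "diarrhoea"]]) == (0, 0, 0)


def test_inject_multiplicity_interpolation(trial_df):
    target_path = {"control": (1.23, 2.17), "intervention": (1.51, 2.29)}
    flat = generate_dataset(
        _flat_config(seed=21, baseline_rate=5000.0)
    )
    out = inject_multiplicity(flat, target_path)
    T = flat["month_index"].max() + 1
    month = 24
    sel = out[(out.month_index == month) & (out.arm == "control")]
    cats = ["malaria", "pneumonia", "diarrhoea", "urti", "malnutrition", "other"]
    realised = sel[cats].to_numpy().sum() / sel["all_cause"].sum()
    expected = 1.23 + (2.17 - 1.23) * month / (T - 1)
    assert realised == pytest.approx(expected, abs=0.01)


def test_type_one_error_of_null_generator():
    """With all true RRs = 1, a nominal-5% two-arm test rejects ~5% of the time."""
    cfg_kw = dict(
        months=month_range((2011, 1), 12),
        period_breaks={m: "baseline" for m in month_range((2011, 1), 12)},
        baseline_rate=300.0,
    )
    n_rej = 0
    reps = 200
    for k in range(reps):
        df = generate_dataset(_flat_config(seed=1000 + k, **cfg_kw))
        a = df.loc[df.arm == "intervention", "malaria"].sum()
        b = df.loc[df.arm == "control", "malaria"].sum()
        z = (a - b) / np.sqrt(a + b)
        n_rej += abs(z) > 1.96
    assert 0.01 <= n_rej / reps <= 0.11  # 5% +- binomial noise at 200 replicates


def test_multiplicity_interpolation_endpoints():
    assert multiplicity_at((1.23, 2.17), 0, 48) == 1.23
    assert multiplicity_at((1.23, 2.17), 47, 48) == 2.17
    assert multiplicity_at((1.5, 1.5), 10, 48) == 1.5
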