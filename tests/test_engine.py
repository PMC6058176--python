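"""Deaths-averted engine: arithmetic oracles, limits, invariances."""
import numpy as np
import pandas as pd
import pytest

from radioimpact import (
    CoveragePath,
    InterventionSpec,
    MortalityEnvelope,
    combine_interventions,
    coverage_from_utilisation,
    impact_fraction,
    lives_saved,
    weighted_average_reduction,
)


def _envelope(**kw):
    base = dict(
        years=[2012],
        u5mr={2012: 137.0},
        live_births={2012: 100000.0},
        cause_fractions={"malaria": 0.25},
    )
    base.update(kw)
    return MortalityEnvelope(**base)


def test_deaths_envelope_arithmetic():
    env = _envelope()
    assert env.deaths(2012) == pytest.approx(13700.0)
    assert env.cause_deaths("malaria", 2012) == pytest.approx(3425.0)
    with pytest.raises(ValueError):
        _envelope(u5mr={2012: 0.0})
    with pytest.raises(ValueError):
        _envelope(cause_fractions={"a": 0.7, "b": 0.6})


def test_coverage_from_utilisation_examples():
    assert coverage_from_utilisation(0.4, 0.0, 0.5) == pytest.approx(0.4)
    # ORS: C0=34.5%, diarrhoea effect +73%, receipt 34.5%
    assert coverage_from_utilisation(0.345, 0.73, 0.345) == pytest.approx(0.4319, abs=2e-4)
    # pneumonia care-seeking proxy: q plays no role
    assert coverage_from_utilisation(0.30, 0.39, 1.0, "careseeking_proxy") == pytest.approx(0.417)
    assert coverage_from_utilisation(0.30, 0.39, 0.2, "careseeking_proxy") == pytest.approx(0.417)
    # saturation cap
    assert coverage_from_utilisation(0.9, 0.5, 1.0) == 1.0
    with pytest.raises(ValueError):
        coverage_from_utilisation(0.3, -1.5)
    with pytest.raises(ValueError):
        coverage_from_utilisation(1.2, 0.1)


def test_impact_fraction_against_residual_risk_oracle():
    assert impact_fraction(0.87, 1.0, 0.3, 0.3) == 0.0
    assert impact_fraction(1.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)
    assert impact_fraction(0.87, 1.0, 0.3, 0.4) == pytest.approx(0.087 / 0.739, abs=1e-9)
    rng = np.random.default_rng(99)
    for _ in range(500):
        e, af, c0, c1 = rng.uniform(0, 1, 4)
        if e * af * c0 >= 0.999:
            continue
        phi = impact_fraction(e, af, c0, c1)
        oracle = 1.0 - (1.0 - e * af * c1) / (1.0 - e * af * c0)
        assert phi == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError):
        impact_fraction(1.0, 1.0, 1.0, 0.5)


def test_impact_fraction_monotonicity():
    base = impact_fraction(0.5, 0.8, 0.2, 0.5)
    assert impact_fraction(0.5, 0.8, 0.2, 0.6) > base       # increasing in C1
    assert impact_fraction(0.6, 0.8, 0.2, 0.5) > base       # increasing in E
    assert impact_fraction(0.5, 0.9, 0.2, 0.5) > base       # increasing in AF


def test_combine_interventions():
    assert combine_interventions([0.3]) == pytest.approx(0.3)
    assert combine_interventions([0.1, 0.1]) == pytest.approx(0.19)
    assert combine_interventions([0.11773, 0.05]) == pytest.approx(0.1618435, abs=1e-6)
    rng = np.random.default_rng(5)
    phis = rng.uniform(0, 0.8, size=6)
    perm = rng.permutation(phis)
    assert combine_interventions(phis) == pytest.approx(combine_interventions(perm), abs=1e-15)


def test_lives_saved_single_cause():
    env = MortalityEnvelope(
        years=[2012],
        u5mr={2012: 100.0},
        live_births={2012: 100000.0},
        cause_fractions={"malaria": 1.0},
    )
    # E=AF=1, C0=0 -> C1=0.1 gives phi = 0.1: 1000 of 10 000 deaths averted
    spec = InterventionSpec("act", 1.0, ["malaria"], 1.0, "direct")
    paths = {"act": CoveragePath("act", 0.0, {2012: 0.1})}
    res = lives_saved(env, paths, [spec])
    assert res.totals[2012] == pytest.approx(1000.0)
    assert res.pct_reduction[2012] == pytest.approx(10.0)


def test_lives_saved_limit_removes_cause_fraction():
    env = _envelope(cause_fractions={"malaria": 0.25})
    spec = InterventionSpec("act", 1.0, ["malaria"], 1.0, "direct")
    paths = {"act": CoveragePath("act", 0.0, {2012: 1.0})}
    res = lives_saved(env, paths, [spec])
    assert res.totals[2012] == pytest.approx(env.cause_deaths("malaria", 2012))
    assert res.pct_reduction[2012] == pytest.approx(25.0)


def test_lives_saved_three_cause_spreadsheet_oracle():
    env = MortalityEnvelope(
        years=[2012, 2013],
        u5mr={2012: 100.0, 2013: 90.0},
        live_births={2012: 50000.0, 2013: 52000.0},
        cause_fractions={"malaria": 0.3, "pneumonia": 0.2, "diarrhoea": 0.1},
    )
    specs = [
        InterventionSpec("act", 0.87, ["malaria"], 1.0, "direct"),
        InterventionSpec("abx", 0.70, ["pneumonia"], 1.0, "direct"),
        InterventionSpec("ors", 0.93, ["diarrhoea"], 1.0, "direct"),
    ]
    paths = {
        "act": CoveragePath("act", 0.30, {2012: 0.40, 2013: 0.35}),
        "abx": CoveragePath("abx", 0.47, {2012: 0.60, 2013: 0.55}),
        "ors": CoveragePath("ors", 0.17, {2012: 0.25, 2013: 0.22}),
    }
    res = lives_saved(env, paths, specs)
    # independent spreadsheet-style recomputation
    for y in (2012, 2013):
        total = 0.0
        for spec, cause in (("act", "malaria"), ("abx", "pneumonia"), ("ors", "diarrhoea")):
            sp = next(s for s in specs if s.name == spec)
            p = paths[spec]
            ea = sp.effectiveness
            phi = ea * (p.per_year[y] - p.baseline) / (1 - ea * p.baseline)
            total += env.deaths(y) * env.cause_fractions[cause] * phi
        assert res.totals[y] == pytest.approx(total, abs=1e-9)
        assert res.totals[y] <= sum(
            env.cause_deaths(c, y) for c in env.cause_fractions
        )


def test_detail_table_attribution(trial_df=None):
    env = _envelope(cause_fractions={"malaria": 0.2, "pneumonia": 0.2})
    specs = [
        InterventionSpec("a", 0.5, ["malaria", "pneumonia"], 1.0, "direct"),
        InterventionSpec("b", 0.5, ["malaria"], 1.0, "direct"),
    ]
    paths = {
        "a": CoveragePath("a", 0.2, {2012: 0.4}),
        "b": CoveragePath("b", 0.1, {2012: 0.3}),
    }
    res = lives_saved(env, paths, specs)
    detail = res.detail
    assert set(detail.columns) == {"year", "intervention", "cause", "averted"}
    # residual combination: total <= sum of individual attributions
    assert res.totals[2012] <= detail["averted"].sum() + 1e-9


def test_weighted_average_reduction():
    env = MortalityEnvelope(
        years=[2012, 2013],
        u5mr={2012: 100.0, 2013: 100.0},
        live_births={2012: 1000.0, 2013: 1000.0},
        cause_fractions={"malaria": 0.5},
    )
    spec = InterventionSpec("act", 1.0, ["malaria"], 1.0, "direct")
    paths = {"act": CoveragePath("act", 0.0, {2012: 0.2, 2013: 0.2})}
    res = lives_saved(env, paths, [spec])
    # equal per-year reductions -> the average equals them
    assert weighted_average_reduction(res) == pytest.approx(res.pct_reduction[2012])


def test_mismatched_cause_links_error():
    env = _envelope()
    spec = InterventionSpec("x", 0.5, ["pneumonia"], 1.0, "direct")
    with pytest.raises(ValueError, match="missing from envelope"):
        lives_saved(env, {"x": CoveragePath("x", 0.1, {2012: 0.2})}, [spec])
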