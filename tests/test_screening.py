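"""Null statistics, toxicity filtering, 2-SD hit calling, dose response."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from neuroscreen import (
    NullStats,
    call_hits,
    compute_null_stats,
    dose_response_test,
    toxicity_flag,
    well_exceedance_fraction,
)
from neuroscreen.synth import CompoundEffect, PlateSpec, simulate_plate_table


def _table(rows):
    base = {
        "plate": 1, "well": "A01", "row": "A", "col": 1, "dose_um": 1.0,
        "replicate": 1, "tuj1_intensity": 500.0,
    }
    recs = []
    for r in rows:
        rec = base | r
        rec.setdefault("th_intensity", rec["th_tuj1_ratio"] * rec["tuj1_intensity"])
        recs.append(rec)
    return pd.DataFrame(recs)


def _dmso(ratios, nuclei=1000):
    return [
        {"compound": "DMSO", "role": "DMSO", "th_tuj1_ratio": r, "nuclei_count": nuclei}
        for r in ratios
    ]


# ------------------------------------------------------------- null stats

def test_null_stats_constant_ratios():
    null = compute_null_stats(_table(_dmso([0.2, 0.2, 0.2])))
    assert null.mean_ratio == pytest.approx(0.2)
    assert null.sd_ratio == pytest.approx(0.0, abs=1e-12)
    assert null.n_dmso_wells == 3


def test_null_stats_two_wells_sample_sd():
    null = compute_null_stats(_table(_dmso([0.18, 0.22])))
    assert null.mean_ratio == pytest.approx(0.20)
    assert null.sd_ratio == pytest.approx(0.02 * math.sqrt(2), rel=1e-9)  # n-1


def test_null_stats_requires_dmso():
    with pytest.raises(ValueError):
        compute_null_stats(_table([{"compound": "X", "role": "compound",
                                    "th_tuj1_ratio": 0.2, "nuclei_count": 900}]))


def test_simulated_dmso_sd_near_cv():
    spec = PlateSpec(compounds=[], ratio_cv=0.10, baseline_ratio=0.30, seed=6)
    null = compute_null_stats(simulate_plate_table(spec))
    assert null.sd_ratio == pytest.approx(0.03, rel=0.15)


# --------------------------------------------------------------- toxicity

def test_toxicity_rule_is_strict_more_than_cutoff():
    null = compute_null_stats(_table(_dmso([0.2, 0.2], nuclei=1000)))
    assert toxicity_flag(600, null)          # 40% decrease -> toxic
    assert not toxicity_flag(1000, null)
    assert not toxicity_flag(700, null)      # exactly 30%: boundary, kept
    assert toxicity_flag(699, null)


# -------------------------------------------------------------- hit calls

def _hit_table():
    rows = _dmso(list(np.array([0.18, 0.20, 0.22, 0.20, 0.19, 0.21])))
    for comp, ratios, nuclei in [
        ("UP", (0.25, 0.25), 1000),          # z = 2.5 at sd 0.02 (forced below)
        ("MID", (0.23, 0.23), 1000),         # z = 1.5
        ("TOX", (0.30, 0.30), 500),          # strong but toxic
        ("DOWN", (0.12, 0.12), 1000),        # decrease side
    ]:
        for i, r in enumerate(ratios):
            rows.append({"compound": comp, "role": "compound",
                         "th_tuj1_ratio": r, "nuclei_count": nuclei, "replicate": i + 1})
    return _table(rows)


def _round_null():
    # round numbers for hand arithmetic
    return NullStats(mean_ratio=0.20, sd_ratio=0.02, mean_nuclei=1000.0, n_dmso_wells=6)


def test_hit_call_forced_arithmetic():
    table = _hit_table()
    report = call_hits(table, _round_null()).set_index("compound")
    assert report.loc["UP", "z"] == pytest.approx(2.5)
    assert report.loc["UP", "hit"]
    assert report.loc["UP", "status"] == "hit"
    assert report.loc["MID", "z"] == pytest.approx(1.5)
    assert not report.loc["MID", "hit"]
    assert report.loc["TOX", "toxic"] and not report.loc["TOX", "hit"]
    assert report.loc["TOX", "status"] == "toxic"
    assert report.loc["DOWN", "direction"] == "decrease"
    assert not report.loc["DOWN", "hit"]     # require_increase default


def test_decrease_side_counts_without_increase_filter():
    table = _hit_table()
    report = call_hits(table, _round_null(), require_increase=False).set_index("compound")
    assert report.loc["DOWN", "hit"]         # |z| = 4 > 2


def test_zero_sd_is_an_error():
    table = _table(_dmso([0.2, 0.2]))
    null = compute_null_stats(table)
    with pytest.raises(ValueError):
        call_hits(table, null)


def test_every_compound_gets_exactly_one_call():
    table = _hit_table()
    report = call_hits(table, _round_null())
    assert sorted(report.compound) == ["DOWN", "MID", "TOX", "UP"]
    assert report.compound.is_unique
    n_hit = int(report.hit.sum())
    n_toxic = int(report.toxic.sum())
    n_rest = int((~report.hit & ~report.toxic).sum())
    assert n_hit + n_toxic + n_rest == len(report)
    assert set(report.status) <= {"hit", "not_hit", "toxic"}


def brute_force_calls(table, null, k=2.0, require_increase=True, toxicity_cutoff=0.30):
    """Independent reimplementation: plain loops and direct arithmetic."""
    out = {}
    comp_rows = table[table.role == "compound"]
    for comp in comp_rows.compound.unique():
        sub = comp_rows[comp_rows.compound == comp]
        toxic = any(n < (1 - toxicity_cutoff) * null.mean_nuclei for n in sub.nuclei_count)
        mean = sub.th_tuj1_ratio.mean()
        z = (mean - null.mean_ratio) / null.sd_ratio
        direction = "increase" if z >= 0 else "decrease"
        hit = (not toxic) and abs(z) > k and (direction == "increase" or not require_increase)
        out[comp] = (round(float(z), 12), toxic, hit)
    return out


def test_oracle_equivalence_on_simulated_plate():
    compounds = [CompoundEffect(f"C{i:03d}",
                                th_ratio_multiplier=1.0 + 0.05 * (i % 9),
                                viability_fraction=1.0 if i % 7 else 0.55)
                 for i in range(60)]
    table = simulate_plate_table(PlateSpec(compounds=compounds, seed=17))
    null = compute_null_stats(table)
    report = call_hits(table, null).set_index("compound")
    oracle = brute_force_calls(table, null)
    assert set(report.index) == set(oracle)
    for comp, (z, toxic, hit) in oracle.items():
        assert report.loc[comp, "z"] == pytest.approx(z)
        assert bool(report.loc[comp, "toxic"]) == toxic
        assert bool(report.loc[comp, "hit"]) == hit


def test_viability_below_cutoff_always_flags_noise_free():
    for viability in (0.69, 0.5, 0.3):
        spec = PlateSpec(
            compounds=[CompoundEffect("V", viability_fraction=viability)],
            nuclei_cv=0.0, ratio_cv=0.0, seed=0,
        )
        table = simulate_plate_table(spec)
        null = compute_null_stats(table)
        sub = table[table.compound == "V"]
        assert all(toxicity_flag(n, null) for n in sub.nuclei_count)


def test_well_exceedance_two_sided_vs_one_sided():
    rng = np.random.default_rng(0)
    rows = _dmso(list(0.2 + 0.02 * rng.standard_normal(200)))
    for i, r in enumerate(0.2 + 0.02 * rng.standard_normal(2000)):
        rows.append({"compound": f"C{i}", "role": "compound",
                     "th_tuj1_ratio": r, "nuclei_count": 1000})
    table = _table(rows)
    null = compute_null_stats(table)
    two = well_exceedance_fraction(table, null, k=2.0, two_sided=True)
    one = well_exceedance_fraction(table, null, k=2.0, two_sided=False)
    assert 0.025 < two < 0.07                   # ~4.6% expected
    assert one < two
    assert 0.01 < one < 0.04                    # ~2.3% expected


# ---------------------------------------------------------- dose response

def _dose_table(means, sd, n=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for dose, mu in zip([0.1, 1.0, 10.0], means):
        for _ in range(n):
            rows.append({"compound": "C", "dose_um": dose,
                         "th_tuj1_ratio": mu + sd * rng.standard_normal()})
    return pd.DataFrame(rows)


def test_dose_response_identical_values_not_validated():
    res = dose_response_test(_dose_table([0.3, 0.3, 0.3], sd=0.0), "C")
    assert res.f_statistic == 0.0
    assert res.anova_p == 1.0
    assert not res.validated


def test_dose_response_strong_trend_validated():
    res = dose_response_test(_dose_table([0.0, 5.0, 10.0], sd=0.1), "C")
    assert res.anova_p < 1e-3
    assert res.monotone_trend == pytest.approx(1.0)
    assert res.validated


def test_dose_response_requires_replication():
    bad = _dose_table([0.0, 5.0, 10.0], sd=0.1).iloc[[0, 3, 4, 6, 7, 8]]
    with pytest.raises(ValueError):
        dose_response_test(bad, "C")
    two_groups = _dose_table([0.0, 5.0, 10.0], sd=0.1)
    two_groups = two_groups[two_groups.dose_um > 0.5]
    with pytest.raises(ValueError):
        dose_response_test(two_groups, "C")


def test_dose_response_null_calibration():
    rejections = 0
    trials = 200
    for s in range(trials):
        res = dose_response_test(_dose_table([0.3, 0.3, 0.3], sd=0.05, seed=s), "C")
        rejections += res.validated
    assert 0.01 < rejections / trials < 0.10    # alpha = 0.05 +/- MC error
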