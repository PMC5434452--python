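"""Normality gating, two-group routing, factorial ANOVA, ratios, ddCt."""

import numpy as np
import pytest

from flowquant import (
    AnalysisError,
    ConfigError,
    DonorRecord,
    compare_two_groups,
    ddct_fold_change,
    lps_response_ratio,
    normality_gate,
    percent_increase,
    response_variance_by_group,
    significance_symbol,
    two_way_anova_age_lps,
)
from flowquant.synth import PRESETS


def make_records(rng, means, n_young=16, n_old=14, sd=6.0):
    """2x2 design records with given cell means (young_c, young_l, old_c, old_l)."""
    recs = []
    for age, n in (("young", n_young), ("old", n_old)):
        for trt in ("control", "LPS"):
            mu = means[(age, trt)]
            for i in range(n):
                recs.append(DonorRecord(
                    donor_id=f"{age}_{trt}_d{i:03d}", age_group=age,
                    gender="female", treatment=trt,
                    adherent_density_mm2=float(rng.normal(mu, sd)),
                    rolling_density_mm2=15.0,
                ))
    return recs


# --- normality gate ---------------------------------------------------------

def test_gate_accepts_gaussian_samples_most_of_the_time():
    rng = np.random.default_rng(0)
    accepted = sum(
        normality_gate(list(rng.normal(10, 2, size=50))) for _ in range(300)
    )
    assert 0.90 <= accepted / 300 <= 0.99   # ~1 - alpha


def test_gate_rejects_strong_bimodality():
    rng = np.random.default_rng(1)
    rejected = 0
    for _ in range(100):
        x = np.concatenate([rng.normal(-3, 0.3, 25), rng.normal(3, 0.3, 25)])
        rejected += not normality_gate(list(x))
    assert rejected > 95


def test_gate_degenerate_inputs():
    assert normality_gate([5.0, 5.0, 5.0, 5.0]) is False   # zero variance
    with pytest.warns(UserWarning):
        assert normality_gate([1.0, 2.0]) is False          # n < 3


# --- two-group comparison ---------------------------------------------------

def test_identical_groups_not_significant():
    vals = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
    comp = compare_two_groups(vals, vals)
    assert comp.p_value == pytest.approx(1.0)
    assert comp.significance_symbol == "ns"


def test_routing_normal_vs_rank():
    rng = np.random.default_rng(2)
    a = list(rng.normal(0, 1, 20))
    b = list(rng.normal(0, 1, 20))
    assert compare_two_groups(a, b).test_name == "t_unpaired"
    skewed = list(rng.lognormal(0, 2, 40))
    assert compare_two_groups(skewed, b).test_name == "mann_whitney_u"


def test_power_at_two_sd_shift():
    """n=15 per group with a 2 SD shift is detected nearly always."""
    rng = np.random.default_rng(3)
    hits = sum(
        compare_two_groups(list(rng.normal(0, 1, 15)),
                           list(rng.normal(2, 1, 15))).p_value <= 0.05
        for _ in range(300)
    )
    assert hits / 300 >= 0.95


def test_small_group_raises_named_error():
    with pytest.raises(AnalysisError, match="'b'"):
        compare_two_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0])


def test_group_summaries_mean_sem_n():
    comp = compare_two_groups([10.0, 20.0, 30.0], [1.0, 2.0, 3.0, 4.0])
    ga, gb = comp.group_summaries
    assert ga.mean == pytest.approx(20.0) and ga.n == 3
    assert ga.sem == pytest.approx(10.0 / np.sqrt(3), abs=1e-6)
    assert gb.n == 4


def test_cohorts_at_printed_effect_sizes_detectable_above_alpha():
    """Old vs young control adhesion at the printed means/SEMs: the
    printed summaries imply t = (19-15)/sqrt(2^2+2^2) ~ 1.4, i.e. a
    modest effect whose replication power is well below certainty, but
    the planted difference must still be rejected far more often than
    the 5% null rate, and in the right direction."""
    rng = np.random.default_rng(4)
    yc, oc = PRESETS["young_control"], PRESETS["old_control"]
    hits = 0
    reps = 100
    for _ in range(reps):
        young = rng.normal(yc.adherent_mean,
                           yc.adherent_sem * np.sqrt(yc.n_group), yc.n_group)
        old = rng.normal(oc.adherent_mean,
                         oc.adherent_sem * np.sqrt(oc.n_group), oc.n_group)
        comp = compare_two_groups(list(old), list(young))
        if comp.p_value <= 0.05:
            hits += 1
    assert hits / reps >= 0.15   # >= 3x the nominal type-I rate


@pytest.mark.parametrize("p,symbol", [
    (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.02, "*"),
    (0.01, "**"), (0.002, "**"), (0.001, "***"), (0.0002, "***"),
    (0.0001, "****"), (1e-9, "****"),
])
def test_significance_symbol_convention(p, symbol):
    assert significance_symbol(p) == symbol


# --- two-way ANOVA ----------------------------------------------------------

def test_anova_degenerate_all_equal():
    means = {(a, t): 10.0 for a in ("young", "old")
             for t in ("control", "LPS")}
    rng = np.random.default_rng(5)
    recs = make_records(rng, means, sd=0.0)
    res = two_way_anova_age_lps(recs)
    for factor in ("age", "lps", "interaction"):
        assert res.f_statistics[factor] == 0.0
        assert res.factor_p_values[factor] == 1.0


def test_anova_detects_planted_main_effects():
    rng = np.random.default_rng(6)
    means = {("young", "control"): 15.0, ("young", "LPS"): 19.0,
             ("old", "control"): 19.0, ("old", "LPS"): 26.0}
    recs = make_records(rng, means, sd=4.0)
    res = two_way_anova_age_lps(recs)
    assert res.factor_p_values["age"] <= 0.05
    assert res.factor_p_values["lps"] <= 0.05
    assert res.design_counts[("young", "control")] == 16
    assert res.design_counts[("old", "LPS")] == 14


def test_anova_empty_cell_is_named():
    rng = np.random.default_rng(7)
    means = {(a, t): 10.0 for a in ("young", "old")
             for t in ("control", "LPS")}
    recs = [r for r in make_records(rng, means)
            if not (r.age_group == "old" and r.treatment == "LPS")]
    with pytest.raises(AnalysisError, match="old.*LPS"):
        two_way_anova_age_lps(recs)


def test_anova_power_at_printed_group_statistics():
    """Cohorts drawn at the printed means/SEMs (n=16/14): each main
    effect is recovered at 0.05 in a clear majority of replicates (the
    SEM-reconstructed donor spread implies ~0.7 power for age and ~0.8
    for LPS, so near-certain joint detection is not attainable)."""
    rng = np.random.default_rng(8)
    age_hits = lps_hits = 0
    reps = 60
    for _ in range(reps):
        recs = []
        for name in ("young_control", "young_LPS", "old_control", "old_LPS"):
            p = PRESETS[name]
            age, trt = name.split("_")
            for i in range(p.n_group):
                recs.append(DonorRecord(
                    f"{name}_{i}", age, "female", trt,
                    float(rng.normal(p.adherent_mean,
                                     p.adherent_sem * np.sqrt(p.n_group))),
                    15.0,
                ))
        res = two_way_anova_age_lps(recs)
        age_hits += res.factor_p_values["age"] <= 0.05
        lps_hits += res.factor_p_values["lps"] <= 0.05
    assert age_hits / reps >= 0.5
    assert lps_hits / reps >= 0.6


# --- response ratios and qPCR ----------------------------------------------

def test_lps_response_ratio_arithmetic():
    assert lps_response_ratio(19.0, 19.0) == pytest.approx(1.0)
    assert percent_increase(19.0, 15.0) == pytest.approx(26.6667, abs=1e-3)
    assert percent_increase(26.0, 19.0) == pytest.approx(36.8421, abs=1e-3)
    both = (percent_increase(19.0, 15.0) + percent_increase(26.0, 19.0)) / 2
    assert both == pytest.approx(31.754, abs=1e-2)
    with pytest.raises(AnalysisError):
        lps_response_ratio(10.0, 0.0)


def test_ddct_fold_change_values():
    assert ddct_fold_change(25.0, 20.0, 5.0).fold_change == pytest.approx(1.0)
    assert ddct_fold_change(26.0, 20.0, 5.0).fold_change == pytest.approx(0.5)
    assert ddct_fold_change(23.0, 20.0, 5.0).fold_change == pytest.approx(4.0)
    with pytest.raises(ConfigError):
        ddct_fold_change(float("nan"), 20.0, 5.0)


def test_ddct_matches_direct_recomputation_and_is_multiplicative():
    rng = np.random.default_rng(9)
    for _ in range(50):
        ct_t, ct_r, cal = rng.uniform(10, 40, size=3)
        res = ddct_fold_change(ct_t, ct_r, cal)
        assert res.fold_change == pytest.approx(
            2.0 ** (-((ct_t - ct_r) - cal)))
    # fold(a + b) = fold(a) * fold(b) in the ddCt argument
    f = lambda ddct: ddct_fold_change(20.0 + ddct, 20.0, 0.0).fold_change
    assert f(1.3 + 0.9) == pytest.approx(f(1.3) * f(0.9))
    assert f(2.0) < f(1.0) < f(0.0)   # strictly decreasing


def test_response_variance_by_group():
    young = [0.8, 0.9, 0.7, 1.4, 1.5, 1.6, 1.2, 1.3]   # heterogeneous
    old = [1.3, 1.35, 1.4, 1.3, 1.38, 1.32]            # homogeneous
    var = response_variance_by_group({"young": young, "old": old})
    assert var["young"] > var["old"]
    same = response_variance_by_group({"g": [1.2, 1.2, 1.2]})
    assert same["g"] == 0.0
    shifted = response_variance_by_group({"g": [x + 5 for x in young]})
    assert shifted["g"] == pytest.approx(var["young"])
    with pytest.raises(AnalysisError):
        response_variance_by_group({"solo": [1.0]})
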