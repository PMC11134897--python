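import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from hrvreact import (BASELINE, CriteriaConfig, EchoPanel, FOLLOWUP,
                      SubjectRecord, categorical_test, classify_cardiotoxicity,
                      compare_groups, echo_criterion, las_significant_reduction,
                      normality_gate, pearson_matrix, rm_anova)
from hrvreact.clinical import ECHO_FIELDS
from hrvreact.errors import (ConfigurationError, DegenerateInputError,
                             InsufficientDataError, MissingDataError,
                             NonPositiveDataError)

from oracles import rm_anova_ss_loop


# ---------------------------------------------------------------- gate

def test_gate_passes_normal_draws_most_of_the_time(rng):
    flags = []
    for _ in range(200):
        _, flag = normality_gate(rng.normal(10.0, 2.0, 50))
        flags.append(flag)
    assert np.mean(flags) <= 0.10  # estimated-parameter KS is conservative


def test_gate_transforms_heavy_tailed_data(rng):
    flags = []
    for _ in range(200):
        x = rng.lognormal(0.0, 1.2, 50)
        out, flag = normality_gate(x)
        flags.append(flag)
        if flag:
            np.testing.assert_allclose(out, np.log10(x))
    assert np.mean(flags) > 0.5


def test_gate_never_alters_data_when_flag_false(rng):
    x = rng.normal(0.0, 1.0, 50)
    out, flag = normality_gate(x)
    if not flag:
        np.testing.assert_array_equal(out, x)


def test_gate_degenerate_and_nonpositive_inputs():
    with pytest.raises(DegenerateInputError):
        normality_gate(np.full(20, 3.0))
    with pytest.raises(InsufficientDataError):
        normality_gate([1.0, 2.0, 3.0])
    skewed_with_zero = np.array([0.0] + [1.0] * 48 + [1000.0])
    with pytest.raises(NonPositiveDataError):
        normality_gate(skewed_with_zero)


# ---------------------------------------------------------------- t-tests

def test_identical_paired_vectors():
    res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_textbook_two_sample_case():
    res = compare_groups([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
    assert res.statistic == pytest.approx(-2.0, rel=1e-12)
    assert res.df == 8
    assert res.p_value == pytest.approx(0.08051623795726262, rel=1e-9)
    assert res.mean_a == pytest.approx(3.0)
    assert res.sd_a == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))


def test_group_swap_negates_t():
    a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 3.5, 5.0]
    r1 = compare_groups(a, b)
    r2 = compare_groups(b, a)
    assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


def test_zero_variance_flagged():
    res = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert math.isnan(res.statistic) and math.isnan(res.p_value)


def test_paired_requires_equal_lengths():
    with pytest.raises(ConfigurationError):
        compare_groups([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


# ---------------------------------------------------------------- RM-ANOVA

def test_rm_anova_identical_conditions():
    m = np.tile(np.array([[800.0], [900.0], [1000.0]]), (1, 3))
    res = rm_anova(m)
    assert res.F == 0.0 and res.p_value == 1.0


def test_rm_anova_matches_ss_decomposition_oracle(rng):
    m = rng.normal(50.0, 10.0, size=(3, 3))
    m[:, 1] += 5.0
    res = rm_anova(m)
    assert res.F == pytest.approx(rm_anova_ss_loop(m.tolist()), rel=1e-10)
    assert (res.df1, res.df2) == (2, 4)


def test_rm_anova_agrees_with_pingouin(rng):
    m = rng.normal(0.0, 1.0, size=(8, 3))
    m[:, 2] += 0.8
    res = rm_anova(m)
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(8), 3),
        "condition": np.tile(np.arange(3), 8),
        "value": m.ravel()})
    ref = pg.rm_anova(data=long, dv="value", within="condition", subject="subject")
    assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
    assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)


def test_rm_anova_rejects_missing_cells():
    m = np.ones((4, 3))
    m[1, 2] = np.nan
    with pytest.raises(MissingDataError):
        rm_anova(m)


# ---------------------------------------------------------------- categorical

def test_balanced_table_has_zero_statistic():
    res = categorical_test([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)
    assert res.method == "chi-squared"


def test_chi_squared_path_without_continuity_correction():
    res = categorical_test([[1, 9], [9, 1]])
    assert res.method == "chi-squared"  # expected counts exactly 5
    assert res.statistic == pytest.approx(12.8, rel=1e-12)
    assert res.p_value == pytest.approx(0.000346619351134667, rel=1e-9)


def test_fisher_path_for_small_expected_counts():
    res = categorical_test([[2, 3], [3, 2]])
    assert res.method == "fisher"  # expected counts 2.5 < 5
    assert res.p_value == pytest.approx(1.0)


def test_zero_margin_rejected():
    with pytest.raises(DegenerateInputError):
        categorical_test([[0, 0], [5, 3]])


# ---------------------------------------------------------------- Pearson

def test_exact_linear_relation_gives_unit_correlation(rng):
    x = rng.normal(0.0, 1.0, 30)
    echo = pd.DataFrame({"e": x})
    hrv = pd.DataFrame({"h": 2.0 * x + 1.0})
    r, p = pearson_matrix(echo, hrv)
    assert r.loc["e", "h"] == pytest.approx(1.0)
    assert p.loc["e", "h"] < 1e-20


def test_constant_column_flagged_missing(rng):
    echo = pd.DataFrame({"e": np.full(20, 5.0)})
    hrv = pd.DataFrame({"h": rng.normal(0.0, 1.0, 20)})
    r, _ = pearson_matrix(echo, hrv)
    assert math.isnan(r.loc["e", "h"])


# ---------------------------------------------------------------- clinical rules

@pytest.mark.parametrize("baseline,followup,expected", [
    (40.0, 34.0, True),    # drops below the 35% normal threshold
    (30.0, 28.0, False),   # already low; 6.67% relative drop is not enough
    (50.0, 44.0, True),    # 12% relative reduction
    (36.0, 35.0, False),   # stays at/above threshold, 2.8% relative drop
])
def test_lasr_significant_reduction_rule(baseline, followup, expected):
    assert las_significant_reduction(baseline, followup) is expected


def test_lasr_rejects_nonpositive_values():
    with pytest.raises(ConfigurationError):
        las_significant_reduction(0.0, 30.0)


def _panel(lvef=65.0, gls=-24.0):
    values = {name: 30.0 for name in ECHO_FIELDS}
    values.update(lvef3d_pct=lvef, gls_pct=gls, lv_edv_ml=80.0, lv_esv_ml=30.0)
    return EchoPanel(**values)


def _record(lvef=(65.0, 62.0), gls=(-24.0, -23.5), trop=(False, False)):
    return SubjectRecord(
        subject_id="S001",
        echo={BASELINE: _panel(lvef[0], gls[0]), FOLLOWUP: _panel(lvef[1], gls[1])},
        troponin_positive={BASELINE: trop[0], FOLLOWUP: trop[1]})


def test_gls_relative_reduction_triggers_echo_criterion():
    assert echo_criterion(_panel(gls=-24.0), _panel(gls=-21.0)) is True
    assert classify_cardiotoxicity(_record(gls=(-24.0, -21.0))) == "echo"


def test_small_changes_classify_as_none():
    assert classify_cardiotoxicity(_record()) == "none"


def test_lvef_drop_alone_triggers_echo_criterion():
    rec = _record(lvef=(64.0, 50.0))
    assert classify_cardiotoxicity(rec) == "echo"


def test_new_troponin_positivity_and_both():
    assert classify_cardiotoxicity(_record(trop=(False, True))) == "troponin"
    assert classify_cardiotoxicity(
        _record(gls=(-24.0, -21.0), trop=(False, True))) == "both"
    # already positive at baseline is not a new conversion
    assert classify_cardiotoxicity(_record(trop=(True, True))) == "none"


def test_missing_followup_is_unclassifiable():
    rec = _record()
    del rec.echo[FOLLOWUP]
    with pytest.raises(MissingDataError, match="unclassifiable|missing"):
        classify_cardiotoxicity(rec)


def test_thresholds_are_configurable():
    loose = CriteriaConfig(gls_relative_reduction=0.20)
    assert classify_cardiotoxicity(_record(gls=(-24.0, -21.0)), loose) == "none"
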