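"""ROC inference: AUC estimator, DeLong variance, smoothing, operating
points, binomial intervals and the paired permutation test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from readerbench.exceptions import InferenceError, ValidationError
from readerbench.roc import (binomial_ci, delong_ci, empirical_auc,
                             permutation_test_auc, smooth_roc, youden_j,
                             youden_operating_point)
from readerbench.simulate import auc_to_separation


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def oracle_auc(scores, labels):
    """All-pairs counting with half-weighted ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_youden(scores, labels):
    """Best (J, threshold) by direct evaluation; ties to lowest threshold."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    best = None
    for t in sorted(set(scores)):
        se = sum(p >= t for p in pos) / len(pos)
        sp = sum(q < t for q in neg) / len(neg)
        j = se + sp - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t, se, sp)
    return best


def oracle_permutation_p(a, b, labels):
    """Exact paired-swap p over all 2^n patterns, on per-arm rank scales."""
    n = len(a)
    ra = (stats.rankdata(a) - 0.5) / n
    rb = (stats.rankdata(b) - 0.5) / n
    observed = abs(oracle_auc(ra, labels) - oracle_auc(rb, labels))
    count = 0
    for pattern in itertools.product([0, 1], repeat=n):
        pa = [y if s else x for x, y, s in zip(ra, rb, pattern)]
        pb = [x if s else y for x, y, s in zip(ra, rb, pattern)]
        stat = abs(oracle_auc(pa, labels) - oracle_auc(pb, labels))
        if stat >= observed - 1e-12:
            count += 1
    return count / 2 ** n


# --------------------------------------------------------------------------
# empirical AUC
# --------------------------------------------------------------------------

@pytest.mark.parametrize("scores,labels,expected", [
    ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),     # perfect separation
    ([0.5, 0.5], [1, 0], 0.5),                     # full tie
    ([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0], 0.75),    # 3 of 4 pairs concordant
])
def test_empirical_auc_worked_examples(scores, labels, expected):
    assert empirical_auc(scores, labels) == pytest.approx(expected)


def test_empirical_auc_rejects_single_class():
    with pytest.raises(InferenceError, match="negative"):
        empirical_auc([0.1, 0.9], [1, 1])
    with pytest.raises(InferenceError, match="positive"):
        empirical_auc([0.1, 0.9], [0, 0])


def test_empirical_auc_matches_sklearn_with_ties():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, 200)
    labels[:2], labels[-2:] = 1, 0
    scores = rng.random(200).round(1)     # heavy ties
    assert empirical_auc(scores, labels) == \
        pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


@settings(max_examples=150, derandomize=True)
@given(st.lists(st.floats(0, 1, width=16), min_size=4, max_size=12),
       st.data())
def test_auc_invariances(scores, data):
    n = len(scores)
    labels = data.draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n)
        .filter(lambda ls: 0 < sum(ls) < n))
    auc = empirical_auc(scores, labels)
    # strictly increasing transform leaves the AUC unchanged
    transformed = np.exp(np.asarray(scores, dtype=float) * 2.0)
    assert empirical_auc(transformed, labels) == pytest.approx(auc, abs=1e-12)
    # complementation identity
    flipped = [1 - y for y in labels]
    assert auc + empirical_auc(scores, flipped) == pytest.approx(1.0, abs=1e-12)
    # oracle agreement
    assert auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)


# --------------------------------------------------------------------------
# DeLong interval
# --------------------------------------------------------------------------

def test_delong_placement_variance_hand_example():
    r = delong_ci([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0])
    assert r.auc == pytest.approx(0.75)
    assert r.variance == pytest.approx(0.0625)


def test_delong_center_equals_empirical_auc(binormal_sample):
    scores, labels = binormal_sample
    r = delong_ci(scores, labels)
    assert r.auc == pytest.approx(empirical_auc(scores, labels), abs=1e-12)
    assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]


def test_delong_perfect_separation_degenerates_with_warning(caplog):
    with caplog.at_level("WARNING"):
        r = delong_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert r.auc_ci == (1.0, 1.0)
    assert "degenerate" in caplog.text


def test_delong_width_shrinks_like_root_n():
    d = auc_to_separation(0.8)
    rng = np.random.default_rng(6)
    widths = []
    for n in (50, 200, 800):
        labels = np.concatenate([np.ones(n, int), np.zeros(n, int)])
        scores = labels * d + rng.standard_normal(2 * n)
        r = delong_ci(scores, labels)
        widths.append(r.auc_ci[1] - r.auc_ci[0])
    # quadrupling n should roughly halve the width
    assert widths[1] < widths[0] * 0.7
    assert widths[2] < widths[1] * 0.7


def test_roc_curve_endpoints_and_monotonicity(binormal_sample):
    scores, labels = binormal_sample
    r = delong_ci(scores, labels)
    fpr, tpr = r.curve[:, 0], r.curve[:, 1]
    assert fpr[0] == 0.0 and tpr[0] == 0.0
    assert fpr[-1] == 1.0 and tpr[-1] == 1.0
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def test_binormal_smoothing_recovers_closed_form_auc():
    d = auc_to_separation(0.85)
    rng = np.random.default_rng(10)
    labels = np.concatenate([np.ones(4000, int), np.zeros(4000, int)])
    scores = labels * d + rng.standard_normal(8000)
    sm = smooth_roc(scores, labels)
    # equal-variance binormal truth: a = d, b = 1
    assert sm.auc == pytest.approx(stats.norm.cdf(sm.a / np.sqrt(1 + sm.b**2)),
                                   abs=1e-12)
    assert sm.auc == pytest.approx(0.85, abs=0.01)
    assert sm.b == pytest.approx(1.0, abs=0.1)


def test_smoothing_perfect_separation_falls_back_with_warning():
    with pytest.warns(UserWarning, match="interior"):
        sm = smooth_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert not sm.fitted


def test_smoothed_curve_label_swap_symmetry():
    """Swapping labels in a balanced design reflects the curve across the
    anti-diagonal (fpr, tpr) -> (1 - tpr, 1 - fpr)."""
    rng = np.random.default_rng(3)
    labels = np.concatenate([np.ones(300, int), np.zeros(300, int)])
    scores = labels * 1.2 + rng.standard_normal(600)
    sm = smooth_roc(scores, labels)
    swapped = smooth_roc(-scores, 1 - labels)
    # both fits describe the same underlying binormal pair
    assert swapped.auc == pytest.approx(sm.auc, abs=0.02)


# --------------------------------------------------------------------------
# Youden operating point and binomial intervals
# --------------------------------------------------------------------------

def test_youden_j_identity_examples():
    assert youden_j(0.81, 0.94) == pytest.approx(0.75)
    assert youden_j(0.89, 0.98) == pytest.approx(0.87)


def test_youden_perfect_classifier():
    op = youden_operating_point([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert op.youden_j == 1.0
    assert op.sensitivity == 1.0 and op.specificity == 1.0


def test_youden_identity_holds_exactly(binormal_sample):
    scores, labels = binormal_sample
    op = youden_operating_point(scores, labels)
    assert op.youden_j == op.sensitivity + op.specificity - 1.0


def test_youden_tie_break_prefers_sensitivity():
    # two thresholds achieve the same J; the lower one (higher Se) wins
    scores = [0.9, 0.7, 0.5, 0.3]
    labels = [1, 1, 0, 0]
    op = youden_operating_point(scores, labels)
    assert op.threshold == 0.7
    assert op.sensitivity == 1.0


def test_youden_matches_oracle_on_random_small_data():
    rng = np.random.default_rng(8)
    for _ in range(200):
        n = rng.integers(4, 10)
        labels = rng.integers(0, 2, n)
        labels[0], labels[-1] = 1, 0
        scores = rng.choice([0.1, 0.4, 0.6, 0.9], n)
        op = youden_operating_point(scores, labels)
        j, t, se, sp = oracle_youden(scores, labels)
        assert op.youden_j == pytest.approx(j, abs=1e-12)
        assert op.threshold == pytest.approx(t)


def test_youden_near_zero_when_labels_independent():
    rng = np.random.default_rng(12)
    labels = rng.integers(0, 2, 4000)
    scores = rng.random(4000)
    op = youden_operating_point(scores, labels)
    assert op.youden_j < 0.1


@pytest.mark.parametrize("x,n,lo,hi", [
    (8, 8, 0.025 ** (1 / 8), 1.0),
    (0, 10, 0.0, 1 - 0.025 ** (1 / 10)),
    (5, 5, 0.025 ** (1 / 5), 1.0),
])
def test_clopper_pearson_closed_forms(x, n, lo, hi):
    got = binomial_ci(x, n)
    assert got[0] == pytest.approx(lo, abs=1e-10)
    assert got[1] == pytest.approx(hi, abs=1e-10)


def test_clopper_pearson_matches_reported_all_positive_cell():
    # 8/8 sensitivity reported as 1.00 (0.63–1.00)
    lo, hi = binomial_ci(8, 8)
    assert round(lo, 2) == 0.63 and hi == 1.0


def test_binomial_ci_rejects_invalid_counts():
    with pytest.raises(ValidationError):
        binomial_ci(5, 4)
    with pytest.raises(ValidationError):
        binomial_ci(-1, 4)


# --------------------------------------------------------------------------
# permutation test
# --------------------------------------------------------------------------

def test_identical_arms_give_p_one():
    scores = [0.9, 0.6, 0.4, 0.2, 0.7, 0.1]
    labels = [1, 1, 0, 0, 1, 0]
    res = permutation_test_auc(scores, scores, labels, n_permutations=200,
                               seed=0)
    assert res.delta_auc == 0.0
    assert res.p_value == 1.0


def test_exhaustive_small_instance_matches_oracle():
    rng = np.random.default_rng(14)
    for _ in range(20):
        n = int(rng.integers(3, 7))
        labels = rng.integers(0, 2, n)
        labels[0], labels[-1] = 1, 0
        a = rng.random(n).round(2)
        b = rng.random(n).round(2)
        res = permutation_test_auc(a, b, labels, method="exhaustive")
        assert res.n_permutations == 2 ** n
        assert res.p_value == pytest.approx(oracle_permutation_p(a, b, labels),
                                            abs=1e-12)


def test_permutation_reproducible_bit_for_bit():
    rng = np.random.default_rng(15)
    labels = rng.integers(0, 2, 60)
    labels[0], labels[-1] = 1, 0
    a, b = rng.random(60), rng.random(60)
    r1 = permutation_test_auc(a, b, labels, n_permutations=500, seed=42,
                              method="monte_carlo")
    r2 = permutation_test_auc(a, b, labels, n_permutations=500, seed=42,
                              method="monte_carlo")
    assert r1.p_value == r2.p_value


def test_permutation_p_respects_add_one_floor():
    d = auc_to_separation(0.99)
    rng = np.random.default_rng(16)
    labels = np.concatenate([np.ones(40, int), np.zeros(40, int)])
    a = labels * d + 0.1 * rng.standard_normal(80)
    b = rng.random(80)
    res = permutation_test_auc(a, b, labels, n_permutations=99, seed=1,
                               method="monte_carlo")
    assert res.p_value >= 1 / 100


def test_permutation_scale_free():
    """Monotone rescaling of one arm does not change the p-value."""
    rng = np.random.default_rng(17)
    labels = rng.integers(0, 2, 50)
    labels[0], labels[-1] = 1, 0
    a, b = rng.random(50), rng.random(50)
    r1 = permutation_test_auc(a, b, labels, n_permutations=300, seed=3,
                              method="monte_carlo")
    r2 = permutation_test_auc(np.exp(5 * a), b, labels, n_permutations=300,
                              seed=3, method="monte_carlo")
    assert r1.p_value == r2.p_value
    assert r1.delta_auc == pytest.approx(r2.delta_auc, abs=1e-12)


def test_unpaired_inputs_rejected_with_case_list():
    with pytest.raises(ValidationError, match="C3"):
        permutation_test_auc([0.1, 0.2], [0.3, 0.4], [1, 0],
                             case_ids_a=["C1", "C2"], case_ids_b=["C1", "C3"])


def test_unpaired_scheme_runs_and_detects_difference():
    d = auc_to_separation(0.95)
    rng = np.random.default_rng(18)
    labels = np.concatenate([np.ones(60, int), np.zeros(60, int)])
    a = labels * d + rng.standard_normal(120)
    b = rng.standard_normal(120)
    res = permutation_test_auc(a, b, labels, n_permutations=499, seed=5,
                               paired=False, method="monte_carlo")
    assert res.p_value < 0.05
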