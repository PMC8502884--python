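"""ROC/Youden/Wilcoxon statistics, the barycentric projection, and the
packaged clinical cohort."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edematrack.exceptions import ParameterError, ValidationError
from edematrack.stats import (
    load_table1,
    roc,
    sens_spec_at,
    ternary_coordinates,
    wilcoxon_signed_rank,
    youden,
)


@pytest.fixture(scope="module")
def cohort():
    return load_table1()


class TestFixture:
    def test_shape_and_labels(self, cohort):
        assert len(cohort) == 24
        assert int(cohort["motor_decline"].sum()) == 7
        assert cohort["edema_volume_mm3"].min() > 0
        assert cohort["ltd_mm"].min() >= 0


class TestRoc:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], "greater")
        assert r.auc == 1.0
        assert youden(r)[1] == 1.0

    def test_identical_distributions_auc_half(self):
        r = roc([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1], "greater")
        assert r.auc == pytest.approx(0.5)
        assert youden(r)[1] == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc([1, 2, 3], [1, 1, 1], "greater")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_mannwhitney_equals_trapezoid(self, seed):
        """AUC as the rank statistic equals the trapezoidal ROC integral."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        values = np.round(rng.normal(size=n), 1)  # coarse: force ties
        labels = rng.random(n) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = roc(values, labels, "greater")
        # thresholds ascending -> both fpr and sens non-increasing; reverse
        # for a monotone curve from (0,0) to (1,1)
        fpr = (1.0 - r.specificity)[::-1]
        trap = np.trapezoid(r.sensitivity[::-1], fpr)
        assert abs(r.auc - trap) < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_direction_flip_complements_auc(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=20)  # continuous: no ties
        labels = np.arange(20) < 8
        a = roc(values, labels, "greater").auc
        b = roc(values, labels, "less").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_youden_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(size=25), 1)
        labels = rng.random(25) > 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = roc(values, labels, "greater")
        # brute force over all midpoint thresholds
        best = max(
            sum(sens_spec_at(values, labels, t, "greater")) - 1.0
            for t in r.thresholds
        )
        assert youden(r)[1] == pytest.approx(best, abs=1e-12)
        s, sp = sens_spec_at(values, labels, youden(r)[0], "greater")
        assert s + sp - 1 == pytest.approx(youden(r)[1], abs=1e-12)


class TestClinicalCohort:
    """Diagnostic numbers recomputed from the packaged per-patient table."""

    def test_edema_volume_row(self, cohort):
        v = cohort["edema_volume_mm3"].values
        decline = cohort["motor_decline"].values.astype(bool)
        r = roc(v, ~decline, "greater")  # no-decline group has larger volumes
        assert round(r.auc, 3) == 0.689
        sens, spec = sens_spec_at(v, ~decline, 20260.0, "greater")
        assert round(sens, 3) == 0.471
        assert spec == 1.0

    def test_ltd_specificity_at_printed_cutoff(self, cohort):
        v = cohort["ltd_mm"].values
        decline = cohort["motor_decline"].values.astype(bool)
        _, spec = sens_spec_at(v, ~decline, 16.9, "greater")
        assert spec == 1.0  # every decline-labelled patient sits below 16.9 mm

    def test_threshold_below_all_values_gives_full_sensitivity(self, cohort):
        v = cohort["edema_volume_mm3"].values
        decline = cohort["motor_decline"].values.astype(bool)
        sens, _ = sens_spec_at(v, ~decline, 0.0, "greater")
        assert sens == 1.0


def _wilcoxon_enumeration(d):
    """2^n enumeration oracle for the two-sided exact p-value."""
    from itertools import product
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in product((0, 1), repeat=len(d)):
        s = sum(r for r, take in zip(ranks, signs) if take)
        if min(s, ranks.sum() - s) <= w_obs + 1e-12:
            count += 1
    return w_obs, count / 2 ** len(d)


class TestWilcoxon:
    def test_hand_ranked_example(self):
        w, p = wilcoxon_signed_rank([1, -2, 3, -4, 5], [0, 0, 0, 0, 0])
        assert w == 6.0  # negative rank sum 2 + 4
        assert p == pytest.approx(_wilcoxon_enumeration([1, -2, 3, -4, 5])[1])

    def test_constant_shift_gives_w_zero(self):
        x = np.arange(8.0)
        w, p = wilcoxon_signed_rank(x + 1.0, x)
        assert w == 0.0
        assert p == pytest.approx(2 / 2**8)

    def test_exact_p_matches_enumeration_n10(self, rng):
        for _ in range(5):
            d = np.round(rng.normal(size=10), 2)
            d[d == 0] = 0.5
            w, p = wilcoxon_signed_rank(d, np.zeros(10))
            w2, p2 = _wilcoxon_enumeration(d)
            assert w == w2 and p == pytest.approx(p2, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        x = rng.normal(size=11)
        y = rng.normal(size=11)
        w, p = wilcoxon_signed_rank(x, y)
        ref = scipy_wilcoxon(x, y, mode="exact")
        assert w == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_symmetric_under_swap(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        assert wilcoxon_signed_rank(x, y) == wilcoxon_signed_rank(y, x)

    def test_large_n_normal_approximation_close_to_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.8, size=40) + 0.3
        _, p = wilcoxon_signed_rank(x, y)
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_signed_rank([1.0, 1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0, 1.0])


class TestTernary:
    @pytest.mark.parametrize(
        "frac, expected",
        [
            ((1, 0, 0), (0.0, 0.0)),
            ((0, 1, 0), (1.0, 0.0)),
            ((0, 0, 1), (0.5, np.sqrt(3) / 2)),
            ((1 / 3, 1 / 3, 1 / 3), (0.5, np.sqrt(3) / 6)),
        ],
    )
    def test_vertices_and_centroid(self, frac, expected):
        np.testing.assert_allclose(ternary_coordinates(*frac), expected, atol=1e-12)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValidationError):
            ternary_coordinates(0.5, 0.5, 0.5)
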