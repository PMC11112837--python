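"""Kappa statistics, Spearman rho and Landis-Koch interpretation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drscreen import (
    ContingencyTable,
    InputError,
    UndefinedStatisticError,
    WeightScheme,
    cohen_kappa,
    contingency_table,
    landis_koch_band,
    spearman_rho,
    weighted_kappa,
)


def table(rows):
    arr = np.asarray(rows)
    return ContingencyTable(arr, tuple(str(i) for i in range(arr.shape[0])))


# random non-degenerate tables: at least two nonzero cells not all in one
# row/column pair, so Pe < 1
@st.composite
def random_tables(draw, k_max=5):
    k = draw(st.integers(2, k_max))
    cells = draw(
        st.lists(st.integers(0, 30), min_size=k * k, max_size=k * k).map(
            lambda v: np.asarray(v).reshape(k, k)
        )
    )
    t = table(cells)
    if t.n == 0:
        cells[0][0] += 1
        cells[1][1] += 1
        t = table(cells)
    try:
        cohen_kappa(t)
    except UndefinedStatisticError:
        cells[0][0] += 1
        cells[1][1] += 1
        t = table(cells)
    return t


class TestContingencyTable:
    def test_hand_enumeration(self):
        t = contingency_table([0, 0, 1], [0, 1, 1], 2)
        assert t.counts.tolist() == [[1, 1], [0, 1]]

    def test_oslo_structure(self, oslo_gradable):
        from drscreen import grade_codes

        t = contingency_table(
            grade_codes(oslo_gradable, "manual"), grade_codes(oslo_gradable, "ai"), 4
        )
        assert np.diag(t.counts).tolist() == [52, 2, 5, 3]
        off = t.counts - np.diag(np.diag(t.counts))
        assert off[2, 1] == 2 and off.sum() == 2

    def test_self_agreement_is_diagonal(self):
        v = [0, 1, 2, 3, 2, 1]
        t = contingency_table(v, v, 4)
        assert (t.counts - np.diag(np.diag(t.counts))).sum() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            contingency_table([0, 1], [0], 2)

    def test_out_of_range_code_rejected(self):
        with pytest.raises(InputError):
            contingency_table([0, 2], [0, 1], 2)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(table([[5, 0], [0, 5]])).kappa == pytest.approx(1.0)

    def test_symmetric_2x2_by_direct_formula(self):
        # Po = 90/100, Pe = 0.5*0.5 + 0.5*0.5 = 0.5 -> kappa = 0.4/0.5
        res = cohen_kappa(table([[45, 5], [5, 45]]))
        assert res.kappa == pytest.approx(0.8)
        assert res.observed_agreement == pytest.approx(0.9)
        assert res.expected_agreement == pytest.approx(0.5)

    def test_oslo_binary_table_is_perfect(self):
        assert cohen_kappa(table([[52, 0], [0, 12]])).kappa == pytest.approx(1.0)

    def test_oslo_linear_weighted_kappa_matches_report(self, oslo_gradable):
        from drscreen import grade_codes

        t = contingency_table(
            grade_codes(oslo_gradable, "manual"), grade_codes(oslo_gradable, "ai"), 4
        )
        res = weighted_kappa(t, WeightScheme.linear(4))
        assert round(res.kappa, 2) == 0.95
        assert res.band == "very good"
        assert res.p_value < 0.001

    def test_diagonal_table_any_scheme_is_one(self):
        t = table(np.diag([3, 1, 4, 1]))
        for scheme in (WeightScheme.linear(4), WeightScheme.quadratic(4)):
            assert weighted_kappa(t, scheme).kappa == pytest.approx(1.0)

    def test_identity_scheme_equals_unweighted(self):
        t = table([[45, 5], [5, 45]])
        assert weighted_kappa(t, WeightScheme.identity(2)).kappa == pytest.approx(
            cohen_kappa(t).kappa
        )

    def test_degenerate_table_raises(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_kappa(table([[7, 0], [0, 0]]))

    def test_brute_force_2x2(self):
        # direct enumeration of Po and Pe from raw pair counts
        rng = np.random.default_rng(42)
        for _ in range(20):
            c = rng.integers(0, 20, size=(2, 2))
            if c.sum() == 0:
                continue
            n = c.sum()
            po = (c[0, 0] + c[1, 1]) / n
            pe = (c[0].sum() * c[:, 0].sum() + c[1].sum() * c[:, 1].sum()) / n**2
            if pe >= 1:
                continue
            assert cohen_kappa(table(c)).kappa == pytest.approx((po - pe) / (1 - pe))


class TestKappaProperties:
    @settings(derandomize=True, max_examples=80)
    @given(random_tables())
    def test_kappa_bounded(self, t):
        assert -1.0 - 1e-12 <= cohen_kappa(t).kappa <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=80)
    @given(random_tables())
    def test_identity_weight_equivalence(self, t):
        a = cohen_kappa(t).kappa
        b = weighted_kappa(t, WeightScheme.identity(t.k)).kappa
        assert abs(a - b) < 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(random_tables(), st.integers(2, 7))
    def test_scale_invariance(self, t, factor):
        scaled = table(t.counts * factor)
        assert weighted_kappa(scaled, WeightScheme.linear(t.k)).kappa == pytest.approx(
            weighted_kappa(t, WeightScheme.linear(t.k)).kappa
        )

    @settings(derandomize=True, max_examples=50)
    @given(random_tables(), st.randoms(use_true_random=False))
    def test_permutation_invariance(self, t, rnd):
        perm = list(range(t.k))
        rnd.shuffle(perm)
        perm = np.asarray(perm)
        w = WeightScheme.linear(t.k).weights
        permuted = ContingencyTable(
            t.counts[np.ix_(perm, perm)], tuple(t.category_labels[i] for i in perm)
        )
        scheme = WeightScheme("custom", w[np.ix_(perm, perm)])
        assert weighted_kappa(permuted, scheme).kappa == pytest.approx(
            weighted_kappa(t, WeightScheme("custom", w)).kappa
        )

    @settings(derandomize=True, max_examples=40)
    @given(random_tables(k_max=4))
    def test_cross_check_against_statsmodels(self, t):
        from statsmodels.stats.inter_rater import cohens_kappa

        for wt, scheme in (("linear", WeightScheme.linear(t.k)), (None, WeightScheme.identity(t.k))):
            ours = weighted_kappa(t, scheme)
            theirs = cohens_kappa(t.counts, wt=wt)
            assert ours.kappa == pytest.approx(theirs.kappa, abs=1e-10)
            assert ours.standard_error == pytest.approx(theirs.var_kappa**0.5, abs=1e-10)

    def test_cross_check_against_sklearn(self, oslo_gradable):
        from sklearn.metrics import cohen_kappa_score

        from drscreen import grade_codes

        m = grade_codes(oslo_gradable, "manual")
        a = grade_codes(oslo_gradable, "ai")
        t = contingency_table(m, a, 4)
        assert weighted_kappa(t, WeightScheme.linear(4)).kappa == pytest.approx(
            cohen_kappa_score(m, a, weights="linear")
        )
        assert weighted_kappa(t, WeightScheme.quadratic(4)).kappa == pytest.approx(
            cohen_kappa_score(m, a, weights="quadratic")
        )


class TestSpearman:
    def test_identical_vectors(self):
        rho, _ = spearman_rho([0, 1, 2, 2, 3], [0, 1, 2, 2, 3])
        assert rho == pytest.approx(1.0)

    def test_reversed_vectors(self):
        rho, _ = spearman_rho([0, 1, 2, 3], [3, 2, 1, 0])
        assert rho == pytest.approx(-1.0)

    def test_oslo_value_near_one(self, oslo_gradable):
        from drscreen import grade_codes

        rho, p = spearman_rho(
            grade_codes(oslo_gradable, "manual"), grade_codes(oslo_gradable, "ai")
        )
        assert 0.9 < rho <= 1.0
        assert p < 0.001

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1, 1], [0, 1, 2, 3])


class TestLandisKoch:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.95, "very good"), (0.20, "poor"), (-0.5, "poor"), (0.21, "fair"),
            (0.40, "fair"), (0.41, "moderate"), (0.60, "moderate"), (0.61, "good"),
            (0.80, "good"), (0.81, "very good"), (1.0, "very good"),
        ],
    )
    def test_band_boundaries(self, kappa, band):
        assert landis_koch_band(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            landis_koch_band(1.5)
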