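"""TOST equivalence machinery against hand calculations, published rows,
and a numerical-integration oracle."""
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from forumlab import literature
from forumlab.equivalence import (
    BoundarySpec,
    CohortComparison,
    EquivalenceError,
    aggregate_mean,
    directional_test,
    pooled_sd,
    tost,
)
from forumlab.types import CohortSummary


def t_sf_oracle(t, df):
    """P(T > t) by numerical integration of the t density."""

    def pdf(x):
        return math.exp(
            gammaln((df + 1) / 2) - gammaln(df / 2)
            - 0.5 * math.log(df * math.pi)
            - (df + 1) / 2 * math.log1p(x * x / df)
        )

    if t >= 0:
        val, _ = integrate.quad(pdf, t, math.inf)
        return val
    val, _ = integrate.quad(pdf, -math.inf, t)
    return 1.0 - val


def tost_oracle(mA, sA, nA, mB, sB, nB, d=0.499):
    sp = math.sqrt(((nA - 1) * sA**2 + (nB - 1) * sB**2) / (nA + nB - 2))
    b = d * sp
    se = sp * math.sqrt(1 / nA + 1 / nB)
    df = nA + nB - 2
    delta = mB - mA
    p_lower = t_sf_oracle((delta + b) / se, df)
    p_upper = 1.0 - t_sf_oracle((delta - b) / se, df)
    return b, max(p_lower, p_upper)


class TestPooledSD:
    def test_equal_groups(self):
        assert pooled_sd([(10, 2.0), (10, 2.0)]) == pytest.approx(2.0)

    def test_hand_evaluated_formula(self):
        # sqrt((1*0 + 1*4) / 2) = sqrt(2)
        assert pooled_sd([(2, 0.0), (2, 2.0)]) == pytest.approx(math.sqrt(2))

    def test_convexity_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = [
                (int(rng.integers(2, 100)), float(rng.uniform(0.1, 9)))
                for _ in range(int(rng.integers(2, 5)))
            ]
            sp = pooled_sd(groups)
            sds = [s for _, s in groups]
            assert min(sds) <= sp <= max(sds)

    def test_degrees_of_freedom_error(self):
        with pytest.raises(EquivalenceError):
            pooled_sd([(1, 2.0), (10, 2.0)])


class TestAggregateMean:
    def test_published_dheas_aggregate(self):
        # four reporting studies combine to n=1288, mean 265.5
        studies = [
            CohortSummary("dheas", 634, 286.3, 119.8),
            CohortSummary("dheas", 372, 288.3, 127.4),
            CohortSummary("dheas", 213, 163.9, 83.4),
            CohortSummary("dheas", 69, 265.3, 118.3),
        ]
        agg = aggregate_mean(studies)
        assert agg.n == 1288
        assert round(agg.mean, 1) == 265.5

    def test_single_study_identity(self):
        (s,) = [CohortSummary("fsh", 319, 6.2, 2.1)]
        agg = aggregate_mean([s])
        assert (agg.n, agg.mean) == (319, 6.2)

    def test_equal_n_symmetry(self):
        agg = aggregate_mean(
            [CohortSummary("x", 50, 10.0, 1.0), CohortSummary("x", 50, 20.0, 1.0)]
        )
        assert agg.mean == pytest.approx(15.0)

    def test_missing_test_error(self):
        with pytest.raises(EquivalenceError):
            aggregate_mean([CohortSummary("fsh", 10, 5.0, 1.0)], "lh")


class TestTOST:
    def test_published_fsh_row_equivalent(self):
        b, p, eq = tost(5.8, 3.1, 214, 5.9, 6.4, 1883)
        assert eq and p < 0.001

    def test_identical_large_groups(self):
        _, p, eq = tost(10.0, 2.0, 5000, 10.0, 2.0, 5000)
        assert eq and p < 1e-12

    def test_boundary_is_d_times_pooled_sd(self):
        spec = BoundarySpec(cohen_d=0.3)
        b, _, _ = tost(5.0, 2.0, 30, 6.0, 4.0, 50, spec)
        assert b == pytest.approx(0.3 * pooled_sd([(30, 2.0), (50, 4.0)]))

    def test_monotone_in_boundary_and_delta(self):
        # larger boundary -> easier equivalence (p nonincreasing in d)
        ps = [
            tost(5.0, 2.0, 40, 5.5, 2.0, 40, BoundarySpec(cohen_d=d))[1]
            for d in (0.2, 0.499, 0.8)
        ]
        assert ps[0] >= ps[1] >= ps[2]
        # larger |delta| at fixed boundary -> p nondecreasing
        ps = [tost(5.0, 2.0, 40, 5.0 + dlt, 2.0, 40)[1] for dlt in (0.0, 0.5, 1.5)]
        assert ps[0] <= ps[1] <= ps[2]

    def test_degenerate_inputs_raise(self):
        with pytest.raises(EquivalenceError):
            tost(5.0, 0.0, 10, 5.0, 0.0, 10)
        with pytest.raises(EquivalenceError):
            tost(5.0, 1.0, 1, 5.0, 1.0, 10)

    def test_numerical_integration_oracle(self):
        """p agrees with direct integration of the t density to 1e-6."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            nA, nB = int(rng.integers(2, 400)), int(rng.integers(2, 2000))
            mA, mB = rng.uniform(0, 50, 2)
            sA, sB = rng.uniform(0.1, 30, 2)
            b, p, _ = tost(mA, sA, nA, mB, sB, nB)
            b_o, p_o = tost_oracle(mA, sA, nA, mB, sB, nB)
            assert b == pytest.approx(b_o, abs=1e-9)
            assert p == pytest.approx(p_o, abs=1e-6)


class TestDirectional:
    def test_published_dheas_literature_lower(self):
        direction, p = directional_test(396.5, 165.2, 381, 265.5, 293.7, 1288)
        assert direction == "B-lower" and p < 0.001

    def test_identical_groups_none(self):
        direction, _ = directional_test(5.0, 1.0, 50, 5.0, 1.0, 50)
        assert direction == "none"

    def test_antisymmetry(self):
        d1, p1 = directional_test(5.0, 1.0, 50, 6.0, 1.0, 60)
        d2, p2 = directional_test(6.0, 1.0, 60, 5.0, 1.0, 50)
        assert {d1, d2} == {"B-lower", "B-higher"}
        assert p1 == pytest.approx(p2)


@pytest.fixture(scope="module")
def fitted():
    cohort = literature.subreddit_summaries()
    model = CohortComparison(
        cohort,
        {
            "aggregate": literature.published_aggregate_summaries(),
            **literature.study_summaries(),
        },
    )
    return model.fit()


class TestCohortComparison:
    def test_verdict_exclusivity(self, fitted):
        allowed = {"equivalent", "B-lower", "B-higher", "inconclusive"}
        for row in fitted.rows:
            assert row.verdict in allowed
            if row.verdict == "equivalent":
                assert row.equivalent and row.p_directional is None
            else:
                assert not row.equivalent

    def test_age_vs_tosi_literature_lower(self, fitted):
        assert fitted.verdict_of("age", "tosi") == "B-lower"

    def test_unreported_cells_absent(self, fitted):
        # Tosi et al does not report FSH
        with pytest.raises(KeyError):
            fitted.verdict_of("fsh", "tosi")

    def test_matrix_and_summary_render(self, fitted):
        matrix = fitted.matrix()
        assert matrix.loc["age", "tosi"] == "b"
        text = fitted.summary()
        assert "boundary" in text and "equivalent" in text

    def test_p_values_in_unit_interval(self, fitted):
        frame = fitted.to_frame()
        assert frame.p_tost.between(0, 1).all()
        assert frame.boundary.gt(0).all()
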