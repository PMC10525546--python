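"""Weekly tabulation and the dialogic-weight cohesion index.

The worked-example week is checked against an independent sum-product
oracle: (count, weight, variable) triples typed directly from the published
weight and frequency tables, reduced with plain arithmetic — no package
code on the oracle path.
"""

from datetime import date, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

import drcohesion as dc
from drcohesion.cohesion import round_half_up

# (raw label, count, dW, variable) — the worked-example week joined by hand.
ORACLE_ROWS = [
    ("Description", 242, 20.0, "x"),
    ("Proposal", 4, 18.27, "y"),
    ("Anticipation", 1, 19.14, "x"),
    ("Consideration", 6, 12.18, "x"),
    ("Declaration of aims", 8, 13.92, "y"),
    ("Possibility", 10, 17.4, "y"),
    ("Evaluation", 50, 11.31, "y"),
    ("Confirmation", 31, 5.22, "x"),
    ("Prescription", 24, 14.79, "y"),
    ("Specification", 63, 8.7, "x"),
    ("Implication", 7, 10.44, "x"),
    ("Reshaping", 22, 16.53, "y"),
    ("Comment", 254, 15.66, "y"),
    ("Judgement", 71, 4.35, "y"),
    ("Cause of action", 39, 1.74, "x"),
    ("Deresponsibility", 11, 9.57, "y"),
    ("Certify Reality", 321, 0.87, "y"),
    ("Opinion", 23, 13.05, "y"),
    ("Justification", 13, 7.83, "y"),
    ("Contraposition", 16, 2.61, "y"),
    ("Generalisation", 40, 6.96, "x"),
    ("Non answer", 29, 6.09, "y"),
    ("Prevision", 38, 3.48, "x"),
]


def oracle_means():
    n_x = sum(c for _, c, _, v in ORACLE_ROWS if v == "x")
    n_y = sum(c for _, c, _, v in ORACLE_ROWS if v == "y")
    x_mean = sum(c * w for _, c, w, v in ORACLE_ROWS if v == "x") / n_x
    y_mean = sum(c * w for _, c, w, v in ORACLE_ROWS if v == "y") / n_y
    return x_mean, y_mean, n_x, n_y


def make_annotations(counts: dict, week_start=date(2021, 12, 31)):
    out = []
    k = 0
    for label, count in counts.items():
        for _ in range(count):
            out.append(
                dc.AnnotatedOccurrence(
                    occurrence_id=f"a{k}",
                    dr_label=label,
                    raw_label=label,
                    annotator="t",
                    published_at=week_start + timedelta(days=k % 7),
                )
            )
            k += 1
    return out


class TestTabulation:
    def test_worked_example_counts_and_shares(self, worked_tabulation):
        """The replayed worked-example week reproduces every printed count
        and 2-dp share (raw labels resolved to canonical names)."""
        tab = worked_tabulation
        assert tab.total == 1323
        assert tab.counts["Description"] == 242
        assert tab.counts["Certify Reality"] == 321
        assert tab.counts["Prediction"] == 38  # "Prevision" rows
        assert tab.counts["Delegating to others"] == 11  # "Deresponsibility"
        assert tab.shares["Description"] == 18.29
        assert tab.shares["Certify Reality"] == 24.26
        assert tab.shares["Comment"] == 19.20
        assert tab.shares["Judgement"] == 5.37
        assert tab.shares["Specification"] == 4.76
        assert tab.shares["Evaluation"] == 3.78

    def test_single_annotation_full_share(self, registry, worked_week):
        tab = dc.tabulate(make_annotations({"Comment": 1}), worked_week, registry)
        assert tab.total == 1
        assert tab.shares["Comment"] == 100.00

    def test_out_of_window_rejected_with_count(self, registry, worked_week):
        anns = make_annotations({"Comment": 5}) + make_annotations(
            {"Comment": 3}, week_start=date(2022, 1, 10)
        )
        tab = dc.tabulate(anns, worked_week, registry)
        assert tab.total == 5
        assert tab.n_out_of_window == 3

    def test_empty_week_is_error(self, registry, worked_week):
        with pytest.raises(dc.EmptyWeekError):
            dc.tabulate([], worked_week, registry)

    def test_permutation_invariance(self, registry, worked_week):
        anns = make_annotations({"Comment": 10, "Description": 5, "Judgement": 2})
        forward = dc.tabulate(anns, worked_week, registry)
        backward = dc.tabulate(list(reversed(anns)), worked_week, registry)
        assert forward.counts == backward.counts
        assert forward.shares == backward.shares


class TestVariableMeans:
    def test_worked_example_against_sum_product_oracle(self, worked_tabulation, registry):
        x_mean, y_mean, n_x, n_y = oracle_means()
        means = dc.variable_means(worked_tabulation, registry)
        assert (means.n_x, means.n_y) == (n_x, n_y) == (467, 856)
        assert means.x_mean == pytest.approx(x_mean, abs=1e-12)
        assert means.y_mean == pytest.approx(y_mean, abs=1e-12)
        # frozen oracle values, recomputed by hand before the build
        assert means.x_mean == pytest.approx(13.2628, abs=1e-4)
        assert means.y_mean == pytest.approx(8.1004, abs=1e-4)

    def test_zero_mass_variable_undefined_not_zero(self, registry, worked_week):
        tab = dc.tabulate(make_annotations({"Description": 5}), worked_week, registry)
        means = dc.variable_means(tab, registry)
        assert means.x_mean == 20.0
        assert means.y_mean is None
        assert means.n_y == 0

    def test_scale_invariance(self, registry, worked_week):
        base = {"Description": 3, "Comment": 4, "Judgement": 1}
        small = dc.variable_means(
            dc.tabulate(make_annotations(base), worked_week, registry), registry
        )
        big = dc.variable_means(
            dc.tabulate(
                make_annotations({k: 10 * v for k, v in base.items()}), worked_week, registry
            ),
            registry,
        )
        assert small.x_mean == pytest.approx(big.x_mean)
        assert small.y_mean == pytest.approx(big.y_mean)

    @given(
        counts=st.dictionaries(
            st.sampled_from([r[0] for r in ORACLE_ROWS]),
            st.integers(min_value=0, max_value=500),
            min_size=1,
        ).filter(lambda d: sum(d.values()) > 0 and sum(d.values()) <= 10_000)
    )
    def test_oracle_equivalence_random_tabulations(self, counts):
        """Pipeline means equal a brute-force sum-product over random count
        vectors to 1e-9."""
        registry = dc.load_registry()
        week = dc.Week(date(2021, 12, 31), date(2022, 1, 6))
        weights = {raw: (w, v) for raw, _, w, v in ORACLE_ROWS}
        tab = dc.tabulate(make_annotations(counts), week, registry)
        means = dc.variable_means(tab, registry)
        for var, got in (("x", means.x_mean), ("y", means.y_mean)):
            num = sum(c * weights[l][0] for l, c in counts.items() if weights[l][1] == var)
            den = sum(c for l, c in counts.items() if weights[l][1] == var)
            if den == 0:
                assert got is None
            else:
                assert got == pytest.approx(num / den, abs=1e-9)


class TestCohesionIndex:
    def test_worked_example_default_strategy(self, worked_tabulation, registry):
        """xy-mean on the worked-example week: (13.2628 + 8.1004)/2 → 10.68."""
        x_mean, y_mean, _, _ = oracle_means()
        result = dc.cohesion_index(worked_tabulation, registry)
        assert result.index == pytest.approx((x_mean + y_mean) / 2, abs=1e-12)
        assert result.rounded_index == 10.68
        assert result.strategy == "xy-mean"
        assert not result.single_variable

    @pytest.mark.parametrize("k", [1, 7, 100])
    def test_single_variable_boundary_cases(self, registry, worked_week, k):
        hi = dc.cohesion_index(
            dc.tabulate(make_annotations({"Description": k}), worked_week, registry), registry
        )
        assert hi.rounded_index == 20.00 and hi.single_variable
        lo = dc.cohesion_index(
            dc.tabulate(make_annotations({"Certify Reality": k}), worked_week, registry),
            registry,
        )
        assert lo.rounded_index == 0.87 and lo.single_variable

    def test_pooled_mean_strategy_registered(self, worked_tabulation, registry):
        result = dc.cohesion_index(worked_tabulation, registry, strategy="pooled-mean")
        x_mean, y_mean, n_x, n_y = oracle_means()
        assert result.index == pytest.approx(
            (x_mean * n_x + y_mean * n_y) / (n_x + n_y), abs=1e-12
        )

    def test_unknown_strategy_lists_registered(self, worked_tabulation, registry):
        with pytest.raises(dc.ConfigurationError, match="xy-mean"):
            dc.cohesion_index(worked_tabulation, registry, strategy="geometric")

    @given(
        counts=st.dictionaries(
            st.sampled_from([r[0] for r in ORACLE_ROWS]),
            st.integers(min_value=0, max_value=1000),
            min_size=1,
        ).filter(lambda d: sum(d.values()) > 0)
    )
    def test_boundedness(self, counts):
        """Any non-empty tabulation yields an index within the registry's
        weight range [0.87, 20]."""
        registry = dc.load_registry()
        week = dc.Week(date(2021, 12, 31), date(2022, 1, 6))
        tab = dc.tabulate(make_annotations(counts), week, registry)
        result = dc.cohesion_index(tab, registry)
        assert 0.87 <= result.index <= 20.0

    @pytest.mark.parametrize(
        "lower, higher",
        [("Cause of action", "Description"), ("Certify Reality", "Comment")],
    )
    def test_within_variable_monotonicity(self, registry, worked_week, lower, higher):
        """Moving one annotation from a lower-dW to a higher-dW repertoire of
        the same variable never decreases the index."""
        base = {"Description": 5, "Comment": 5, lower: 10, higher: 2}
        shifted = dict(base)
        shifted[lower] -= 1
        shifted[higher] += 1
        before = dc.cohesion_index(
            dc.tabulate(make_annotations(base), worked_week, registry), registry
        )
        after = dc.cohesion_index(
            dc.tabulate(make_annotations(shifted), worked_week, registry), registry
        )
        assert after.index >= before.index


class TestDeltaAndTrend:
    @staticmethod
    def result(week_start: date, index: float) -> dc.CohesionResult:
        return dc.CohesionResult(
            week=dc.Week.starting(week_start),
            x_mean=index,
            y_mean=index,
            n_x=1,
            n_y=1,
            index=index,
            strategy="xy-mean",
        )

    def test_decrease(self):
        prev = self.result(date(2021, 12, 24), 11.24)
        curr = self.result(date(2021, 12, 31), 10.76)
        delta = dc.weekly_delta(curr, prev)
        assert delta.delta == pytest.approx(-0.48)
        assert delta.direction == "decreased"

    def test_stable_below_reporting_precision(self):
        prev = self.result(date(2021, 12, 24), 10.0)
        curr = self.result(date(2021, 12, 31), 10.004)
        assert dc.weekly_delta(curr, prev).direction == "stable"

    def test_increase(self):
        prev = self.result(date(2021, 12, 24), 5.0)
        curr = self.result(date(2021, 12, 31), 15.0)
        delta = dc.weekly_delta(curr, prev)
        assert delta.delta == pytest.approx(10.0)
        assert delta.direction == "increased"

    def test_identical_weeks_rejected(self):
        r = self.result(date(2021, 12, 31), 10.0)
        with pytest.raises(dc.CohesionError):
            dc.weekly_delta(r, r)

    def test_gap_warns_but_computes(self):
        prev = self.result(date(2021, 12, 3), 10.0)
        curr = self.result(date(2021, 12, 31), 11.0)
        with pytest.warns(UserWarning, match="consecutive"):
            delta = dc.weekly_delta(curr, prev)
        assert delta.direction == "increased"

    def test_threshold_query(self):
        results = [
            self.result(date(2021, 12, 3), 13.0),
            self.result(date(2021, 12, 10), 9.0),
            self.result(date(2021, 12, 17), 11.0),
        ]
        series = dc.trend_series(results)
        assert [w.start for w in series.weeks_above(12)] == [date(2021, 12, 3)]

    def test_phase_bands_label_weeks(self):
        results = [self.result(date(2021, 12, 3), 13.0), self.result(date(2021, 12, 10), 9.0)]
        series = dc.trend_series(
            results, phase_bands=[("phase-1", date(2021, 12, 1), date(2021, 12, 5))]
        )
        assert [p for _, _, p in series.rows] == ["phase-1", None]

    def test_unsorted_input_rejected(self):
        results = [self.result(date(2021, 12, 10), 9.0), self.result(date(2021, 12, 3), 13.0)]
        with pytest.raises(dc.CohesionError, match="sorted"):
            dc.trend_series(results)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(10.675, 10.68), (10.684999, 10.68), (0.005, 0.01), (18.285, 18.29)],
    )
    def test_half_up_at_two_decimals(self, value, expected):
        assert round_half_up(value) == expected
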