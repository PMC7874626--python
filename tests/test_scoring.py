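import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hacrp.core import HospitalRecord
from hacrp.psi90 import Psi90Result
from hacrp.scoring import (
    DegenerateMeasureError,
    assign_deciles,
    fit_winsorization,
    score_cohort_winsorized,
    score_domain1_decile,
    score_domain2_decile,
    winsorized_z,
)

from .oracles import decile_bruteforce, winsorize_fit_bruteforce


class TestAssignDeciles:
    def test_ten_distinct_values_fill_every_decile(self):
        values = {f"H{i}": float(i) for i in range(10)}
        assert sorted(assign_deciles(values).values()) == list(range(1, 11))

    def test_ties_share_the_worse_decile(self):
        # max-rank: a,b at rank 2 of 3 -> ceil(20/3) = 7; c -> 10
        assert assign_deciles({"a": 1.0, "b": 1.0, "c": 2.0}) == {
            "a": 7, "b": 7, "c": 10}

    def test_all_equal_values_land_in_decile_ten(self):
        assert set(assign_deciles({f"H{i}": 3.3 for i in range(7)}).values()) == {10}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assign_deciles({})

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 30), min_size=1, max_size=200))
    def test_matches_bruteforce_oracle_with_ties(self, raw):
        pairs = [(f"H{i}", float(v) / 3.0) for i, v in enumerate(raw)]
        assert assign_deciles(pairs) == decile_bruteforce(pairs)

    @settings(max_examples=50, deadline=None)
    # values on a coarse grid so log stays strictly monotone at float
    # resolution
    @given(st.lists(st.floats(0.1, 100.0, allow_nan=False).map(lambda v: round(v, 3)),
                    min_size=2, max_size=50, unique=True))
    def test_invariant_under_monotone_transform(self, values):
        pairs = [(f"H{i}", v) for i, v in enumerate(values)]
        logged = [(h, math.log(v)) for h, v in pairs]
        assert assign_deciles(pairs) == assign_deciles(logged)


class TestDecileDomainScores:
    def test_worst_composite_scores_decile_ten(self):
        psi90 = [Psi90Result(f"H{i}", float(i), 10, False) for i in range(20)]
        scores = score_domain1_decile(psi90)
        assert scores["H19"] == 10
        assert scores["H0"] == 1

    def test_median_of_101_reporters_scores_six(self):
        # rank 51 of 101 -> ceil(510/101) = 6
        records = [HospitalRecord(f"H{i}", sir_measures={"SSI": float(i)})
                   for i in range(101)]
        assert score_domain2_decile(records, ["SSI"])["H50"] == 6

    def test_domain2_is_mean_of_reported_measure_deciles(self):
        records = (
            [HospitalRecord(f"A{i}", sir_measures={"SSI": float(i)}) for i in range(9)]
            + [HospitalRecord("X", sir_measures={"SSI": 3.1, "CDI": 9.0})]
            + [HospitalRecord(f"B{i}", sir_measures={"CDI": float(i)}) for i in range(9)]
        )
        scores = score_domain2_decile(records, ["SSI", "CDI"])
        # X: SSI rank 5/10 -> decile 5, CDI rank 10/10 -> 10, mean 7.5
        assert scores["X"] == pytest.approx(7.5)

    def test_hospital_reporting_nothing_gets_no_score(self):
        records = [HospitalRecord("H1", sir_measures={"SSI": 1.0}),
                   HospitalRecord("H2")]
        assert score_domain2_decile(records, ["SSI"])["H2"] is None

    def test_unreported_measures_never_contribute(self):
        records = [HospitalRecord("H1", sir_measures={"SSI": 9.0}),
                   HospitalRecord("H2", sir_measures={"SSI": 1.0, "CDI": 99.0})]
        scores = score_domain2_decile(records, ["SSI", "CDI"])
        # H1's score is built from SSI alone, untouched by H2's CDI
        assert scores["H1"] == 10.0


class TestWinsorization:
    def test_percentiles_of_1_to_100_under_ceil_convention(self):
        values = {f"H{i}": float(i) for i in range(1, 101)}
        bounds = fit_winsorization(values, "SSI")
        assert bounds.p5 == 5.0
        assert bounds.p95 == 95.0
        assert bounds.n_eligible == 100

    def test_interior_values_unchanged_by_winsorization(self):
        values = [("a", 10.0), ("b", 11.0), ("c", 12.0), ("d", 13.0)]
        bounds = fit_winsorization(values)
        arr = np.array([v for _, v in values])
        assert bounds.mean_w == pytest.approx(arr.mean())
        assert bounds.sd_w == pytest.approx(arr.std(ddof=1))

    def test_constant_measure_is_degenerate(self):
        with pytest.raises(DegenerateMeasureError):
            fit_winsorization([("a", 2.0), ("b", 2.0), ("c", 2.0)])

    def test_z_of_mean_is_zero_and_tail_values_clamp(self):
        values = {f"H{i}": float(i) for i in range(1, 101)}
        bounds = fit_winsorization(values)
        assert winsorized_z(bounds.mean_w, bounds) == pytest.approx(0.0)
        assert winsorized_z(1.0, bounds) == winsorized_z(-50.0, bounds)
        assert winsorized_z(95.0, bounds) == pytest.approx(
            (bounds.p95 - bounds.mean_w) / bounds.sd_w)

    @settings(max_examples=100, deadline=None)
    # SIR-like ratios at reporting precision; avoids degenerate spreads
    # below float-squaring resolution
    @given(st.lists(st.floats(0.0, 50.0, allow_nan=False).map(lambda v: round(v, 4)),
                    min_size=2,
                    max_size=150).filter(lambda v: len(set(v)) > 1))
    def test_fit_matches_bruteforce_oracle(self, values):
        bounds = fit_winsorization([(f"H{i}", v) for i, v in enumerate(values)])
        p5, p95, m, sd = winsorize_fit_bruteforce(values)
        assert (bounds.p5, bounds.p95) == (p5, p95)
        assert bounds.mean_w == pytest.approx(m, abs=1e-12)
        assert bounds.sd_w == pytest.approx(sd, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.1, 20.0, allow_nan=False), min_size=5,
                    max_size=80).filter(lambda v: len(set(v)) > 1),
           st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    def test_z_equivariant_under_positive_affine_transform(self, values, a, b):
        pairs = [(f"H{i}", v) for i, v in enumerate(values)]
        moved = [(h, a * v + b) for h, v in pairs]
        bounds, bounds2 = fit_winsorization(pairs), fit_winsorization(moved)
        for (_, v), (_, u) in zip(pairs, moved):
            assert winsorized_z(u, bounds2) == pytest.approx(
                winsorized_z(v, bounds), rel=1e-7, abs=1e-9)


class TestWinsorizedCohort:
    def _records(self, n=40, rng=None):
        rng = rng or np.random.default_rng(7)
        return [
            HospitalRecord(
                f"H{i:03d}",
                sir_measures={"SSI": float(rng.lognormal(0, 0.4)),
                              "CDI": float(rng.lognormal(0, 0.4))})
            for i in range(n)
        ]

    def test_full_reporting_standardizes_each_measure(self):
        records = self._records()
        psi90 = [Psi90Result(r.hospital_id, 1.0 + i / 100, 10, False)
                 for i, r in enumerate(records)]
        scores, bounds = score_cohort_winsorized(records, psi90, ["SSI", "CDI"])
        for key in ("SSI", "CDI"):
            z = np.array([winsorized_z(r.sir_measures[key], bounds[key])
                          for r in records])
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_tied_hospitals_get_identical_scores(self):
        records = self._records(20)
        twin_a = HospitalRecord("T1", {"PSI-12": 1.5}, {"SSI": 2.0, "CDI": 0.5})
        twin_b = HospitalRecord("T2", {"PSI-12": 1.5}, {"SSI": 2.0, "CDI": 0.5})
        cohort = records + [twin_a, twin_b]
        psi90 = [Psi90Result(r.hospital_id, 1.0, 1, True) for r in records]
        psi90 += [Psi90Result("T1", 1.5, 1, True), Psi90Result("T2", 1.5, 1, True)]
        scores, _ = score_cohort_winsorized(cohort, psi90, ["SSI", "CDI"])
        by_id = {s.hospital_id: s for s in scores}
        assert by_id["T1"].domain1 == by_id["T2"].domain1
        assert by_id["T1"].domain2 == by_id["T2"].domain2

    def test_nonreporter_gets_no_domain2(self):
        records = self._records(10) + [HospitalRecord("N", {"PSI-12": 1.0})]
        psi90 = [Psi90Result(r.hospital_id, float(i + 1), 1, True)
                 for i, r in enumerate(records)]
        scores, _ = score_cohort_winsorized(records, psi90, ["SSI", "CDI"])
        assert {s.hospital_id: s.domain2 for s in scores}["N"] is None
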