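import math
import random

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faersig.cohort import SMQDefinition
from faersig.signals import (AuditError, ContingencyTable, annotate,
                             audit_printed, build_table, compute_signals,
                             detect_sdrs, invert_ror, ror_ci)


class TestRorCi:
    def test_unit_table(self):
        r = ror_ci(ContingencyTable(1, 1, 1, 1))
        assert r.ror == 1.0
        assert r.ci_low == pytest.approx(math.exp(-3.919928), rel=1e-6)
        assert r.ci_high == pytest.approx(math.exp(3.919928), rel=1e-6)
        assert r.ci_low == pytest.approx(0.0199, abs=1e-4)
        assert round(r.ci_high, 2) == 50.40
        assert not r.corrected

    def test_zero_cell_haldane_corrected(self):
        r = ror_ci(ContingencyTable(3, 7, 0, 90))
        assert r.corrected
        assert r.ror == pytest.approx((3.5 * 90.5) / (7.5 * 0.5))

    def test_point_estimate_within_ci(self):
        r = ror_ci(ContingencyTable(5, 95, 50, 850))
        assert r.ci_low <= r.ror <= r.ci_high

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500), st.integers(1, 500))
    def test_transpose_inverse(self, a, b, c, d):
        r1 = ror_ci(ContingencyTable(a, b, c, d))
        r2 = ror_ci(ContingencyTable(c, d, a, b))
        assert r1.ror == pytest.approx(1.0 / r2.ror)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(1, 200), st.integers(1, 200),
           st.integers(1, 200), st.integers(1, 200), st.integers(2, 9))
    def test_scale_invariant_point_estimate(self, a, b, c, d, k):
        r1 = ror_ci(ContingencyTable(a, b, c, d))
        r2 = ror_ci(ContingencyTable(k * a, k * b, k * c, k * d))
        assert r1.ror == pytest.approx(r2.ror)


class TestBuildTable:
    def test_enumeration(self):
        universe = pd.DataFrame({"primaryid": list("1234"),
                                 "group": ["D+T", "D+T", None, None]})
        reac = pd.DataFrame({"primaryid": ["1", "3"],
                             "pt": ["Atrial fibrillation"] * 2})
        t = build_table("D+T", "Atrial fibrillation", universe, reac)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_report_level_counting(self):
        universe = pd.DataFrame({"primaryid": ["1", "2"],
                                 "group": ["D+T", None]})
        reac = pd.DataFrame({"primaryid": ["1", "1"],
                             "pt": ["Atrial fibrillation"] * 2})
        t = build_table("D+T", "Atrial fibrillation", universe, reac)
        assert t.a == 1

    def test_group_only_pt_flags_correction(self):
        universe = pd.DataFrame({"primaryid": ["1", "2", "3"],
                                 "group": ["D+T", "D+T", None]})
        reac = pd.DataFrame({"primaryid": ["1"], "pt": ["Brugada syndrome"]})
        t = build_table("D+T", "Brugada syndrome", universe, reac)
        assert t.c == 0
        assert ror_ci(t).corrected


class TestInvertRor:
    def test_published_brugada_row(self):
        t = invert_ror(4, 8895, 14_077_067, 25.12)
        assert t.c == 252
        assert t.b == 8891
        r = ror_ci(t)
        assert round(r.ror, 2) == 25.12

    def test_symmetric_table(self):
        t = invert_ror(1, 2, 4, 1.0)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_published_myocarditis_row(self):
        t = invert_ror(10, 2111, 14_077_067, 10.26)
        r = ror_ci(t)
        assert r.ci_low == pytest.approx(5.51, abs=0.01)
        assert r.ci_high == pytest.approx(19.1, abs=0.05)

    def test_precondition_violations(self):
        with pytest.raises(ValueError):
            invert_ror(0, 10, 100, 2.0)
        with pytest.raises(ValueError):
            invert_ror(5, 5, 100, 2.0)

    def test_no_positive_solution(self):
        # ROR so large that no whole comparator report can produce it
        with pytest.raises(AuditError):
            invert_ror(99, 100, 102, 1e9)


class TestDetectSdrs:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["group", "pt", "a", "ci_low"])

    def test_rule(self):
        out = detect_sdrs(self.frame([("D+T", "x", 4, 9.35),
                                      ("D+T", "y", 2, 5.0),
                                      ("D+T", "z", 10, 0.8)]))
        assert list(out["is_sdr"]) == [True, False, False]

    def test_monotone_in_ci_low_and_n(self):
        base = detect_sdrs(self.frame([("g", "p", 3, 1.01)]))["is_sdr"][0]
        assert base
        for a, ci in [(4, 1.01), (3, 2.0), (400, 50.0)]:
            assert detect_sdrs(self.frame([("g", "p", a, ci)]))["is_sdr"][0]
        for a, ci in [(2, 1.01), (3, 1.0), (0, 9.0)]:
            assert not detect_sdrs(self.frame([("g", "p", a, ci)]))["is_sdr"][0]


class TestAnnotate:
    def test_flags(self):
        frame = pd.DataFrame({
            "group": ["D+T", "D+T"],
            "pt": ["Electrocardiogram QT prolonged",
                   "Atrioventricular block complete"]})
        out = annotate(frame,
                       ime_list=["electrocardiogram qt prolonged"],
                       dme_list=[],
                       label_map={"D+T": ["Atrioventricular block complete"]})
        out = out.set_index("pt")
        qt = out.loc["Electrocardiogram QT prolonged"]
        avb = out.loc["Atrioventricular block complete"]
        assert qt["is_ime"] and not qt["expected"]
        assert avb["expected"] and not avb["is_ime"]


class TestOracleEquivalence:
    def test_exhaustive_counting_small_universes(self):
        """ROR from build_table equals a brute-force odds ratio obtained by
        enumerating every report."""
        rng = random.Random(42)
        smq = [SMQDefinition("fixture", frozenset({"Atrial fibrillation"}))]
        for _ in range(20):
            n = rng.randint(20, 100)
            reports = []
            for i in range(n):
                group = "D+T" if rng.random() < 0.3 else None
                has_pt = rng.random() < (0.4 if group else 0.15)
                reports.append((str(i), group, has_pt))
            universe = pd.DataFrame(
                [(p, g) for p, g, _ in reports],
                columns=["primaryid", "group"])
            reac = pd.DataFrame(
                [(p, "Atrial fibrillation") for p, _, h in reports if h],
                columns=["primaryid", "pt"])
            t = build_table("D+T", "Atrial fibrillation", universe, reac)
            # independent oracle: direct enumeration
            a = sum(1 for _, g, h in reports if g == "D+T" and h)
            b = sum(1 for _, g, h in reports if g == "D+T" and not h)
            c = sum(1 for _, g, h in reports if g != "D+T" and h)
            d = sum(1 for _, g, h in reports if g != "D+T" and not h)
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
            if min(a, b, c, d) > 0:
                assert ror_ci(t).ror == pytest.approx((a * d) / (b * c))
            # compute_signals agrees with the single-pair route
            table = compute_signals(universe, reac, smq)
            if a >= 1:
                row = table.query("pt == 'Atrial fibrillation'").iloc[0]
                assert (row.a, row.b, row.c, row.d) == (a, b, c, d)


def test_audit_printed_reconstructs_rows():
    rows = [{"group": "D+T", "pt": "Brugada syndrome", "n": 4,
             "ror": 25.12, "ci_low": 9.35, "ci_high": 67.45},
            {"group": "V+C", "pt": "Myocarditis", "n": 10,
             "ror": 10.26, "ci_low": 5.51, "ci_high": 19.1}]
    out = audit_printed(rows, universe_n=14_077_067,
                        group_totals={"D+T": 8895, "V+C": 2111})
    assert out["passed"].all()
    assert out.iloc[0]["c_solved"] == 252
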