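import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quadcount as qc
from quadcount.datasets import crowd_table, penguin_table

stripe_tables = st.lists(
    st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=6),
    min_size=3,
    max_size=10,
).filter(lambda tbl: sum(map(sum, tbl)) > 0)


def make_sample(counts_by_addr, t, T):
    counts = {qc.QuadratAddress(*a): c for a, c in counts_by_addr.items()}
    return qc.QuadratSample(counts=counts, spec=qc.GridSpec(t=t, T=T))


class TestEstimateN:
    def test_crowd_value(self, crowd_summary):
        sample = make_sample({(1, 1): 50}, t=50, T=250)
        assert qc.estimate_n(sample) == pytest.approx(1250.0)

    def test_penguin_value(self, penguin_summary):
        sample = make_sample({(1, 1): 123}, t=30, T=200)
        assert qc.estimate_n(sample) == pytest.approx(123 * 400 / 9)

    def test_full_tiling_recovers_n(self):
        sample = make_sample({(1, 1): 77}, t=10, T=10)
        assert qc.estimate_n(sample) == 77.0

    def test_zero_iff_empty(self):
        assert qc.estimate_n(make_sample({}, t=5, T=10)) == 0.0


class TestVarIndependence:
    def test_crowd_value(self):
        counts = {(i, 1): c for i, c in enumerate(
            [1, 5, 3, 4, 3, 3, 2, 4, 2, 4, 4, 3, 3, 3, 2, 2, 2]
        )}
        sample = make_sample(counts, t=50, T=250)
        assert qc.var_independence(sample) == pytest.approx(11250.0)

    def test_sample_variance_hand_check(self):
        # s2 of the 17 nonempty counts is (164 - 2500/17)/16 = 18/17
        counts = np.array([1, 5, 3, 4, 3, 3, 2, 4, 2, 4, 4, 3, 3, 3, 2, 2, 2])
        assert counts.sum() == 50
        assert (counts**2).sum() == 164
        s2 = (164 - 2500 / 17) / 16
        assert s2 == pytest.approx(18 / 17)
        assert float(np.var(counts, ddof=1)) == pytest.approx(s2)
        assert 5**4 * 17 * s2 == pytest.approx(11250.0)

    def test_equal_counts_give_zero(self):
        sample = make_sample({(1, 1): 3, (2, 1): 3, (3, 1): 3}, t=5, T=10)
        assert qc.var_independence(sample) == 0.0

    def test_too_few_quadrats(self):
        with pytest.raises(qc.InsufficientSampleError):
            qc.var_independence(make_sample({(1, 1): 4}, t=5, T=10))


class TestSplitStripes:
    def test_crowd_odd_even_totals(self, crowd_summary):
        assert crowd_summary.q_oi.tolist() == [4.0, 3.0, 6.0, 6.0, 6.0, 2.0]
        assert crowd_summary.q_ei.tolist() == [5.0, 5.0, 3.0, 7.0, 3.0, 0.0]
        assert crowd_summary.split_sum_sq == 28.0
        assert crowd_summary.total_q == 50

    def test_penguin_stripe_totals(self, penguin_summary):
        assert penguin_summary.q_i.tolist() == [
            1.0, 4.0, 10.0, 21.0, 15.0, 19.0, 15.0, 16.0, 12.0, 5.0, 4.0, 1.0,
        ]
        assert penguin_summary.total_q == 123

    def test_single_quadrat_stripe(self):
        s = qc.StripeSummary.from_table([[7], [1], [2]], tau=0.5)
        assert s.q_oi.tolist() == [7.0, 1.0, 2.0]
        assert s.q_ei.tolist() == [0.0, 0.0, 0.0]

    def test_interior_zero_stripe_kept_and_edges_trimmed(self):
        sample = make_sample(
            {(1, 1): 0, (2, 1): 4, (3, 2): 0, (4, 1): 1, (5, 3): 0}, t=5, T=25
        )
        summary = qc.split_stripes(sample)
        # stripes run 2..4: leading/trailing empty stripes dropped,
        # the interior all-zero stripe kept with total 0
        assert summary.n == 3
        assert summary.q_i.tolist() == [4.0, 0.0, 1.0]

    def test_positions_preserve_parity(self):
        # a count at position 2 is even even when position 1 is empty
        sample = make_sample({(1, 1): 0, (1, 2): 5}, t=5, T=25)
        summary = qc.split_stripes(sample)
        assert summary.q_oi.tolist() == [0.0]
        assert summary.q_ei.tolist() == [5.0]

    def test_empty_sample_rejected(self):
        with pytest.raises(qc.InsufficientSampleError):
            qc.split_stripes(make_sample({}, t=5, T=10))


class TestSplittingNu:
    def test_crowd_value(self, crowd_summary):
        assert qc.splitting_nu(crowd_summary) == pytest.approx(6.892308, abs=5e-7)

    def test_full_tiling_gives_zero(self):
        s = qc.StripeSummary.from_table([[3, 1], [2, 2], [5, 0]], tau=1.0)
        assert qc.splitting_nu(s) == 0.0

    def test_penguin_brute_force_oracle(self, penguin_summary):
        # independent odd/even re-tally with plain python loops
        ss = 0.0
        for stripe in penguin_table():
            odd = sum(c for k, c in enumerate(stripe) if k % 2 == 0)
            even = sum(c for k, c in enumerate(stripe) if k % 2 == 1)
            ss += (odd - even) ** 2
        tau = 0.15
        expected = (1 - tau) ** 2 / (3 - 2 * tau) * ss
        assert qc.splitting_nu(penguin_summary) == pytest.approx(expected)
        assert ss == 91.0


class TestVarCavalieri:
    def test_crowd_values(self, crowd_summary):
        q = crowd_summary.q_i
        n = len(q)
        c0, c1, c2 = (float(q[: n - k] @ q[k:]) for k in (0, 1, 2))
        assert (c0, c1, c2) == (480.0, 396.0, 292.0)
        total, between, within = qc.var_cavalieri(crowd_summary)
        assert between == pytest.approx(4715.669, abs=5e-3)
        assert within == pytest.approx(4307.692, abs=5e-3)
        assert total == pytest.approx(9023.361, abs=5e-3)

    def test_full_tiling_gives_zero(self):
        s = qc.StripeSummary.from_table([[3, 1], [2, 2], [5, 0]], tau=1.0)
        assert qc.var_cavalieri(s).total == 0.0

    def test_too_few_stripes(self):
        s = qc.StripeSummary.from_table([[3], [2]], tau=0.5)
        with pytest.raises(qc.TooFewStripesError):
            qc.var_cavalieri(s)

    def test_negative_bracket_clamped(self):
        s = qc.StripeSummary.from_table([[4], [5], [4]], tau=0.1)
        with pytest.warns(RuntimeWarning, match="clamp"):
            total, between, within = qc.var_cavalieri(s)
        assert between == 0.0
        assert total == within == pytest.approx(qc.splitting_nu(s) / 0.1**4)

    @settings(max_examples=60, deadline=None)
    @given(tbl=stripe_tables, tau=st.floats(min_value=0.05, max_value=1.0))
    def test_reversal_invariance_and_nonnegativity(self, tbl, tau):
        s = qc.StripeSummary.from_table(tbl, tau=tau)
        if s.n <= 2:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fwd = qc.var_cavalieri(s)
            rev = qc.var_cavalieri(s.reversed_stripes())
        assert fwd.total == pytest.approx(rev.total, rel=1e-12, abs=1e-12)
        assert fwd.total >= 0 and fwd.between >= 0 and fwd.within >= 0


class TestCoefficientOfError:
    def test_crowd_cav(self):
        assert qc.coefficient_of_error(9023.361, 1250) == pytest.approx(7.60, abs=5e-3)

    def test_crowd_ind(self):
        assert qc.coefficient_of_error(11250, 1250) == pytest.approx(8.49, abs=5e-3)

    def test_zero_variance(self):
        assert qc.coefficient_of_error(0.0, 10.0) == 0.0

    def test_zero_estimate_rejected(self):
        with pytest.raises(ValueError):
            qc.coefficient_of_error(1.0, 0.0)


class TestReports:
    def test_crowd_report(self, crowd_summary):
        rep = qc.report_from_stripes(crowd_summary, t=50, T=250)
        assert rep.n_hat == pytest.approx(1250.0)
        assert rep.n_hat_rounded == 1250
        assert rep.var_ind == pytest.approx(11250.0)
        assert rep.var_cav == pytest.approx(9023.361, abs=5e-3)
        assert rep.var_cav == pytest.approx(rep.var_cav_between + rep.var_cav_within)
        assert rep.ce_cav_pct == pytest.approx(7.60, abs=5e-3)
        assert rep.ce_ind_pct == pytest.approx(8.49, abs=5e-3)
        assert rep.q_total == 50
        assert rep.n_nonempty == 17

    def test_penguin_report_rounding(self, penguin_summary):
        rep = qc.report_from_stripes(penguin_summary, t=30, T=200)
        assert rep.n_hat == pytest.approx(5466.667, abs=1e-3)
        assert rep.n_hat_rounded == 5467  # round-half-up
        assert round(rep.ce_cav_pct, 2) == 5.08

    def test_report_from_sample_matches_manual(self, rng):
        pts = rng.uniform([0, 0], [500, 400], (200, 2))
        pat = qc.PointPattern(points=pts, bounds=qc.Rect(0, 0, 500, 400))
        spec = qc.GridSpec(t=25, T=100, offset=(0.4, 0.1))
        sample = qc.count_points(pat, spec)
        rep = qc.report_from_sample(sample)
        summary = qc.split_stripes(sample)
        rep2 = qc.report_from_stripes(summary, t=25, T=100)
        assert rep.n_hat == rep2.n_hat
        assert rep.var_cav == pytest.approx(rep2.var_cav)
        assert rep.var_ind == pytest.approx(rep2.var_ind)

    def test_tau_mismatch_rejected(self, crowd_summary):
        with pytest.raises(ValueError):
            qc.report_from_stripes(crowd_summary, t=30, T=200)

    def test_empty_sample_report(self):
        sample = make_sample({}, t=5, T=10)
        rep = qc.report_from_sample(sample)
        assert rep.n_hat == 0.0
        assert any("empty" in w for w in rep.warnings)
        assert rep.to_dict()["var_ind"] is None

    def test_json_serialization(self, crowd_summary):
        import json

        rep = qc.report_from_stripes(crowd_summary, t=50, T=250)
        blob = json.loads(rep.to_json())
        assert blob["n_hat_rounded"] == 1250
        assert blob["spec"]["t"] == 50
        assert "quadrats" in rep.to_text()


class TestStripeTableIO:
    def test_roundtrip_ragged(self, tmp_path):
        stripes = penguin_table()
        depth = max(len(s) for s in stripes)
        rows = []
        for p in range(depth):
            rows.append(
                ",".join(str(s[p]) if p < len(s) else "" for s in stripes)
            )
        header = ",".join(f"stripe_{i+1}" for i in range(len(stripes)))
        path = tmp_path / "sheet.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        back = qc.read_stripe_table(path)
        assert back == stripes

    def test_crowd_sheet(self, tmp_path):
        stripes = crowd_table()
        header = ",".join(f"s{i}" for i in range(6))
        rows = [",".join(str(s[p]) for s in stripes) for p in range(7)]
        path = tmp_path / "crowd.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        summary = qc.StripeSummary.from_table(qc.read_stripe_table(path), tau=0.2)
        assert summary.total_q == 50
        assert summary.split_sum_sq == 28.0
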