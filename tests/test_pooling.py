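"""Normalisation and the four positive-pool scoring methods."""

import numpy as np
import pandas as pd
import pytest

from poolanchor.pooling import (
    PoolLayout,
    ScoringError,
    SignalMatrix,
    automated_scoring,
    boxplot_scoring,
    complete_manual,
    complete_semi_automated,
    normalize,
)

from conftest import GEOMETRY, normalised_matrix


class TestNormalize:
    def test_constant_matrix_becomes_ones(self, tiny_layout):
        pools = tiny_layout.pool_ids()
        sm = SignalMatrix(
            pd.DataFrame(5.0, index=["p1", "p2", "p3"], columns=pools), state="raw"
        )
        out = normalize(sm, tiny_layout)
        assert out.state == "probe_normalised"
        assert (out.data.to_numpy() == 1.0).all()

    def test_pool_step_hand_example(self, tiny_layout):
        # pool column [2, 4, 6] with all other columns [4, 4, 4]:
        # step 1 divides by the pool median 4 -> [0.5, 1.0, 1.5]; the row
        # medians stay 1 so step 2 leaves the column unchanged
        pools = tiny_layout.pool_ids()
        sm = SignalMatrix(
            pd.DataFrame(
                {p: ([2.0, 4.0, 6.0] if p == pools[0] else [4.0, 4.0, 4.0])
                 for p in pools},
                index=["a", "b", "c"],
            ),
            state="raw",
        )
        out = normalize(sm, tiny_layout)
        np.testing.assert_allclose(out.data[pools[0]].to_numpy(), [0.5, 1.0, 1.5])

    def test_probe_step_hand_example(self, tiny_layout):
        # a probe whose post-step-1 values split into 0.5s and 2.0s
        # (row median 1.25) ends as 0.4s and 1.6s
        pools = tiny_layout.pool_ids()
        half = len(pools) // 2
        target = [0.5] * half + [2.0] * (len(pools) - half)
        frame = pd.DataFrame(
            [target, [1.0] * len(pools), [1.0] * len(pools)],
            index=["t", "f1", "f2"],
            columns=pools,
        )
        out = normalize(SignalMatrix(frame, state="raw"), tiny_layout)
        np.testing.assert_allclose(
            sorted(set(out.data.loc["t"].round(10))), [0.4, 1.6]
        )

    def test_row_medians_are_exactly_one(self, tiny_layout, rng):
        pools = tiny_layout.pool_ids()
        sm = SignalMatrix(
            pd.DataFrame(
                rng.lognormal(0, 0.5, size=(20, len(pools))),
                index=[f"p{i}" for i in range(20)],
                columns=pools,
            ),
            state="raw",
        )
        out = normalize(sm, tiny_layout)
        np.testing.assert_allclose(out.data.median(axis=1).to_numpy(), 1.0)

    def test_zero_pool_median_names_pool(self, tiny_layout):
        pools = tiny_layout.pool_ids()
        frame = pd.DataFrame(1.0, index=["p1", "p2", "p3"], columns=pools)
        frame[pools[5]] = 0.0
        sm = SignalMatrix(frame, state="raw")
        with pytest.raises(ScoringError, match=pools[5]):
            normalize(sm, tiny_layout)

    def test_rejects_already_normalised_input(self, tiny_layout):
        sm = normalised_matrix(tiny_layout, {"p1": {}})
        with pytest.raises(ScoringError, match="raw"):
            normalize(sm, tiny_layout)


class TestAutomatedScoring:
    def test_flat_axis_yields_no_positives(self, tiny_layout):
        sm = normalised_matrix(tiny_layout, {"p1": {}})
        res = automated_scoring(sm, tiny_layout)
        assert res.calls["p1"].n_positive == 0

    def test_single_spike_hand_arithmetic(self, tiny_layout):
        # plate axis: nineteen 1.0 and one 10.0 -> mean 1.45, sample SD
        # 2.0125, threshold 1.45 + 2.8 x 2.0125 = 7.085 -> the spike is the
        # only pass-1 positive
        sm = normalised_matrix(tiny_layout, {"p1": {"P01": 10.0}})
        res = automated_scoring(sm, tiny_layout)
        call = res.calls["p1"]
        assert call.positives["plate"] == ["P01"]
        assert call.thresholds["plate"][0] == pytest.approx(7.0849, abs=1e-3)
        vals = np.array([10.0] + [1.0] * 19)
        assert call.thresholds["plate"][0] == pytest.approx(
            vals.mean() + 2.8 * vals.std(ddof=1)
        )

    def test_moderate_spike_caught_in_second_pass(self, tiny_layout):
        # plate axis with spikes 30 and 8 among eighteen 1.0:
        # pass 1: mean 2.8, SD 6.591, threshold 21.25 -> only the 30 caught;
        # pass 2 (30 deleted): mean 1.368, SD 1.606, threshold 5.865 -> 8 caught
        sm = normalised_matrix(tiny_layout, {"p1": {"P01": 30.0, "P02": 8.0}})
        res = automated_scoring(sm, tiny_layout)
        call = res.calls["p1"]
        assert sorted(call.positives["plate"]) == ["P01", "P02"]
        vals1 = np.array([30.0, 8.0] + [1.0] * 18)
        assert call.thresholds["plate"][0] == pytest.approx(
            vals1.mean() + 2.8 * vals1.std(ddof=1)
        )
        assert call.thresholds["plate"][0] > 8.0
        vals2 = np.array([8.0] + [1.0] * 18)
        assert call.thresholds["plate"][1] == pytest.approx(
            vals2.mean() + 2.8 * vals2.std(ddof=1)
        )
        assert call.thresholds["plate"][1] < 8.0

    def test_tie_at_threshold_is_not_positive(self, tiny_layout):
        sm = normalised_matrix(tiny_layout, {"p1": {}})
        res = automated_scoring(sm, tiny_layout)
        # SD = 0 so threshold = mean = value for every pool: none positive
        assert res.calls["p1"].n_positive == 0

    def test_scale_invariance(self, tiny_layout, rng):
        pools = tiny_layout.pool_ids()
        base = rng.lognormal(0, 0.5, size=len(pools))
        base[3] = 40.0
        frame = pd.DataFrame([base, base * 17.0], index=["p1", "p2"], columns=pools)
        sm = SignalMatrix(frame, state="probe_normalised")
        res = automated_scoring(sm, tiny_layout)
        assert res.calls["p1"].positives == res.calls["p2"].positives

    def test_row_independence_under_permutation(self, tiny_layout, rng):
        pools = tiny_layout.pool_ids()
        frame = pd.DataFrame(
            rng.lognormal(0, 0.5, size=(6, len(pools))),
            index=[f"p{i}" for i in range(6)],
            columns=pools,
        )
        res_a = automated_scoring(SignalMatrix(frame, state="probe_normalised"),
                                  tiny_layout)
        res_b = automated_scoring(
            SignalMatrix(frame.iloc[::-1], state="probe_normalised"), tiny_layout
        )
        for probe in frame.index:
            assert res_a.calls[probe].positives == res_b.calls[probe].positives

    def test_pass_monotonicity(self, tiny_layout, rng):
        pools = tiny_layout.pool_ids()
        frame = pd.DataFrame(
            rng.lognormal(0, 1.0, size=(10, len(pools))),
            index=[f"p{i}" for i in range(10)],
            columns=pools,
        )
        sm = SignalMatrix(frame, state="probe_normalised")
        sets = []
        for n_passes in (1, 2, 3):
            res = automated_scoring(sm, tiny_layout, n_passes=n_passes)
            sets.append(
                {
                    (probe, axis, pid)
                    for probe, call in res.calls.items()
                    for axis, pids in call.positives.items()
                    for pid in pids
                }
            )
        assert sets[0] <= sets[1] <= sets[2]

    def test_axis_with_too_few_pools_rejected(self):
        from poolanchor.core_io import BACRecord, PhysicalMap

        pm = PhysicalMap([BACRecord("Y1", 1, "A", 1, "c", 0, 100)])
        small = PoolLayout.from_physical_map(pm, 2, 16, 24)
        sm = normalised_matrix(small, {"p1": {}})
        with pytest.raises(ScoringError, match="plate"):
            automated_scoring(sm, small)


class TestBoxplotScoring:
    def test_single_outlier_among_equal_values(self):
        # eight values: seven 1.0 and one 9.0 -> Q1 = Q3 = 1, IQR = 0,
        # fence = 1 -> the 9.0 is positive
        from poolanchor.core_io import BACRecord, PhysicalMap

        pm = PhysicalMap([BACRecord("Y1", 1, "A", 1, "c", 0, 100)])
        small = PoolLayout.from_physical_map(pm, 8, 16, 24)
        sm = normalised_matrix(small, {"p1": {"P01": 9.0}})
        res = boxplot_scoring(sm, small)
        assert res.calls["p1"].positives["plate"] == ["P01"]

    def test_monotone_ramp_without_outliers(self, tiny_layout):
        # plate axis 1..20: Q3 + 1.5 x IQR = 15.25 + 1.5 x 9.5 = 29.5 > 20
        plate_pools = tiny_layout.pool_ids("plate")
        sm = normalised_matrix(
            tiny_layout,
            {"p1": {pid: float(i + 1) for i, pid in enumerate(plate_pools)}},
        )
        res = boxplot_scoring(sm, tiny_layout)
        assert res.calls["p1"].positives["plate"] == []
        assert res.calls["p1"].thresholds["plate"][0] == pytest.approx(29.5)

    def test_all_equal_yields_none(self, tiny_layout):
        sm = normalised_matrix(tiny_layout, {"p1": {}})
        res = boxplot_scoring(sm, tiny_layout)
        assert res.calls["p1"].n_positive == 0


class TestCompletionMethods:
    def _result_with(self, layout, probe, positives):
        from poolanchor.pooling import ProbeCall, ScoringResult

        call = ProbeCall(probe_id=probe)
        for axis, pids in positives.items():
            call.positives[axis] = pids
        return ScoringResult(method="automated", calls={probe: call})

    def test_semi_automated_unique_overlapping_pair(self, tiny_map, tiny_layout):
        # plates {P10, P11}, rows {H, I}, column {5}: only (P10,H,5) and
        # (P11,I,5) exist and their BACs overlap -> both wells assigned
        res = self._result_with(
            tiny_layout,
            "pr",
            {"plate": ["P10", "P11"], "row": ["RH", "RI"], "column": ["C05"]},
        )
        out = complete_semi_automated(res, tiny_layout, tiny_map)
        assert out.assigned["pr"] == [(10, "H", 5), (11, "I", 5)]

    def test_semi_automated_nonoverlapping_unresolved(self, tiny_map, tiny_layout):
        # (P12,J,6) and (P13,K,7) exist but are on disjoint contigs
        res = self._result_with(
            tiny_layout,
            "pr",
            {"plate": ["P12", "P13"], "row": ["RJ", "RK"], "column": ["C06", "C07"]},
        )
        # 2/2/2 is six positives, not the semi-automated 2/2/1 pattern
        out = complete_semi_automated(res, tiny_layout, tiny_map)
        assert "pr" not in out.assigned
        res2 = self._result_with(
            tiny_layout,
            "pr",
            {"plate": ["P04", "P06"], "row": ["RD", "RF"], "column": ["C04"]},
        )
        # (P04,D,4) and (P06,F,4)? the latter does not exist; and the
        # existing alternatives do not overlap -> unresolved
        out2 = complete_semi_automated(res2, tiny_layout, tiny_map)
        assert "pr" not in out2.assigned

    def test_manual_unique_candidate_well(self, tiny_map, tiny_layout):
        # plate P03 + row F positive; scanning columns, only column 11
        # holds a BAC at (P03, F, *)
        res = self._result_with(
            tiny_layout, "pr", {"plate": ["P03"], "row": ["RF"], "column": []}
        )
        out = complete_manual(res, tiny_layout, tiny_map)
        assert out.assigned["pr"] == [(3, "F", 11)]

    def test_manual_missing_candidate_unresolved(self, tiny_map, tiny_layout):
        # row F + column 6: scanning plates, only (P06,F,6) holds a BAC
        res = self._result_with(
            tiny_layout, "pr", {"plate": [], "row": ["RF"], "column": ["C06"]}
        )
        out = complete_manual(res, tiny_layout, tiny_map)
        assert out.assigned["pr"] == [(6, "F", 6)]
        # no BAC lives in plate 9 at all -> no candidate well
        res2 = self._result_with(
            tiny_layout, "pr", {"plate": ["P09"], "row": ["RA"], "column": []}
        )
        out2 = complete_manual(res2, tiny_layout, tiny_map)
        assert "pr" not in out2.assigned

    def test_manual_two_candidates_unresolved(self):
        from poolanchor.core_io import BACRecord, PhysicalMap

        pm = PhysicalMap(
            [
                BACRecord("Y1", 1, "A", 1, "c1", 0, 100_000),
                BACRecord("Y2", 2, "A", 1, "c2", 200_000, 300_000),
            ]
        )
        layout = PoolLayout.from_physical_map(pm, 20, 16, 24)
        res = self._result_with(
            layout, "pr", {"plate": [], "row": ["RA"], "column": ["C01"]}
        )
        out = complete_manual(res, layout, pm)
        assert "pr" not in out.assigned
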