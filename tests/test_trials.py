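"""Trial segmentation, locomotion classification, metrics, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oispipe.errors import InputError
from oispipe.trials import (
    LocomotionTrace,
    Trial,
    build_trial_table,
    classify_locomotion,
    filter_rest_and_onset_trials,
    rank_by_locomotion,
    segment_trials,
    trial_metrics,
)

FR = 32.0


def _trace(duration_s, triggers, loco_values=None):
    n = int(duration_s * FR)
    times = np.arange(n) / FR
    return LocomotionTrace(
        values=np.zeros(n) if loco_values is None else loco_values,
        times_s=times,
        trigger_times_s=np.asarray(triggers, float),
    )


def _hemo(duration_s, value=0.0):
    n = int(duration_s * FR)
    x = np.full(n, value)
    return {"hbt": x, "hbo": x.copy(), "hbr": x.copy()}


def _make_trial(stim_type="2s", loco=None, hbt=None):
    pre, post = (5.0, 20.0) if stim_type == "2s" else (10.0, 60.0)
    stim = 2.0 if stim_type == "2s" else 16.0
    n = int((pre + post) * FR)
    t = np.arange(n) / FR
    z = np.zeros(n)
    return Trial(
        times_s=t,
        hbt=z if hbt is None else hbt,
        hbo=z.copy(),
        hbr=z.copy(),
        loco=z.copy() if loco is None else loco,
        onset_s=pre,
        offset_s=pre + stim,
        stim_type=stim_type,
    )


class TestSegmentTrials:
    def test_window_arithmetic_2s(self):
        duration = 200.0
        loco = _trace(duration, [100.0])
        trials = segment_trials(_hemo(duration), loco.times_s, loco, "2s")
        (tr,) = trials
        assert len(tr.hbt) == 800  # (100+20)*32 - (100-5)*32
        assert tr.onset_s == 5.0 and tr.offset_s == 7.0

    def test_thirty_interior_triggers_yield_thirty_trials(self):
        triggers = 10.0 + np.arange(30) * 26.0
        duration = triggers[-1] + 25.0
        loco = _trace(duration, triggers)
        trials = segment_trials(_hemo(duration), loco.times_s, loco, "2s")
        assert len(trials) == 30
        assert [t.trial_id for t in trials] == list(range(1, 31))

    def test_boundary_trigger_dropped_with_warning(self, caplog):
        triggers = [2.0, 100.0]
        loco = _trace(150.0, triggers)
        with caplog.at_level("WARNING"):
            trials = segment_trials(_hemo(150.0), loco.times_s, loco, "2s")
        assert len(trials) == 1
        assert any("dropped" in r.message for r in caplog.records)

    def test_rezeroing_subtracts_pre_onset_mean(self):
        duration = 100.0
        hemo = _hemo(duration, value=3.5)  # constant trace
        loco = _trace(duration, [50.0])
        (tr,) = segment_trials(hemo, loco.times_s, loco, "2s")
        assert np.allclose(tr.hbt, 0.0)

    def test_no_triggers_raises(self):
        loco = _trace(100.0, [])
        with pytest.raises(InputError):
            segment_trials(_hemo(100.0), loco.times_s, loco, "2s")


class TestClassifyLocomotion:
    def _loco_from_bits(self, bits):
        """8 bins: 4 x 1 s in the pre window [1, 5), 4 x 1.5 s in [5, 11)."""
        n = int(25 * FR)
        loco = np.zeros(n)
        for i, b in enumerate(bits[:4]):
            if b:
                lo, hi = int((1 + i) * FR), int((2 + i) * FR)
                loco[lo:hi] = 3
        for i, b in enumerate(bits[4:]):
            if b:
                lo, hi = int((5 + 1.5 * i) * FR), int((5 + 1.5 * (i + 1)) * FR)
                loco[lo:hi] = 3
        return loco

    def test_all_zero_is_category_1(self):
        assert classify_locomotion(_make_trial()) == 1

    @pytest.mark.parametrize(
        "pre,stim,expected", [(True, False, 2), (False, True, 3), (True, True, 4)]
    )
    def test_single_window_categories(self, pre, stim, expected):
        bits = [pre, 0, 0, 0, stim, 0, 0, 0]
        trial = _make_trial(loco=self._loco_from_bits(bits))
        assert classify_locomotion(trial) == expected

    def test_exhaustive_truth_table(self):
        """All 2^8 binary window patterns agree with the two-window oracle."""
        for bits in itertools.product([0, 1], repeat=8):
            trial = _make_trial(loco=self._loco_from_bits(bits))
            got = classify_locomotion(trial)
            pre, stim = any(bits[:4]), any(bits[4:])
            expected = {(0, 0): 1, (1, 0): 2, (0, 1): 3, (1, 1): 4}[(pre, stim)]
            assert got == expected, bits

    def test_debounce_ignores_jitter_blips(self):
        loco = np.zeros(int(25 * FR))
        loco[int(6 * FR)] = 5  # single-sample blip during stimulation
        trial = _make_trial(loco=loco)
        assert classify_locomotion(trial, debounce_s=0.125) == 1
        assert classify_locomotion(trial, debounce_s=0.0) == 3

    def test_short_trial_raises(self):
        tr = _make_trial()
        tr = Trial(
            times_s=tr.times_s[:100], hbt=tr.hbt[:100], hbo=tr.hbo[:100],
            hbr=tr.hbr[:100], loco=tr.loco[:100], onset_s=5.0, offset_s=7.0,
            stim_type="2s",
        )
        with pytest.raises(InputError):
            classify_locomotion(tr)

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        cats = []
        for _ in range(50):
            loco = (rng.random(int(25 * FR)) < 0.02).astype(float) * 4
            cats.append(classify_locomotion(_make_trial(loco=loco)))
        assert set(cats) <= {1, 2, 3, 4}
        assert len(cats) == 50


class TestTrialMetrics:
    def test_boxcar_closed_form(self):
        t = np.arange(int(25 * FR)) / FR
        hbt = np.where((t >= 5.0) & (t <= 10.0), 2.0, 0.0)
        m = trial_metrics(_make_trial(hbt=hbt))
        assert m["hbt_auc"] == pytest.approx(10.0, abs=1e-12)
        assert m["hbt_peak"] == pytest.approx(2.0)

    def test_zero_trace(self):
        m = trial_metrics(_make_trial())
        assert m["hbt_auc"] == 0.0 and m["hbt_peak"] == 0.0

    def test_matches_fine_grid_riemann_oracle(self):
        rng = np.random.default_rng(9)
        n = int(25 * FR)
        t = np.arange(n) / FR
        hbt = np.cumsum(rng.normal(0, 0.1, n))
        m = trial_metrics(_make_trial(hbt=hbt))
        # midpoint Riemann sum on the piecewise-linear interpolant, 1000x finer
        fine = np.linspace(5.0, 10.0, 5 * 1000 * 32 + 1)
        mid = 0.5 * (fine[:-1] + fine[1:])
        oracle = float(np.sum(np.interp(mid, t, hbt)) * (fine[1] - fine[0]))
        assert m["hbt_auc"] == pytest.approx(oracle, rel=1e-6)

    def test_auc_linearity(self):
        rng = np.random.default_rng(2)
        n = int(25 * FR)
        x, y = rng.normal(size=n), rng.normal(size=n)
        ax = trial_metrics(_make_trial(hbt=x))["hbt_auc"]
        ay = trial_metrics(_make_trial(hbt=y))["hbt_auc"]
        axy = trial_metrics(_make_trial(hbt=2 * x + 3 * y))["hbt_auc"]
        assert axy == pytest.approx(2 * ax + 3 * ay, rel=1e-9)

    def test_16s_metric_window(self):
        pre = 10.0
        n = int(70 * FR)
        t = np.arange(n) / FR
        hbt = np.where((t >= pre) & (t <= pre + 20.0), 1.0, 0.0)
        m = trial_metrics(_make_trial(stim_type="16s", hbt=hbt))
        assert m["hbt_auc"] == pytest.approx(20.0, abs=1e-9)


def _table(loco_aucs, animal="a1", session="s1"):
    n = len(loco_aucs)
    return pd.DataFrame(
        {
            "animal_id": [animal] * n,
            "group": ["WT"] * n,
            "session_id": [session] * n,
            "trial_id": np.arange(1, n + 1),
            "loco_category": [1] * n,
            "loco_auc": loco_aucs,
        }
    )


class TestRankByLocomotion:
    def test_thirty_trials_give_six_and_six(self):
        ranked = rank_by_locomotion(_table(np.random.default_rng(1).random(30)))
        assert ranked["bottom20"].sum() == 6
        assert ranked["top20"].sum() == 6
        assert not (ranked["bottom20"] & ranked["top20"]).any()

    def test_tie_break_by_trial_id(self):
        ranked = rank_by_locomotion(_table(np.ones(30)))
        assert list(ranked.loc[ranked["bottom20"], "trial_id"]) == [1, 2, 3, 4, 5, 6]

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(4)
        aucs = rng.random(30)
        ranked = rank_by_locomotion(_table(aucs))
        order = np.argsort(aucs, kind="stable")
        bottom = set(order[:6] + 1)
        top = set(order[-6:] + 1)
        assert set(ranked.loc[ranked["bottom20"], "trial_id"]) == bottom
        assert set(ranked.loc[ranked["top20"], "trial_id"]) == top

    def test_small_stratum_warns_and_leaves_empty(self):
        with pytest.warns(UserWarning):
            ranked = rank_by_locomotion(_table([1.0, 2.0, 3.0]))
        assert not ranked["bottom20"].any() and not ranked["top20"].any()

    def test_stratified_by_animal_session(self):
        t1 = _table(np.arange(30.0), animal="a1")
        t2 = _table(np.arange(30.0)[::-1], animal="a2")
        ranked = rank_by_locomotion(pd.concat([t1, t2], ignore_index=True))
        per_animal = ranked.groupby("animal_id")[["bottom20", "top20"]].sum()
        assert (per_animal == 6).all().all()


class TestFilterRestAndOnset:
    def test_category_selection(self):
        table = _table([0.0] * 5)
        table["loco_category"] = [1, 2, 3, 4, 1]
        rest, onset = filter_rest_and_onset_trials(table)
        assert list(rest["trial_id"]) == [1, 5]
        assert list(onset["trial_id"]) == [3]

    def test_all_category_2_warns_empty(self):
        table = _table([0.0] * 4)
        table["loco_category"] = 2
        with pytest.warns(UserWarning):
            rest, onset = filter_rest_and_onset_trials(table)
        assert rest.empty and onset.empty

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(8)
        table = _table([0.0] * 40)
        table["loco_category"] = rng.integers(1, 5, 40)
        rest, onset = filter_rest_and_onset_trials(table)
        assert set(rest.index) == set(table.index[table["loco_category"] == 1])
        assert set(onset.index) == set(table.index[table["loco_category"] == 3])
        assert len(rest) + len(onset) + (
            (table["loco_category"] == 2) | (table["loco_category"] == 4)
        ).sum() == len(table)


def test_build_trial_table_counts_partition():
    rng = np.random.default_rng(3)
    triggers = 10.0 + np.arange(10) * 26.0
    duration = triggers[-1] + 25.0
    n = int(duration * FR)
    loco = LocomotionTrace(
        values=(rng.random(n) < 0.01).astype(float) * 3,
        times_s=np.arange(n) / FR,
        trigger_times_s=triggers,
    )
    hemo = {k: rng.normal(0, 0.1, n) for k in ("hbt", "hbo", "hbr")}
    trials = segment_trials(hemo, loco.times_s, loco, "2s")
    table = build_trial_table(trials)
    assert len(table) == 10
    assert table["loco_category"].isin([1, 2, 3, 4]).all()
    assert table["loco_category"].value_counts().sum() == 10
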