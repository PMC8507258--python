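import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from mirmark.datatypes import ClinicalTable
from mirmark.errors import ValidationError
from mirmark.survival import (cox_hr, enumerate_panels, logrank_test, median_split,
                              panel_count, panel_groups, screen_panels)


def logrank_oracle(ta, ea, tb, eb):
    """Hand O/E/V log-rank table over the distinct event times."""
    ta, ea, tb, eb = (np.asarray(x, float) for x in (ta, ea, tb, eb))
    times = np.unique(np.r_[ta[ea == 1], tb[eb == 1]])
    O = E = V = 0.0
    for t in times:
        n1, n2 = (ta >= t).sum(), (tb >= t).sum()
        n = n1 + n2
        d1 = ((ta == t) & (ea == 1)).sum()
        d = d1 + ((tb == t) & (eb == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, float(chi2_dist.sf(chi2, 1))


class TestMedianSplit:
    def test_even_split(self):
        g = median_split(pd.Series([1.0, 2, 3, 4], index=list("abcd"), name="m"))
        assert sorted(g.higher_ids) == ["c", "d"]
        assert sorted(g.lower_ids) == ["a", "b"]
        assert g.medians["m"] == 2.5

    def test_tie_goes_to_lower(self):
        g = median_split(pd.Series([1.0, 2, 3], index=list("abc")))
        assert g.higher_ids == ["c"]
        assert sorted(g.lower_ids) == ["a", "b"]

    @pytest.mark.parametrize("seed", range(3))
    def test_partition(self, seed):
        rng = np.random.default_rng(seed)
        v = pd.Series(rng.normal(size=17), index=[f"p{i}" for i in range(17)])
        g = median_split(v)
        assert g.n_higher + g.n_lower == 17
        assert not set(g.higher_ids) & set(g.lower_ids)

    def test_identical_values_error(self):
        with pytest.raises(ValidationError):
            median_split(pd.Series([2.0, 2.0, 2.0]))

    def test_rank_invariance(self):
        rng = np.random.default_rng(4)
        v = pd.Series(rng.normal(size=20), index=[f"p{i}" for i in range(20)])
        base = median_split(v)
        trans = median_split(np.exp(v))
        assert set(base.higher_ids) == set(trans.higher_ids)


class TestPanelGroups:
    def _frame(self, rng, n_mirnas=4, n_patients=40):
        return pd.DataFrame(
            rng.normal(8, 1, size=(n_mirnas, n_patients)),
            index=[f"m{i}" for i in range(n_mirnas)],
            columns=[f"p{i}" for i in range(n_patients)],
        )

    def test_concordance_rule(self):
        frame = pd.DataFrame(
            [[1.0, 1, 5, 5], [1.0, 5, 1, 5]],
            index=["mA", "mB"], columns=list("wxyz"))
        g = panel_groups(frame, ["mA", "mB"])
        assert g.higher_ids == ["z"]       # above both medians
        assert g.lower_ids == ["w"]        # at/below both
        assert sorted(g.excluded_ids) == ["x", "y"]  # above exactly one

    def test_nested_panel_monotone_shrinkage(self):
        rng = np.random.default_rng(0)
        frame = self._frame(rng)
        small = panel_groups(frame, ["m0", "m1"])
        big = panel_groups(frame, ["m0", "m1", "m2"])
        assert set(big.higher_ids) <= set(small.higher_ids)
        assert set(big.lower_ids) <= set(small.lower_ids)

    def test_partition_of_analyzed_patients(self):
        rng = np.random.default_rng(1)
        frame = self._frame(rng)
        frame.iloc[0, :3] = np.nan
        g = panel_groups(frame, ["m0", "m1", "m2"])
        analyzed = set(g.higher_ids) | set(g.lower_ids) | set(g.excluded_ids)
        assert analyzed == set(frame.columns[3:])  # NaN patients excluded

    def test_singleton_has_no_exclusions(self):
        rng = np.random.default_rng(2)
        g = panel_groups(self._frame(rng), ["m0"])
        assert g.excluded_ids == []

    def test_unknown_mirna_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValidationError):
            panel_groups(self._frame(rng), ["m0", "nope"])

    def test_meanscore_keeps_everyone(self):
        rng = np.random.default_rng(5)
        frame = self._frame(rng)
        g = panel_groups(frame, ["m0", "m1", "m2"], grouping="meanscore")
        assert g.excluded_ids == []
        assert g.n_higher + g.n_lower == frame.shape[1]

    def test_five_panel_groups_shrink_geometrically(self):
        # independent expression: each side of a 5-panel expects n/32 patients
        rng = np.random.default_rng(6)
        frame = self._frame(rng, n_mirnas=5, n_patients=100)
        g = panel_groups(frame, list(frame.index))
        assert max(g.n_higher, g.n_lower) < 30


class TestLogrank:
    def test_identical_groups(self):
        t, e = [1.0, 2, 3, 4], [1, 1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "ta, ea, tb, eb",
        [
            ([1, 2], [1, 1], [3, 4], [1, 1]),
            ([1, 2, 5, 6], [1, 1, 0, 1], [3, 4, 7], [1, 1, 1]),
            ([1.5, 2.5, 3.5, 9], [1, 0, 1, 0], [1.5, 4, 8, 8], [1, 1, 1, 0]),
        ],
    )
    def test_matches_hand_table(self, ta, ea, tb, eb):
        expected = logrank_oracle(ta, ea, tb, eb)
        got = logrank_test(ta, ea, tb, eb)
        assert got[0] == pytest.approx(expected[0], abs=1e-10)
        assert got[1] == pytest.approx(expected[1], abs=1e-10)

    def test_replication_sharpens_the_test(self):
        ta, ea = [1.0, 2, 3, 6], [1, 1, 1, 0]
        tb, eb = [4.0, 5, 7, 8], [1, 1, 1, 1]
        chi1, p1 = logrank_test(ta, ea, tb, eb)
        chi2_, p2 = logrank_test(ta * 2, ea * 2, tb * 2, eb * 2)
        assert chi2_ > chi1 and p2 < p1


class TestCoxHr:
    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(0)
        g = np.r_[np.ones(40), np.zeros(40)]
        t = np.r_[rng.exponential(0.5, 40), rng.exponential(1.5, 40)]
        e = np.ones(80)
        a = cox_hr(g, t, e)
        b = cox_hr(1 - g, t, e)
        assert a.converged and b.converged
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-6)

    def test_null_hr_near_one_on_large_sample(self):
        rng = np.random.default_rng(1)
        n = 400
        g = np.r_[np.ones(n), np.zeros(n)]
        t = rng.exponential(1.0, 2 * n)
        res = cox_hr(g, t, np.ones(2 * n))
        assert 0.8 < res.hr < 1.25

    def test_complete_separation_flagged_not_crash(self):
        g = np.r_[np.ones(5), np.zeros(5)]
        t = np.r_[np.arange(1.0, 6), np.arange(100.0, 105)]
        res = cox_hr(g, t, np.ones(10))
        assert not res.converged

    def test_missing_level_errors(self):
        with pytest.raises(ValidationError):
            cox_hr(np.ones(4), [1, 2, 3, 4], [1, 1, 1, 1])


class TestEnumeratePanels:
    def test_counts(self):
        assert panel_count(25, 2, 5) == 68380
        assert panel_count(8, 2, 3) == 84
        assert panel_count(3, 2, 3) == 4

    def test_small_enumeration(self):
        panels = list(enumerate_panels(["A", "B", "C"], 2, 3))
        assert panels == [("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C")]

    def test_deterministic_order(self):
        names = [f"m{i}" for i in range(8)]
        assert list(enumerate_panels(names, 2, 3)) == list(enumerate_panels(names, 2, 3))
        assert sum(1 for _ in enumerate_panels(names, 2, 3)) == panel_count(8, 2, 3)

    def test_bad_range_errors(self):
        with pytest.raises(ValidationError):
            list(enumerate_panels(["a", "b"], 3, 2))


def _screen_inputs(rng, n_patients=120, n_mirnas=5, log_hr=0.0, panel=("m0", "m1")):
    patients = [f"p{i}" for i in range(n_patients)]
    frame = pd.DataFrame(rng.normal(8, 1, size=(n_mirnas, n_patients)),
                         index=[f"m{i}" for i in range(n_mirnas)], columns=patients)
    score = frame.loc[list(panel)].mean(axis=0)
    score = (score - score.mean()) / score.std()
    haz = 0.1 * np.exp(log_hr * score.to_numpy())
    times = rng.exponential(1.0 / haz)
    clin = ClinicalTable(pd.DataFrame(
        {"stage": "II", "os_time": times, "os_event": 1,
         "rfs_time": times, "rfs_event": 1},
        index=pd.Index(patients, name="patient_id")))
    return frame, clin


class TestScreenPanels:
    def test_infeasible_min_group_rejects_everything(self):
        rng = np.random.default_rng(0)
        frame, clin = _screen_inputs(rng, n_patients=80)
        res = screen_panels(frame, clin, stage=None, k_min=2, k_max=2,
                            min_group=81, compute_hr=False)
        assert res.skipped  # cannot even have 2*min_group patients

        res = screen_panels(frame, clin, stage=None, k_min=2, k_max=2,
                            min_group=40, compute_hr=False)
        assert not res.skipped
        assert res.counts["tested"].sum() == 0
        assert res.counts["rejected"].sum() == res.counts["enumerated"].sum()

    def test_detects_planted_panel_and_sorts_by_p(self):
        rng = np.random.default_rng(1)
        frame, clin = _screen_inputs(rng, n_patients=200, log_hr=1.5)
        res = screen_panels(frame, clin, stage="II", k_min=2, k_max=2,
                            min_group=20, compute_hr=True)
        assert (res.results["logrank_p"].diff().dropna() >= 0).all()
        top = res.results.iloc[0]
        assert top["panel"] == ("m0", "m1")
        assert top["passes"] and top["logrank_p"] < 0.01
        assert top["hr"] > 1.5 and top["cox_converged"]
        # passes column is exactly the alpha rule
        assert (res.results["passes"] == (res.results["logrank_p"] < 0.05)).all()

    def test_missing_endpoint_errors(self):
        rng = np.random.default_rng(2)
        frame, clin = _screen_inputs(rng)
        clin.data.drop(columns=["rfs_time", "rfs_event"], inplace=True)
        with pytest.raises(ValidationError):
            screen_panels(frame, clin, endpoint="RFS", min_group=10)

    def test_stage_without_patients_is_skipped_with_reason(self):
        rng = np.random.default_rng(3)
        frame, clin = _screen_inputs(rng)
        res = screen_panels(frame, clin, stage="IV", min_group=30)
        assert res.skipped and "patients" in res.reason
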