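"""Group comparison, event selection and the supporting filters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicemark.diffsplice import (
    DiffspliceError,
    MetastasisCriteria,
    bonferroni,
    filter_exon_usage_results,
    intersect_cohorts,
    select_metastasis_events,
    stromal_correlation,
    wilcoxon_rank_sum,
)
from splicemark.diffsplice import test_events as run_contrast
from splicemark.psi import PsiMatrix


def exact_rank_sum_p(x, y):
    """Independent oracle: exhaustive enumeration over rank assignments.

    Two-sided p = fraction of all C(n, n_x) group assignments of the pooled
    values whose rank-sum deviates from its null mean at least as much as
    the observed one (midranks for ties).
    """
    pooled = np.concatenate([x, y])
    n, n_x = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    mean_w = n_x * (n + 1) / 2.0
    obs = abs(ranks[:n_x].sum() - mean_w)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_x):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_five_vs_five(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.p_value == pytest.approx(2 / 252)

    def test_too_few_values_refused_with_reason(self):
        res = wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0, 3.0])
        assert res.p_value is None
        assert "3" in res.reason

    def test_missing_values_dropped(self):
        res = wilcoxon_rank_sum(
            [1, 2, 3, math.nan], [4, 5, 6, math.nan]
        )
        assert res.n_x == 3 and res.n_y == 3

    @pytest.mark.parametrize("n_x,n_y", [(3, 3), (3, 4), (4, 3), (3, 5), (4, 4)])
    def test_exact_agreement_with_enumeration_oracle(self, n_x, n_y):
        """Tie-free inputs with combined n <= 8: exact oracle equivalence."""
        rng = np.random.default_rng(n_x * 10 + n_y)
        for _ in range(20):
            pooled = rng.permutation(rng.uniform(size=n_x + n_y))
            x, y = pooled[:n_x], pooled[n_x:]
            res = wilcoxon_rank_sum(x, y)
            assert res.p_value == pytest.approx(exact_rank_sum_p(x, y), rel=1e-9)

    def test_tied_samples_approximation_tracks_enumeration(self):
        # with ties the exact distribution is unavailable and the tie- and
        # continuity-corrected normal approximation is used; at 10 vs 10 it
        # must track the enumeration p closely
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.integers(0, 5, size=10).astype(float)
            y = rng.integers(0, 5, size=10).astype(float)
            res = wilcoxon_rank_sum(x, y)
            assert abs(res.p_value - exact_rank_sum_p(x, y)) < 0.05


def _psi_matrix(values, samples):
    frame = pd.DataFrame(values, columns=samples)
    frame.index = [f"e{i}" for i in range(len(frame))]
    totals = pd.DataFrame(100, index=frame.index, columns=frame.columns)
    return PsiMatrix("psi_exon", frame, totals)


class TestTestEvents:
    def test_delta_psi_is_mean_difference(self):
        samples = [f"n{i}" for i in range(5)] + [f"t{i}" for i in range(5)]
        design = {s: ("NC" if s.startswith("n") else "CRC") for s in samples}
        matrix = _psi_matrix([[0.5] * 5 + [0.85] * 5], samples)
        res = run_contrast(matrix, design, ("NC", "CRC"))
        assert res.loc["e0", "delta_psi"] == pytest.approx(0.35)

    def test_all_missing_event_reported_untestable(self):
        samples = ["n1", "n2", "n3", "t1", "t2", "t3"]
        design = {s: ("NC" if s.startswith("n") else "CRC") for s in samples}
        matrix = _psi_matrix([[math.nan] * 6], samples)
        res = run_contrast(matrix, design, ("NC", "CRC"))
        assert math.isnan(res.loc["e0", "p_value"])
        assert not res.loc["e0", "pass_default"]

    def test_small_effect_fails_joint_filter(self):
        rng = np.random.default_rng(1)
        samples = [f"n{i}" for i in range(10)] + [f"t{i}" for i in range(10)]
        design = {s: ("NC" if s.startswith("n") else "CRC") for s in samples}
        # significant but small shift: p < 0.05, dPSI = 0.15 < 0.20
        vals = [list(0.40 + 0.001 * rng.random(10)) +
                list(0.55 + 0.001 * rng.random(10))]
        matrix = _psi_matrix(vals, samples)
        res = run_contrast(matrix, design, ("NC", "CRC"))
        assert res.loc["e0", "p_value"] < 0.05
        assert not res.loc["e0", "pass_default"]

    def test_missing_contrast_group_rejected(self):
        matrix = _psi_matrix([[0.5, 0.5]], ["a", "b"])
        with pytest.raises(DiffspliceError):
            run_contrast(matrix, {"a": "NC", "b": "NC"}, ("NC", "CRC"))


def _result_frame(rows):
    frame = pd.DataFrame(rows).set_index("event_id")
    return frame


class TestIntersectCohorts:
    def _frame(self, delta, p, passing=True):
        return _result_frame(
            [{"event_id": "e0", "delta_psi": delta, "p_value": p,
              "pass_default": passing, "mean_a": 0.5, "mean_b": 0.5 + delta}]
        )

    def test_same_sign_retained(self):
        inter = intersect_cohorts(
            {"c1": self._frame(0.3, 0.01), "c2": self._frame(0.4, 0.02)}
        )
        assert list(inter.index) == ["e0"]

    def test_opposite_signs_dropped_when_direction_aware(self):
        cohorts = {"c1": self._frame(0.3, 0.01), "c2": self._frame(-0.4, 0.02)}
        assert intersect_cohorts(cohorts).empty
        assert not intersect_cohorts(cohorts, direction_aware=False).empty

    def test_empty_second_cohort_empty_intersection(self):
        empty = self._frame(0.3, 0.01).iloc[:0]
        assert intersect_cohorts({"c1": self._frame(0.3, 0.01), "c2": empty}).empty


class TestMetastasisSelection:
    def _contrasts(self, delta_mc=-0.40, p_mc=5e-4, delta_crc=-0.20,
                   mean_mc=0.20, mean_crc=0.40, flip_cohort2=False):
        mc = _result_frame(
            [{"event_id": "e0", "delta_psi": delta_mc, "p_value": p_mc,
              "mean_a": 0.60, "mean_b": mean_mc, "pass_default": True}]
        )
        crc1 = _result_frame(
            [{"event_id": "e0", "delta_psi": delta_crc, "p_value": 0.01,
              "mean_a": 0.60, "mean_b": mean_crc, "pass_default": True}]
        )
        crc2 = crc1.copy()
        if flip_cohort2:
            crc2["delta_psi"] = -crc2["delta_psi"]
        return mc, {"c1": crc1, "c2": crc2}

    def test_event_meeting_all_criteria_selected(self):
        mc, crcs = self._contrasts()
        sel = select_metastasis_events(mc, crcs)
        assert bool(sel.loc["e0", "selected"])

    def test_insufficient_further_shift_rejected(self):
        mc, crcs = self._contrasts(mean_mc=0.30)  # shift -0.10 < 0.15
        sel = select_metastasis_events(mc, crcs)
        assert not sel.loc["e0", "pass_further_shift"]
        assert not sel.loc["e0", "selected"]

    def test_sign_flip_in_one_cohort_rejected(self):
        mc, crcs = self._contrasts(flip_cohort2=True)
        sel = select_metastasis_events(mc, crcs)
        assert not sel.loc["e0", "pass_consistent_sign"]
        assert not sel.loc["e0", "selected"]

    def test_weak_p_rejected(self):
        mc, crcs = self._contrasts(p_mc=0.005)
        sel = select_metastasis_events(mc, crcs)
        assert not sel.loc["e0", "pass_p"]

    def test_selection_subset_of_mc_filter(self):
        # monotonicity of conjunction on a random table
        rng = np.random.default_rng(4)
        rows_mc, rows_crc = [], []
        for i in range(50):
            delta = rng.uniform(-0.6, 0.6)
            rows_mc.append(
                {"event_id": f"e{i}", "delta_psi": delta,
                 "p_value": rng.uniform(0, 0.01), "mean_a": 0.5,
                 "mean_b": 0.5 + delta, "pass_default": True}
            )
            rows_crc.append(
                {"event_id": f"e{i}",
                 "delta_psi": delta * rng.choice([1, -1], p=[0.8, 0.2]),
                 "p_value": 0.01, "mean_a": 0.5,
                 "mean_b": 0.5 + delta * rng.uniform(0, 1),
                 "pass_default": True}
            )
        sel = select_metastasis_events(
            _result_frame(rows_mc), {"c1": _result_frame(rows_crc)}
        )
        assert (
            sel["selected"] <= (sel["pass_effect"] & sel["pass_p"])
        ).all()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(DiffspliceError):
            MetastasisCriteria(mc_vs_nc_abs_delta_min=1.5)


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni(0.01, m=16) == pytest.approx(0.16)
        assert bonferroni(0.2, m=10) == 1.0
        assert bonferroni(0.3, m=1) == pytest.approx(0.3)

    def test_defaults_to_family_size(self):
        adj = bonferroni([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.09])

    def test_invalid_p_rejected(self):
        with pytest.raises(DiffspliceError):
            bonferroni([0.0, 0.5])


class TestStromalCorrelation:
    def test_monotone_pairs(self):
        usage = pd.DataFrame({f"s{i}": [float(i)] for i in range(6)}).T
        usage.columns = ["j1"]
        usage = usage.T
        stromal = pd.Series([10.0 * i for i in range(6)],
                            index=[f"s{i}" for i in range(6)])
        res = stromal_correlation(usage, stromal)
        assert res.loc["j1", "rho"] == pytest.approx(1.0)
        anti = stromal_correlation(usage, stromal.iloc[::-1].set_axis(stromal.index))
        assert anti.loc["j1", "rho"] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        usage = pd.DataFrame([[1.0, 2.0, 3.0]], index=["j1"],
                             columns=["a", "b", "c"])
        stromal = pd.Series([2.0, 1.0, 3.0], index=["a", "b", "c"])
        res = stromal_correlation(usage, stromal)
        assert res.loc["j1", "rho"] == pytest.approx(0.5)

    def test_too_few_pairs_missing(self):
        usage = pd.DataFrame([[1.0, 2.0]], index=["j1"], columns=["a", "b"])
        stromal = pd.Series([1.0, 2.0], index=["a", "b"])
        res = stromal_correlation(usage, stromal)
        assert math.isnan(res.loc["j1", "rho"])


class TestExonUsageFilter:
    def test_threshold_rules(self):
        table = pd.DataFrame(
            {"padj": [1e-4, 0.005, 1e-5], "fold_change": [3.0, 10.0, 1.5]},
            index=["keep", "weak_p", "weak_fc"],
        )
        kept = filter_exon_usage_results(table)
        assert list(kept.index) == ["keep"]

    def test_strong_downregulation_kept(self):
        table = pd.DataFrame({"padj": [1e-4], "fold_change": [0.25]})
        assert len(filter_exon_usage_results(table)) == 1

    def test_empty_table_passes_through(self):
        table = pd.DataFrame({"padj": [], "fold_change": []})
        assert filter_exon_usage_results(table).empty

    def test_missing_columns_rejected(self):
        with pytest.raises(DiffspliceError):
            filter_exon_usage_results(pd.DataFrame({"padj": [0.1]}))
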