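"""Differential splicing: group comparison, selection and filters.

PSI values of two sample groups are compared with the two-sided Wilcoxon
rank-sum test; the effect size is dPSI, the difference of group mean PSI.
Defaults follow the discovery cutoffs p < 0.05 and |dPSI| > 0.20; the
metastasis filter additionally requires p < 0.001, a consistent sign across
contrasts and a further shift of at least 0.15 between metastatic and
primary-tumor means.  Discovery p-values are left unadjusted (the
validation stage applies Bonferroni); this mirrors the two-stage design of
discovery cohorts followed by an independent validation cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psi import PsiMatrix

__all__ = [
    "DiffspliceError",
    "WilcoxonResult",
    "MetastasisCriteria",
    "wilcoxon_rank_sum",
    "test_events",
    "intersect_cohorts",
    "select_metastasis_events",
    "bonferroni",
    "stromal_correlation",
    "filter_exon_usage_results",
]

DEFAULT_P_MAX = 0.05
DEFAULT_DPSI_MIN = 0.20
MIN_PER_GROUP = 3
EXACT_MAX_N = 25


class DiffspliceError(ValueError):
    pass


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float | None   # rank-sum W of the first sample (midranks)
    p_value: float | None
    n_x: int
    n_y: int
    reason: str | None = None


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    min_per_group: int = MIN_PER_GROUP,
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact null distribution when the combined sample size is <= 25 with no
    ties; otherwise normal approximation with tie and continuity correction.
    Missing values are dropped; groups below ``min_per_group`` refuse the
    test (p is None with a reason).
    """
    x = np.asarray([v for v in np.asarray(x, dtype=float) if not math.isnan(v)])
    y = np.asarray([v for v in np.asarray(y, dtype=float) if not math.isnan(v)])
    n_x, n_y = len(x), len(y)
    if n_x < min_per_group or n_y < min_per_group:
        return WilcoxonResult(
            None, None, n_x, n_y,
            reason=f"need >= {min_per_group} non-missing values per group",
        )
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (n_x + n_y <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + n_x * (n_x + 1) / 2.0  # U -> rank-sum of x
    return WilcoxonResult(w, float(res.pvalue), n_x, n_y)


def test_events(
    psi: PsiMatrix,
    design: Mapping[str, str],
    contrast: tuple[str, str],
    p_max: float = DEFAULT_P_MAX,
    dpsi_min: float = DEFAULT_DPSI_MIN,
    min_per_group: int = MIN_PER_GROUP,
) -> pd.DataFrame:
    """Per-event Wilcoxon + dPSI for one contrast (B vs A; dPSI = mean_B - mean_A).

    Samples with missing PSI are dropped per event (pairwise deletion).
    Returns a DataFrame indexed by event_id with columns: method, mean_a,
    mean_b, median_a, median_b, delta_psi, n_a, n_b, p_value, pass_default,
    reason.
    """
    group_a, group_b = contrast
    samples_a = [s for s in psi.samples if design.get(s) == group_a]
    samples_b = [s for s in psi.samples if design.get(s) == group_b]
    if not samples_a or not samples_b:
        raise DiffspliceError(
            f"contrast groups {contrast} not present in the design"
        )
    rows = []
    for event_id, row in psi.values.iterrows():
        a_vals = row[samples_a].to_numpy(dtype=float)
        b_vals = row[samples_b].to_numpy(dtype=float)
        a_vals = a_vals[~np.isnan(a_vals)]
        b_vals = b_vals[~np.isnan(b_vals)]
        res = wilcoxon_rank_sum(a_vals, b_vals, min_per_group=min_per_group)
        mean_a = float(np.mean(a_vals)) if a_vals.size else math.nan
        mean_b = float(np.mean(b_vals)) if b_vals.size else math.nan
        delta = mean_b - mean_a
        passed = (
            res.p_value is not None
            and res.p_value < p_max
            and abs(delta) > dpsi_min
        )
        rows.append(
            {
                "event_id": event_id,
                "method": psi.method,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "median_a": float(np.median(a_vals)) if a_vals.size else math.nan,
                "median_b": float(np.median(b_vals)) if b_vals.size else math.nan,
                "delta_psi": delta,
                "n_a": res.n_x,
                "n_b": res.n_y,
                "p_value": math.nan if res.p_value is None else res.p_value,
                "pass_default": bool(passed),
                "reason": res.reason or "",
            }
        )
    return pd.DataFrame(rows).set_index("event_id")


def intersect_cohorts(
    results_by_cohort: Mapping[str, pd.DataFrame],
    direction_aware: bool = True,
) -> pd.DataFrame:
    """Events passing the default cutoffs in every cohort.

    With ``direction_aware`` the dPSI sign must agree across cohorts.
    Returns per-cohort delta/p columns for the retained events.
    """
    if not results_by_cohort:
        raise DiffspliceError("no cohorts supplied")
    cohorts = list(results_by_cohort)
    shared: pd.Index | None = None
    for name, frame in results_by_cohort.items():
        passing = frame.index[frame["pass_default"]]
        shared = passing if shared is None else shared.intersection(passing)
    assert shared is not None
    if direction_aware and len(shared):
        signs = np.vstack(
            [
                np.sign(results_by_cohort[c].loc[shared, "delta_psi"].to_numpy())
                for c in cohorts
            ]
        )
        consistent = (signs == signs[0]).all(axis=0) & (signs[0] != 0)
        shared = shared[consistent]
    out = pd.DataFrame(index=shared)
    for c in cohorts:
        out[f"delta_psi_{c}"] = results_by_cohort[c].loc[shared, "delta_psi"]
        out[f"p_value_{c}"] = results_by_cohort[c].loc[shared, "p_value"]
    return out


@dataclass(frozen=True)
class MetastasisCriteria:
    """Selection thresholds for metastasis-associated events."""

    mc_vs_nc_abs_delta_min: float = 0.20
    mc_vs_nc_p_max: float = 0.001
    further_shift_min: float = 0.15

    def __post_init__(self) -> None:
        for v in (
            self.mc_vs_nc_abs_delta_min,
            self.mc_vs_nc_p_max,
            self.further_shift_min,
        ):
            if not (0 < v < 1):
                raise DiffspliceError(f"criterion threshold {v} outside (0, 1)")


def select_metastasis_events(
    mc_vs_nc: pd.DataFrame,
    crc_vs_nc_by_cohort: Mapping[str, pd.DataFrame],
    criteria: MetastasisCriteria = MetastasisCriteria(),
) -> pd.DataFrame:
    """Apply the metastasis-association filter.

    ``mc_vs_nc`` is the metastasis-vs-normal contrast from the trio cohort
    (mean_b = metastasis mean); ``crc_vs_nc_by_cohort`` maps each cohort to
    its primary-tumor-vs-normal contrast, and must include the trio cohort
    itself (its mean_b supplies the primary-tumor mean for the
    further-shift rule).  Kept events satisfy, in the same direction:

    * |dPSI(MC - NC)| above the threshold with p below the cap,
    * dPSI sign agreement across all supplied contrasts,
    * |mean(MC) - mean(CRC)| >= further_shift_min.

    Consistency is sign agreement only; the primary contrasts need not be
    individually significant (flagged in the output columns).
    """
    if not crc_vs_nc_by_cohort:
        raise DiffspliceError("need at least one CRC-vs-NC contrast")
    shared = mc_vs_nc.index
    for frame in crc_vs_nc_by_cohort.values():
        shared = shared.intersection(frame.index)
    first_cohort = next(iter(crc_vs_nc_by_cohort))

    out = pd.DataFrame(index=shared)
    delta_mc = mc_vs_nc.loc[shared, "delta_psi"].to_numpy()
    p_mc = mc_vs_nc.loc[shared, "p_value"].to_numpy()
    out["delta_psi_mc_nc"] = delta_mc
    out["p_value_mc_nc"] = p_mc
    out["pass_effect"] = np.abs(delta_mc) > criteria.mc_vs_nc_abs_delta_min
    with np.errstate(invalid="ignore"):
        out["pass_p"] = p_mc < criteria.mc_vs_nc_p_max

    signs = np.sign(delta_mc)
    consistent = signs != 0
    for name, frame in crc_vs_nc_by_cohort.items():
        d = frame.loc[shared, "delta_psi"].to_numpy()
        out[f"delta_psi_crc_nc_{name}"] = d
        consistent = consistent & (np.sign(d) == signs)
    out["pass_consistent_sign"] = consistent

    mean_mc = mc_vs_nc.loc[shared, "mean_b"].to_numpy()
    mean_crc = crc_vs_nc_by_cohort[first_cohort].loc[shared, "mean_b"].to_numpy()
    shift = mean_mc - mean_crc
    out["further_shift"] = shift
    out["pass_further_shift"] = (np.abs(shift) >= criteria.further_shift_min) & (
        np.sign(shift) == signs
    )

    out["selected"] = (
        out["pass_effect"]
        & out["pass_p"]
        & out["pass_consistent_sign"]
        & out["pass_further_shift"]
    )
    return out


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: min(1, p * m); m defaults to the list length."""
    arr = np.asarray(p_values, dtype=float)
    if ((arr <= 0) | (arr > 1)).any():
        raise DiffspliceError("p-values must lie in (0, 1]")
    m_eff = m if m is not None else arr.size
    adj = np.minimum(1.0, arr * m_eff)
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index)
    if np.isscalar(p_values):
        return float(adj)
    return adj


def stromal_correlation(
    usage: pd.DataFrame | pd.Series,
    stromal_pct: pd.Series,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of junction usage with stromal content.

    One row per junction: rho, two-sided p, Bonferroni-adjusted p over the
    tested junction set.  Junctions with fewer than ``min_pairs`` paired
    non-missing observations are reported missing.
    """
    if isinstance(usage, pd.Series):
        usage = usage.to_frame().T
    rows = []
    for junction, values in usage.iterrows():
        paired = pd.concat([values, stromal_pct], axis=1, join="inner").dropna()
        if len(paired) < min_pairs:
            rows.append({"junction": junction, "rho": math.nan, "p_value": math.nan})
            continue
        rho, p = stats.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
        rows.append({"junction": junction, "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows).set_index("junction")
    tested = out["p_value"].notna()
    out["p_adj"] = math.nan
    if tested.any():
        # perfectly monotone inputs yield p exactly 0, which min(1, p*m)
        # maps to 0 without needing the (0, 1] precondition
        out.loc[tested, "p_adj"] = np.minimum(
            1.0, out.loc[tested, "p_value"] * int(tested.sum())
        )
    return out


def filter_exon_usage_results(
    table: pd.DataFrame,
    padj_max: float = 0.001,
    fc_min: float = 2.0,
    padj_col: str = "padj",
    fc_col: str = "fold_change",
    fold_is_log2: bool = False,
) -> pd.DataFrame:
    """Threshold an external differential-exon-usage results table.

    Keeps rows with adjusted p below ``padj_max`` and |log2 ratio| above
    log2(``fc_min``).  ``fc_col`` holds a linear fold change unless
    ``fold_is_log2`` is set.
    """
    for col in (padj_col, fc_col):
        if col not in table.columns:
            raise DiffspliceError(f"missing required column {col!r}")
    if table.empty:
        return table.copy()
    log2fc = (
        table[fc_col].astype(float)
        if fold_is_log2
        else np.log2(table[fc_col].astype(float))
    )
    keep = (table[padj_col].astype(float) < padj_max) & (
        np.abs(log2fc) > np.log2(fc_min)
    )
    return table.loc[keep.fillna(False)].copy()
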