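"""Group comparisons on cell tables: condition contrasts, axial contrasts,
and the area-metabolism correlation.

Conventions follow the figures the analysis feeds: cell-level contrasts
use a two-sided Welch t-test on volume-mean fraction bound with medians
and interquartile ranges as the reported estimates; donor-level contrasts
collapse cells to per-donor means and use a paired two-sided t-test;
bottom-vs-top axial contrasts pair the same cells at the two planes.  Raw
per-comparison p-values are reported (no multiplicity correction by
default; Holm is available behind a flag).  Significance tiers render as
* (p <= 0.05), ** (p <= 0.01), *** (p <= 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cellmetrics import CellRecord

__all__ = ["ComparisonResult", "compare_conditions", "compare_z",
           "area_fbound_correlation", "significance_stars"]


@dataclass
class ComparisonResult:
    """One statistical contrast between control and activated groups."""

    grouping: str
    estimate_control: float
    estimate_activated: float
    iqr_control: tuple[float, float]
    iqr_activated: tuple[float, float]
    test_name: str
    statistic: float
    p_value: float
    n_control: int
    n_activated: int
    paired: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "na"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def _split(records: list[CellRecord], timepoint: float | None
           ) -> tuple[list[CellRecord], list[CellRecord]]:
    sel = [r for r in records
           if (timepoint is None or r.timepoint == timepoint)
           and np.isfinite(r.volume_mean_fbound)]
    ctrl = [r for r in sel if r.condition == "control"]
    act = [r for r in sel if r.condition == "activated"]
    return ctrl, act


def compare_conditions(records: list[CellRecord], timepoint: float | None = None,
                       level: str = "cell") -> ComparisonResult:
    """Control vs activated contrast of volume-mean fraction bound.

    ``level='cell'``: two-sided Welch t-test across cells, medians + IQR
    reported.  ``level='donor'``: cells are first collapsed to per-donor
    means within each condition and a paired two-sided t-test is run
    across donors (each donor contributes one matched pair).
    """
    ctrl, act = _split(records, timepoint)
    if not ctrl or not act:
        raise ValueError("both conditions must be present")
    if level == "cell":
        x = np.array([r.volume_mean_fbound for r in ctrl])
        y = np.array([r.volume_mean_fbound for r in act])
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least 2 cells per condition")
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        med_c, iqr_c = _median_iqr(x)
        med_a, iqr_a = _median_iqr(y)
        return ComparisonResult(
            grouping=f"timepoint={timepoint}", estimate_control=med_c,
            estimate_activated=med_a, iqr_control=iqr_c, iqr_activated=iqr_a,
            test_name="welch_t", statistic=float(stat), p_value=float(p),
            n_control=len(x), n_activated=len(y), paired=False)
    if level == "donor":
        donors = sorted({r.donor_or_replicate for r in ctrl}
                        & {r.donor_or_replicate for r in act})
        if len(donors) < 2:
            raise ValueError("donor-level test needs >= 2 matched donors")
        x = np.array([np.mean([r.volume_mean_fbound for r in ctrl
                               if r.donor_or_replicate == d]) for d in donors])
        y = np.array([np.mean([r.volume_mean_fbound for r in act
                               if r.donor_or_replicate == d]) for d in donors])
        stat, p = sps.ttest_rel(x, y)
        med_c, iqr_c = _median_iqr(x)
        med_a, iqr_a = _median_iqr(y)
        return ComparisonResult(
            grouping=f"timepoint={timepoint} (donor means)",
            estimate_control=med_c, estimate_activated=med_a,
            iqr_control=iqr_c, iqr_activated=iqr_a, test_name="paired_t",
            statistic=float(stat), p_value=float(p), n_control=len(x),
            n_activated=len(y), paired=True)
    raise ValueError("level must be 'cell' or 'donor'")


def compare_z(records: list[CellRecord], timepoint: float | None = None,
              bottom_z: int = 0, top_z: int | None = None
              ) -> tuple[list[ComparisonResult], dict[str, ComparisonResult]]:
    """Axial contrasts of the per-Z fraction bound.

    Returns (per-Z control-vs-activated Welch tests, within-condition
    bottom-vs-top paired t-tests keyed by condition).  Bottom defaults to
    the coverslip-proximal plane and top to the last plane; only cells
    with valid values at both planes enter a paired test.  Planes where a
    group is absent are skipped.
    """
    ctrl, act = _split(records, timepoint)
    if not ctrl and not act:
        raise ValueError("no records selected")
    n_z = max(len(r.per_z_mean_fbound) for r in ctrl + act)
    if top_z is None:
        top_z = n_z - 1
    per_z: list[ComparisonResult] = []
    for z in range(n_z):
        x = np.array([r.per_z_mean_fbound[z] for r in ctrl
                      if len(r.per_z_mean_fbound) > z])
        y = np.array([r.per_z_mean_fbound[z] for r in act
                      if len(r.per_z_mean_fbound) > z])
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            continue
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        med_c, iqr_c = _median_iqr(x)
        med_a, iqr_a = _median_iqr(y)
        per_z.append(ComparisonResult(
            grouping=f"z_index={z}", estimate_control=med_c,
            estimate_activated=med_a, iqr_control=iqr_c, iqr_activated=iqr_a,
            test_name="welch_t", statistic=float(stat), p_value=float(p),
            n_control=len(x), n_activated=len(y)))
    bottom_top: dict[str, ComparisonResult] = {}
    for name, group in (("control", ctrl), ("activated", act)):
        pairs = [(r.per_z_mean_fbound[bottom_z], r.per_z_mean_fbound[top_z])
                 for r in group if len(r.per_z_mean_fbound) > max(bottom_z, top_z)]
        pairs = [(b, t) for b, t in pairs if np.isfinite(b) and np.isfinite(t)]
        if len(pairs) < 2:
            continue
        b = np.array([p_[0] for p_ in pairs])
        t = np.array([p_[1] for p_ in pairs])
        if np.allclose(b, t):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_rel(b, t)
        med_b, iqr_b = _median_iqr(b)
        med_t, iqr_t = _median_iqr(t)
        bottom_top[name] = ComparisonResult(
            grouping=f"{name}: bottom z={bottom_z} vs top z={top_z}",
            estimate_control=med_b, estimate_activated=med_t,
            iqr_control=iqr_b, iqr_activated=iqr_t, test_name="paired_t",
            statistic=float(stat), p_value=float(p), n_control=len(b),
            n_activated=len(t), paired=True)
    return per_z, bottom_top


def area_fbound_correlation(records: list[CellRecord],
                            timepoint: float | None = None,
                            by_condition: bool = True) -> dict[str, dict]:
    """Pearson (and Spearman) correlation of cell area with fraction bound.

    Computed per condition and pooled; groups with fewer than 3 cells or
    zero variance in either variable report NaN coefficients (degenerate,
    not an error).  Each entry also carries the scatter table columns.
    """
    sel = [r for r in records
           if (timepoint is None or r.timepoint == timepoint)
           and np.isfinite(r.volume_mean_fbound)]
    groups: dict[str, list[CellRecord]] = {"pooled": sel}
    if by_condition:
        for cond in sorted({r.condition for r in sel}):
            groups[cond] = [r for r in sel if r.condition == cond]
    out: dict[str, dict] = {}
    for name, grp in groups.items():
        area = np.array([r.area_um2 for r in grp])
        fb = np.array([r.volume_mean_fbound for r in grp])
        entry = {"n": len(grp), "area_um2": area, "fbound": fb,
                 "pearson_r": float("nan"), "pearson_p": float("nan"),
                 "spearman_rho": float("nan"), "spearman_p": float("nan")}
        if len(grp) >= 3 and np.std(area) > 0 and np.std(fb) > 0:
            r_p = sps.pearsonr(area, fb)
            r_s = sps.spearmanr(area, fb)
            entry.update(pearson_r=float(r_p.statistic), pearson_p=float(r_p.pvalue),
                         spearman_rho=float(r_s.statistic), spearman_p=float(r_s.pvalue))
        out[name] = entry
    return out


def holm_correction(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; raw values are the default)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
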