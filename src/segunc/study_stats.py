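"""Observer-study statistics beyond the VGC rating analysis.

Paired two-sided Wilcoxon signed-rank tests compare per-case editing
times and per-metric distributions between the two study conditions;
a Fligner-Killeen test compares pooled inter-observer spread between the
conditions; descriptive volume-ratio thresholds flag outlying
observer-case pairs.

Zero differences are discarded before ranking (Wilcoxon's original
treatment); an exact null distribution is used for n <= 15 without tied
absolute differences, otherwise the tie-corrected normal approximation
with continuity correction.  The heavy lifting is delegated to
scipy.stats behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 15

METRIC_COLUMNS = ["dice", "surface_dice", "hausdorff_mm", "asd_mm", "volume_diff_cc", "apl_mm"]


@dataclass
class PairedSample:
    """Matched per-case values from step 1 (x) and step 2 (y)."""

    x: np.ndarray
    y: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size == 0 or self.x.shape != self.y.shape:
            raise ValueError("paired sample needs equal-length nonempty vectors")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("paired sample contains missing values")
        if self.labels is None:
            self.labels = np.arange(self.x.size)


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of positive-difference ranks)
    p_value: float
    n_effective: int
    method: str  # "exact" | "approx" | "degenerate"


def wilcoxon_signed_rank(
    sample: PairedSample, exact_max_n: int = EXACT_MAX_N
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Reports W+ (rank sum of positive differences x - y) alongside the
    two-sided p-value.  All-zero differences yield p = 1.0 with a warning.
    """
    d = sample.x - sample.y
    d = d[d != 0.0]
    n_eff = int(d.size)
    if n_eff == 0:
        warnings.warn("all paired differences are zero; Wilcoxon test degenerate")
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0, method="degenerate")

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n_eff
    method = "exact" if (n_eff <= exact_max_n and not has_ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        method=method,
        correction=(method == "approx"),
    )
    return WilcoxonResult(
        statistic=w_plus, p_value=float(res.pvalue), n_effective=n_eff, method=method
    )


@dataclass
class FlignerResult:
    statistic: float
    df: int
    p_value: float


def fligner_killeen(groups: Sequence[np.ndarray]) -> FlignerResult:
    """Fligner-Killeen rank-based test for equal variances across groups.

    Median-centred absolute deviations are pooled, ranked, transformed to
    normal scores, and compared across groups with a chi-square statistic
    on (groups - 1) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
    stat, p = stats.fligner(*arrays)
    return FlignerResult(statistic=float(stat), df=len(arrays) - 1, p_value=float(p))


# ---------------------------------------------------------------------------
# Panel-level comparisons
# ---------------------------------------------------------------------------

_PANEL_KEY = ["observer", "case_id", "organ"]


def _check_panel_frame(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = set(_PANEL_KEY) - set(df.columns)
    if missing:
        raise ValueError(f"{name} panels missing key columns {sorted(missing)}")
    return df


def paired_metric_comparison(
    panels_step1: pd.DataFrame,
    panels_step2: pd.DataFrame,
    metrics: Sequence[str] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Per-(observer, organ, metric) Wilcoxon comparison of the two steps.

    Both panel tables must be computed against the same DL reference and
    matched on (observer, case, organ); unmatched keys raise with the
    offending key list.  ``median_diff`` is median(step1 - step2):
    positive when step 1 carried the larger values.
    """
    p1 = _check_panel_frame(panels_step1, "step1")
    p2 = _check_panel_frame(panels_step2, "step2")
    k1 = set(map(tuple, p1[_PANEL_KEY].itertuples(index=False)))
    k2 = set(map(tuple, p2[_PANEL_KEY].itertuples(index=False)))
    if k1 != k2:
        raise ValueError(
            f"unmatched panel keys; only-step1={sorted(k1 - k2)[:5]}, "
            f"only-step2={sorted(k2 - k1)[:5]}"
        )
    merged = p1.merge(p2, on=_PANEL_KEY, suffixes=("_s1", "_s2"))

    rows = []
    for (observer, organ), grp in merged.groupby(["observer", "organ"]):
        for metric in metrics:
            a = grp[f"{metric}_s1"].to_numpy()
            b = grp[f"{metric}_s2"].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() == 0:
                continue
            res = wilcoxon_signed_rank(PairedSample(x=a[ok], y=b[ok]))
            rows.append(
                {
                    "observer": observer,
                    "organ": organ,
                    "metric": metric,
                    "median_diff": float(np.median(a[ok] - b[ok])),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": int(ok.sum()),
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def interobserver_variance_comparison(
    panels_step1: pd.DataFrame,
    panels_step2: pd.DataFrame,
    metrics: Sequence[str] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Fligner-Killeen test of pooled inter-observer spread, step 1 vs step 2.

    For each organ and metric, all observers' values are pooled within a
    step and the two pooled distributions are compared.
    """
    p1 = _check_panel_frame(panels_step1, "step1")
    p2 = _check_panel_frame(panels_step2, "step2")
    if p1["observer"].nunique() < 2:
        raise ValueError("need at least 2 observers")
    rows = []
    for organ in sorted(set(p1["organ"]) | set(p2["organ"])):
        for metric in metrics:
            g1 = p1.loc[p1["organ"] == organ, metric].dropna().to_numpy()
            g2 = p2.loc[p2["organ"] == organ, metric].dropna().to_numpy()
            if g1.size < 2 or g2.size < 2:
                continue
            res = fligner_killeen([g1, g2])
            rows.append(
                {
                    "organ": organ,
                    "metric": metric,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "n_step1": g1.size,
                    "n_step2": g2.size,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Volume-ratio outliers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierConfig:
    """Per-organ volume-ratio windows outside which a pair is flagged."""

    prostate_high: float = 1.1
    prostate_low: float = 0.91
    rectum_high: float = 1.25
    rectum_low: float = 0.8

    def __post_init__(self) -> None:
        for organ, (lo, hi) in self.bounds().items():
            if not lo < 1.0 < hi:
                raise ValueError(f"{organ}: need low < 1 < high, got ({lo}, {hi})")

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "prostate_ctv": (self.prostate_low, self.prostate_high),
            "rectum": (self.rectum_low, self.rectum_high),
        }


def volume_ratio_outliers(
    ratios: pd.DataFrame, cfg: OutlierConfig = OutlierConfig()
) -> pd.DataFrame:
    """Flag observer-case pairs whose step-2/step-1 volume ratio is extreme.

    ``ratios`` needs columns case_id, observer, organ, volume_ratio.
    Undefined ratios (NaN) are flagged separately as ``undefined``.
    """
    bounds = cfg.bounds()
    rows = []
    for _, row in ratios.iterrows():
        organ = row["organ"]
        if organ not in bounds:
            raise ValueError(f"no outlier bounds for organ {organ!r}")
        lo, hi = bounds[organ]
        ratio = row["volume_ratio"]
        if pd.isna(ratio):
            flag = "undefined"
        elif ratio > hi:
            flag = "high"
        elif ratio < lo:
            flag = "low"
        else:
            continue
        rows.append(
            {
                "case_id": row["case_id"],
                "observer": row["observer"],
                "organ": organ,
                "volume_ratio": ratio,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows, columns=["case_id", "observer", "organ", "volume_ratio", "flag"])


# ---------------------------------------------------------------------------
# Editing-time comparison
# ---------------------------------------------------------------------------

def time_comparison(records, observers: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-observer Wilcoxon comparison of per-case editing times, step 1 vs 2.

    Times are per-case totals (both organs jointly).  Returns one row per
    observer with the step medians, the median reduction and the test.
    """
    by_obs: dict[str, dict[str, dict[int, float]]] = {}
    for rec in records:
        if rec.time_min is None:
            continue
        if observers is not None and rec.observer_id not in observers:
            continue
        by_obs.setdefault(rec.observer_id, {}).setdefault(rec.case_id, {})[rec.step] = rec.time_min

    rows = []
    for obs in sorted(by_obs):
        cases = {c: t for c, t in by_obs[obs].items() if set(t) == {1, 2}}
        if len(cases) < 2:
            continue
        labels = sorted(cases)
        t1 = np.array([cases[c][1] for c in labels])
        t2 = np.array([cases[c][2] for c in labels])
        res = wilcoxon_signed_rank(PairedSample(x=t1, y=t2, labels=np.array(labels)))
        med1, med2 = float(np.median(t1)), float(np.median(t2))
        rows.append(
            {
                "observer": obs,
                "n_cases": len(labels),
                "median_step1_min": med1,
                "median_step2_min": med2,
                "median_change_min": med2 - med1,
                "percent_change": 100.0 * (med1 - med2) / med1 if med1 > 0 else np.nan,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
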