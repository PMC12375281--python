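"""Visual grading characteristics (VGC) analysis of paired ordinal ratings.

VGC is a nonparametric, rank-invariant ROC-style analysis for ordinal
image-quality data observed under two conditions.  For thresholds running
from the top of the rating scale downward, the curve plots the fraction of
condition-1 ratings at or above the threshold against the same fraction
for condition 2; the trapezoidal area under this curve (AUC) equals the
tie-corrected rank statistic P(r2 > r1) + 0.5 * P(r2 = r1) over all cross
pairs.  AUC = 0.5 means no difference between conditions; AUC > 0.5 means
condition 2 (here: editing with the uncertainty map, step 2) was rated
higher.

Uncertainty comes from a case-level bootstrap (percentile interval, hence
asymmetric) and significance from a paired permutation test that swaps
the two conditions within each case with probability 1/2.  Both resample
cases only — a fixed-reader analysis: in pooled-group mode a resampled or
swapped case carries all its observers' pairs.

The module exposes a small model/results pair::

    res = VGCModel(step1, step2, scale_size=5).fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import QUESTION_SCALES, RatingRecord

DEFAULT_N_BOOT = 2000
DEFAULT_N_PERM = 2000
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Curve and AUC
# ---------------------------------------------------------------------------

def _validate_ratings(r1, r2, scale_size: int) -> tuple[np.ndarray, np.ndarray]:
    r1 = np.asarray(r1, dtype=np.int64)
    r2 = np.asarray(r2, dtype=np.int64)
    if r1.size == 0 or r1.shape != r2.shape:
        raise ValueError("rating vectors must be nonempty and equal length")
    for r in (r1, r2):
        if r.min() < 1 or r.max() > scale_size:
            raise ValueError(f"ratings outside 1..{scale_size}")
    return r1, r2


def vgc_points(step1_ratings, step2_ratings, scale_size: int) -> list[tuple[float, float]]:
    """Ordered VGC curve points, beginning at (0, 0) and ending at (1, 1).

    For thresholds t = scale_size down to 1, the point is (fraction of
    step-1 ratings >= t, fraction of step-2 ratings >= t).
    """
    r1, r2 = _validate_ratings(step1_ratings, step2_ratings, scale_size)
    points = [(0.0, 0.0)]
    for t in range(scale_size, 0, -1):
        points.append((float((r1 >= t).mean()), float((r2 >= t).mean())))
    return points


def _auc_rows(r1: np.ndarray, r2: np.ndarray, scale_size: int) -> np.ndarray:
    """Trapezoid VGC AUC for each row of (B, n) rating matrices."""
    thresholds = np.arange(scale_size, 0, -1)
    x = (r1[..., None, :] >= thresholds[:, None]).mean(axis=-1)
    y = (r2[..., None, :] >= thresholds[:, None]).mean(axis=-1)
    zeros = np.zeros(x.shape[:-1] + (1,))
    x = np.concatenate([zeros, x], axis=-1)
    y = np.concatenate([zeros, y], axis=-1)
    return np.trapezoid(y, x, axis=-1)


def vgc_auc(step1_ratings, step2_ratings, scale_size: int) -> float:
    """Trapezoidal area under the VGC curve."""
    r1, r2 = _validate_ratings(step1_ratings, step2_ratings, scale_size)
    return float(_auc_rows(r1[None, :], r2[None, :], scale_size)[0])


# ---------------------------------------------------------------------------
# Input container and resampling
# ---------------------------------------------------------------------------

@dataclass
class VGCInput:
    """Paired ratings for one analysis selection.

    Pairs sharing a ``case_id`` are resampled and permuted together
    (fixed-reader analysis); in per-observer data every pair is its own
    case.
    """

    step1: np.ndarray
    step2: np.ndarray
    scale_size: int
    case_ids: np.ndarray
    observer_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.step1, self.step2 = _validate_ratings(self.step1, self.step2, self.scale_size)
        self.case_ids = np.asarray(self.case_ids)
        if self.case_ids.shape != self.step1.shape:
            raise ValueError("case_ids must align with the rating pairs")
        if self.step1.size < 2:
            raise ValueError("need at least 2 rating pairs")

    @property
    def n_pairs(self) -> int:
        return int(self.step1.size)

    def case_groups(self) -> list[np.ndarray]:
        cases, inverse = np.unique(self.case_ids, return_inverse=True)
        return [np.flatnonzero(inverse == i) for i in range(len(cases))]


def vgc_bootstrap(
    inp: VGCInput,
    n_boot: int = DEFAULT_N_BOOT,
    seed: Optional[int] = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, float, float]:
    """Case-level bootstrap of the VGC AUC.

    Returns (boot_sd, ci_low, ci_high) with a percentile
    100*(1-alpha)% interval.  Each resampled case keeps its (step1, step2)
    pair(s) intact; in pooled mode all of a case's observers travel with it.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    groups = inp.case_groups()
    if len(groups) < 2:
        raise ValueError("bootstrap needs at least 2 distinct cases")
    rng = np.random.default_rng(seed)
    n_cases = len(groups)
    choice = rng.integers(0, n_cases, size=(n_boot, n_cases))

    sizes = {len(g) for g in groups}
    if len(sizes) == 1:
        index_matrix = np.stack(groups)  # (n_cases, pairs_per_case)
        picked = index_matrix[choice].reshape(n_boot, -1)
        aucs = _auc_rows(inp.step1[picked], inp.step2[picked], inp.scale_size)
    else:  # unequal observers per case: per-replicate gather
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate([groups[c] for c in choice[b]])
            aucs[b] = _auc_rows(
                inp.step1[idx][None, :], inp.step2[idx][None, :], inp.scale_size
            )[0]
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(aucs.std(ddof=1)), float(lo), float(hi)


def vgc_permutation_p(
    inp: VGCInput,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
) -> float:
    """Two-sided paired permutation p-value for AUC != 0.5.

    Each permutation independently swaps the two conditions within each
    case with probability 1/2 (all of a case's observer pairs swap
    together); p is the fraction of permutations with |AUC* - 0.5| at
    least the observed |AUC - 0.5|.  No add-one correction, so extreme
    results can report 0.0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    groups = inp.case_groups()
    n_cases = len(groups)

    pair_case = np.empty(inp.n_pairs, dtype=np.int64)
    for ci, g in enumerate(groups):
        pair_case[g] = ci
    swap_case = rng.random((n_perm, n_cases)) < 0.5
    swap = swap_case[:, pair_case]  # (n_perm, n_pairs)

    r1 = np.where(swap, inp.step2[None, :], inp.step1[None, :])
    r2 = np.where(swap, inp.step1[None, :], inp.step2[None, :])
    auc_perm = _auc_rows(r1, r2, inp.scale_size)
    auc_obs = vgc_auc(inp.step1, inp.step2, inp.scale_size)
    return float(
        (np.abs(auc_perm - 0.5) >= np.abs(auc_obs - 0.5) - 1e-12).mean()
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class VGCResults:
    """Point estimate, resampling uncertainty and test for one VGC analysis."""

    auc: float
    boot_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int
    n_cases: int
    scale_size: int
    label: str = ""
    n_boot: int = DEFAULT_N_BOOT
    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    seed: Optional[int] = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> str:
        lines = [
            "VGC analysis" + (f" — {self.label}" if self.label else ""),
            "-" * 52,
            f"pairs: {self.n_pairs}   cases: {self.n_cases}   scale: 1..{self.scale_size}",
            f"AUC            {self.auc:8.3f}",
            f"bootstrap SD   {self.boot_sd:8.3f}   ({self.n_boot} resamples)",
            f"{100 * (1 - self.alpha):.0f}% CI         [{self.ci_low:6.3f}, {self.ci_high:6.3f}] (percentile)",
            f"p (two-sided)  {self.p_value:8.3f}   ({self.n_perm} permutations)",
            "AUC > 0.5 means condition 2 rated higher than condition 1.",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "auc": self.auc,
            "boot_sd": self.boot_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "n_cases": self.n_cases,
        }


class VGCModel:
    """Paired ordinal rating comparison between two conditions.

    Parameters
    ----------
    step1, step2 : sequences of int
        Paired ordinal ratings, one entry per (case, observer) pair.
    scale_size : int
        Number of categories (4 for quality, 5 for confidence).
    case_ids : sequence, optional
        Case label per pair; defaults to one case per pair.
    """

    def __init__(self, step1, step2, scale_size: int, case_ids=None, label: str = ""):
        step1 = np.asarray(step1)
        if case_ids is None:
            case_ids = np.arange(step1.size)
        self.data = VGCInput(
            step1=step1, step2=np.asarray(step2), scale_size=scale_size,
            case_ids=np.asarray(case_ids),
        )
        self.label = label

    @classmethod
    def from_records(
        cls,
        records: Sequence[RatingRecord],
        question: str,
        organ: str,
        observers: Optional[Sequence[str]] = None,
        label: str = "",
    ) -> "VGCModel":
        """Build the paired input from rating records for one question/organ.

        Cases present in only one step are excluded with a warning; the
        exclusion count is kept on the model as ``n_excluded``.
        """
        by_key: dict[tuple[str, str], dict[int, int]] = {}
        for rec in records:
            if rec.question != question or rec.organ != organ:
                continue
            if observers is not None and rec.observer_id not in observers:
                continue
            by_key.setdefault((rec.observer_id, rec.case_id), {})[rec.step] = rec.rating_ordinal
        pairs = {k: v for k, v in by_key.items() if set(v) == {1, 2}}
        n_excluded = len(by_key) - len(pairs)
        if n_excluded:
            warnings.warn(
                f"{question}/{organ}: excluded {n_excluded} unpaired observer-case entries"
            )
        if not pairs:
            raise ValueError(f"no complete pairs for {question}/{organ}")
        keys = sorted(pairs)
        model = cls(
            step1=[pairs[k][1] for k in keys],
            step2=[pairs[k][2] for k in keys],
            scale_size=QUESTION_SCALES[question],
            case_ids=[k[1] for k in keys],
            label=label or f"{question}/{organ}",
        )
        model.n_excluded = n_excluded
        return model

    def fit(
        self,
        n_boot: int = DEFAULT_N_BOOT,
        n_perm: int = DEFAULT_N_PERM,
        alpha: float = DEFAULT_ALPHA,
        seed: Optional[int] = None,
    ) -> VGCResults:
        ss = np.random.SeedSequence(seed)
        boot_seed, perm_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        auc = vgc_auc(self.data.step1, self.data.step2, self.data.scale_size)
        boot_sd, ci_low, ci_high = vgc_bootstrap(self.data, n_boot, boot_seed, alpha)
        p = vgc_permutation_p(self.data, n_perm, perm_seed)
        return VGCResults(
            auc=auc, boot_sd=boot_sd, ci_low=ci_low, ci_high=ci_high, p_value=p,
            n_pairs=self.data.n_pairs, n_cases=len(self.data.case_groups()),
            scale_size=self.data.scale_size, label=self.label,
            n_boot=n_boot, n_perm=n_perm, alpha=alpha, seed=seed,
        )


def vgc_analysis(
    records: Sequence[RatingRecord],
    question: str,
    organ: str,
    mode: str = "per_observer",
    n_boot: int = DEFAULT_N_BOOT,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: Optional[int] = None,
) -> dict[str, VGCResults]:
    """Run the VGC analysis per observer and/or for the pooled group.

    ``mode`` is ``"per_observer"``, ``"pooled_group"`` or ``"both"``.
    Pooled mode concatenates all observers' pairs and resamples/permutes
    by case (fixed-reader).
    """
    if mode not in ("per_observer", "pooled_group", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    observers = sorted({r.observer_id for r in records if r.question == question})
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(observers) + 1)]
    out: dict[str, VGCResults] = {}
    if mode in ("per_observer", "both"):
        for obs, s in zip(observers, seeds):
            model = VGCModel.from_records(
                records, question, organ, observers=[obs], label=f"{obs} {question}/{organ}"
            )
            out[obs] = model.fit(n_boot=n_boot, n_perm=n_perm, alpha=alpha, seed=s)
    if mode in ("pooled_group", "both"):
        model = VGCModel.from_records(
            records, question, organ, label=f"group {question}/{organ}"
        )
        out["group"] = model.fit(n_boot=n_boot, n_perm=n_perm, alpha=alpha, seed=seeds[-1])
    return out


def results_frame(results: dict[str, VGCResults], question: str = "", organ: str = "") -> pd.DataFrame:
    """Tabulate VGC results the way observer studies report them."""
    rows = []
    for who, res in results.items():
        d = res.to_dict()
        d.update({"observer": who, "question": question, "organ": organ})
        rows.append(d)
    cols = ["observer", "question", "organ", "auc", "boot_sd", "ci_low", "ci_high", "p_value", "n_pairs", "n_cases"]
    return pd.DataFrame(rows)[cols]
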