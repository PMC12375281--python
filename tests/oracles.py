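"""Independent brute-force oracles used to check the library implementations.

Deliberately naive: surfaces by explicit neighbour shifts, distances by
full pairwise matrices, the VGC AUC by direct cross-pair counting, and the
exact Wilcoxon null by full sign-pattern enumeration.  None of these share
code with the package paths they verify.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def surface_mask_oracle(mask: np.ndarray) -> np.ndarray:
    """Voxels of the mask with a 6-face neighbour outside (edge counts)."""
    m = mask.astype(bool)
    padded = np.pad(m, 1, constant_values=False)
    has_outside = np.zeros_like(m)
    for axis in range(3):
        for shift in (-1, 1):
            neighbor = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
            has_outside |= ~neighbor
    return m & has_outside


def _points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    return np.argwhere(surface_mask_oracle(mask)) * np.asarray(spacing)


def surface_metrics_oracle(a: np.ndarray, b: np.ndarray, spacing, tau_mm: float):
    """(surface_dice, hausdorff, asd) from the full pairwise distance matrix."""
    pa, pb = _points_mm(a, spacing), _points_mm(b, spacing)
    dm = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    d_ab = dm.min(axis=1)
    d_ba = dm.min(axis=0)
    sdice = ((d_ab <= tau_mm).sum() + (d_ba <= tau_mm).sum()) / (d_ab.size + d_ba.size)
    hd = max(d_ab.max(), d_ba.max())
    asd = np.concatenate([d_ab, d_ba]).mean()
    return float(sdice), float(hd), float(asd)


def dice_oracle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a.astype(bool) & b.astype(bool)).sum()) / (na + nb)


def _boundary_2d_oracle(mask2d: np.ndarray) -> np.ndarray:
    m = mask2d.astype(bool)
    padded = np.pad(m, 1, constant_values=False)
    has_outside = np.zeros_like(m)
    for axis in range(2):
        for shift in (-1, 1):
            neighbor = np.roll(padded, shift, axis=axis)[1:-1, 1:-1]
            has_outside |= ~neighbor
    return m & has_outside


def apl_oracle(reference: np.ndarray, edited: np.ndarray, spacing, tau_mm: float) -> float:
    """Slice-wise added path length by explicit per-pixel distance checks."""
    in_plane = np.asarray(spacing[1:])
    count = 0
    for z in range(reference.shape[0]):
        eb = np.argwhere(_boundary_2d_oracle(edited[z])) * in_plane
        if eb.size == 0:
            continue
        rb = np.argwhere(_boundary_2d_oracle(reference[z])) * in_plane
        if rb.size == 0:
            count += len(eb)
            continue
        for p in eb:
            d = np.sqrt(((rb - p) ** 2).sum(-1)).min()
            if d > tau_mm:
                count += 1
    return count * float(in_plane.mean())


def vgc_auc_oracle(r1, r2) -> float:
    """Tie-corrected rank statistic P(r2 > r1') + 0.5 P(r2 = r1') over cross pairs."""
    r1, r2 = np.asarray(r1), np.asarray(r2)
    total = 0.0
    for a in r1:
        for b in r2:
            if b > a:
                total += 1.0
            elif b == a:
                total += 0.5
    return total / (r1.size * r2.size)


def wilcoxon_exact_p_oracle(d: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign patterns.

    Requires nonzero differences without tied magnitudes.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = n * (n + 1) / 2
    w_min = min(w_plus, total - w_plus)
    ws = np.zeros(2**n)
    for pattern in range(2**n):
        signs = np.array([(pattern >> i) & 1 for i in range(n)])
        ws[pattern] = (ranks * signs).sum()
    p = ((ws <= w_min).sum() + (ws >= total - w_min).sum()) / 2**n
    return min(1.0, float(p))


def sample_std_oracle(values: np.ndarray) -> float:
    """Two-pass sample standard deviation (divisor K-1)."""
    values = np.asarray(values, dtype=float)
    mean = values.sum() / values.size
    return float(np.sqrt(((values - mean) ** 2).sum() / (values.size - 1)))
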