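"""Pearson colocalization within cell masks.

The Pearson correlation coefficient (PCC) of two channels over the
pixels of one cell mask measures how tightly the two signals co-vary:
+1 for identical patterns, ~0 for independent ones, -1 for mutually
exclusive ones.  Populations are summarized as mean ± sample SD over
cells, the convention used when quoting colocalization of fluorescent
fusion pairs.  Per-cell masks (rather than the whole field) are the
default because background pixels would otherwise dominate and inflate
the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ColocResult", "ColocSummary", "pcc_within_mask", "pcc_per_cell", "summarize_pcc"]

MIN_MASK_PIXELS = 10


@dataclass
class ColocResult:
    cell_id: int
    channel_pair: tuple
    pcc: float | None  # None when a channel has zero variance in the mask
    n_pixels: int
    flags: tuple = ()


@dataclass
class ColocSummary:
    mean: float
    sd: float  # sample SD (n-1); NaN for n = 1, flagged
    n_cells: int
    n_undefined: int = 0
    flags: tuple = ()


def pcc_within_mask(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: np.ndarray,
    cell_id: int = 0,
    pair: tuple = ("a", "b"),
) -> ColocResult:
    """PCC of two channels over the pixels of one boolean mask.

    Raises on shape mismatch or masks of fewer than 10 pixels; a channel
    with zero variance inside the mask yields an undefined (None) PCC,
    flagged rather than raised.
    """
    channel_a = np.asarray(channel_a, float)
    channel_b = np.asarray(channel_b, float)
    if channel_a.shape != channel_b.shape or channel_a.shape != np.asarray(mask).shape:
        raise ValueError("channel/mask shapes differ")
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    if n < MIN_MASK_PIXELS:
        raise ValueError(f"mask has {n} px (< {MIN_MASK_PIXELS})")
    a = channel_a[mask]
    b = channel_b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ColocResult(cell_id, pair, None, n, ("zero_variance",))
    r = float(stats.pearsonr(a, b).statistic)
    return ColocResult(cell_id, pair, r, n)


def pcc_per_cell(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    labels: np.ndarray,
    pair: tuple = ("a", "b"),
) -> list[ColocResult]:
    """PCC for every labeled cell; tiny cells are skipped."""
    out = []
    for cell_id in np.unique(labels):
        if cell_id == 0:
            continue
        m = labels == cell_id
        if m.sum() < MIN_MASK_PIXELS:
            continue
        out.append(pcc_within_mask(channel_a, channel_b, m, cell_id=int(cell_id), pair=pair))
    return out


def summarize_pcc(results: list[ColocResult]) -> ColocSummary:
    """Mean ± sample SD of the defined per-cell PCCs.

    Cells with undefined PCC are excluded and counted; all-undefined
    input is an error.  A single defined cell gives SD = NaN, flagged.
    """
    vals = [r.pcc for r in results if r.pcc is not None]
    n_undef = sum(1 for r in results if r.pcc is None)
    if not vals:
        raise ValueError("summarize_pcc: no defined PCC values")
    arr = np.asarray(vals, float)
    if len(arr) == 1:
        return ColocSummary(float(arr[0]), float("nan"), 1, n_undef, ("sd_undefined_n1",))
    return ColocSummary(float(arr.mean()), float(arr.std(ddof=1)), len(arr), n_undef)
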