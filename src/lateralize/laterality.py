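"""Contralateral/ipsilateral modulation and the piecewise laterality index.

For a Go-type unit the per-side normalized modulation is
c, i = FR_peak / FR_baseline - 1, where FR_peak is the mean rate over the
peak +/- 150 ms period (peak located on the 20-ms PETH within [-1.0, +0.5] s
around release onset, independently per side) and FR_baseline is the mean
rate over [-1000, -700] ms.  The laterality index is

    (c - i) / (c + i)   if c > 0 and i > 0
    +1                  if c > 0 and i < 0
    -1                  if c < 0 and i > 0

ranging from -1 (ipsilateral preference) to +1 (contralateral preference).
Units suppressed on both sides (c < 0 and i < 0) have no defined index and
are excluded with a reason code.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .units import PETH_WINDOW, Peth, build_peth

BASELINE_WINDOW = (-1.0, -0.7)  # s re release onset
PEAK_HALF_BINS = 7  # peak +/- 150 ms on the 20-ms PETH


@dataclass
class LateralityResult:
    c: float = np.nan
    i: float = np.nan
    index: float = np.nan
    fr_peak_contra: float = np.nan
    fr_peak_ipsi: float = np.nan
    fr_baseline_contra: float = np.nan
    fr_baseline_ipsi: float = np.nan
    exclusion_reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.index)


def normalized_modulation(fr_peak: float, fr_baseline: float) -> float:
    """c, i = FR_peak / FR_baseline - 1; undefined for a silent baseline."""
    if fr_baseline <= 0:
        raise ValueError("normalized modulation undefined for zero baseline rate")
    return fr_peak / fr_baseline - 1.0


def laterality_index(c: float, i: float) -> float:
    """Piecewise laterality index in [-1, +1]; NaN when both are negative.

    Boundary cases with c = 0 or i = 0 fall to the ratio branch whenever
    both are >= 0 and c + i > 0 (the continuous limit of that branch).
    """
    if c > 0 and i < 0:
        return 1.0
    if c < 0 and i > 0:
        return -1.0
    if c >= 0 and i >= 0 and (c + i) > 0:
        return (c - i) / (c + i)
    return np.nan


def peak_rate_in_window(peth: Peth,
                        baseline_window: tuple[float, float] = BASELINE_WINDOW,
                        peak_half_bins: int = PEAK_HALF_BINS
                        ) -> tuple[float, float]:
    """(FR_peak, FR_baseline) from one side's 20-ms PETH.

    FR_peak is the mean rate over the 15-bin window centered at the maximum
    bin (truncated at the PETH edges); FR_baseline is the mean rate over
    [-1000, -700] ms.
    """
    k = int(np.argmax(peth.rate))
    lo, hi = max(0, k - peak_half_bins), min(peth.rate.size, k + peak_half_bins + 1)
    fr_peak = float(np.mean(peth.rate[lo:hi]))
    centers = peth.bin_centers
    base_mask = (centers >= baseline_window[0]) & (centers <= baseline_window[1])
    fr_baseline = float(np.mean(peth.rate[base_mask]))
    return fr_peak, fr_baseline


def unit_laterality(spikes: np.ndarray,
                    contra_onsets: Sequence[float],
                    ipsi_onsets: Sequence[float],
                    window: tuple[float, float] = PETH_WINDOW,
                    baseline_mode: str = "pooled") -> LateralityResult:
    """Laterality of one Go-type unit from its per-side trial sets.

    The peak is located independently per side.  By default the baseline
    rate pools both sides' trials (pre-movement holding activity should not
    depend on the upcoming side, and the shared baseline cancels correlated
    estimation error in c and i); ``baseline_mode="per_side"`` uses each
    side's own trials instead.  Excluded (reason code set) when the baseline
    is silent or when both modulations are negative.
    """
    if len(contra_onsets) == 0 or len(ipsi_onsets) == 0:
        return LateralityResult(exclusion_reason="no_trials")
    if baseline_mode not in ("pooled", "per_side"):
        raise ValueError("baseline_mode must be 'pooled' or 'per_side'")
    res = LateralityResult()
    peaks, bases, ns = {}, {}, {}
    for side, onsets in (("contra", contra_onsets), ("ipsi", ipsi_onsets)):
        peth = build_peth(spikes, onsets, window=window)
        fr_peak, fr_base = peak_rate_in_window(peth)
        peaks[side], bases[side], ns[side] = fr_peak, fr_base, peth.n_trials
        setattr(res, f"fr_peak_{side}", fr_peak)
        setattr(res, f"fr_baseline_{side}", fr_base)
    if baseline_mode == "pooled":
        pooled = ((bases["contra"] * ns["contra"] + bases["ipsi"] * ns["ipsi"])
                  / (ns["contra"] + ns["ipsi"]))
        bases = {"contra": pooled, "ipsi": pooled}
    mods = {}
    for side in ("contra", "ipsi"):
        if bases[side] <= 0:
            res.exclusion_reason = "zero_baseline"
            return res
        mods[side] = normalized_modulation(peaks[side], bases[side])
    res.c, res.i = mods["contra"], mods["ipsi"]
    idx = laterality_index(res.c, res.i)
    if not np.isfinite(idx):
        res.exclusion_reason = "suppressed_both_sides"
        return res
    res.index = idx
    return res


def laterality_summary(df: pd.DataFrame,
                       group_cols: Sequence[str] = ("area", "condition", "cell_class"),
                       index_col: str = "laterality_index",
                       category_col: str = "side_category") -> pd.DataFrame:
    """Per-group laterality distribution summary.

    Expects one row per unit with a defined index.  Returns mean, SEM, n and
    the contra/ipsi/bilateral category proportions per group; groups with no
    defined index are omitted.
    """
    rows = []
    valid = df[np.isfinite(df[index_col].astype(float))]
    for keys, g in valid.groupby(list(group_cols)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = g[index_col].to_numpy(dtype=float)
        row = dict(zip(group_cols, keys))
        row.update(
            n=len(vals),
            mean=float(vals.mean()),
            sem=float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
            median=float(np.median(vals)),
        )
        if category_col in g:
            cats = g[category_col]
            n_cat = max(len(cats), 1)
            for cat in ("contralateral", "ipsilateral", "bilateral"):
                row[f"prop_{cat}"] = float((cats == cat).sum()) / n_cat
        rows.append(row)
    return pd.DataFrame(rows)


def empirical_cdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and cumulative fractions, for cumulative-distribution
    plots of laterality indices."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, v.size + 1) / v.size
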