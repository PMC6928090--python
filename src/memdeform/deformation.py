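"""Per-frame deformation statistics and hill/valley categorization.

The deformation of a surface at one frame is the mean of its k largest
valid grid heights (the "top" value) minus the mean of its k smallest
(the "bottom" value), with k = 5 by default.  Each valid cell is a
hill (h_i > h̄) or a valley (h_i < h̄), further classified by the
deviation |h_i − h̄|:

    Category I   (large)   |h_i − h̄| ≥ 8 Å
    Category II  (medium)  4 Å ≤ |h_i − h̄| < 8 Å
    Category III (weak)    0 < |h_i − h̄| < 4 Å

Cells exactly at h̄ are labelled valley (the "otherwise" branch) but
tallied separately so no observation is silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .heightmap import HeightMap, global_mean_height

CATEGORIES = ("I", "II", "III")
DEFAULT_THRESHOLDS = (4.0, 8.0)


@dataclass(frozen=True)
class DeformationRecord:
    time: float  # ns
    top: float  # Å
    bottom: float  # Å
    deformation: float  # Å, top − bottom
    skewness: float  # adjusted Fisher–Pearson, dimensionless
    k: int


@dataclass
class CategoryTally:
    """Counts of hills and valleys per deformation category for one frame.

    ``hills`` and ``valleys`` count strictly non-zero deviations;
    ``zero_deviation`` cells (h_i = h̄ exactly) are labelled valley in
    the label map but kept out of the category counts.
    """

    hills: dict
    valleys: dict
    zero_deviation: int
    thresholds: tuple
    n_valid: int
    time: float = 0.0
    labels: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_hills(self) -> int:
        return sum(self.hills.values())

    @property
    def n_valleys(self) -> int:
        return sum(self.valleys.values())


def top_bottom_deformation(hm: HeightMap, k: int = 5) -> DeformationRecord:
    """Top/bottom statistic: mean of the k extreme valid heights each side."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    h = hm.valid_heights()
    if h.size < k:
        raise ValueError(f"only {h.size} valid cells but k={k}")
    part = np.partition(h, (k - 1, h.size - k))
    bottom = float(np.mean(part[:k]))
    top = float(np.mean(part[h.size - k:]))
    if h.size > 2 and np.ptp(h) > 0:
        skew = float(stats.skew(h, bias=False))
    else:
        skew = float("nan")  # undefined for degenerate distributions
    return DeformationRecord(
        time=hm.time, top=top, bottom=bottom, deformation=top - bottom,
        skewness=skew, k=k,
    )


def classify_cells(hm: HeightMap, thresholds: tuple = DEFAULT_THRESHOLDS) -> CategoryTally:
    """Label each valid cell hill/valley and tally the deformation categories."""
    t1, t2 = thresholds
    if not (0 < t1 < t2):
        raise ValueError(f"thresholds must satisfy 0 < t1 < t2, got {thresholds}")
    hbar = global_mean_height(hm)
    dev = hm.heights - hbar
    absdev = np.abs(dev)

    cat = np.full(hm.heights.shape, "", dtype=object)
    cat[hm.valid & (absdev >= t2)] = "I"
    cat[hm.valid & (absdev >= t1) & (absdev < t2)] = "II"
    cat[hm.valid & (absdev < t1)] = "III"

    side = np.full(hm.heights.shape, "", dtype=object)
    side[hm.valid & (dev > 0)] = "hill"
    side[hm.valid & (dev <= 0)] = "valley"  # ties fall to valley

    hills = {c: int(np.sum(hm.valid & (dev > 0) & (cat == c))) for c in CATEGORIES}
    valleys = {c: int(np.sum(hm.valid & (dev < 0) & (cat == c))) for c in CATEGORIES}
    zero = int(np.sum(hm.valid & (dev == 0)))
    labels = np.where(hm.valid, side.astype(str) + ":" + cat.astype(str), "")
    return CategoryTally(
        hills=hills, valleys=valleys, zero_deviation=zero,
        thresholds=(float(t1), float(t2)), n_valid=hm.n_valid, time=hm.time,
        labels=labels,
    )


def cumulative_category_distribution(tallies, mode: str = "pooled") -> dict:
    """Fraction of hill and valley observations per category across frames.

    ``pooled`` treats every cell-frame observation equally; ``per_frame``
    averages the per-frame category distributions.  Zero-deviation cells
    are excluded, so each side's three fractions sum to 1.
    """
    tallies = list(tallies)
    if not tallies:
        raise ValueError("no tallies given")
    out = {}
    for which in ("hills", "valleys"):
        if mode == "pooled":
            counts = np.array([
                sum(getattr(t, which)[c] for t in tallies) for c in CATEGORIES
            ], dtype=float)
            total = counts.sum()
            out[which] = counts / total if total > 0 else counts
        elif mode == "per_frame":
            per_frame = []
            for t in tallies:
                counts = np.array([getattr(t, which)[c] for c in CATEGORIES], dtype=float)
                if counts.sum() > 0:
                    per_frame.append(counts / counts.sum())
            out[which] = (np.mean(per_frame, axis=0) if per_frame
                          else np.zeros(len(CATEGORIES)))
        else:
            raise ValueError(f"mode must be 'pooled' or 'per_frame', got {mode!r}")
    return out


def deformation_time_series(maps, k: int = 5) -> tuple:
    """Per-frame deformation records plus (mean, SE) of the deformation.

    SE is the sample standard deviation over frames divided by √n_frames,
    treating frames as independent observations.
    """
    records = [top_bottom_deformation(hm, k=k) for hm in maps]
    if len(records) < 2:
        raise ValueError("need at least 2 frames for a standard error")
    values = np.array([r.deformation for r in records])
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size))
    return records, {"mean": mean, "se": se, "n": int(values.size)}


def skewness_trend(records) -> dict:
    """OLS fit of skewness against time; slope in ns⁻¹.

    A slope statistically indistinguishable from zero indicates the
    height-distribution asymmetry does not accumulate over the run.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError(f"need >= 3 records for a trend, got {len(records)}")
    t = np.array([r.time for r in records])
    s = np.array([r.skewness for r in records])
    fit = stats.linregress(t, s)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "stderr": float(fit.stderr),
        "pvalue": float(fit.pvalue),
    }
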