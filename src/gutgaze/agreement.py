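"""Agreement statistics: Dice, two-way agreement ICC, limits of agreement.

Repeatability of visual annotation and its agreement with manual calipers or
network predictions are quantified three ways: Dice overlap of the part
segmentations, the intraclass correlation for absolute agreement with both
measurements treated as random single raters (McGraw–Wong ICC(A,1), the
"two-way agreement" model of the R ``irr`` package), and Bland–Altman bias
with 95% limits of agreement (bias ± 1.96·SD of the paired differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reconstruction import DiameterMap, LabelVolume

__all__ = [
    "PairedDiameters",
    "ICCResult",
    "AgreementReport",
    "dice",
    "icc_two_way_agreement",
    "limits_of_agreement",
    "sample_diameter_at",
    "compare",
    "caliper_value",
]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); NaN (undefined) if both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / denom


class ICCResult(NamedTuple):
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def icc_two_way_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (n_subjects, k_raters) with no missing cells.  The point
    estimate is (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) from the
    two-way ANOVA mean squares, and the confidence interval uses the
    McGraw–Wong F-based approximation.  A table with zero total variance is
    degenerate: agreement is trivially perfect, reported as ICC 1 with a
    collapsed CI and flagged.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be (n >= 3 subjects, k >= 2 raters)")
    if not np.isfinite(x).all():
        raise ValueError("ratings must not contain missing values")
    n, k = x.shape
    gm = x.mean()
    sst = ((x - gm) ** 2).sum()
    if sst == 0:
        return ICCResult(1.0, 1.0, 1.0, degenerate=True)
    ssr = k * ((x.mean(axis=1) - gm) ** 2).sum()
    ssc = n * ((x.mean(axis=0) - gm) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if 1.0 - icc < 1e-12:
        return ICCResult(float(icc), float(icc), float(icc), degenerate=False)
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    fl = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    fu = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = (n * (msr - fl * mse)) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = (n * (fu * msr - mse)) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    return ICCResult(float(icc), float(lo), float(hi), degenerate=False)


@dataclass(frozen=True)
class PairedDiameters:
    """Matched diameter measurements (mm) from two sources at the same sites."""

    a: np.ndarray
    b: np.ndarray
    sites: tuple | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or a.size < 2:
            raise ValueError("a and b must be equal-length vectors with n >= 2")
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("diameters must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def ratings(self) -> np.ndarray:
        return np.column_stack([self.a, self.b])


def limits_of_agreement(pairs: PairedDiameters | Sequence) -> tuple[float, float]:
    """Bland–Altman bias and 95% LOA half-width 1.96·SD(differences), sample SD."""
    if isinstance(pairs, PairedDiameters):
        d = pairs.a - pairs.b
    else:
        a, b = pairs
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    return float(d.mean()), float(1.96 * d.std(ddof=1))


def sample_diameter_at(
    diam: DiameterMap, location, search_radius: float = 5.0
) -> float:
    """Diameter value (map units) at a world-mm location.

    Reads the nearest voxel; on a masked map a zero there falls back to the
    nearest non-zero voxel within ``search_radius`` mm (caliper sites sit on
    the bowel surface and may land one voxel outside the reconstructed tube).
    """
    grid = diam.grid
    idx = np.rint(grid.world_to_index(np.asarray(location, dtype=float))).astype(int)
    if (idx < 0).any() or (idx >= np.asarray(grid.shape)).any():
        raise ValueError(f"location {location} outside the grid")
    value = float(diam.values[tuple(idx)])
    if value > 0 or not diam.masked:
        return value
    # nearest non-zero within the search radius
    rad_vox = np.ceil(search_radius / np.asarray(grid.spacing)).astype(int)
    lo = np.maximum(idx - rad_vox, 0)
    hi = np.minimum(idx + rad_vox + 1, grid.shape)
    window = diam.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    nz = np.argwhere(window > 0)
    if nz.size == 0:
        raise ValueError(f"no non-zero diameter within {search_radius} mm of {location}")
    centers = grid.index_to_world(nz + lo)
    d2 = ((centers - np.asarray(location, dtype=float)) ** 2).sum(axis=1)
    best = nz[np.argmin(d2)]
    if math.sqrt(d2.min()) > search_radius:
        raise ValueError(f"no non-zero diameter within {search_radius} mm of {location}")
    return float(window[tuple(best)])


def caliper_value(measurement, mode: str = "mean") -> float:
    """The manual diameter a caliper pair represents: mean (default), short or long axis."""
    if mode == "mean":
        return (measurement.short_axis + measurement.long_axis) / 2.0
    if mode == "short":
        return measurement.short_axis
    if mode == "long":
        return measurement.long_axis
    raise ValueError(f"mode must be mean/short/long, got {mode!r}")


@dataclass(frozen=True)
class AgreementReport:
    """Per-part Dice plus diameter agreement for one comparison of two sources."""

    comparison: str
    dice_stats: Mapping[str, tuple[float, float, int]]  # part -> (mean, sd, n)
    icc: ICCResult | None = None
    bias: float | None = None
    loa_halfwidth: float | None = None
    n_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for part, (mean, sd, n) in self.dice_stats.items():
            rows.append(
                {"comparison": self.comparison, "part": part, "metric": "dice_mean",
                 "value": mean, "n": n}
            )
            rows.append(
                {"comparison": self.comparison, "part": part, "metric": "dice_sd",
                 "value": sd, "n": n}
            )
        if self.icc is not None:
            for metric, value in (
                ("icc", self.icc.icc),
                ("icc_ci_low", self.icc.ci_low),
                ("icc_ci_high", self.icc.ci_high),
                ("bias_mm", self.bias),
                ("loa_halfwidth_mm", self.loa_halfwidth),
            ):
                rows.append(
                    {"comparison": self.comparison, "part": "all", "metric": metric,
                     "value": value, "n": self.n_pairs}
                )
        return pd.DataFrame(rows)


def _part_masks(labels: LabelVolume, part) -> np.ndarray:
    if part == "all":
        return labels.values > 0
    return labels.values == int(part)


def compare(
    source_a: Mapping[str, tuple[LabelVolume, DiameterMap]],
    source_b: Mapping[str, tuple[LabelVolume, DiameterMap]],
    parts: Sequence = (1, 2, 3),
    exclusion_rule: str = "both_empty",
    sites: Sequence[tuple[str, tuple[float, float, float]]] | None = None,
    search_radius: float = 5.0,
    comparison: str = "A_vs_B",
) -> AgreementReport:
    """Full agreement analysis between two annotation/prediction sources.

    Sources map scan ids to (LabelVolume, DiameterMap) on a shared grid per
    scan.  Per-part Dice is averaged across scans; a (scan, part) empty in
    both sources is excluded (the part is simply absent there — default
    rule), while a part empty in only one source counts as Dice 0.  With
    ``exclusion_rule="either_empty"`` any scan missing the part in either
    source is dropped.  If ``sites`` are given, both diameter maps are
    sampled there (in mm) and ICC plus Bland–Altman limits are computed over
    the matched pairs; sites unreadable in either map are dropped.
    """
    if exclusion_rule not in ("both_empty", "either_empty"):
        raise ValueError(f"unknown exclusion rule {exclusion_rule!r}")
    shared = sorted(set(source_a) & set(source_b))
    if not shared:
        raise ValueError("sources share no scan ids")
    all_parts = list(parts) + ["all"]
    dice_stats: dict[str, tuple[float, float, int]] = {}
    for part in all_parts:
        scores = []
        for sid in shared:
            la, _ = source_a[sid]
            lb, _ = source_b[sid]
            ma = _part_masks(la, part)
            mb = _part_masks(lb, part)
            empty_a, empty_b = not ma.any(), not mb.any()
            if empty_a and empty_b:
                continue
            if exclusion_rule == "either_empty" and (empty_a or empty_b):
                continue
            scores.append(dice(ma, mb))
        n = len(scores)
        if n:
            arr = np.asarray(scores)
            dice_stats[str(part)] = (float(arr.mean()), float(arr.std(ddof=1)) if n > 1 else 0.0, n)
        else:
            dice_stats[str(part)] = (float("nan"), float("nan"), 0)

    icc_res = None
    bias = halfwidth = None
    n_pairs = 0
    if sites:
        va, vb = [], []
        for sid, loc in sites:
            if sid not in source_a or sid not in source_b:
                continue
            try:
                da = sample_diameter_at(source_a[sid][1], loc, search_radius)
                db = sample_diameter_at(source_b[sid][1], loc, search_radius)
            except ValueError:
                continue
            if da > 0 and db > 0:
                va.append(da)
                vb.append(db)
        if len(va) >= 3:
            pairs = PairedDiameters(np.asarray(va), np.asarray(vb))
            icc_res = icc_two_way_agreement(pairs.ratings())
            bias, halfwidth = limits_of_agreement(pairs)
            n_pairs = len(va)
    return AgreementReport(comparison, dice_stats, icc_res, bias, halfwidth, n_pairs)
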