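"""Retention-time conversion between chromatographic platforms.

Two repositories acquired with different columns or gradients cannot be
compared by raw RT, but peaks of compounds detected on both platforms
("anchors") trace out a smooth monotone relation between the two time axes.
This module discovers anchors by mutual-nearest unique m/z matching, fits a
low-order polynomial regression to their RT pairs with a single robust
outlier-trim pass, and applies the fitted curve to convert query RTs —
flagging conversions that extrapolate beyond the anchor range.

Monotonicity of the fitted curve is enforced: elution order must be preserved
for the converted RT to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .core import MetabRepoError, SampleTable, ToleranceSpec

__all__ = ["AnchorPair", "RTModel", "RTCalibrationError", "find_anchor_pairs", "fit_rt_model", "convert_rt"]


class RTCalibrationError(MetabRepoError):
    pass


@dataclass(frozen=True)
class AnchorPair:
    """One commonly detected peak pairing a source RT with a target RT."""

    source_peak: str
    target_peak: str
    source_rt: float
    target_rt: float
    delta_ppm: float


@dataclass(frozen=True)
class RTModel:
    """Fitted monotone mapping of source-platform RT onto target-platform RT."""

    source_platform: str
    target_platform: str
    form: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]  # numpy polyval order (highest degree first)
    rt_range: tuple[float, float]  # fitted source-RT range
    residual_mad: float
    n_anchors: int

    @classmethod
    def identity(cls, platform: str = "self", rt_range: tuple[float, float] = (0.0, np.inf)) -> "RTModel":
        return cls(platform, platform, "linear", (1.0, 0.0), rt_range, 0.0, 0)


def find_anchor_pairs(
    table_a: SampleTable,
    table_b: SampleTable,
    mz_tol: ToleranceSpec,
    min_intensity_quantile: float = 0.0,
) -> list[AnchorPair]:
    """Mutual-nearest unique m/z matches between two samples' peak lists.

    Both sides are first filtered to peaks at or above the given per-table
    intensity quantile; a pair is kept only when each peak is the other's
    nearest m/z neighbour within tolerance (which suppresses isomer
    mis-pairs). Pairs come back sorted by source RT.
    """
    if table_a.polarity != table_b.polarity:
        raise RTCalibrationError("anchor discovery requires matching polarities")
    if not 0 <= min_intensity_quantile < 1:
        raise RTCalibrationError(
            f"min_intensity_quantile must be in [0, 1), got {min_intensity_quantile}"
        )

    def retained(table: SampleTable):
        peaks = table.peaks
        if not peaks or min_intensity_quantile == 0:
            return list(peaks)
        cut = float(np.quantile([p.intensity for p in peaks], min_intensity_quantile))
        return [p for p in peaks if p.intensity >= cut]

    pa = retained(table_a)
    pb = retained(table_b)
    if not pa or not pb:
        return []
    mz_b = np.array([p.mz for p in pb])
    order_b = np.argsort(mz_b, kind="stable")
    mz_b_sorted = mz_b[order_b]
    mz_a = np.array([p.mz for p in pa])
    order_a = np.argsort(mz_a, kind="stable")
    mz_a_sorted = mz_a[order_a]

    def nearest(sorted_vals: np.ndarray, x: float) -> int:
        j = int(np.searchsorted(sorted_vals, x))
        best, best_d = -1, np.inf
        for cand in (j - 1, j):
            if 0 <= cand < sorted_vals.size:
                d = abs(sorted_vals[cand] - x)
                if d < best_d:
                    best, best_d = cand, d
        return best

    pairs: list[AnchorPair] = []
    for ia, peak_a in enumerate(pa):
        jb = nearest(mz_b_sorted, peak_a.mz)
        peak_b = pb[order_b[jb]]
        if abs(peak_a.mz - peak_b.mz) > mz_tol.mz_tol_da(peak_a.mz):
            continue
        # mutual check: is peak_a also the nearest source peak to peak_b?
        ja = nearest(mz_a_sorted, peak_b.mz)
        if order_a[ja] != ia:
            continue
        pairs.append(
            AnchorPair(
                source_peak=peak_a.peak_id,
                target_peak=peak_b.peak_id,
                source_rt=peak_a.rt,
                target_rt=peak_b.rt,
                delta_ppm=(peak_b.mz - peak_a.mz) / peak_a.mz * 1e6,
            )
        )
    # uniqueness on the target side (mutual-nearest already gives source side)
    seen_target: dict[str, AnchorPair] = {}
    for pair in pairs:
        if pair.target_peak in seen_target:
            prev = seen_target[pair.target_peak]
            if abs(pair.delta_ppm) < abs(prev.delta_ppm):
                seen_target[pair.target_peak] = pair
        else:
            seen_target[pair.target_peak] = pair
    out = sorted(seen_target.values(), key=lambda p: (p.source_rt, p.source_peak))
    return out


def _check_monotone(coeffs: np.ndarray, lo: float, hi: float) -> bool:
    """Strictly increasing derivative over [lo, hi] for degree <= 2."""
    deriv = np.polyder(coeffs)
    if deriv.size == 1:  # linear fit
        return deriv[0] > 0
    # derivative is linear in rt: positive at both ends suffices
    return np.polyval(deriv, lo) > 0 and np.polyval(deriv, hi) > 0


def fit_rt_model(
    pairs: Sequence[AnchorPair],
    form: str = "linear",
    source_platform: str = "source",
    target_platform: str = "target",
) -> RTModel:
    """Least-squares RT regression with one outlier-trim pass.

    Residuals beyond 3x the median absolute deviation are dropped once and
    the curve refit. The fitted curve must be strictly increasing over the
    anchor RT range; a non-monotone quadratic is an error (use linear).
    """
    degree = {"linear": 1, "quadratic": 2}.get(form)
    if degree is None:
        raise RTCalibrationError(f"form must be 'linear' or 'quadratic', got {form!r}")
    min_pairs = degree + 1
    if len(pairs) < min_pairs:
        raise RTCalibrationError(
            f"{form} fit needs >= {min_pairs} anchor pairs, got {len(pairs)}"
        )
    x = np.array([p.source_rt for p in sorted(pairs, key=lambda p: (p.source_rt, p.source_peak))])
    y = np.array([p.target_rt for p in sorted(pairs, key=lambda p: (p.source_rt, p.source_peak))])
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= 3 * mad
        if keep.sum() >= min_pairs and keep.sum() < keep.size:
            x, y = x[keep], y[keep]
            coeffs = np.polyfit(x, y, degree)
            resid = y - np.polyval(coeffs, x)
            mad = float(np.median(np.abs(resid - np.median(resid))))
    lo, hi = float(x.min()), float(x.max())
    if not _check_monotone(coeffs, lo, hi):
        raise RTCalibrationError(
            "fitted curve is not strictly increasing over the anchor range; "
            "try form='linear'"
        )
    return RTModel(
        source_platform=source_platform,
        target_platform=target_platform,
        form=form,
        coefficients=tuple(float(c) for c in coeffs),
        rt_range=(lo, hi),
        residual_mad=mad,
        n_anchors=int(x.size),
    )


def convert_rt(model: RTModel, rt: float) -> tuple[float, bool]:
    """Map a source RT onto the target platform.

    Returns ``(converted_rt, extrapolated)``; the fitted curve is evaluated
    as-is outside the anchor range, and the flag marks such conversions.
    """
    lo, hi = model.rt_range
    extrapolated = not (lo <= rt <= hi)
    value = float(np.polyval(np.asarray(model.coefficients), rt))
    return value, extrapolated
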