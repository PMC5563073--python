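"""FRAP recovery analysis and the fluorescence variation index (FVI).

Recovery is normalized as ``R(t) = (F(t) - F_0) / F_p`` where ``F`` is the
background-corrected mean intensity in the region of interest, ``F_0`` its
value in the first post-bleach frame, and ``F_p`` the pre-bleach mean. The
recovery time course is fitted by a single exponential ``A (1 - e^{-t/tau})``
anchored at ``R(0) = 0``; FVI time courses are fitted by a quadratic.
Nested fits are compared with the extra sum-of-squares F test.

FVI is the ratio of the pixel-intensity standard deviation in the branch
mask to that in the shaft mask of the same axon. Spatially uniform recovery
gives FVI near 1; focal hotspots concentrated in branches push it above 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.optimize
import scipy.stats
from skimage.exposure import match_histograms
from skimage.registration import phase_cross_correlation

__all__ = [
    "FrapSeries",
    "RecoveryCurve",
    "FitResult",
    "FviSeries",
    "drift_correct",
    "bleach_correct",
    "normalize_recovery",
    "fit_single_exponential",
    "fit_quadratic",
    "extra_sos_f_test",
    "compute_fvi",
    "fvi_series",
]


@dataclass
class FrapSeries:
    """Pre-/post-bleach image stacks with analysis masks.

    ``shaft_mask`` and ``branch_mask`` must be disjoint and contained in
    ``roi_mask``; ``background_region`` must lie outside the bleached region
    of interest so the post-bleach background estimate is valid.
    """

    pre_bleach: np.ndarray  # (n_pre, H, W)
    post_bleach: np.ndarray  # (n_post, H, W)
    t_s: np.ndarray  # seconds since first post-bleach frame
    roi_mask: np.ndarray
    shaft_mask: np.ndarray
    branch_mask: np.ndarray
    background_region: np.ndarray
    frame_interval_s: float = 1.0
    pixel_size_um: float = 0.118

    def __post_init__(self) -> None:
        if self.pre_bleach.ndim != 3 or self.pre_bleach.shape[0] < 1:
            raise ValueError("need at least one pre-bleach frame")
        if len(self.t_s) != self.post_bleach.shape[0]:
            raise ValueError("t_s length must match post-bleach frame count")
        if (self.shaft_mask & self.branch_mask).any():
            raise ValueError("shaft and branch masks must be disjoint")
        if ((self.shaft_mask | self.branch_mask) & ~self.roi_mask).any():
            raise ValueError("shaft/branch masks must lie within the roi mask")
        if (self.background_region & self.roi_mask).any():
            raise ValueError("background region must not overlap the roi")


@dataclass
class RecoveryCurve:
    """Normalized recovery ``R(t)``; ``R(0) = 0`` by construction."""

    t_s: np.ndarray
    r: np.ndarray

    def at(self, t: float) -> float:
        """R at the frame closest to time ``t`` (seconds)."""
        return float(self.r[int(np.argmin(np.abs(self.t_s - t)))])


@dataclass
class FitResult:
    model: str
    params: dict
    sse: float
    df: int
    n: int = 0

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("SSE cannot be negative")
        if self.df <= 0:
            raise ValueError("fit must have positive degrees of freedom")


@dataclass
class FviSeries:
    t_s: np.ndarray
    fvi: np.ndarray  # NaN marks frames with zero shaft variance


# ---------------------------------------------------------------------------
# pre-correction
# ---------------------------------------------------------------------------


def drift_correct(stack, reference_index=0, upsample_factor=10):
    """Register every frame to a reference frame by phase correlation.

    Returns ``(corrected_stack, shifts)`` where ``shifts[i]`` is the
    translation (row, col) detected for frame ``i`` and the corrected stack
    has that translation removed. Featureless frames yield zero shift with a
    warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("drift correction needs a stack of >= 2 frames")
    ref = stack[reference_index]
    corrected = np.empty_like(stack)
    shifts = np.zeros((stack.shape[0], 2))
    for i, frame in enumerate(stack):
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            warnings.warn(f"frame {i} is featureless; assuming zero drift")
            corrected[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        shifts[i] = shift
        corrected[i] = ndi.shift(frame, shift, order=1, mode="nearest")
    return corrected, shifts


def bleach_correct(stack, reference_index=0):
    """Photobleaching correction by histogram matching to a reference frame.

    Each frame's intensity histogram is monotonically mapped onto the
    reference frame's histogram, which equalizes the per-frame intensity
    distribution (and hence the mean) across the series up to quantization.
    """
    stack = np.asarray(stack, dtype=float)
    ref = stack[reference_index]
    out = np.empty_like(stack)
    for i, frame in enumerate(stack):
        if np.ptp(frame) == 0:
            out[i] = frame  # constant frame: identity mapping
        else:
            out[i] = match_histograms(frame, ref)
    return out


# ---------------------------------------------------------------------------
# recovery normalization and fits
# ---------------------------------------------------------------------------


def normalize_recovery(series: FrapSeries, roi_mask=None) -> RecoveryCurve:
    """Compute ``R(t) = (F(t) - F_0) / F_p`` from a FRAP series.

    Intensities are background-corrected per frame using the mean over
    ``background_region``; ``F_p`` is the mean pre-bleach roi intensity and
    ``F_0`` the roi intensity of the first post-bleach frame.
    """
    roi = series.roi_mask if roi_mask is None else roi_mask
    bg_mask = series.background_region
    if not bg_mask.any() or not roi.any():
        raise ValueError("roi and background region must be non-empty")

    def _roi_minus_bg(frame):
        return frame[roi].mean() - frame[bg_mask].mean()

    f_p = float(np.mean([_roi_minus_bg(f) for f in series.pre_bleach]))
    if f_p <= 0:
        raise ValueError(
            "pre-bleach roi intensity does not exceed background; "
            "bleach reference invalid"
        )
    f = np.array([_roi_minus_bg(frame) for frame in series.post_bleach])
    f0 = f[0]
    return RecoveryCurve(t_s=np.asarray(series.t_s, dtype=float), r=(f - f0) / f_p)


def fit_single_exponential(curve: RecoveryCurve) -> FitResult:
    """Least-squares fit of ``R(t) = A (1 - e^{-t/tau})``.

    ``A`` is constrained to (0, 1] and ``tau`` to positive values;
    several starting points are tried and the best converged fit returned.
    A flat curve converges to the ``A -> 0`` boundary, which is flagged in
    the result parameters.
    """
    t = np.asarray(curve.t_s, dtype=float)
    r = np.asarray(curve.r, dtype=float)
    if len(t) < 4:
        raise ValueError("exponential fit needs at least 4 points")

    def model(params):
        a, tau = params
        return a * (1.0 - np.exp(-t / tau))

    def residuals(params):
        return model(params) - r

    t_span = max(t.max(), 1.0)
    a0 = float(np.clip(np.max(r) if np.max(r) > 0 else 0.1, 1e-3, 1.0))
    starts = [
        (a0, t_span / 10.0),
        (a0, t_span / 3.0),
        (min(1.0, 2 * a0), t_span),
        (0.5, t_span / 5.0),
    ]
    best = None
    tried = []
    for start in starts:
        res = scipy.optimize.least_squares(
            residuals, x0=start, bounds=([1e-9, 1e-6], [1.0, np.inf])
        )
        tried.append((start, res.status))
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            f"single-exponential fit did not converge; initializations tried: {tried}"
        )
    a, tau = best.x
    sse = float(2 * best.cost)
    # a flat curve is degenerate: A -> 0 and A -> 0 * huge tau fit equally
    # well, so flag "no recovery" by the fitted curve's maximum value
    pred_max = a * (1.0 - np.exp(-t.max() / tau))
    return FitResult(
        model="single_exponential",
        params={"A": float(a), "tau_s": float(tau),
                "at_zero_boundary": bool(pred_max < 1e-3)},
        sse=sse,
        df=len(t) - 2,
        n=len(t),
    )


def fit_quadratic(series) -> FitResult:
    """Ordinary least squares fit of ``y(t) = c0 + c1 t + c2 t^2``.

    Accepts an :class:`FviSeries`, :class:`RecoveryCurve` or ``(t, y)`` pair;
    NaN samples (undefined FVI frames) are dropped.
    """
    if isinstance(series, FviSeries):
        t, y = series.t_s, series.fvi
    elif isinstance(series, RecoveryCurve):
        t, y = series.t_s, series.r
    else:
        t, y = series
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 4:
        raise ValueError("quadratic fit needs at least 4 finite points")
    coeffs = np.polynomial.polynomial.polyfit(t, y, 2)
    pred = np.polynomial.polynomial.polyval(t, coeffs)
    sse = float(((y - pred) ** 2).sum())
    return FitResult(
        model="quadratic",
        params={"c0": float(coeffs[0]), "c1": float(coeffs[1]), "c2": float(coeffs[2])},
        sse=sse,
        df=len(t) - 3,
        n=len(t),
    )


def extra_sos_f_test(fit_shared: FitResult, fits_separate) -> tuple:
    """Extra sum-of-squares F test between nested fits.

    ``fit_shared`` is the single fit to the pooled data; ``fits_separate``
    are the per-condition fits of the same model. Returns ``(F, p)`` with
    ``F = ((SSE_sh - SSE_sep)/(df_sh - df_sep)) / (SSE_sep/df_sep)``.
    """
    sse_sep = float(sum(f.sse for f in fits_separate))
    df_sep = int(sum(f.df for f in fits_separate))
    d_df = fit_shared.df - df_sep
    if d_df <= 0:
        raise ValueError("shared fit must have more degrees of freedom (nested models)")
    if sse_sep > fit_shared.sse * (1 + 1e-9):
        raise ValueError(
            "separate fits have larger SSE than the shared fit; models are "
            "not nested or fits did not converge"
        )
    f_stat = ((fit_shared.sse - sse_sep) / d_df) / (sse_sep / df_sep)
    p = float(scipy.stats.f.sf(f_stat, d_df, df_sep))
    return float(f_stat), p


# ---------------------------------------------------------------------------
# fluorescence variation index
# ---------------------------------------------------------------------------


def compute_fvi(frame, branch_mask, shaft_mask) -> float:
    """FVI of one frame: SD over branch pixels / SD over shaft pixels.

    Population (n-denominator) standard deviations, pooled across all branch
    pixels of the axon. Returns NaN when the shaft SD is zero.
    """
    branch_mask = np.asarray(branch_mask, dtype=bool)
    shaft_mask = np.asarray(shaft_mask, dtype=bool)
    if not branch_mask.any() or not shaft_mask.any():
        raise ValueError("both masks must be non-empty")
    frame = np.asarray(frame, dtype=float)
    sd_shaft = frame[shaft_mask].std()
    if sd_shaft == 0:
        return float("nan")
    return float(frame[branch_mask].std() / sd_shaft)


def fvi_series(stack, branch_mask, shaft_mask, t_s=None) -> FviSeries:
    """FVI per frame of a stack (or of a :class:`FrapSeries` post-bleach)."""
    if isinstance(stack, FrapSeries):
        if t_s is None:
            t_s = stack.t_s
        branch_mask = stack.branch_mask if branch_mask is None else branch_mask
        shaft_mask = stack.shaft_mask if shaft_mask is None else shaft_mask
        stack = stack.post_bleach
    stack = np.asarray(stack, dtype=float)
    if t_s is None:
        t_s = np.arange(stack.shape[0], dtype=float)
    vals = np.array([compute_fvi(f, branch_mask, shaft_mask) for f in stack])
    return FviSeries(t_s=np.asarray(t_s, dtype=float), fvi=vals)
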