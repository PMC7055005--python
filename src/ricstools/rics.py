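"""Raster image correlation spectroscopy: spatial ACF estimation,
moving-average detrending, model fitting, beam-waist calibration, and the
cross-correlation (ccRICS) interaction index.

Model
-----
For spatial lags ``xi`` (fast/pixel axis) and ``psi`` (slow/line axis) the
single-component RICS model is

    G(xi, psi) = offset + G0 * S(xi, psi) * G_D(xi, psi)

with the lag time ``tau = tau_p*|xi| + tau_l*|psi|``, the diffusion part
``G_D = (1 + 4 D tau / w0^2)^-1 * (1 + 4 D tau / wz^2)^-1/2`` and the
scanning part ``S = exp(-(dr^2 (xi^2+psi^2)/w0^2) / (1 + 4 D tau / w0^2))``.
``G0`` is proportional to ``gamma / N`` with the 3D Gaussian shape factor
``gamma = 2^(-3/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

from .geometry import GAMMA_3D, ImageSeries, ScanConfig

__all__ = [
    "ACFSurface",
    "RICSFitResult",
    "InteractionResult",
    "moving_average_subtract",
    "spatial_acf",
    "rics_model",
    "fit_rics",
    "calibrate_beam_waist",
    "interaction_index",
]


@dataclass
class ACFSurface:
    """2D spatial correlation surface G(xi, psi), lag 0 centred.

    ``G[i, j]`` corresponds to ``psi = psi_lags[i]`` (slow axis) and
    ``xi = xi_lags[j]`` (fast axis, positive = scan direction).
    """

    G: np.ndarray
    xi_lags: np.ndarray
    psi_lags: np.ndarray
    kind: str = "auto"                     # "auto" | "cross"
    ma_window: Optional[int] = None
    mean_intensities: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("auto", "cross"):
            raise ValueError("kind must be 'auto' or 'cross'")
        if self.G.shape != (len(self.psi_lags), len(self.xi_lags)):
            raise ValueError("G shape does not match lag axes")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("correlation surface contains non-finite values")

    def value_at(self, xi: int, psi: int) -> float:
        i = int(np.flatnonzero(self.psi_lags == psi)[0])
        j = int(np.flatnonzero(self.xi_lags == xi)[0])
        return float(self.G[i, j])


def moving_average_subtract(series: ImageSeries | np.ndarray, M: int) -> np.ndarray:
    """Remove the slowly varying (immobile) component from an image series.

    Frame ``i`` becomes ``I_i - MA_i + c`` where ``MA_i`` is the per-pixel
    mean over a centred window of exactly ``M`` frames (the window is clamped
    at the series ends, so ``M = n_frames`` reduces to subtracting the global
    per-pixel temporal mean) and ``c`` is the scalar mean of the MA stack,
    re-added so that the overall mean intensity is preserved exactly.
    """
    data = np.asarray(series.counts if isinstance(series, ImageSeries) else series,
                      dtype=float)
    F = data.shape[0]
    if not 2 <= M <= F:
        raise ValueError(f"moving-average window M={M} outside [2, {F}]")
    csum = np.cumsum(data, axis=0)
    lo = np.clip(np.arange(F) - (M - 1) // 2, 0, F - M)
    hi = lo + M                               # exclusive
    win_sum = csum[hi - 1] - np.where((lo > 0)[:, None, None], csum[lo - 1], 0.0)
    ma = win_sum / M
    return data - ma + ma.mean()


def spatial_acf(series_a: ImageSeries | np.ndarray,
                series_b: Optional[ImageSeries | np.ndarray] = None,
                max_lag: Optional[tuple[int, int]] = None,
                ma_window: Optional[int] = None) -> ACFSurface:
    """Frame-averaged spatial (cross-)correlation of a raster series.

    Per frame, ``G(xi, psi) = <dI_A(x, y) dI_B(x+xi, y+psi)> / (<I_A><I_B>)``
    with ``dI = I - frame mean``, computed by zero-padded FFT (no circular
    wrap) and normalised by the number of contributing pixel pairs at each
    lag.  ``max_lag`` is ``(psi_max, xi_max)``.
    """
    A = np.asarray(series_a.counts if isinstance(series_a, ImageSeries) else series_a,
                   dtype=float)
    if series_b is None or series_b is series_a:
        B, kind = A, "auto"
    else:
        B = np.asarray(series_b.counts if isinstance(series_b, ImageSeries)
                       else series_b, dtype=float)
        kind = "cross"
    if A.shape != B.shape:
        raise ValueError("series shapes differ")
    if A.ndim == 2:
        A, B = A[None], B[None]
    F, R, C = A.shape
    pm = min(R - 1, 64) if max_lag is None else min(max_lag[0], R - 1)
    xm = min(C - 1, 64) if max_lag is None else min(max_lag[1], C - 1)
    counts = np.outer(R - np.abs(np.arange(-pm, pm + 1)),
                      C - np.abs(np.arange(-xm, xm + 1)))
    acc = np.zeros((2 * pm + 1, 2 * xm + 1))
    mean_a = mean_b = 0.0
    for f in range(F):
        ma_, mb_ = A[f].mean(), B[f].mean()
        if ma_ == 0 or mb_ == 0:
            raise ValueError(f"frame {f} has zero mean intensity")
        dA, dB = A[f] - ma_, B[f] - mb_
        FA = np.fft.rfft2(dA, s=(2 * R, 2 * C))
        FB = np.fft.rfft2(dB, s=(2 * R, 2 * C))
        corr = np.fft.irfft2(np.conj(FA) * FB, s=(2 * R, 2 * C))
        corr = np.fft.fftshift(corr)       # lag 0 at (R, C)
        crop = corr[R - pm:R + pm + 1, C - xm:C + xm + 1]
        acc += crop / (counts * ma_ * mb_)
        mean_a += ma_ / F
        mean_b += mb_ / F
    means = (mean_a,) if kind == "auto" else (mean_a, mean_b)
    return ACFSurface(G=acc / F, xi_lags=np.arange(-xm, xm + 1),
                      psi_lags=np.arange(-pm, pm + 1), kind=kind,
                      ma_window=ma_window, mean_intensities=means)


def rics_model(xi: np.ndarray, psi: np.ndarray, D: float, G0: float,
               offset: float, scan: ScanConfig,
               w0: Optional[float] = None) -> np.ndarray:
    """Evaluate the single-component RICS model at integer pixel lags.

    ``w0`` overrides the scan's beam waist (used during calibration); the
    axial radius is tied as ``wz = AR * w0``.
    """
    xi = np.asarray(xi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    w0_ = scan.w0 if w0 is None else w0
    wz_ = scan.AR * w0_
    tau = scan.dwell_time * np.abs(xi) + scan.line_time * np.abs(psi)
    lat = 1.0 + 4.0 * D * tau / w0_ ** 2
    axi = 1.0 + 4.0 * D * tau / wz_ ** 2
    g_d = 1.0 / (lat * np.sqrt(axi))
    s = np.exp(-(scan.pixel_size ** 2 * (xi ** 2 + psi ** 2) / w0_ ** 2) / lat)
    return offset + G0 * s * g_d


@dataclass
class RICSFitResult:
    """Single-component RICS fit: diffusion coefficient and amplitude."""

    D: float
    G0: float
    offset: float
    w0: float
    chi2: float
    converged: bool
    residual: np.ndarray = field(repr=False, default=None)
    n_points: int = 0

    @property
    def N_apparent(self) -> float:
        """Apparent particle number gamma / G0, gamma = 2^(-3/2)."""
        return GAMMA_3D / self.G0


_D_STARTS = (0.1, 1.0, 10.0)


def fit_rics(acf: ACFSurface, scan: ScanConfig,
             fixed: Optional[dict] = None,
             fit_range: tuple[int, int] = (16, 32),
             exclude_zero_lag: Optional[bool] = None) -> RICSFitResult:
    """Nonlinear least-squares fit of the RICS model to a correlation surface.

    Free parameters are ``(D, G0, offset)``; passing ``fixed={"D": value}``
    instead frees the beam waist ``w0`` (calibration mode).  The zero-lag
    point carries uncorrelated shot noise for auto-correlations and is
    excluded by default there, but kept for cross-correlations where detector
    noise is independent between channels.  ``fit_range`` is
    ``(psi_max, xi_max)``.  Fits are started from several diffusion scales
    and the lowest-chi2 solution is kept.
    """
    fixed = dict(fixed or {})
    if exclude_zero_lag is None:
        exclude_zero_lag = acf.kind == "auto"
    pm = min(fit_range[0], acf.psi_lags.max())
    xm = min(fit_range[1], acf.xi_lags.max())
    sel_p = np.abs(acf.psi_lags) <= pm
    sel_x = np.abs(acf.xi_lags) <= xm
    psi_g, xi_g = np.meshgrid(acf.psi_lags[sel_p], acf.xi_lags[sel_x],
                              indexing="ij")
    data = acf.G[np.ix_(sel_p, sel_x)]
    mask = np.ones(data.shape, dtype=bool)
    if exclude_zero_lag:
        mask &= ~((psi_g == 0) & (xi_g == 0))

    calibrate = "D" in fixed
    g0_start = float(np.nanmax(np.where(mask, data, -np.inf)))
    if not np.isfinite(g0_start) or g0_start <= 0:
        g0_start = max(abs(float(data.mean())), 1e-6)
    off_start = float(np.median(data[np.abs(psi_g) >= max(pm - 2, 1)]))

    def residual(params: lmfit.Parameters) -> np.ndarray:
        model = rics_model(xi_g, psi_g, params["D"].value, params["G0"].value,
                           params["offset"].value, scan,
                           w0=params["w0"].value)
        return (model - data)[mask]

    best = None
    d_starts = (fixed["D"],) if calibrate else fixed.get("_d_starts", _D_STARTS)
    for d0 in d_starts:
        params = lmfit.Parameters()
        params.add("D", value=float(d0), min=0.0, max=1e4, vary=not calibrate)
        params.add("G0", value=g0_start,
                   min=1e-8 if acf.kind == "auto" else -np.inf)
        params.add("offset", value=off_start)
        params.add("w0", value=float(fixed.get("w0", scan.w0)),
                   min=scan.pixel_size / 2, max=100 * scan.w0, vary=calibrate)
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("RICS fit failed from every start point")

    p = best.params
    model_full = rics_model(xi_g, psi_g, p["D"].value, p["G0"].value,
                            p["offset"].value, scan, w0=p["w0"].value)
    return RICSFitResult(
        D=float(p["D"].value), G0=float(p["G0"].value),
        offset=float(p["offset"].value), w0=float(p["w0"].value),
        chi2=float(best.chisqr), converged=bool(best.success),
        residual=np.where(mask, data - model_full, np.nan),
        n_points=int(mask.sum()))


def calibrate_beam_waist(acf: ACFSurface, scan: ScanConfig,
                         D_known: float = 40.0,
                         fit_range: tuple[int, int] = (16, 32)) -> RICSFitResult:
    """Estimate the beam waist from a fast-diffusing calibration-dye series.

    Fits the RICS model with the diffusion coefficient fixed at the dye's
    known value (default 40 µm²/s) and the lateral waist ``w0`` free; the
    axial radius follows as ``AR * w0``.
    """
    if D_known <= 0:
        raise ValueError("calibration diffusion coefficient must be positive")
    return fit_rics(acf, scan, fixed={"D": float(D_known)}, fit_range=fit_range)


@dataclass
class InteractionResult:
    """ccRICS interaction index: fitted cross amplitude over the fitted
    auto amplitude of the reference channel."""

    G_cc: float
    G_ref: float
    index: float
    ma_window: int
    cross_fit: RICSFitResult = field(repr=False, default=None)
    ref_fit: RICSFitResult = field(repr=False, default=None)


def interaction_index(series1: ImageSeries, series2: ImageSeries,
                      M: int = 10, reference_channel: int = 2,
                      fit_range: tuple[int, int] = (16, 32),
                      max_lag: Optional[tuple[int, int]] = None,
                      ) -> InteractionResult:
    """Interaction index from a simultaneous two-channel acquisition.

    Both channels are detrended with an ``M``-frame moving average; the
    cross-correlation surface and the reference channel's auto-correlation
    surface are each fitted with the RICS model (diffusion free per surface)
    and the index is the ratio of fitted amplitudes ``G_cc / G_ref``.  The
    index is proportional to the fraction of reference-channel molecules
    co-diffusing with partner-channel complexes; it may be negative for
    anticorrelated channels.
    """
    if series1.scan != series2.scan:
        raise ValueError("channels were not acquired with the same scan")
    if reference_channel not in (1, 2):
        raise ValueError("reference_channel must be 1 or 2")
    scan = series1.scan
    d1 = moving_average_subtract(series1, M)
    d2 = moving_average_subtract(series2, M)
    ref = d2 if reference_channel == 2 else d1
    if max_lag is None:
        max_lag = (min(fit_range[0] + 4, scan.rows - 1),
                   min(fit_range[1] + 4, scan.cols - 1))
    acf_ref = spatial_acf(ref, max_lag=max_lag, ma_window=M)
    acf_cc = spatial_acf(d1, d2, max_lag=max_lag, ma_window=M)
    ref_fit = fit_rics(acf_ref, scan, fit_range=fit_range)
    cross_fit = fit_rics(acf_cc, scan, fit_range=fit_range)
    if ref_fit.G0 <= 0:
        raise ValueError("reference-channel amplitude is not positive; "
                         "interaction index undefined")
    index = cross_fit.G0 / ref_fit.G0
    return InteractionResult(G_cc=cross_fit.G0, G_ref=ref_fit.G0, index=index,
                             ma_window=M, cross_fit=cross_fit, ref_fit=ref_fit)
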