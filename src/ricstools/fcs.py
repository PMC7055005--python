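"""Fluorescence correlation spectroscopy: temporal autocorrelation of binned
photon traces and fitting with the standard 3D (anomalous) diffusion model

    G(t_c) = offset + sum_k A_k * [1 + (t_c/tau_xy_k)^alpha_k]^-1
                              * [1 + (t_c/tau_xy_k)^alpha_k / AR_k^2]^-1/2

where ``A_k`` is the amplitude of species k, ``tau_xy_k`` its lateral
diffusion time, ``alpha_k`` the anomalous-diffusion exponent and ``AR_k`` the
axial-to-lateral ratio of the observation volume.  The diffusion coefficient
follows from the calibrated beam waist as ``D = w0^2 / (4 tau_xy)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

from .geometry import PhotonTrace

__all__ = [
    "FCSModel",
    "FCSCurve",
    "temporal_acf",
    "fcs_model_eval",
    "fit_fcs",
    "FCSFitResult",
]


@dataclass
class FCSModel:
    """Parameters of the 3D diffusion correlation model (per species)."""

    A: tuple[float, ...]
    tau_xy: tuple[float, ...]
    alpha: tuple[float, ...]
    AR: tuple[float, ...]
    offset: float = 0.0

    def __post_init__(self) -> None:
        ns = len(self.A)
        if not (len(self.tau_xy) == len(self.alpha) == len(self.AR) == ns):
            raise ValueError("per-species parameter tuples differ in length")
        if any(a <= 0 for a in self.A) or any(t <= 0 for t in self.tau_xy):
            raise ValueError("amplitudes and diffusion times must be positive")
        if any(not 0 < al <= 2 for al in self.alpha):
            raise ValueError("anomaly exponents must lie in (0, 2]")
        if any(ar < 1 for ar in self.AR):
            raise ValueError("axial ratios must be >= 1")

    @property
    def n_species(self) -> int:
        return len(self.A)


@dataclass
class FCSCurve:
    """Autocorrelation curve G(t_c) at strictly increasing lag times (s)."""

    lags: np.ndarray
    G: np.ndarray
    n_pairs: np.ndarray = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G contains non-finite values")


def temporal_acf(trace: PhotonTrace | np.ndarray, max_lag: float = 1.0,
                 bin_width: Optional[float] = None) -> FCSCurve:
    """Linear-lag temporal autocorrelation of a binned photon trace.

    ``G(t_c) = <dI(t) dI(t+t_c)> / <I>^2`` averaged over all valid pairs,
    normalised by the full-trace mean; lag zero is excluded.
    """
    if isinstance(trace, PhotonTrace):
        counts = np.asarray(trace.counts, dtype=float)
        bw = trace.bin_width
    else:
        counts = np.asarray(trace, dtype=float)
        if bin_width is None:
            raise ValueError("bin_width required for a bare array")
        bw = bin_width
    n = counts.size
    if n < 100:
        raise ValueError("trace must contain at least 100 bins")
    if max_lag > n * bw / 4:
        raise ValueError("max_lag exceeds a quarter of the trace duration")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("trace has zero mean")
    d = counts - mean
    k_max = int(max_lag / bw)
    lags = np.arange(1, k_max + 1)
    G = np.array([np.mean(d[:-k] * d[k:]) for k in lags]) / mean ** 2
    return FCSCurve(lags=lags * bw, G=G, n_pairs=n - lags)


def fcs_model_eval(t_c: np.ndarray, model: FCSModel) -> np.ndarray:
    """Evaluate the 3D diffusion correlation model at lag times ``t_c``."""
    t_c = np.asarray(t_c, dtype=float)
    g = np.full(t_c.shape, model.offset, dtype=float)
    for A, tau, alpha, ar in zip(model.A, model.tau_xy, model.alpha, model.AR):
        x = (t_c / tau) ** alpha
        g = g + A / ((1.0 + x) * np.sqrt(1.0 + x / ar ** 2))
    return g


@dataclass
class FCSFitResult:
    """One-species FCS fit plus the derived diffusion coefficient."""

    model: FCSModel
    D: Optional[float]
    chi2: float
    converged: bool
    residual: np.ndarray = field(repr=False, default=None)


def _binned_model_eval(t_c: np.ndarray, model: FCSModel,
                       bin_width: float) -> np.ndarray:
    """Model smeared by the triangular kernel of bin-integrated intensity.

    Correlating counts integrated over bins of width ``Delta`` measures
    ``int (1-|u|/Delta) G(t+u) du / Delta`` rather than ``G(t)``; this matters
    when the diffusion time is comparable to the bin width.
    """
    nodes = np.linspace(-1.0, 1.0, 17)
    weights = 1.0 - np.abs(nodes)
    weights /= weights.sum()
    t = np.maximum(t_c[None, :] + bin_width * nodes[:, None], 0.0)
    return weights @ fcs_model_eval(t, model)


def fit_fcs(curve: FCSCurve, n_species: int = 1,
            fixed: Optional[dict] = None,
            w0: Optional[float] = None,
            bin_width: Optional[float] = None,
            refine_window: Optional[float] = 5.0) -> FCSFitResult:
    """Least-squares fit of the diffusion model to an autocorrelation curve.

    Defaults follow common one-photon practice: one species with the anomaly
    exponent fixed at 1 and the axial ratio fixed at 5 (``fixed={"alpha": 1,
    "AR": 5}``).  ``w0`` (µm), typically from the RICS calibration, converts
    the fitted lateral diffusion time to ``D = w0^2/(4 tau_xy)``; without it
    the diffusion coefficient is not reported.

    ``bin_width`` enables the triangular smearing correction for curves
    correlated from bin-integrated counts (important once ``tau_xy`` is within
    an order of magnitude of the bin).  After an initial fit over the full
    curve, the fit is repeated restricted to lags up to ``refine_window``
    fitted diffusion times (iterating until the window is stable, never below
    six lags): the power-law tail carries almost no diffusion information but
    its correlated noise tilts long-window fits, so confining the fit to the
    decaying part with a free offset removes that bias.  Pass
    ``refine_window=None`` to disable.
    """
    if n_species != 1:
        raise NotImplementedError("only the one-species model is implemented")
    fixed = {"alpha": 1.0, "AR": 5.0} if fixed is None else dict(fixed)

    def run(lags: np.ndarray, data: np.ndarray, tau0: float):
        params = lmfit.Parameters()
        a0 = max(float(data[: max(3, len(data) // 50)].mean()), 1e-6)
        params.add("A", value=a0, min=1e-12)
        params.add("tau_xy", value=tau0, min=lags[0] / 1000, max=lags[-1] * 100)
        params.add("alpha", value=float(fixed.get("alpha", 1.0)), min=0.05,
                   max=2.0, vary="alpha" not in fixed)
        params.add("AR", value=float(fixed.get("AR", 5.0)), min=1.0,
                   vary="AR" not in fixed)
        params.add("offset", value=0.0)

        def model_of(p: lmfit.Parameters) -> FCSModel:
            return FCSModel(A=(p["A"].value,), tau_xy=(p["tau_xy"].value,),
                            alpha=(p["alpha"].value,), AR=(p["AR"].value,),
                            offset=p["offset"].value)

        def residual(p: lmfit.Parameters) -> np.ndarray:
            m = model_of(p)
            pred = (_binned_model_eval(lags, m, bin_width) if bin_width
                    else fcs_model_eval(lags, m))
            return pred - data

        res = lmfit.minimize(residual, params, method="least_squares")
        return res, model_of(res.params)

    lags, data = curve.lags, curve.G
    a0 = float(data[: max(3, len(data) // 50)].mean())
    below = np.flatnonzero(data < a0 / 2)
    tau0 = float(lags[below[0]]) if below.size else float(lags[len(lags) // 2])
    res, model = run(lags, data, tau0)
    if refine_window is not None:
        full_lags, full_data = lags, data
        for _ in range(4):
            n_keep = int(np.searchsorted(full_lags,
                                         refine_window * model.tau_xy[0],
                                         side="right"))
            n_keep = max(n_keep, 6)
            if n_keep >= len(lags) and lags is full_lags:
                break
            if n_keep == len(lags):
                break
            lags, data = full_lags[:n_keep], full_data[:n_keep]
            res, model = run(lags, data, model.tau_xy[0])
    D = None if w0 is None else w0 ** 2 / (4.0 * model.tau_xy[0])
    pred = (_binned_model_eval(lags, model, bin_width) if bin_width
            else fcs_model_eval(lags, model))
    return FCSFitResult(model=model, D=D, chi2=float(res.chisqr),
                        converged=bool(res.success), residual=pred - data)
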