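"""Fluorescence decay after photoconversion (FDAP) trace analysis.

A photoconvertible tag is switched in a small strip at a cell boundary and
the converted (red) intensity inside the same strip is followed for a few
hundred frames.  Two models summarise the decay:

* reaction-dominant dissociation: ``I(t) = C + (1 - C) exp(-k_off t)``,
  with off-rate ``k_off`` (1/s) and immobile fraction ``C``;
* effective diffusion: the strip-averaged solution of 1-D free diffusion
  of a top-hat initial profile, parameterised by an apparent diffusion
  coefficient ``D_a`` (µm²/s).

Raw traces are first corrected for per-scan photobleaching by dividing by
``q**n`` (n = scan number after photoconversion); ``q`` is measured from a
chemically fixed, immobilized control with :class:`PhotobleachControlModel`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

from .gradient import FitError

__all__ = [
    "FDAPTrace",
    "BleachModel",
    "DissociationFit",
    "EffectiveDiffusionFit",
    "DissociationModel",
    "EffectiveDiffusionModel",
    "PhotobleachControlModel",
    "bleach_correct",
    "fit_bleach_control",
    "fit_dissociation",
    "fit_effective_diffusion",
    "goodness_of_fit",
    "strip_diffusion_decay",
]

DEFAULT_BLEACH_Q = 0.9991  # per-scan retention measured on fixed controls
DEFAULT_STRIP_HALFWIDTH = 0.83  # µm; photoconversion strip is 1.66 µm wide


@dataclass(frozen=True)
class FDAPTrace:
    """Normalized photoconverted-intensity time series.

    t          seconds since photoconversion, strictly increasing
    frame      scan index after photoconversion, starting at 1
    intensity  red fluorescence normalized to the first post-conversion frame
    meta       acquisition metadata (fps, strip geometry, corrections applied)
    """

    t: np.ndarray
    frame: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        frame = np.asarray(self.frame, dtype=int)
        inten = np.asarray(self.intensity, dtype=float)
        if not (t.shape == frame.shape == inten.shape) or t.ndim != 1:
            raise ValueError("t, frame and intensity must be equal-length 1-D arrays")
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("time axis must be strictly increasing")
        if frame.size and frame.min() < 1:
            raise ValueError("frames are indexed from 1 after photoconversion")
        if not np.isfinite(inten).all():
            raise ValueError("intensity contains non-finite values")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "frame", frame)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class BleachModel:
    """Per-scan retention factor q in (0, 1]: intensity loses (1-q) per scan."""

    q: float

    def __post_init__(self):
        if not 0 < self.q <= 1:
            raise ValueError(f"bleach factor q must be in (0, 1], got {self.q}")


@dataclass(frozen=True)
class DissociationFit:
    """Fitted dissociation kinetics of a bleach-corrected FDAP trace."""

    k_off: float
    C: float
    sse: float
    r2: float
    k_off_stderr: float
    C_stderr: float
    max_abs_residual: float
    frac_within_5pct: float
    frac_within_10pct: float
    k_off_identifiable: bool = True

    def predict(self, t) -> np.ndarray:
        return dissociation_decay(np.asarray(t, dtype=float), self.k_off, self.C)

    def summary(self) -> str:
        lines = [
            "Dissociation model fit: I(t) = C + (1 - C) exp(-k_off t)",
            f"  k_off (1/s)      : {self.k_off:.6g} +/- {self.k_off_stderr:.2g}"
            + ("" if self.k_off_identifiable else "   [not identifiable]"),
            f"  C (immobile)     : {self.C:.6g} +/- {self.C_stderr:.2g}",
            f"  SSE              : {self.sse:.6g}",
            f"  R^2              : {self.r2:.6f}",
            f"  max |residual|   : {self.max_abs_residual:.4f}",
            f"  within 0.05/0.10 : {self.frac_within_5pct:.1%} / {self.frac_within_10pct:.1%}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class EffectiveDiffusionFit:
    """Fitted apparent diffusion coefficient of a bleach-corrected trace."""

    D_a: float
    sse: float
    r2: float
    D_a_stderr: float
    C: float = 0.0
    halfwidth: float = DEFAULT_STRIP_HALFWIDTH

    def predict(self, t) -> np.ndarray:
        phi = strip_diffusion_decay(np.asarray(t, dtype=float), self.D_a, self.halfwidth)
        return self.C + (1.0 - self.C) * phi

    def summary(self) -> str:
        return "\n".join([
            "Effective-diffusion fit (strip-averaged 1-D top-hat decay)",
            f"  D_a (um^2/s) : {self.D_a:.6g} +/- {self.D_a_stderr:.2g}",
            f"  offset C     : {self.C:.6g}",
            f"  SSE          : {self.sse:.6g}",
            f"  R^2          : {self.r2:.6f}",
        ])


def dissociation_decay(t, k_off, C):
    return C + (1.0 - C) * np.exp(-k_off * t)


def strip_diffusion_decay(t, D_a, halfwidth):
    """Mean labelled concentration in the conversion strip under free 1-D diffusion.

    The photoconverted profile starts as a top-hat of half-width w and unit
    amplitude; free diffusion with coefficient D_a gives

        u(x, t) = 1/2 [erf((w - x)/s) + erf((w + x)/s)],  s = sqrt(4 D_a t),

    and averaging u over the readout strip [-w, w] (same rectangle as the
    conversion) yields the closed form

        I(t) = erf(2w/s) - s/(2 w sqrt(pi)) * (1 - exp(-4 w^2 / s^2)).

    I(0) = 1 and I -> 0 like 1/sqrt(t).
    """
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    if D_a <= 0:
        return out
    pos = t > 0
    s = np.sqrt(4.0 * D_a * t[pos])
    z = 2.0 * halfwidth / s
    out[pos] = erf(z) - (1.0 - np.exp(-z * z)) / (z * math.sqrt(math.pi))
    return out


# ----------------------------------------------------------------------


def bleach_correct(trace: FDAPTrace, model: BleachModel | float = DEFAULT_BLEACH_Q) -> FDAPTrace:
    """Divide intensity[n] by q**n (n = scan number after photoconversion)."""
    if not isinstance(model, BleachModel):
        model = BleachModel(q=float(model))
    corrected = trace.intensity / model.q ** trace.frame.astype(float)
    meta = dict(trace.meta)
    meta["bleach_corrected_q"] = model.q
    return FDAPTrace(t=trace.t, frame=trace.frame, intensity=corrected, meta=meta)


class PhotobleachControlModel:
    """Fits intensity[n] = q**n to an immobilized (fixed-sample) control trace."""

    def __init__(self, trace: FDAPTrace):
        self.trace = trace

    def fit(self, clip: bool = False) -> BleachModel:
        n = self.trace.frame.astype(float)
        y = self.trace.intensity
        popt, _ = curve_fit(lambda nn, q: q ** nn, n, y, p0=[0.999],
                            bounds=(1e-6, 1.5), maxfev=10000)
        q = float(popt[0])
        if q > 1.0:
            warnings.warn(f"fitted bleach factor q = {q:.6f} > 1 (increasing trace)",
                          stacklevel=2)
            if clip:
                q = 1.0
        return BleachModel(q=q)


def fit_bleach_control(trace: FDAPTrace, clip: bool = False) -> BleachModel:
    return PhotobleachControlModel(trace).fit(clip=clip)


class DissociationModel:
    """Reaction-dominant FDAP model I(t) = C + (1 - C) exp(-k_off t).

    The trace must be bleach-corrected and normalized so the model starts
    at 1.  ``fit()`` returns a :class:`DissociationFit` with parameter
    uncertainties and the residual-band diagnostics used to judge fit
    quality (fractions of residuals within 0.05 and 0.10).
    """

    #: below this fitted mobile amplitude (1 - C), k_off has no leverage
    _IDENTIFIABILITY_AMPLITUDE = 1e-3

    def __init__(self, trace: FDAPTrace):
        self.trace = trace

    def fit(self, p0: tuple[float, float] | None = None) -> DissociationFit:
        t, y = self.trace.t, self.trace.intensity
        if p0 is None:
            tail = float(np.median(y[-max(1, y.size // 10):]))
            p0 = (0.1, min(max(tail, 0.0), 1.0))
        try:
            popt, pcov = curve_fit(dissociation_decay, t, y, p0=p0,
                                   bounds=([0.0, 0.0], [np.inf, 1.0]),
                                   xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                   maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"dissociation fit did not converge: {exc}") from exc
        k_off, C = float(popt[0]), float(popt[1])
        pred = dissociation_decay(t, k_off, C)
        sse, r2, resid = goodness_of_fit(y, pred)
        err = np.sqrt(np.diag(pcov))
        identifiable = (1.0 - C) > self._IDENTIFIABILITY_AMPLITUDE
        abs_resid = np.abs(resid)
        return DissociationFit(
            k_off=k_off, C=C, sse=sse, r2=r2,
            k_off_stderr=float(err[0]), C_stderr=float(err[1]),
            max_abs_residual=float(abs_resid.max()),
            frac_within_5pct=float((abs_resid <= 0.05).mean()),
            frac_within_10pct=float((abs_resid <= 0.10).mean()),
            k_off_identifiable=identifiable,
        )


def fit_dissociation(trace: FDAPTrace, p0=None) -> DissociationFit:
    return DissociationModel(trace).fit(p0=p0)


class EffectiveDiffusionModel:
    """Apparent-diffusion FDAP model (see :func:`strip_diffusion_decay`).

    ``include_offset=True`` adds an immobile fraction:
    I(t) = C + (1 - C) * Phi(t; D_a).
    """

    def __init__(self, trace: FDAPTrace, halfwidth: float = DEFAULT_STRIP_HALFWIDTH,
                 include_offset: bool = False):
        if halfwidth <= 0:
            raise ValueError("strip halfwidth must be positive")
        self.trace = trace
        self.halfwidth = halfwidth
        self.include_offset = include_offset

    def fit(self, D0: float = 0.05) -> EffectiveDiffusionFit:
        t, y = self.trace.t, self.trace.intensity
        if y[-1] >= y[0]:
            raise FitError("trace does not decay; cannot fit a diffusion model")
        w = self.halfwidth
        if self.include_offset:
            def model(tt, D_a, C):
                return C + (1.0 - C) * strip_diffusion_decay(tt, D_a, w)
            p0, bounds = [D0, 0.0], ([1e-12, 0.0], [np.inf, 1.0])
        else:
            def model(tt, D_a):
                return strip_diffusion_decay(tt, D_a, w)
            p0, bounds = [D0], (1e-12, np.inf)
        try:
            popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"effective-diffusion fit did not converge: {exc}") from exc
        D_a = float(popt[0])
        C = float(popt[1]) if self.include_offset else 0.0
        pred = model(t, *popt)
        sse, r2, _ = goodness_of_fit(y, pred)
        err = np.sqrt(np.diag(pcov))
        return EffectiveDiffusionFit(D_a=D_a, sse=sse, r2=r2,
                                     D_a_stderr=float(err[0]), C=C, halfwidth=w)


def fit_effective_diffusion(trace: FDAPTrace,
                            strip_halfwidth: float = DEFAULT_STRIP_HALFWIDTH,
                            include_offset: bool = False,
                            D0: float = 0.05) -> EffectiveDiffusionFit:
    return EffectiveDiffusionModel(trace, strip_halfwidth, include_offset).fit(D0=D0)


def goodness_of_fit(observed, predicted):
    """(SSE, R^2, residuals) with R^2 = 1 - SSE / SST about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    resid = obs - pred
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return sse, r2, resid
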