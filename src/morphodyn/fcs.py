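"""Fluorescence correlation spectroscopy (FCS) curve modelling and fitting.

Intensity fluctuations of fluorophores diffusing through a 3-D Gaussian
confocal volume are summarised by the autocorrelation function

    G(tau) = 1 + (1/N) * T(tau) * sum_i F_i (1 + tau/tau_i)^-1
                                        * (1 + tau/(S^2 tau_i))^-1/2

with particle number ``N`` (NoP), diffusion times ``tau_i``, fast fraction
``F_fast`` for the two-component model, structure parameter ``S = z0/w0``
and an optional triplet (dark-state blinking) factor
``T(tau) = 1 + T_trip/(1 - T_trip) * exp(-tau/tau_trip)``.

Models: one diffusing component ("T + 3D") or two ("T + 3D + 3D"),
compared with the least-squares Akaike information criterion
``AIC = n ln(SSE/n) + 2k``.  Diffusion times convert to coefficients via
``D = w0^2 / (4 tau_D)`` after calibrating ``w0`` on a dye of known D
(Rhodamine 6G, 280 µm²/s).

A hand-rolled multi-tau correlator (:func:`autocorrelate`) turns raw photon
traces into correlation curves with logarithmically spaced lags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .gradient import FitError

__all__ = [
    "ConfocalVolume",
    "FCSParams",
    "CorrelationCurve",
    "FCSFit",
    "FCSModel",
    "g_model",
    "fit_fcs",
    "select_model",
    "qc_filter",
    "calibrate_volume",
    "autocorrelate",
    "DETECTION_VOLUMES",
]

DEFAULT_S = 5.0


@dataclass(frozen=True)
class ConfocalVolume:
    """Gaussian detection volume: lateral 1/e^2 radius w0 and S = z0/w0."""

    w0: float
    S: float = DEFAULT_S

    def __post_init__(self):
        if self.w0 <= 0 or self.S <= 0:
            raise ValueError("w0 and S must be positive")

    @property
    def z0(self) -> float:
        return self.S * self.w0

    @property
    def v_eff(self) -> float:
        """Effective volume pi^(3/2) w0^2 z0 in µm^3 (= femtoliters)."""
        return math.pi ** 1.5 * self.w0 ** 2 * self.z0

    @classmethod
    def from_veff(cls, v_eff: float, S: float = DEFAULT_S) -> "ConfocalVolume":
        w0 = (v_eff / (math.pi ** 1.5 * S)) ** (1.0 / 3.0)
        return cls(w0=w0, S=S)

    def tau_d(self, D: float) -> float:
        return self.w0 ** 2 / (4.0 * D)

    def diffusion_coefficient(self, tau_d: float) -> float:
        return self.w0 ** 2 / (4.0 * tau_d)


#: instrument presets: effective detection volumes in fl
DETECTION_VOLUMES = {"leica": 0.3, "zeiss": 0.12}


@dataclass(frozen=True)
class FCSParams:
    """Parameters of the triplet + 3-D diffusion autocorrelation model."""

    N: float
    tau_fast: float
    tau_slow: float | None = None
    F_fast: float = 1.0
    T_trip: float = 0.0
    tau_trip: float = 1e-5
    model: str = "one_component"

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not 0 <= self.F_fast <= 1:
            raise ValueError("F_fast must be in [0, 1]")
        if not 0 <= self.T_trip < 1:
            raise ValueError("T_trip must be in [0, 1)")
        if self.model == "two_component":
            if self.tau_slow is None:
                raise ValueError("two_component model needs tau_slow")
            if not self.tau_fast < self.tau_slow:
                raise ValueError("tau_fast must be smaller than tau_slow")
        elif self.model != "one_component":
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def k_free(self) -> int:
        """Number of free parameters when fitted."""
        k = 2 if self.model == "one_component" else 4
        if self.T_trip > 0:
            k += 2
        return k


@dataclass(frozen=True)
class CorrelationCurve:
    """Lag times (s) and autocorrelation values, optionally with per-lag SDs."""

    tau: np.ndarray
    G: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        G = np.asarray(self.G, dtype=float)
        if tau.shape != G.shape or tau.ndim != 1:
            raise ValueError("tau and G must be equal-length 1-D arrays")
        if (tau <= 0).any() or (np.diff(tau) <= 0).any():
            raise ValueError("tau must be positive and strictly increasing")
        if not np.isfinite(G).all():
            raise ValueError("G contains non-finite values")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "G", G)


@dataclass(frozen=True)
class FCSFit:
    """Fitted FCS parameters with AIC and quality-control status."""

    params: FCSParams
    D_fast: float
    D_slow: float | None
    aic: float
    sse: float
    r2: float
    n_lags: int
    curve: CorrelationCurve
    volume: ConfocalVolume
    baseline: float = 0.0
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def delta_g0(self) -> float:
        """Fitted fluctuation amplitude 1/N."""
        return 1.0 / self.params.N

    def concentration(self) -> float:
        """Particles per µm^3 implied by N and the detection volume."""
        return self.params.N / self.volume.v_eff

    def summary(self) -> str:
        p = self.params
        lines = [
            f"FCS fit: {'T+3D' if p.model == 'one_component' else 'T+3D+3D'}",
            f"  N (NoP)        : {p.N:.4g}",
            f"  D_fast (um2/s) : {self.D_fast:.4g}  (tau = {p.tau_fast:.3g} s)",
        ]
        if p.model == "two_component":
            lines += [
                f"  D_slow (um2/s) : {self.D_slow:.4g}  (tau = {p.tau_slow:.3g} s)",
                f"  F_fast         : {p.F_fast:.4g}",
            ]
        if p.T_trip > 0:
            lines.append(f"  triplet        : T = {p.T_trip:.3g}, tau = {p.tau_trip:.3g} s")
        lines += [
            f"  SSE            : {self.sse:.4g}",
            f"  R^2            : {self.r2:.6f}",
            f"  AIC            : {self.aic:.2f}",
        ]
        if self.excluded:
            lines.append(f"  EXCLUDED       : {self.exclusion_reason}")
        return "\n".join(lines)


# ----------------------------------------------------------------------


def g_model(tau, params: FCSParams, vol: ConfocalVolume | None = None) -> np.ndarray:
    """Autocorrelation model G(tau) for the given parameters.

    The structure parameter is taken from ``vol`` (default S = 5).  The
    confocal volume affects only the tau_D <-> D conversion, never the curve
    shape beyond S.
    """
    tau = np.asarray(tau, dtype=float)
    S = (vol.S if vol is not None else DEFAULT_S)
    if params.T_trip >= 1.0:
        raise ValueError("T_trip = 1 leaves no fluorescent population")

    def comp(tau_d):
        return 1.0 / ((1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (S * S * tau_d)))

    if params.model == "one_component":
        diff = comp(params.tau_fast)
    else:
        diff = params.F_fast * comp(params.tau_fast) \
            + (1.0 - params.F_fast) * comp(params.tau_slow)
    trip = 1.0
    if params.T_trip > 0:
        trip = 1.0 + params.T_trip / (1.0 - params.T_trip) * np.exp(-tau / params.tau_trip)
    return 1.0 + diff * trip / params.N


# parameter bounds used by the fitter (log10 space for N and taus)
_BOUNDS = {
    "N": (1e-3, 1e4),
    "tau": (1e-6, 1.0),
    "T_trip": (0.0, 0.5),
    "tau_trip": (1e-6, 1e-2),
}


class FCSModel:
    """Weighted least-squares FCS model fit with seeded multi-start.

    Parameters
    ----------
    curve : CorrelationCurve
    model : {"one_component", "two_component"}
    vol : ConfocalVolume, optional
        Calibrated detection geometry; defaults to the Zeiss preset.
    fit_triplet : bool
        Free the triplet fraction and relaxation time.
    fit_baseline : bool
        Free an additive long-lag baseline offset.  Useful for finite
        ensembles: a correlation curve measured on a closed system with M
        particles converges to 1 - 1/M rather than 1 at long lags, and real
        instruments drift similarly; fitting the baseline removes the bias
        this constant puts on the diffusion time.
    """

    def __init__(self, curve: CorrelationCurve, model: str = "one_component",
                 vol: ConfocalVolume | None = None, fit_triplet: bool = False,
                 fit_baseline: bool = False,
                 lag_range: tuple[float, float] | None = None):
        if model not in ("one_component", "two_component"):
            raise ValueError(f"unknown model {model!r}")
        if lag_range is not None:
            keep = (curve.tau >= lag_range[0]) & (curve.tau <= lag_range[1])
            curve = CorrelationCurve(
                tau=curve.tau[keep], G=curve.G[keep],
                weights=None if curve.weights is None else curve.weights[keep])
        if curve.tau.size < 10:
            raise ValueError("need at least 10 lag points")
        self.curve = curve
        self.model = model
        self.vol = vol if vol is not None else ConfocalVolume.from_veff(
            DETECTION_VOLUMES["zeiss"], DEFAULT_S)
        self.fit_triplet = fit_triplet
        self.fit_baseline = fit_baseline

    # --- parameter vector <-> FCSParams ------------------------------
    def _unpack(self, theta):
        i = 0
        N = 10.0 ** theta[i]; i += 1
        tau_fast = 10.0 ** theta[i]; i += 1
        tau_slow, F_fast = None, 1.0
        if self.model == "two_component":
            tau_slow = 10.0 ** theta[i]; i += 1
            F_fast = theta[i]; i += 1
            if tau_slow < tau_fast:  # keep the labels sorted
                tau_fast, tau_slow = tau_slow, tau_fast
                F_fast = 1.0 - F_fast
        T_trip, tau_trip = 0.0, 1e-5
        if self.fit_triplet:
            T_trip = theta[i]; i += 1
            tau_trip = 10.0 ** theta[i]; i += 1
        baseline = theta[i] if self.fit_baseline else 0.0
        params = FCSParams(N=N, tau_fast=tau_fast, tau_slow=tau_slow,
                           F_fast=min(max(F_fast, 0.0), 1.0),
                           T_trip=T_trip, tau_trip=tau_trip, model=self.model)
        return params, baseline

    def _bounds(self):
        lo = [math.log10(_BOUNDS["N"][0]), math.log10(_BOUNDS["tau"][0])]
        hi = [math.log10(_BOUNDS["N"][1]), math.log10(_BOUNDS["tau"][1])]
        if self.model == "two_component":
            lo += [math.log10(_BOUNDS["tau"][0]), 0.0]
            hi += [math.log10(_BOUNDS["tau"][1]), 1.0]
        if self.fit_triplet:
            lo += [_BOUNDS["T_trip"][0], math.log10(_BOUNDS["tau_trip"][0])]
            hi += [_BOUNDS["T_trip"][1], math.log10(_BOUNDS["tau_trip"][1])]
        if self.fit_baseline:
            lo += [-0.2]
            hi += [0.2]
        return np.array(lo), np.array(hi)

    def _heuristic_start(self):
        tau, G = self.curve.tau, self.curve.G
        amp = max(G[0] - 1.0, 1e-6)
        N0 = 1.0 / amp
        # half-decay lag as tau_fast guess
        target = 1.0 + amp / 2.0
        below = np.nonzero(G <= target)[0]
        tau_half = tau[below[0]] if below.size else tau[tau.size // 2]
        start = [math.log10(N0), math.log10(tau_half)]
        if self.model == "two_component":
            start += [math.log10(min(tau_half * 100.0, 0.5)), 0.5]
        if self.fit_triplet:
            start += [0.1, -4.0]
        if self.fit_baseline:
            start += [0.0]
        return np.array(start)

    def _residuals(self, theta):
        params, baseline = self._unpack(theta)
        resid = g_model(self.curve.tau, params, self.vol) + baseline - self.curve.G
        if self.curve.weights is not None:
            resid = resid / self.curve.weights
        return resid

    def fit(self, n_starts: int = 8, seed: int = 0) -> FCSFit:
        """Fit from ``n_starts`` seeded random starts plus a heuristic one.

        Raises :class:`FitError` when no start converges or the curve has no
        fluctuation amplitude.
        """
        if self.curve.G.max() - 1.0 <= 1e-12:
            raise FitError("curve has no fluctuation amplitude (G = 1); N unbounded")
        lo, hi = self._bounds()
        rng = np.random.default_rng(seed)
        starts = [self._heuristic_start()]
        for _ in range(n_starts):
            starts.append(lo + (hi - lo) * rng.random(lo.size))
        starts = [np.clip(s, lo + 1e-9, hi - 1e-9) for s in starts]

        best = None
        for s in starts:
            try:
                sol = least_squares(self._residuals, s, bounds=(lo, hi),
                                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                    max_nfev=5000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("FCS fit failed from all starts")

        params, baseline = self._unpack(best.x)
        pred = g_model(self.curve.tau, params, self.vol) + baseline
        resid = pred - self.curve.G
        sse = float(np.sum(resid ** 2))
        sst = float(np.sum((self.curve.G - self.curve.G.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        n = self.curve.tau.size
        k = lo.size  # free parameters actually fitted
        aic = n * math.log(max(sse, 1e-300) / n) + 2 * k
        D_fast = self.vol.diffusion_coefficient(params.tau_fast)
        D_slow = (self.vol.diffusion_coefficient(params.tau_slow)
                  if params.tau_slow else None)
        return FCSFit(params=params, D_fast=D_fast, D_slow=D_slow, aic=aic,
                      sse=sse, r2=r2, n_lags=n, curve=self.curve,
                      volume=self.vol, baseline=float(baseline))


def fit_fcs(curve: CorrelationCurve, model: str = "one_component",
            vol: ConfocalVolume | None = None, fit_triplet: bool = False,
            fit_baseline: bool = False, n_starts: int = 8, seed: int = 0) -> FCSFit:
    return FCSModel(curve, model, vol, fit_triplet, fit_baseline).fit(
        n_starts=n_starts, seed=seed)


def select_model(fit_1: FCSFit, fit_2: FCSFit) -> FCSFit:
    """Pick the fit with the lower AIC; ties go to the simpler model."""
    if fit_1.curve.tau.shape != fit_2.curve.tau.shape or \
            not np.allclose(fit_1.curve.tau, fit_2.curve.tau):
        raise ValueError("fits were made on different curves")
    if fit_1.aic == fit_2.aic:
        return fit_1 if fit_1.params.k_free <= fit_2.params.k_free else fit_2
    return fit_1 if fit_1.aic < fit_2.aic else fit_2


def qc_filter(fits, d_max: float = 80.0, d_ratio_min: float = 3.0):
    """Quality filter on fitted curves.

    Excludes fits with D_fast above ``d_max`` (µm²/s; dark-state blinking
    masquerading as ultrafast diffusion) and two-component fits whose
    components are degenerate (D_fast / D_slow below ``d_ratio_min``), which
    makes F_fast meaningless.  Returns ``(kept, excluded)`` where excluded
    fits carry their reason.
    """
    kept, excluded = [], []
    for f in fits:
        reason = None
        if f.D_fast > d_max:
            reason = f"D_fast over threshold ({f.D_fast:.3g} > {d_max} um2/s)"
        elif f.params.model == "two_component" and f.D_slow:
            if f.D_fast / f.D_slow < d_ratio_min:
                reason = ("degenerate components: D_fast/D_slow = "
                          f"{f.D_fast / f.D_slow:.3g} < {d_ratio_min}")
        if reason is None:
            kept.append(f)
        else:
            excluded.append(replace(f, excluded=True, exclusion_reason=reason))
    return kept, excluded


def calibrate_volume(tau_D_ref: float, D_ref: float = 280.0,
                     S: float = DEFAULT_S) -> ConfocalVolume:
    """Detection geometry from a calibration dye's diffusion time.

    Rhodamine 6G (D = 280 µm²/s) is the usual standard: measure its tau_D,
    then w0 = sqrt(4 D_ref tau_D_ref) and V_eff = pi^(3/2) w0^3 S.
    """
    if tau_D_ref <= 0 or D_ref <= 0 or S <= 0:
        raise ValueError("calibration inputs must be positive")
    w0 = math.sqrt(4.0 * D_ref * tau_D_ref)
    return ConfocalVolume(w0=w0, S=S)


# ----------------------------------------------------------------------
# Multi-tau correlator


def _mt_estimate(y: np.ndarray, k: int) -> float:
    """Symmetric-normalized autocorrelation of y at integer lag k."""
    left = y[:-k]
    right = y[k:]
    ml, mr = left.mean(), right.mean()
    return float(np.dot(left, right) / left.size / (ml * mr))


def _multi_tau_single(y: np.ndarray, dt: float, m: int):
    taus, gs = [], []
    # level 0: lags 1 .. 2m on the raw signal
    for k in range(1, 2 * m + 1):
        taus.append(k * dt)
        gs.append(_mt_estimate(y, k))
    level = 1
    cur = y
    while True:
        if cur.size % 2:
            cur = cur[:-1]
        cur = 0.5 * (cur[::2] + cur[1::2])
        if cur.size < 2 * m + 1:
            break
        spacing = dt * (2 ** level)
        for k in range(m + 1, 2 * m + 1):
            taus.append(k * spacing)
            gs.append(_mt_estimate(cur, k))
        level += 1
    return np.array(taus), np.array(gs)


def autocorrelate(trace, dt: float, m: int = 16, n_segments: int = 1) -> CorrelationCurve:
    """Multi-tau autocorrelation of an intensity trace.

    Estimator (symmetric normalization)::

        G(tau) = <I(t) I(t+tau)> / (<I>_left <I>_right)

    where the means run over the overlapping windows.  Lags are logarithmic:
    the first 2m lags at the raw sampling interval, then for each further
    octave the signal is block-averaged by 2 and lags m+1..2m of the binned
    signal are used, until the binned trace is shorter than 2m+1 samples.
    A constant trace has zero fluctuation and yields G = 1 at every lag.

    With ``n_segments > 1`` the trace is split into equal segments, the
    correlation is averaged across them and the per-lag standard error is
    stored as fit weights — the usual way instruments tame the large
    long-lag variance of a single estimate.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or y.size < 2 * m + 2:
        raise ValueError("trace too short for the requested channel count")
    if y.mean() == 0:
        raise ValueError("zero-mean trace cannot be normalized")
    if n_segments <= 1:
        taus, gs = _multi_tau_single(y, dt, m)
        return CorrelationCurve(tau=taus, G=gs)
    seg_len = y.size // n_segments
    if seg_len < 2 * m + 2:
        raise ValueError("segments too short for the requested channel count")
    curves = [_multi_tau_single(y[i * seg_len:(i + 1) * seg_len], dt, m)
              for i in range(n_segments)]
    taus = curves[0][0]
    stack = np.vstack([g for _, g in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) / math.sqrt(n_segments)
    sd = np.maximum(sd, 1e-12)
    return CorrelationCurve(tau=taus, G=mean, weights=sd)
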