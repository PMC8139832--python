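"""Seeded synthetic-data generators emulating the microscope.

Every analysis stage in this package can be exercised without external data:

* :func:`gen_fdap_trace` / :func:`gen_fixed_control` — photoconversion
  decays at 25 frames/s for 400 frames with per-scan photobleaching and
  additive Gaussian noise, plus the bleaching-only immobilized control;
* :func:`gen_brownian_fcs` — photon-count traces from point emitters
  random-walking through a periodic box and detected by a 3-D Gaussian
  confocal volume, with Poisson photon noise, one or two diffusing species
  and optional triplet (dark-state) blinking;
* :func:`gen_noisy_gradient` — multiplicative lognormal noise on bound-peak
  series for decay-length robustness studies.

All randomness flows through :class:`RNGSpec`: the same (seed, stream)
always yields bit-identical output (PCG64 with a fixed spawning scheme).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .fdap import FDAPTrace
from .gradient import Peak

__all__ = [
    "RNGSpec",
    "BrownianSimConfig",
    "BrownianTrace",
    "gen_fdap_trace",
    "gen_fixed_control",
    "gen_brownian_fcs",
    "gen_noisy_gradient",
]


@dataclass(frozen=True)
class RNGSpec:
    """Reproducible random stream: a seed plus a named sub-stream."""

    seed: int
    stream: str = "default"

    def rng(self) -> np.random.Generator:
        # stream label -> stable integer via CRC32 so streams never collide
        # across generators sharing one seed
        key = zlib.crc32(self.stream.encode())
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), key]))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, RNGSpec):
        return rng.rng()
    if isinstance(rng, np.random.Generator):
        return rng
    return RNGSpec(int(rng)).rng()


# ----------------------------------------------------------------------
# FDAP


def gen_fdap_trace(k_off: float, C: float, q: float = 0.9991,
                   fps: float = 25.0, n_frames: int = 400,
                   noise_sd: float = 0.02, rng=0) -> FDAPTrace:
    """Synthetic photoconversion decay with bleaching and additive noise.

    intensity[n] = (C + (1 - C) exp(-k_off n/fps)) * q**n + Normal(0, noise_sd)

    for scan n = 1..n_frames.  Defaults mirror the acquisition protocol the
    analyses assume (25 frames/s, 400 frames = 16 s) and a noise level that
    leaves dissociation-fit residuals mostly within 0.05.
    """
    rng = _as_rng(rng)
    n = np.arange(1, n_frames + 1)
    t = n / fps
    clean = (C + (1.0 - C) * np.exp(-k_off * t)) * q ** n
    noise = rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else 0.0
    return FDAPTrace(t=t, frame=n, intensity=clean + noise,
                     meta={"fps": fps, "q_true": q, "k_off_true": k_off,
                           "C_true": C, "noise_sd": noise_sd})


def gen_fixed_control(q: float = 0.9991, fps: float = 25.0, n_frames: int = 400,
                      noise_sd: float = 0.01, rng=0) -> FDAPTrace:
    """Immobilized (fixed-sample) control: pure q**n bleaching plus noise."""
    rng = _as_rng(rng)
    n = np.arange(1, n_frames + 1)
    clean = q ** n.astype(float)
    noise = rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else 0.0
    return FDAPTrace(t=n / fps, frame=n, intensity=clean + noise,
                     meta={"fps": fps, "q_true": q, "fixed_control": True,
                           "noise_sd": noise_sd})


# ----------------------------------------------------------------------
# Brownian-dynamics FCS traces


@dataclass(frozen=True)
class BrownianSimConfig:
    """Brownian photon-trace simulation settings.

    n_particles  total emitters in the periodic box
    D_values     one or two diffusion coefficients (µm²/s)
    fractions    per-species number fractions (must sum to 1)
    box          lateral periodic box edge (µm); at least 6 w0.  The axial
                 edge is S times larger, mirroring the elongation of the
                 detection volume — a cube of lateral size would let
                 particles wrap through the Gaussian axially and bias both
                 the amplitude and the decay of the correlation
    w0, S        Gaussian detection geometry (lateral radius µm, z0/w0)
    brightness   expected photons per particle per second at volume centre
    dt           sampling interval (s); must resolve the fastest tau_D
    duration     trace length (s)
    triplet      optional (T_trip, tau_trip) dark-state blinking
    """

    n_particles: int = 228
    D_values: tuple = (20.0,)
    fractions: tuple = (1.0,)
    box: float = 1.5
    w0: float = 0.2
    S: float = 5.0
    brightness: float = 3.0e5
    dt: float = 2.5e-5
    duration: float = 10.0
    triplet: tuple | None = None

    def __post_init__(self):
        if len(self.D_values) != len(self.fractions):
            raise ValueError("need one fraction per species")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.box < 6.0 * self.w0 - 1e-12:
            raise ValueError("box edge must be at least 6 w0")
        d_max = max(self.D_values)
        if d_max > 0:
            tau_fast = self.w0 ** 2 / (4.0 * d_max)
            if self.dt > tau_fast / 10.0:
                raise ValueError(
                    f"dt = {self.dt} too coarse: fastest tau_D = {tau_fast:.3g} s "
                    "requires dt <= tau_D/10"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def box_edges(self) -> tuple[float, float, float]:
        return (self.box, self.box, self.S * self.box)

    @property
    def box_volume(self) -> float:
        ex, ey, ez = self.box_edges
        return ex * ey * ez

    def mean_occupancy(self) -> float:
        """Expected particle count in V_eff = pi^(3/2) w0^3 S."""
        v_eff = math.pi ** 1.5 * self.w0 ** 3 * self.S
        return self.n_particles / self.box_volume * v_eff


@dataclass(frozen=True)
class BrownianTrace:
    """Photon counts per sampling interval plus the generating config."""

    counts: np.ndarray
    dt: float
    config: BrownianSimConfig


def _species_counts(cfg: BrownianSimConfig) -> list[int]:
    counts = [int(round(f * cfg.n_particles)) for f in cfg.fractions]
    counts[-1] = cfg.n_particles - sum(counts[:-1])
    return counts


def gen_brownian_fcs(cfg: BrownianSimConfig, rng=0) -> BrownianTrace:
    """Simulate a photon-count trace from diffusing point emitters.

    Particles take Normal(0, sqrt(2 D dt)) steps per axis in a periodic cube
    centred on the detection volume.  Expected photons per interval are
    brightness * dt * exp(-2 r_lat^2/w0^2 - 2 z^2/z0^2) summed over emitters;
    recorded counts are Poisson draws.  Triplet blinking, when configured, is
    an independent two-state telegraph process per particle with equilibrium
    dark fraction T_trip and relaxation time tau_trip.
    """
    rng = _as_rng(rng)
    n_steps = cfg.n_samples
    w0, z0 = cfg.w0, cfg.S * cfg.w0
    edges = np.array(cfg.box_edges)
    half = edges / 2.0

    # per-particle step SD by species
    sp_counts = _species_counts(cfg)
    sigmas = np.repeat([math.sqrt(2.0 * D * cfg.dt) for D in cfg.D_values], sp_counts)

    pos = rng.uniform(-half, half, size=(cfg.n_particles, 3))

    # triplet telegraph rates: equilibrium dark fraction T, correlation
    # time tau => k_dark = T/tau, k_bright = (1-T)/tau
    use_trip = cfg.triplet is not None
    if use_trip:
        T_trip, tau_trip = cfg.triplet
        p_to_dark = 1.0 - math.exp(-(T_trip / tau_trip) * cfg.dt)
        p_to_bright = 1.0 - math.exp(-((1.0 - T_trip) / tau_trip) * cfg.dt)
        bright = rng.random(cfg.n_particles) >= T_trip

    amp = cfg.brightness * cfg.dt
    counts = np.empty(n_steps, dtype=np.int64)
    chunk = 20000
    done = 0
    while done < n_steps:
        n_c = min(chunk, n_steps - done)
        steps = rng.normal(0.0, 1.0, size=(n_c, cfg.n_particles, 3)) * sigmas[None, :, None]
        traj = pos + np.cumsum(steps, axis=0)
        traj = (traj + half) % edges - half  # periodic wrap
        pos = traj[-1]
        lat2 = traj[:, :, 0] ** 2 + traj[:, :, 1] ** 2
        z2 = traj[:, :, 2] ** 2
        psf = np.exp(-2.0 * lat2 / w0 ** 2 - 2.0 * z2 / z0 ** 2)
        if use_trip:
            states = np.empty((n_c, cfg.n_particles), dtype=bool)
            for i in range(n_c):
                r = rng.random(cfg.n_particles)
                bright = np.where(bright, r >= p_to_dark, r < p_to_bright)
                states[i] = bright
            psf = psf * states
        expected = amp * psf.sum(axis=1)
        counts[done:done + n_c] = rng.poisson(expected)
        done += n_c
    return BrownianTrace(counts=counts.astype(float), dt=cfg.dt, config=cfg)


# ----------------------------------------------------------------------
# Gradient peaks


def gen_noisy_gradient(peaks: list[Peak], noise_sd: float, rng=0) -> list[Peak]:
    """Multiplicative lognormal noise on peak values (noise_sd ~ fractional SD)."""
    rng = _as_rng(rng)
    if noise_sd <= 0:
        return list(peaks)
    factors = np.exp(rng.normal(0.0, noise_sd, size=len(peaks)))
    return [Peak(p.site_index, p.x_peak, p.v_peak * f)
            for p, f in zip(peaks, factors)]
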