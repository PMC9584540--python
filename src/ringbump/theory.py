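"""Closed-form and semi-analytic predictions for multi-bump ring attractors.

For the cosine inhibitory kernel the Fourier transform W-tilde(q) has a
closed form whose maximizer selects the bump spacing (lambda = 2.28 l).  The
baseline bump profile is a truncated cosine g(x) = a cos(kappa x) + d whose
parameters follow from a single transcendental equation in psi = kappa z,
where z is the half-width at which g crosses zero.  From a baseline profile
(taken from a noiseless, driveless simulation) we predict the four dynamical
quantities: the path-integration velocity v_drive under a drive b, the
diffusion coefficients D_input and D_spike under fast noise, and the drift
field v_conn(theta) produced by quenched connectivity noise, together with
the escape drive and the speed-irregularity statistics that follow from it.

All network-distance integrals are discrete sums over lattice sites and all
derivatives are central differences on the ring; the ReLU identities
phi' phi' = phi' and phi' phi = phi let every formula be evaluated from the
baseline synaptic inputs g alone.  Velocities are reported in neurons/s
(degrees/s under circular mapping) and diffusion coefficients in neurons^2/s
(deg^2/s); the neural time constant tau is in ms, hence the factors of 1000.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np
from scipy import optimize

from .model import Connectivity, ModelConfig, activation, activation_prime

_MS_PER_S = 1000.0


class TheoryError(RuntimeError):
    """Raised when a prediction is requested outside the model's validity."""


# -- kernel spectrum and wavelength selection --------------------------------


def kernel_fourier(config: ModelConfig, q) -> np.ndarray:
    """Continuous Fourier transform of the cosine kernel.

    W-tilde(q) = -w k^2 sin(2 pi q / k) / (k^2 q - q^3) with k = pi / l.
    The removable singularities at q = 0 (value -2 pi w / k) and q = +-k
    (value pi w / k by l'Hopital) are handled explicitly.
    """
    k = np.pi / config.l
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    out = np.empty_like(q)
    eps = 1e-9 * k
    near0 = np.abs(q) < eps
    neark = np.abs(np.abs(q) - k) < eps
    regular = ~(near0 | neark)
    qr = q[regular]
    out[regular] = -config.w * k**2 * np.sin(2 * np.pi * qr / k) / (k**2 * qr - qr**3)
    # q -> 0: sin(2 pi q/k) ~ 2 pi q / k, denominator ~ k^2 q.
    out[near0] = -2.0 * np.pi * config.w / k
    # q -> k: l'Hopital gives -2 pi w k cos(2 pi) / (k^2 - 3 k^2) = pi w / k.
    out[neark] = np.pi * config.w / k
    return out[0] if scalar else out


def preferred_wavenumber(config: ModelConfig) -> float:
    """Wavenumber q* > 0 maximizing W-tilde(q)."""
    k = np.pi / config.l
    grid = np.linspace(0.05 * k, 3.0 * k, 4096)
    vals = kernel_fourier(config, grid)
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda q: -kernel_fourier(config, q), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise TheoryError(f"wavenumber optimizer failed in bracket ({lo}, {hi})")
    return float(res.x)


def preferred_wavelength(config: ModelConfig) -> float:
    """Bump distance selected by the kernel: 2 pi / argmax_q W-tilde(q) ~ 2.28 l."""
    return 2.0 * np.pi / preferred_wavenumber(config)


def growth_rate(config: ModelConfig, q, phi_prime_g0: float = 1.0) -> np.ndarray:
    """Linear growth rate r(q) = (2 phi'[g0] W-tilde(q) - 1) / tau in 1/ms."""
    return (2.0 * phi_prime_g0 * kernel_fourier(config, q) - 1.0) / config.tau


# -- baseline bump shape -----------------------------------------------------


@dataclasses.dataclass
class TheoryBumpShape:
    """Closed-form baseline profile g(x) = a cos(kappa x) + d (bump at x0 = 0)."""

    lam: float
    kappa: float
    z: float
    psi: float
    G: float
    a: float
    d: float
    profile: Callable[[np.ndarray], np.ndarray]


def bump_shape(config: ModelConfig, lam: Optional[float] = None) -> TheoryBumpShape:
    """Solve for the baseline bump profile at bump distance lam (default N/M).

    psi = kappa z obeys psi - cos(psi) sin(psi) = pi / (2 W-tilde(kappa)),
    solved by bracketed root-finding on (0, pi); the cosine amplitude is
    a = G/pi = A / [(4w/k)(sin psi - psi cos psi) - cos psi] and the offset
    d = -a cos(psi).
    """
    lam = config.lam if lam is None else float(lam)
    kappa = 2.0 * np.pi / lam
    Wk = float(kernel_fourier(config, kappa))
    if Wk <= 0:
        raise TheoryError(f"W-tilde({kappa:.4g}) <= 0: no bump solution at lam={lam}")
    target = np.pi / (2.0 * Wk)

    def f(psi):
        return psi - np.cos(psi) * np.sin(psi) - target

    lo, hi = 1e-6, np.pi - 1e-6
    if f(lo) > 0 or f(hi) < 0:
        raise TheoryError("no root for psi in (0, pi); config outside model validity")
    psi = float(optimize.brentq(f, lo, hi, xtol=1e-10))
    k = np.pi / config.l
    a = config.A / (
        (4.0 * config.w / k) * (np.sin(psi) - psi * np.cos(psi)) - np.cos(psi)
    )
    G = np.pi * a
    d = -a * np.cos(psi)
    z = psi / kappa

    def profile(x, a=a, d=d, kappa=kappa):
        return a * np.cos(kappa * np.asarray(x, dtype=float)) + d

    return TheoryBumpShape(lam=lam, kappa=kappa, z=z, psi=psi, G=G, a=a, d=d, profile=profile)


def lyapunov_closed_form(config: ModelConfig, lam: Optional[float] = None) -> float:
    """Lyapunov value of the closed-form steady state: -N A a (sin psi - psi cos psi)/(2 pi)."""
    shape = bump_shape(config, lam)
    return -config.N * config.A * shape.a * (np.sin(shape.psi) - shape.psi * np.cos(shape.psi)) / (2.0 * np.pi)


def lyapunov(
    config: ModelConfig,
    conn: Connectivity,
    rates: np.ndarray,
    reduced: bool = False,
) -> float:
    """Discrete Lyapunov functional of a single-population rate profile.

    Full form: L = -sum_xy Wbar(x-y) s(x) s(y) + sum_x F(s) - A sum_x s with
    F(s) = int_0^s phi^-1, where Wbar is the xi-symmetrized single-population
    kernel (half the summed two-population connectivity).  With
    ``reduced=True`` the steady-state ReLU shortcut -(A/2) sum s is returned.
    """
    s = np.asarray(rates, dtype=float)
    if np.any(s < 0):
        raise ValueError("rates must be nonnegative")
    if reduced:
        if config.activation != "relu":
            raise TheoryError("reduced form only holds for ReLU activation")
        return float(-0.5 * config.A * s.sum())
    kbar = conn.symmetrized_kernel()
    conv = np.fft.irfft(np.fft.rfft(kbar) * np.fft.rfft(s), n=config.N)
    quad = -float(s @ conv)
    if config.activation == "relu":
        integral = 0.5 * float((s**2).sum())
    elif config.activation == "logistic":
        smax = config.logistic_max
        if np.any(s >= smax):
            raise TheoryError("rates outside invertible range of logistic activation")
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(s > 0, s * np.log(s / (smax - s)), 0.0)
        integral = float(
            (config.logistic_threshold * s
             + (term + smax * np.log1p(-s / smax)) / config.logistic_gain).sum()
        )
    else:  # pragma: no cover - guarded by config validation
        raise TheoryError(f"unsupported activation {config.activation}")
    return quad + integral - config.A * float(s.sum())


# -- dynamical predictions from a baseline profile ---------------------------


#: Subcell refinement factor for the network-distance integrals.  The
#: baseline g is smooth on the lattice, so its trigonometric interpolant is
#: the natural continuum extension; evaluating the phi'-weighted integrals on
#: a 16x finer grid resolves the kink at the bump edges, which otherwise
#: contributes an O(1/bump-width) quadrature error.
UPSAMPLE = 16


def _fine_profile(g_base: np.ndarray, factor: int = UPSAMPLE):
    """Trigonometric interpolant of g and its spectral derivatives on a fine grid."""
    g = np.asarray(g_base, dtype=float)
    N = g.size
    gh = np.fft.rfft(g)
    q = 2j * np.pi * np.fft.rfftfreq(N, d=1.0)
    nf = N * factor
    gf = np.fft.irfft(gh, nf) * factor
    d1 = np.fft.irfft(gh * q, nf) * factor
    d2 = np.fft.irfft(gh * q * q, nf) * factor
    return gf, d1, d2, 1.0 / factor


def _sums(config: ModelConfig, g_base: np.ndarray):
    """Quadratures S1 = int phi' (dg/dx)^2 dx and S2 = int phi' d2g/dx2 dx."""
    gf, d1, d2, h = _fine_profile(g_base)
    w = activation_prime(gf, config.activation, config)
    S1 = float((w * d1**2).sum() * h)
    S2 = float((w * d2).sum() * h)
    if S1 <= 0:
        raise TheoryError("no bumps: flat baseline profile")
    return gf, d1, d2, w, S1, S2


def _circular_factor(config: ModelConfig) -> float:
    return 360.0 * config.M / config.N


def predict_drive_velocity(config: ModelConfig, g_base: np.ndarray, b: float) -> float:
    """Path-integration velocity v_drive for constant drive b.

    v = -gamma b xi sum phi' g'' / (tau sum phi' g'^2) in neurons/s; when the
    shift xi is a sizeable fraction of l (xi >= l/10) the exact
    shifted-difference numerator is used instead of its xi g'' expansion.
    Under circular mapping the rescaled gamma applies and the result is in
    degrees/s.
    """
    gf, d1, d2, w, S1, S2 = _sums(config, g_base)
    gamma = config.gamma_effective
    if config.xi >= config.l / 10.0:
        shift = int(config.xi * UPSAMPLE)
        diff = np.roll(d1, -shift) - np.roll(d1, shift)
        num = -gamma * b * float((w * diff).sum() / UPSAMPLE)
        v = num / (2.0 * config.tau * S1)
    else:
        v = -gamma * b * config.xi * S2 / (config.tau * S1)
    v *= _MS_PER_S
    if config.mapping == "circular":
        v *= _circular_factor(config)
    return float(v)


def predict_input_diffusion(config: ModelConfig, g_base: np.ndarray, sigma: float) -> float:
    """Diffusion coefficient from per-step Gaussian input noise of std sigma.

    D = sigma^2 dt / (4 tau^2 sum phi' g'^2), in neurons^2/s (deg^2/s under
    circular mapping, where two powers of the neuron->degree conversion
    factor apply).
    """
    _, _, _, _, S1, _ = _sums(config, g_base)
    D = sigma**2 * config.dt / (4.0 * config.tau**2 * S1) * _MS_PER_S
    if config.mapping == "circular":
        D *= _circular_factor(config) ** 2
    return float(D)


def predict_spike_diffusion(config: ModelConfig, g_base: np.ndarray, F: float = 1.0) -> float:
    """Diffusion coefficient from Poisson spiking noise with Fano factor F.

    D = F sum s g'^2 / (4 tau^2 [sum phi' g'^2]^2) in neurons^2/s.
    """
    gf, d1, _, w, S1, _ = _sums(config, g_base)
    s = activation(gf, config.activation, config)
    num = float((s * d1**2).sum() / UPSAMPLE)
    D = F * num / (4.0 * config.tau**2 * S1**2) * _MS_PER_S
    if config.mapping == "circular":
        D *= _circular_factor(config) ** 2
    return float(D)


@dataclasses.dataclass
class DriftField:
    """Position-dependent drift velocity v_conn(theta) in neurons/s."""

    theta_grid: np.ndarray
    v: np.ndarray

    def zero_crossings(self) -> np.ndarray:
        """Theta values where v crosses zero with negative slope (stable rest points)."""
        v = self.v
        nxt = np.roll(v, -1)
        idx = np.nonzero((v > 0) & (nxt <= 0))[0]
        theta = self.theta_grid
        h = float(theta[1] - theta[0]) if theta.size > 1 else 1.0
        out = []
        for i in idx:
            frac = v[i] / (v[i] - nxt[i]) if v[i] != nxt[i] else 0.0
            out.append(float(theta[i]) + frac * h)
        return np.asarray(out)


def predict_drift_field(
    config: ModelConfig,
    g_base: np.ndarray,
    V: np.ndarray,
    theta_grid: Optional[np.ndarray] = None,
) -> DriftField:
    """Drift velocity induced by quenched connectivity noise V.

    v_conn(theta) = -sum_ij Vsum[i, j] s'(i - theta) s(j - theta)
    / (2 tau sum s'^2), where Vsum collapses the four population blocks and
    s', s are the baseline rate derivative and rate translated to theta.
    """
    N = config.N
    V = np.asarray(V, dtype=float)
    if V.shape != (2 * N, 2 * N):
        raise ValueError("V must be 2N x 2N")
    # Recentre the baseline so one bump sits at position 0: the translation
    # s(j - theta) below assumes the profile's bumps lie at multiples of lam.
    from . import tracking

    s_tmp = activation(np.asarray(g_base, dtype=float), config.activation, config)
    p0 = tracking.bump_positions(s_tmp, config.M)[0]
    g_base = np.roll(np.asarray(g_base, dtype=float), -int(round(p0)))
    _, _, _, _, S1, _ = _sums(config, g_base)
    # The V contraction is a genuine per-neuron double sum: use the spectral
    # derivative sampled at lattice sites, phi'-masked.
    g = np.asarray(g_base, dtype=float)
    gh = np.fft.rfft(g)
    qs = 2j * np.pi * np.fft.rfftfreq(N, d=1.0)
    d1_lattice = np.fft.irfft(gh * qs, N)
    mask = activation_prime(g, config.activation, config)
    s = activation(g, config.activation, config)
    ds = mask * d1_lattice
    Vsum = V[:N, :N] + V[:N, N:] + V[N:, :N] + V[N:, N:]
    if theta_grid is None:
        theta_grid = np.arange(N)
    theta_grid = np.asarray(theta_grid)
    idx = (np.arange(N)[None, :] - theta_grid[:, None]) % N
    S_roll = s[idx]        # (T, N): s(j - theta)
    D_roll = ds[idx]       # (T, N): s'(i - theta)
    T1 = Vsum @ S_roll.T   # (N, T)
    num = np.einsum("ti,it->t", D_roll, T1)
    v = -num / (2.0 * config.tau * S1) * _MS_PER_S
    return DriftField(theta_grid=theta_grid, v=v)


def predict_escape_drive(config: ModelConfig, drift_field: DriftField, g_base: np.ndarray) -> float:
    """Smallest drive magnitude that overcomes the worst opposing drift.

    b0 = max_theta |v_conn(theta)| / (dv_drive/db), returned positive.
    """
    slope = abs(predict_drive_velocity(config, g_base, b=1.0))
    vmax = float(np.max(np.abs(drift_field.v)))
    if config.mapping == "circular":
        vmax *= _circular_factor(config)  # match v_drive units (deg/s)
    return vmax / slope


def predict_speed_stats(drift_field: DriftField, v_drive: float) -> tuple:
    """(speed difference, speed variability) of traversal under drive.

    speed difference = 2 |mean_theta v_conn| / |v_drive|; speed variability =
    std_theta v_conn / |v_drive|.  Requires |v_drive| > max |v_conn| (no
    trapping); both v_conn and v_drive must be in the same units.
    """
    v = drift_field.v
    vmax = float(np.max(np.abs(v)))
    if abs(v_drive) <= vmax:
        raise TheoryError(
            f"trapping regime: |v_drive|={abs(v_drive):.3g} <= max|v_conn|={vmax:.3g}"
        )
    diff = 2.0 * abs(float(np.mean(v))) / abs(v_drive)
    var = float(np.std(v)) / abs(v_drive)
    return diff, var
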