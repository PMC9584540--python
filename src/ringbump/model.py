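"""Network configuration, activation nonlinearity, and ring connectivity.

The model is a 1D ring continuous-attractor network with two neural
populations L and R of ``N`` neurons each.  Every neuron receives local
inhibition through a shifted cosine kernel that is strongest at the
inhibition distance ``l``; the synaptic outputs of population L are shifted
by ``-xi`` neurons and those of population R by ``+xi``.  The kernel
amplitude is rescaled as ``w = 8 M / N`` so that the total inhibition per
neuron — and hence the bump shape in scaled coordinates — is invariant
across bump numbers ``M`` and network sizes ``N``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Optional

import numpy as np
import yaml

ACTIVATIONS = ("relu", "logistic")
MAPPINGS = ("linear", "circular")
MODES = ("rate", "spiking")

#: l = WAVELENGTH_COEF * N / M puts the preferred wavelength at the bump
#: spacing N/M (the preferred wavelength is 2.28 l, and 1/2.28 = 0.44).
WAVELENGTH_COEF = 0.44

# Reference configuration anchoring the circular-mapping gamma rescale:
# gamma -> gamma * (N/600) * (3/M).
_GAMMA_REF_N = 600
_GAMMA_REF_M = 3


class ConfigurationError(ValueError):
    """Raised when a model configuration violates its invariants."""


def inhibition_distance_for_bumps(N: int, M: int) -> float:
    """Inhibition distance that makes the preferred wavelength equal N/M.

    The selected bump spacing is 2.28 l, so ``l = 0.44 N / M`` targets M
    equally spaced bumps on a ring of N neurons.
    """
    if N <= 0 or M <= 0:
        raise ConfigurationError("N and M must be positive")
    if M > N / 4:
        raise ConfigurationError(f"M={M} too large for N={N} (need M <= N/4)")
    return WAVELENGTH_COEF * N / M


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Static network and simulation parameters.

    Defaults follow the standard protocol: tau = 10 ms; for rate mode
    dt = 0.5 ms, A = 1, gamma = 0.1; for spiking mode dt = 0.1 ms,
    A = 0.1 /ms, gamma = 0.01 /ms.  ``l`` defaults to 0.44 N/M and
    ``w`` to 8 M/N.
    """

    N: int
    M: int
    l: Optional[float] = None
    xi: int = 2
    w: Optional[float] = None
    tau: float = 10.0
    A: Optional[float] = None
    gamma: Optional[float] = None
    dt: Optional[float] = None
    activation: str = "relu"
    mapping: str = "linear"
    mode: str = "rate"
    burn_in_steps: int = 1000
    # Logistic activation parameters (optional activation; see activation()).
    logistic_gain: float = 2.0
    logistic_threshold: float = 1.0
    logistic_max: float = 3.0

    def __post_init__(self) -> None:
        spiking = self.mode == "spiking"
        if self.l is None:
            object.__setattr__(self, "l", inhibition_distance_for_bumps(self.N, self.M))
        if self.w is None:
            object.__setattr__(self, "w", 8.0 * self.M / self.N)
        if self.A is None:
            object.__setattr__(self, "A", 0.1 if spiking else 1.0)
        if self.gamma is None:
            object.__setattr__(self, "gamma", 0.01 if spiking else 0.1)
        if self.dt is None:
            object.__setattr__(self, "dt", 0.1 if spiking else 0.5)
        self._validate()

    def _validate(self) -> None:
        if self.N <= 0:
            raise ConfigurationError("N must be positive")
        if not 1 <= self.M <= self.N / 4:
            raise ConfigurationError(f"need 1 <= M <= N/4, got M={self.M}, N={self.N}")
        if self.l <= 0:
            raise ConfigurationError("l must be positive")
        if not isinstance(self.xi, (int, np.integer)):
            raise ConfigurationError("xi must be an integer number of neurons")
        if not 0 <= self.xi < self.l:
            raise ConfigurationError(f"need 0 <= xi << l, got xi={self.xi}, l={self.l}")
        if self.w <= 0 or self.tau <= 0 or self.dt <= 0:
            raise ConfigurationError("w, tau and dt must be positive")
        if self.burn_in_steps < 0:
            raise ConfigurationError("burn_in_steps must be nonnegative")
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.mapping not in MAPPINGS:
            raise ConfigurationError(f"unknown mapping {self.mapping!r}")
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def lam(self) -> float:
        """Target bump distance N/M in neurons."""
        return self.N / self.M

    @property
    def gamma_effective(self) -> float:
        """Drive coupling actually used in the dynamics.

        Under circular mapping gamma is rescaled by (N/600)(3/M) so the same
        drive b produces the same angular velocity in deg/s for every (M, N).
        Linear mapping leaves gamma unchanged.
        """
        if self.mapping == "circular":
            return self.gamma * (self.N / _GAMMA_REF_N) * (_GAMMA_REF_M / self.M)
        return self.gamma

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must be a flat key-value mapping")
        return cls.from_dict(data)


# -- activation nonlinearity ------------------------------------------------


def activation(g: np.ndarray, kind: str = "relu", config: Optional[ModelConfig] = None) -> np.ndarray:
    """Firing rate s = phi[g].

    ``relu`` is max(g, 0); ``logistic`` is a saturating sigmoid
    ``s_max / (1 + exp(-gain (g - threshold)))`` with parameters from the
    config (defaults used when no config is given).
    """
    g = np.asarray(g, dtype=float)
    if kind == "relu":
        return np.maximum(g, 0.0)
    if kind == "logistic":
        gain = config.logistic_gain if config is not None else 2.0
        thr = config.logistic_threshold if config is not None else 1.0
        smax = config.logistic_max if config is not None else 3.0
        return smax / (1.0 + np.exp(-gain * (g - thr)))
    raise ConfigurationError(f"unknown activation kind {kind!r}")


def activation_prime(g: np.ndarray, kind: str = "relu", config: Optional[ModelConfig] = None) -> np.ndarray:
    """Derivative phi'[g] of the activation function."""
    g = np.asarray(g, dtype=float)
    if kind == "relu":
        return (g > 0.0).astype(float)
    if kind == "logistic":
        gain = config.logistic_gain if config is not None else 2.0
        smax = config.logistic_max if config is not None else 3.0
        s = activation(g, "logistic", config)
        return gain * s * (1.0 - s / smax)
    raise ConfigurationError(f"unknown activation kind {kind!r}")


# -- connectivity -----------------------------------------------------------


def kernel_profile(x: np.ndarray, l: float, w: float) -> np.ndarray:
    """Continuous cosine inhibitory kernel W(x).

    W(x) = w (cos(pi x / l) - 1)/2 for |x| < 2l and 0 beyond, i.e. zero
    self-coupling and strongest inhibition -w at distance l.
    """
    x = np.asarray(x, dtype=float)
    out = 0.5 * w * (np.cos(np.pi * x / l) - 1.0)
    return np.where(np.abs(x) < 2.0 * l, out, 0.0)


@dataclasses.dataclass
class Connectivity:
    """Circulant two-population kernel plus optional quenched noise.

    ``base_kernel[d]`` is the weight from a presynaptic neuron at ring
    displacement d (wrapped onto 0..N-1).  Population L's outputs act as if
    shifted by -xi neurons and population R's by +xi.  ``noise`` is an
    optional dense 2N x 2N matrix V added to the ideal weights (row/column
    blocks ordered [L, R]); the xi shift is ignored inside V.
    """

    base_kernel: np.ndarray
    xi: int
    N: int
    noise: Optional[np.ndarray] = None
    noise_magnitude: float = 0.0

    def __post_init__(self) -> None:
        self.base_kernel = np.asarray(self.base_kernel, dtype=float)
        if self.base_kernel.shape != (self.N,):
            raise ConfigurationError("base_kernel must have length N")
        if self.noise is not None:
            self.noise = np.asarray(self.noise, dtype=float)
            if self.noise.shape != (2 * self.N, 2 * self.N):
                raise ConfigurationError("noise matrix must be 2N x 2N")
        # Cached spectrum and shift phases for FFT-based recurrent input.
        self._kernel_hat = np.fft.rfft(self.base_kernel)
        m = np.arange(self._kernel_hat.size)
        phase = np.exp(2j * np.pi * m * self.xi / self.N)
        self._phase_L = phase        # output of L sampled at x + xi
        self._phase_R = np.conj(phase)

    def kernel_matrix(self, population: str) -> np.ndarray:
        """Dense N x N weight matrix W_beta[i, j] for presynaptic population beta."""
        if population not in ("L", "R"):
            raise ConfigurationError("population must be 'L' or 'R'")
        shift = self.xi if population == "L" else -self.xi
        i = np.arange(self.N)
        # W_L(i, j) = W(i - j + xi), W_R(i, j) = W(i - j - xi)
        return self.base_kernel[(i[:, None] - i[None, :] + shift) % self.N]

    def symmetrized_kernel(self) -> np.ndarray:
        """Even kernel (W(d - xi) + W(d + xi))/2 entering the Lyapunov functional."""
        k = self.base_kernel
        return 0.5 * (np.roll(k, self.xi) + np.roll(k, -self.xi))

    def recurrent_input(self, s: np.ndarray) -> np.ndarray:
        """Summed recurrent input from both populations.

        ``s`` has shape (..., 2, N) with populations ordered [L, R]; the
        returned array has shape (..., N) and is identical for both target
        populations (the kernel depends only on the presynaptic population).
        """
        sh = np.fft.rfft(s, axis=-1)
        tot = self._kernel_hat * (sh[..., 0, :] * self._phase_L + sh[..., 1, :] * self._phase_R)
        return np.fft.irfft(tot, n=self.N, axis=-1)

    def noise_input(self, s: np.ndarray) -> np.ndarray:
        """Quenched-noise contribution zeta = V s for state s of shape (..., 2, N)."""
        if self.noise is None:
            return np.zeros_like(s)
        flat = s.reshape(s.shape[:-2] + (2 * self.N,))
        zeta = flat @ self.noise.T
        return zeta.reshape(s.shape)

    def to_dense(self) -> np.ndarray:
        """Full 2N x 2N weight matrix (blocks [[LL, LR], [RL, RR]]) including noise."""
        WL = self.kernel_matrix("L")
        WR = self.kernel_matrix("R")
        top = np.hstack([WL, WR])
        dense = np.vstack([top, top])
        if self.noise is not None:
            dense = dense + self.noise
        return dense


def build_connectivity(config: ModelConfig) -> Connectivity:
    """Sample the wrapped cosine kernel on the ring.

    The continuous kernel has support |x| < 2l; tails that would extend past
    the ring are wrapped around, W(x) -> W(x) + W(x - N) + W(x + N), which is
    a no-op whenever the support fits inside the ring.
    """
    d = np.arange(config.N, dtype=float)
    base = (
        kernel_profile(d, config.l, config.w)
        + kernel_profile(d - config.N, config.l, config.w)
        + kernel_profile(d + config.N, config.l, config.w)
    )
    return Connectivity(base_kernel=base, xi=int(config.xi), N=config.N)


def sample_connectivity_noise(
    config: ModelConfig, magnitude: float, seed=None
) -> np.ndarray:
    """Quenched Gaussian connectivity noise V.

    Entries are i.i.d. N(0, magnitude^2) across all four population blocks;
    the matrix is fixed for the lifetime of a simulation.  ``seed`` may be an
    int or a numpy Generator.
    """
    if magnitude < 0:
        raise ConfigurationError("noise magnitude must be nonnegative")
    n = 2 * config.N
    if magnitude == 0:
        return np.zeros((n, n))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.normal(0.0, magnitude, size=(n, n))


def with_noise(conn: Connectivity, V: np.ndarray, magnitude: float = 0.0) -> Connectivity:
    """Copy of ``conn`` carrying the quenched noise matrix V."""
    return Connectivity(
        base_kernel=conn.base_kernel.copy(),
        xi=conn.xi,
        N=conn.N,
        noise=V,
        noise_magnitude=magnitude,
    )


@dataclasses.dataclass
class NetworkState:
    """Synaptic inputs of both populations at one instant."""

    g_L: np.ndarray
    g_R: np.ndarray
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.stack([self.g_L, self.g_R])

    @classmethod
    def from_array(cls, g: np.ndarray, t: float = 0.0) -> "NetworkState":
        return cls(g_L=np.array(g[0]), g_R=np.array(g[1]), t=t)
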