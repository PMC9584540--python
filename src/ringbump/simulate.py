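"""Euler integration of the ring-network dynamics under drive and noise.

The synaptic inputs obey

    tau dg_a/dt + g_a = sum_b W_b s_b + A (-/+) gamma b + zeta_a,

integrated with the explicit Euler method at timestep dt.  Three mutually
exclusive noise models are supported: per-step Gaussian input noise of
standard deviation sigma; Poisson spiking noise, where the recurrent input
uses the stochastic rate s = c/dt with rescaled-Poisson spike counts c; and
quenched connectivity noise, where a fixed Gaussian matrix V contributes
zeta = V s.  The engine operates on batched states of shape (B, 2, N) so
replicate ensembles integrate in lockstep, and can track bump positions at
every step.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np

from . import tracking
from .model import Connectivity, ModelConfig, NetworkState, activation

NOISE_KINDS = ("none", "input", "spiking", "connectivity")


class SimulationError(RuntimeError):
    pass


class BumpCountWarning(UserWarning):
    """Bump formation settled on a different mode than targeted."""


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """One noise model per run: none, input (sigma), spiking (fano), connectivity."""

    kind: str = "none"
    sigma: float = 0.0
    fano: float = 1.0
    conn_magnitude: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.fano <= 0:
            raise ValueError("fano must be positive")
        if self.conn_magnitude < 0:
            raise ValueError("connectivity noise magnitude must be nonnegative")
        if self.kind != "input" and self.sigma > 0:
            raise ValueError("sigma only applies to input noise")
        if self.kind != "connectivity" and self.conn_magnitude > 0:
            raise ValueError("conn_magnitude only applies to connectivity noise")


NO_NOISE = NoiseSpec()


@dataclasses.dataclass
class SimulationRecord:
    """Thinned rate snapshots of one run plus provenance."""

    times: np.ndarray
    rates: np.ndarray  # (n_records, 2, N)
    drive: float
    config: ModelConfig
    noise: NoiseSpec

    def save_tsv(self, path) -> None:
        """Long-format delimited text: time_ms, population, neuron, rate."""
        n_rec, _, N = self.rates.shape
        with open(path, "w") as fh:
            fh.write(f"# drive: {self.drive}\n# config: {self.config.to_dict()}\n")
            fh.write("time_ms\tpopulation\tneuron\trate\n")
            for t, snap in zip(self.times, self.rates):
                for p, pop in enumerate("LR"):
                    for i in range(N):
                        fh.write(f"{t}\t{pop}\t{i}\t{snap[p, i]:.8g}\n")


class Simulation:
    """Batched Euler integrator with optional per-step bump tracking.

    ``g`` has shape (B, 2, N).  All randomness (input noise, spike counts)
    is drawn from the single Generator supplied at construction, so a run is
    reproducible given (seed, config, batch layout).
    """

    def __init__(
        self,
        config: ModelConfig,
        conn: Connectivity,
        g: np.ndarray,
        b: float = 0.0,
        noise: NoiseSpec = NO_NOISE,
        rng: Optional[np.random.Generator] = None,
        V_batch: Optional[np.ndarray] = None,
        check_every: int = 500,
    ):
        g = np.asarray(g, dtype=float)
        if g.ndim == 2:
            g = g[None]
        if g.shape[1:] != (2, config.N):
            raise ValueError("state must have shape (B, 2, N)")
        self.config = config
        self.conn = conn
        self.g = g.copy()
        self.b = float(b)
        self.noise = noise
        self.rng = rng if rng is not None else np.random.default_rng(noise.seed)
        self.V_batch = V_batch
        self.check_every = check_every
        self.step_index = 0
        self._tracked = None  # (wrapped, unwrapped) once tracking starts
        self._Vmat = None
        if noise.kind == "connectivity":
            mat = V_batch if V_batch is not None else conn.noise
            if mat is None:
                raise ValueError("connectivity noise requested but no V supplied")
            # The dense matrix-vector product dominates the step cost; V is a
            # small perturbation (|V| ~ 1e-3), so single precision is ample.
            self._Vmat = np.asarray(mat, dtype=np.float32)

    # -- state access -------------------------------------------------------

    @property
    def batch_size(self) -> int:
        return self.g.shape[0]

    @property
    def t(self) -> float:
        return self.step_index * self.config.dt

    def rates(self) -> np.ndarray:
        """Deterministic rates phi[g], shape (B, 2, N)."""
        return activation(self.g, self.config.activation, self.config)

    def summed_rates(self) -> np.ndarray:
        """S_i = s_L + s_R used for tracking, shape (B, N)."""
        s = self.rates()
        return s[:, 0, :] + s[:, 1, :]

    def positions(self) -> np.ndarray:
        """Current wrapped bump positions, shape (B, M)."""
        return tracking.bump_positions_batch(self.summed_rates(), self.config.M)

    # -- integration --------------------------------------------------------

    def _advance(self, extra_input: Optional[np.ndarray] = None) -> None:
        cfg = self.config
        g = self.g
        if self.noise.kind == "spiking":
            lam = activation(g, cfg.activation, cfg) * (cfg.dt / self.noise.fano)
            counts = self.noise.fano * self.rng.poisson(lam)
            s = counts / cfg.dt
        else:
            s = activation(g, cfg.activation, cfg)
        h = self.conn.recurrent_input(s)  # (B, N)
        drive = cfg.gamma_effective * self.b
        inp = np.stack([h - drive, h + drive], axis=1)
        inp += cfg.A
        if extra_input is not None:
            inp += extra_input[..., None, :] if extra_input.ndim < inp.ndim else extra_input
        if self.noise.kind == "input" and self.noise.sigma > 0:
            inp += self.rng.normal(0.0, self.noise.sigma, size=g.shape)
        elif self.noise.kind == "connectivity":
            flat = s.reshape(self.batch_size, 2 * cfg.N, 1).astype(np.float32)
            if self._Vmat.ndim == 3:
                zeta = np.matmul(self._Vmat, flat)[..., 0]
            else:
                zeta = (self._Vmat @ flat[..., 0].T).T
            inp += zeta.astype(float).reshape(g.shape)
        self.g = g + (cfg.dt / cfg.tau) * (inp - g)
        self.step_index += 1
        if self.step_index % self.check_every == 0 and not np.all(np.isfinite(self.g)):
            raise SimulationError(f"dynamics diverged at step {self.step_index}")

    def run_steps(
        self,
        n_steps: int,
        track: bool = False,
        extra_input_fn=None,
        track_every: int = 1,
    ) -> Optional[np.ndarray]:
        """Advance n_steps; if ``track``, return unwrapped positions.

        Positions are recorded every ``track_every`` steps (shape
        (B, n_steps // track_every, M)); the stride must keep inter-sample
        motion well below a quarter bump distance.  ``extra_input_fn(step)
        -> (B, N) or (B, 2, N)`` injects an additional additive input (used
        for seeded bump formation).
        """
        out = None
        if track:
            if self._tracked is None:
                wrapped = np.sort(self.positions(), axis=1)
                self._tracked = (wrapped, wrapped.copy())
            out = np.empty((self.batch_size, n_steps // track_every, self.config.M))
        rec = 0
        for i in range(n_steps):
            extra = extra_input_fn(self.step_index) if extra_input_fn is not None else None
            self._advance(extra)
            if track and (i + 1) % track_every == 0:
                wrapped, unwrapped = self._tracked
                cand = self.positions()
                matched, delta = tracking.advance_positions(wrapped, cand, self.config.N)
                unwrapped += delta
                self._tracked = (matched, unwrapped)
                out[:, rec, :] = unwrapped
                rec += 1
        return out

    def tracked_origin(self) -> np.ndarray:
        """Unwrapped positions at the start of tracking (after sorting), (B, M)."""
        if self._tracked is None:
            wrapped = np.sort(self.positions(), axis=1)
            self._tracked = (wrapped, wrapped.copy())
        return self._tracked[1].copy()


# -- bump formation ----------------------------------------------------------

JITTER_FRACTION = 0.01  # initial condition g = A + N(0, (0.01 A)^2), i.i.d.


def _seed_input(config: ModelConfig, seed_positions: Sequence[float]) -> np.ndarray:
    """Bell-shaped formation input: amplitude A, Gaussian of std lam/8 per seed."""
    x = np.arange(config.N)
    total = np.zeros(config.N)
    width = config.lam / 8.0
    for p in seed_positions:
        d = tracking.ring_difference(x, p, config.N)
        total += np.exp(-0.5 * (d / width) ** 2)
    return config.A * total


def form_bumps(
    config: ModelConfig,
    conn: Connectivity,
    noise: NoiseSpec = NO_NOISE,
    seed_positions: Optional[Sequence[float]] = None,
    rng=None,
    batch: Optional[int] = None,
    warn: bool = True,
):
    """Run the burn-in from a jittered uniform state and return the formed state.

    The initial condition is g = A plus small i.i.d. Gaussian jitter that
    breaks translation symmetry.  If ``seed_positions`` is given, a bell-
    shaped input centred on each requested phase is applied at full strength
    for the first half of the burn-in and ramped linearly to zero over the
    second half, so bumps form at those phases.  Returns a ``NetworkState``
    (or the raw (B, 2, N) array when ``batch`` is set).  A warning is issued
    when the formed state does not have M bumps.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    B = 1 if batch is None else batch
    g0 = config.A * (1.0 + JITTER_FRACTION * rng.standard_normal((B, 2, config.N)))
    sim = Simulation(config, conn, g0, b=0.0, noise=noise, rng=rng)
    n = config.burn_in_steps
    if seed_positions is not None:
        profile = _seed_input(config, seed_positions)

        def ramp(step, n=n, profile=profile):
            if step < n / 2:
                f = 1.0
            else:
                f = max(0.0, 2.0 * (1.0 - step / n))
            return f * profile[None, :]

        sim.run_steps(n, extra_input_fn=ramp)
    else:
        sim.run_steps(n)
    if warn:
        counts = [tracking.count_bumps(S) for S in sim.summed_rates()]
        bad = [c for c in counts if c != config.M]
        if bad:
            warnings.warn(
                f"bump formation achieved counts {counts} (target M={config.M})",
                BumpCountWarning,
                stacklevel=2,
            )
    if batch is None:
        return NetworkState.from_array(sim.g[0], t=sim.t)
    return sim.g


def relax_to_steady_state(
    config: ModelConfig,
    conn: Connectivity,
    state=None,
    extra_steps: int = 4000,
    tol: float = 1e-12,
    rng=None,
):
    """Noiseless, driveless relaxation to the baseline fixed point.

    Starts from ``state`` (or a fresh formation with seed 0) and integrates
    until the per-step change drops below ``tol`` or ``extra_steps`` elapse.
    Returns the final NetworkState.
    """
    if state is None:
        state = form_bumps(config, conn, rng=rng if rng is not None else 0, warn=False)
    if isinstance(state, NetworkState):
        g = state.as_array()[None]
    else:
        g = np.asarray(state, dtype=float)
        if g.ndim == 2:
            g = g[None]
    sim = Simulation(config, conn, g, b=0.0, noise=NO_NOISE)
    for _ in range(extra_steps // 100):
        before = sim.g.copy()
        sim.run_steps(100)
        if np.max(np.abs(sim.g - before)) < tol:
            break
    return NetworkState.from_array(sim.g[0], t=sim.t)


def baseline_profile(config: ModelConfig, conn: Connectivity, seed: int = 0) -> np.ndarray:
    """Single-population baseline g from a noiseless, driveless simulation.

    This is the profile the dynamical predictions are evaluated on; the two
    populations agree at the fixed point, so their average is returned.
    """
    state = form_bumps(config, conn, rng=seed, warn=False)
    state = relax_to_steady_state(config, conn, state)
    return 0.5 * (state.g_L + state.g_R)


# -- spec-level operations ---------------------------------------------------


def step(
    state: NetworkState,
    conn: Connectivity,
    b: float,
    noise: NoiseSpec,
    config: ModelConfig,
    rng=None,
) -> NetworkState:
    """Single Euler update of one network state."""
    sim = Simulation(config, conn, state.as_array()[None], b=b, noise=noise,
                     rng=rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng))
    sim.run_steps(1)
    return NetworkState.from_array(sim.g[0], t=state.t + config.dt)


def sample_spikes(g: np.ndarray, config: ModelConfig, F: float = 1.0, rng=None) -> np.ndarray:
    """Rescaled-Poisson spike counts c = F * Pois(phi[g] dt / F).

    Counts are nonnegative multiples of F with mean phi[g] dt and variance
    F phi[g] dt.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lam = activation(g, config.activation, config) * (config.dt / F)
    return F * rng.poisson(lam)


def run(
    config: ModelConfig,
    conn: Connectivity,
    b: float,
    noise: NoiseSpec,
    duration_ms: float,
    initial_state: NetworkState,
    rng=None,
    record_every: int = 1,
) -> SimulationRecord:
    """Integrate for duration_ms, recording rate snapshots every record_every steps."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        noise.seed if rng is None else rng
    )
    n_steps = int(round(duration_ms / config.dt))
    sim = Simulation(config, conn, initial_state.as_array()[None], b=b, noise=noise, rng=rng)
    times = [sim.t]
    rates = [sim.rates()[0]]
    done = 0
    while done < n_steps:
        chunk = min(record_every, n_steps - done)
        sim.run_steps(chunk)
        done += chunk
        times.append(sim.t)
        rates.append(sim.rates()[0])
    return SimulationRecord(
        times=np.asarray(times),
        rates=np.asarray(rates),
        drive=b,
        config=config,
        noise=noise,
    )


def run_tracked(
    config: ModelConfig,
    conn: Connectivity,
    b: float,
    noise: NoiseSpec,
    duration_ms: float,
    initial_state,
    rng=None,
    V_batch: Optional[np.ndarray] = None,
) -> tracking.BumpTrajectory:
    """Integrate one run and return the unwrapped bump trajectory (positions at every dt)."""
    trajs = run_ensemble_tracked(
        config, conn, b, noise, duration_ms,
        initial_state if isinstance(initial_state, np.ndarray) and initial_state.ndim == 3
        else initial_state.as_array()[None],
        rng=rng, V_batch=V_batch,
    )
    return trajs[0]


def run_ensemble_tracked(
    config: ModelConfig,
    conn: Connectivity,
    b: float,
    noise: NoiseSpec,
    duration_ms: float,
    initial_states: np.ndarray,
    rng=None,
    V_batch: Optional[np.ndarray] = None,
):
    """Integrate a batch of replicates in lockstep, tracking every timestep.

    ``initial_states`` has shape (B, 2, N).  Returns a list of B
    BumpTrajectory objects with positions at t = 0, dt, ..., duration.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        noise.seed if rng is None else rng
    )
    n_steps = int(round(duration_ms / config.dt))
    sim = Simulation(config, conn, initial_states, b=b, noise=noise, rng=rng, V_batch=V_batch)
    origin = sim.tracked_origin()  # (B, M)
    pos = sim.run_steps(n_steps, track=True)  # (B, n_steps, M)
    times = np.arange(n_steps + 1) * config.dt
    out = []
    for i in range(sim.batch_size):
        full = np.vstack([origin[i][None, :], pos[i]])
        out.append(tracking.BumpTrajectory(times=times, positions=full, N=config.N))
    return out
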