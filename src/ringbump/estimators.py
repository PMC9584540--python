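"""Measurement of velocity, diffusion, escape drive, and speed statistics.

Velocity comes from the mean displacement Theta(u) over time offsets u,
fitted to a line through the origin; diffusion from the ensemble-averaged
mean squared displacement Omega(u) of trajectories relative to the ensemble
mean, fitted to 2 D u.  Offsets run from dt to half the trajectory duration
so every offset retains enough fiducial starting times.  Uncertainties use
the bootstrap: resampled ensembles of replicate simulations, the statistic
recomputed on each.  Under quenched connectivity noise, the escape drive is
found by binary search over the drive, and traversal speed profiles are
binned by integer bump position after Gaussian temporal smoothing.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import simulate, tracking
from .model import Connectivity, ModelConfig

_MS_PER_S = 1000.0


class EstimationError(RuntimeError):
    pass


def _origin_slope(x: np.ndarray, y: np.ndarray):
    """Least-squares slope of a line through the origin, plus its R^2."""
    denom = float((x * x).sum())
    if denom == 0:
        raise EstimationError("degenerate fit: no offsets")
    slope = float((x * y).sum()) / denom
    ss_res = float(((y - slope * x) ** 2).sum())
    ss_tot = float((y**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


def _offset_grid(n: int):
    """Offsets in steps: 1 .. floor((n-1)/2), per the T/2 maximum."""
    return np.arange(1, (n - 1) // 2 + 1)


def mean_displacement(theta: np.ndarray, dt: float) -> tuple:
    """Theta(u) = mean over fiducial t of theta(t+u) - theta(t), for all offsets.

    Returns (u_ms, Theta) with u up to half the duration.  Computed with
    cumulative sums in O(n) per offset.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    js = _offset_grid(n)
    C = np.concatenate([[0.0], np.cumsum(theta)])
    total = C[n]
    counts = n - js
    sums = (total - C[js]) - C[counts]
    return js * dt, sums / counts


def squared_displacement(omega: np.ndarray, dt: float) -> tuple:
    """Omega(u) = mean over t of [omega(t+u) - omega(t)]^2 for all offsets.

    Uses the identity sum (w_{t+u} - w_t)^2 = tail + head - 2 autocorr(u),
    with the autocorrelation from a zero-padded FFT.
    """
    w = np.asarray(omega, dtype=float)
    n = w.size
    js = _offset_grid(n)
    sq = w * w
    Csq = np.concatenate([[0.0], np.cumsum(sq)])
    total = Csq[n]
    tail = total - Csq[js]          # sum_{t=j}^{n-1} w^2
    head = Csq[n - js]              # sum_{t=0}^{n-1-j} w^2
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fw = np.fft.rfft(w, nfft)
    acorr = np.fft.irfft(fw * np.conj(fw), nfft)[:n]
    counts = n - js
    return js * dt, (tail + head - 2.0 * acorr[js]) / counts


@dataclasses.dataclass
class VelocityEstimate:
    v: float  # neurons/s
    per_bump: np.ndarray
    r2: float


def estimate_velocity(traj: tracking.BumpTrajectory, T: Optional[float] = None) -> VelocityEstimate:
    """Bump velocity from the origin-constrained fit Theta(u) ~ v u."""
    pos = traj.positions
    if pos.shape[0] < 2:
        raise EstimationError("trajectory shorter than 2 steps")
    dt = float(traj.times[1] - traj.times[0])
    if T is not None:
        keep = traj.times <= T + 1e-9
        pos = pos[keep]
    vs, r2s = [], []
    for m in range(pos.shape[1]):
        u, Th = mean_displacement(pos[:, m], dt)
        slope, r2 = _origin_slope(u, Th)
        vs.append(slope * _MS_PER_S)
        r2s.append(r2)
    vs = np.asarray(vs)
    return VelocityEstimate(v=float(vs.mean()), per_bump=vs, r2=float(np.mean(r2s)))


@dataclasses.dataclass
class DiffusionEstimate:
    D: float  # neurons^2/s
    per_bump: np.ndarray
    bootstrap_sd: float
    n_replicates: int
    n_boot: int


def _positions_array(ensemble: Sequence[tracking.BumpTrajectory]) -> np.ndarray:
    lengths = {t.positions.shape for t in ensemble}
    if len(lengths) != 1:
        raise EstimationError("mismatched trajectory lengths in ensemble")
    return np.stack([t.positions for t in ensemble])  # (R, T, M)


def _diffusion_from_positions(pos: np.ndarray, dt: float) -> np.ndarray:
    """Per-bump D from an (R, T, M) position array (one bump per simulation)."""
    omega = pos - pos.mean(axis=0, keepdims=True)
    R, T, M = pos.shape
    Ds = np.empty(M)
    for m in range(M):
        acc = None
        for r in range(R):
            u, Om = squared_displacement(omega[r, :, m], dt)
            acc = Om if acc is None else acc + Om
        slope, _ = _origin_slope(u, acc / R)
        Ds[m] = 0.5 * slope * _MS_PER_S
    return Ds


def estimate_diffusion(
    ensemble: Sequence[tracking.BumpTrajectory],
    n_boot: int = 48,
    seed: int = 0,
) -> DiffusionEstimate:
    """Diffusion coefficient from an ensemble of replicate trajectories.

    Ensemble averaging pairs bumps by identity number (one bump per
    simulation); the reported D averages over bump identities.  The
    bootstrap SD resamples replicates with replacement and reruns the whole
    estimate.
    """
    if len(ensemble) < 2:
        raise EstimationError("need at least 2 replicates")
    pos = _positions_array(ensemble)
    dt = float(ensemble[0].times[1] - ensemble[0].times[0])
    Ds = _diffusion_from_positions(pos, dt)
    rng = np.random.default_rng(seed)
    R = pos.shape[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, R, size=R)
        boots[i] = _diffusion_from_positions(pos[idx], dt).mean()
    return DiffusionEstimate(
        D=float(Ds.mean()),
        per_bump=Ds,
        bootstrap_sd=float(boots.std(ddof=1)),
        n_replicates=R,
        n_boot=n_boot,
    )


def bootstrap_sd(
    ensemble: Sequence,
    statistic: Callable[[Sequence], float],
    n_boot: int = 48,
    n_per: Optional[int] = None,
    seed: int = 0,
) -> float:
    """SD of ``statistic`` over bootstrapped ensembles (sampled with replacement)."""
    if not ensemble:
        raise EstimationError("empty ensemble")
    rng = np.random.default_rng(seed)
    n_per = len(ensemble) if n_per is None else n_per
    vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, len(ensemble), size=n_per)
        vals[i] = statistic([ensemble[j] for j in idx])
    return float(vals.std(ddof=1))


# -- connectivity-noise measurements ----------------------------------------

TRAP_SPEED = 0.5        # neurons/s: below this ...
TRAP_WINDOW_MS = 500.0  # ... for this long counts as trapped
ESCAPE_LIMIT = 1.28
ESCAPE_ROUNDS = 8
SMOOTH_WIDTH_MS = 10.0  # Gaussian std of the velocity smoother (= tau)


@dataclasses.dataclass
class EscapeResult:
    b0: float
    b_positive: float
    b_negative: float
    saturated: bool


class _TraversalRun:
    """Chunked simulation that reports traversal or trapping."""

    #: position-sampling stride (steps); 4 x 0.5 ms keeps inter-sample motion
    #: far below a neuron at any realised bump speed
    STRIDE = 4

    def __init__(self, config, conn, b, state, rng):
        self.config = config
        g = state.as_array()[None] if isinstance(state, simulate.NetworkState) else np.asarray(state)
        if g.ndim == 2:
            g = g[None]
        self.sim = simulate.Simulation(
            config, conn, g, b=b,
            noise=simulate.NoiseSpec(kind="connectivity", conn_magnitude=conn.noise_magnitude),
            rng=rng,
        )
        self.sample_dt = self.STRIDE * config.dt
        self.visited = np.zeros(config.N, dtype=bool)
        self.positions = [self.sim.tracked_origin()]
        self._mark(self.positions[0])

    def _mark(self, pos):
        self.visited[np.rint(pos).astype(int).ravel() % self.config.N] = True

    def advance(self, n_steps):
        n_steps = self.STRIDE * max(1, n_steps // self.STRIDE)
        pos = self.sim.run_steps(n_steps, track=True, track_every=self.STRIDE)
        self._mark(pos)
        self.positions.append(pos[:, -1, :])
        return pos

    def traversed(self) -> bool:
        return bool(self.visited.all())


def _classify(config, conn, b, state, max_sim_ms, rng) -> bool:
    """True if the bumps traverse the whole ring under drive b, False if trapped."""
    run = _TraversalRun(config, conn, b, state, rng)
    window_steps = max(1, int(round(TRAP_WINDOW_MS / config.dt)))
    thresh = TRAP_SPEED * TRAP_WINDOW_MS / _MS_PER_S  # neurons per window
    chunk = max(200, window_steps // 2)
    recent = [run.positions[0]]
    steps_done = 0
    total = int(round(max_sim_ms / config.dt))
    while steps_done < total:
        n = min(chunk, total - steps_done)
        pos = run.advance(n)
        steps_done += n
        if run.traversed():
            return True
        recent.append(run.positions[-1])
        lag = int(np.ceil(window_steps / chunk)) + 1
        if len(recent) > lag:
            recent.pop(0)
            disp = np.abs(run.positions[-1] - recent[0])
            if disp.max() < thresh:
                return False  # all bumps essentially stationary for the window
        del pos
    return False  # time cap without traversal counts as trapped


def find_escape_drive(
    config: ModelConfig,
    conn_with_noise: Connectivity,
    state=None,
    max_sim_ms: float = 60000.0,
    seed: int = 0,
) -> EscapeResult:
    """Escape drive by 8-round binary searches over b in (0, 1.28] and (0, -1.28].

    For each test drive the simulation runs until every integer position has
    been visited by a bump (escape) or any bump stays slower than 0.5
    neurons/s for 500 ms (trapped).  The escape drive is the larger magnitude
    of the two directional thresholds, accurate to 1.28 / 2^7 = 0.01.
    """
    if state is None:
        spec = simulate.NoiseSpec(kind="connectivity", conn_magnitude=conn_with_noise.noise_magnitude)
        state = simulate.form_bumps(config, conn_with_noise, noise=spec, rng=seed, warn=False)
    thresholds = []
    saturated = False
    for sign in (1.0, -1.0):
        lo, hi = 0.0, ESCAPE_LIMIT
        escaped_at_hi = None
        for _ in range(ESCAPE_ROUNDS):
            mid = 0.5 * (lo + hi)
            rng = np.random.default_rng(seed)
            if _classify(config, conn_with_noise, sign * mid, state, max_sim_ms, rng):
                hi = mid
                escaped_at_hi = True
            else:
                lo = mid
        if escaped_at_hi is None:
            saturated = True
        thresholds.append(hi)
    b_pos, b_neg = thresholds
    return EscapeResult(
        b0=float(max(b_pos, b_neg)),
        b_positive=float(b_pos),
        b_negative=float(b_neg),
        saturated=saturated,
    )


@dataclasses.dataclass
class SpeedProfile:
    position_bins: np.ndarray
    mean_speed: np.ndarray  # neurons/s, signed mean of smoothed velocity per bin
    sd_speed: np.ndarray
    direction: int  # sign of the drive


def speed_profile_from_trajectory(
    traj: tracking.BumpTrajectory, config: ModelConfig, direction: int
) -> SpeedProfile:
    """Bin time-smoothed instantaneous velocities by integer bump position."""
    dt = float(traj.times[1] - traj.times[0])
    sigma_steps = SMOOTH_WIDTH_MS / dt
    N = config.N
    sums = np.zeros(N)
    sqs = np.zeros(N)
    cnt = np.zeros(N)
    for m in range(traj.M):
        p = traj.positions[:, m]
        vel = np.diff(p) / dt * _MS_PER_S
        vel = gaussian_filter1d(vel, sigma_steps, truncate=3.0)
        bins = np.rint(p[1:]).astype(int) % N
        np.add.at(sums, bins, vel)
        np.add.at(sqs, bins, vel**2)
        np.add.at(cnt, bins, 1)
    filled = cnt > 0
    bins = np.nonzero(filled)[0]
    mean = sums[filled] / cnt[filled]
    var = np.maximum(sqs[filled] / cnt[filled] - mean**2, 0.0)
    return SpeedProfile(
        position_bins=bins,
        mean_speed=mean,
        sd_speed=np.sqrt(var),
        direction=direction,
    )


def measure_speed_profile(
    config: ModelConfig,
    conn_with_noise: Connectivity,
    b: float,
    state=None,
    max_sim_ms: float = 40000.0,
    seed: int = 0,
) -> SpeedProfile:
    """Position-dependent traversal speed under drive b (requires |b| > b0)."""
    if state is None:
        spec = simulate.NoiseSpec(kind="connectivity", conn_magnitude=conn_with_noise.noise_magnitude)
        state = simulate.form_bumps(config, conn_with_noise, noise=spec, rng=seed, warn=False)
    run = _TraversalRun(config, conn_with_noise, b, state, np.random.default_rng(seed))
    chunks = []
    total = int(round(max_sim_ms / config.dt))
    done = 0
    while done < total and not run.traversed():
        n = min(2000, total - done)
        chunks.append(run.advance(n)[0])  # (n, M)
        done += n
    if not run.traversed():
        last = run.positions[-1].ravel() % config.N
        raise EstimationError(
            f"trapping detected near position(s) {np.rint(last).astype(int)} at b={b}"
        )
    origin = run.positions[0][0][None, :]
    pos = np.vstack([origin] + chunks)
    times = np.arange(pos.shape[0]) * run.sample_dt
    traj = tracking.BumpTrajectory(times=times, positions=pos, N=config.N)
    return speed_profile_from_trajectory(traj, config, direction=int(np.sign(b)))


def speed_difference(p_plus: SpeedProfile, p_minus: SpeedProfile) -> float:
    """2 |mean|v+| - mean|v-|| / (mean|v+| + mean|v-|) over position bins."""
    m_plus = float(np.mean(np.abs(p_plus.mean_speed)))
    m_minus = float(np.mean(np.abs(p_minus.mean_speed)))
    return 2.0 * abs(m_plus - m_minus) / (m_plus + m_minus)


def speed_variability(p_plus: SpeedProfile, p_minus: SpeedProfile) -> float:
    """(std|v+| + std|v-|) / (mean|v+| + mean|v-|) over position bins."""
    m_plus = float(np.mean(np.abs(p_plus.mean_speed)))
    m_minus = float(np.mean(np.abs(p_minus.mean_speed)))
    s_plus = float(np.std(np.abs(p_plus.mean_speed)))
    s_minus = float(np.std(np.abs(p_minus.mean_speed)))
    return (s_plus + s_minus) / (m_plus + m_minus)
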