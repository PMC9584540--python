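"""Coordinate mappings and mutual-information readout of the population code.

A ring network can encode a linear coordinate (position: every neuron spans
a fixed physical interval, here 1 cm) or a circular coordinate (orientation:
one bump distance always spans 360 degrees, i.e. 360 M / N degrees per
neuron, with the drive coupling gamma rescaled proportional to N/M so path
integration is consistent across architectures).  Encoding quality is
measured as the mutual information between a discretized coordinate variable
U — replicate simulations initialized on an evenly spaced coordinate grid
and degraded by input noise — and the discretized activity S of a single
neuron, optionally joined with four coarse location cues that each cover one
quadrant of the coordinate range.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np

from . import simulate, tracking
from .model import Connectivity, ModelConfig, build_connectivity

logger = logging.getLogger(__name__)

N_BINS = 6          # activity bins per neuron
PERCENTILE = 99.0   # upper edge of the binning range
LINEAR_CM_PER_NEURON = 1.0


class InformationError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class CoordinateMap:
    """Invertible map between physical coordinate and network position."""

    kind: str
    units_per_neuron: float
    u_max: float
    N: int

    def to_network(self, u) -> np.ndarray:
        return np.asarray(u, dtype=float) / self.units_per_neuron % self.N

    def to_physical(self, pos) -> np.ndarray:
        span = self.u_max
        out = np.asarray(pos, dtype=float) * self.units_per_neuron
        if self.kind == "circular":
            out %= 360.0
        return out


def coordinate_map(config: ModelConfig, kind: str, u_max: float) -> CoordinateMap:
    """Build the linear (1 cm/neuron) or circular (360 M / N deg/neuron) map."""
    if kind == "linear":
        upn = LINEAR_CM_PER_NEURON
    elif kind == "circular":
        if u_max > 360.0:
            raise InformationError("circular coordinate range cannot exceed 360 degrees")
        upn = 360.0 * config.M / config.N
    else:
        raise InformationError(f"unknown mapping kind {kind!r}")
    return CoordinateMap(kind=kind, units_per_neuron=upn, u_max=float(u_max), N=config.N)


def rescale_gamma(config: ModelConfig) -> float:
    """Effective drive coupling: gamma (N/600)(3/M) under circular mapping, else gamma."""
    return config.gamma_effective


@dataclasses.dataclass
class MISamples:
    """Final-rate samples per (coordinate, replicate, neuron)."""

    coordinates: np.ndarray          # physical units, length n_coords
    rates: np.ndarray                # (n_coords, n_rep, 2N)
    valid: np.ndarray                # (n_coords, n_rep) bool, False = excluded replicate
    cmap: CoordinateMap
    config: ModelConfig
    sigma: float


def mi_experiment(
    config: ModelConfig,
    cmap: CoordinateMap,
    sigma: float,
    n_coords: int = 20,
    n_rep: int = 96,
    duration_ms: float = 5000.0,
    seed: int = 0,
    conn: Optional[Connectivity] = None,
) -> MISamples:
    """Generate the rate samples for the mutual-information readout.

    The coordinate range is divided into ``n_coords`` equally spaced values
    u_max/n .. u_max.  For each coordinate, ``n_rep`` replicates are formed
    with bumps seeded at the mapped network phase (and its M-fold copies),
    then evolved for ``duration_ms`` under input noise with no drive; the
    final deterministic rates of all 2N neurons are recorded.  Replicates
    whose bump count differs from M are marked invalid and logged.
    """
    if conn is None:
        conn = build_connectivity(config)
    coords = np.arange(1, n_coords + 1) * (cmap.u_max / n_coords)
    rng = np.random.default_rng(seed)
    noise = simulate.NoiseSpec(kind="input", sigma=sigma)
    rates = np.empty((n_coords, n_rep, 2 * config.N))
    valid = np.ones((n_coords, n_rep), dtype=bool)
    lam = config.lam
    for ci, u in enumerate(coords):
        phase = float(cmap.to_network(u))
        seeds = [(phase + m * lam) % config.N for m in range(config.M)]
        g0 = simulate.form_bumps(
            config, conn, noise=noise, seed_positions=seeds,
            rng=rng, batch=n_rep, warn=False,
        )
        sim = simulate.Simulation(config, conn, g0, b=0.0, noise=noise, rng=rng)
        sim.run_steps(int(round(duration_ms / config.dt)))
        s = sim.rates()  # (n_rep, 2, N)
        for ri in range(n_rep):
            S = s[ri, 0] + s[ri, 1]
            if tracking.count_bumps(S) != config.M:
                valid[ci, ri] = False
        rates[ci] = s.reshape(n_rep, 2 * config.N)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("mi_experiment: excluded %d/%d replicates (bump count != M)",
                       n_bad, valid.size)
    return MISamples(coordinates=coords, rates=rates, valid=valid,
                     cmap=cmap, config=config, sigma=sigma)


def bin_rates(samples: np.ndarray, n_bins: int = N_BINS, percentile: float = PERCENTILE) -> np.ndarray:
    """Discretize rates into ``n_bins`` equal bins from 0 to the pooled 99th percentile.

    The percentile is computed across all neurons and samples; rates above
    it fall in the top bin.  If all rates are equal (degenerate edges) every
    sample lands in the lowest bin.  Returns integer states 0..n_bins-1 with
    the input's shape.
    """
    samples = np.asarray(samples, dtype=float)
    top = np.percentile(samples, percentile)
    if top <= 0:
        return np.zeros(samples.shape, dtype=int)
    edges = np.linspace(0.0, top, n_bins + 1)[1:-1]
    return np.digitize(samples, edges, right=False)


def mutual_information(joint_counts: np.ndarray) -> float:
    """I[S;U] in bits from a counts table of shape (n_states, n_coords).

    p(u) is uniform over coordinates, p(s|u) comes from normalizing each
    column, and p(s) by marginalization; 0 log 0 terms are dropped.
    """
    counts = np.asarray(joint_counts, dtype=float)
    if counts.ndim != 2 or counts.size == 0:
        raise InformationError("joint_counts must be a 2D table")
    col = counts.sum(axis=0)
    if np.any(col == 0):
        raise InformationError("empty coordinate column in counts table")
    p_su = counts / col  # p(s|u)
    n_u = counts.shape[1]
    p_s = p_su.mean(axis=1)  # marginal under uniform p(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_su > 0, p_su / p_s[:, None], 1.0)
        terms = np.where(p_su > 0, p_su * np.log2(ratio), 0.0)
    return float(terms.sum() / n_u)


def cue_states(coordinates: np.ndarray, u_max: float, n_cues: int = 4) -> np.ndarray:
    """Quadrant cue label (0..n_cues-1) for each coordinate in (0, u_max]."""
    u = np.asarray(coordinates, dtype=float)
    if np.any(u <= 0) or np.any(u > u_max + 1e-9):
        raise InformationError("coordinate outside range (0, u_max]")
    lab = np.ceil(u * n_cues / u_max).astype(int) - 1
    return np.clip(lab, 0, n_cues - 1)


@dataclasses.dataclass
class MIResult:
    per_neuron_mi: np.ndarray
    mean_mi: float
    se: float
    with_cues: bool
    n_coords: int
    n_replicates: int


def compute_mi(
    samples: MISamples,
    with_cues: bool = False,
    n_cues: int = 4,
    n_boot: int = 200,
    seed: int = 0,
) -> MIResult:
    """Per-neuron (optionally neuron+cue) mutual information with the coordinate.

    Rates are binned with a pooled percentile rule; for each neuron a counts
    table over activity states x coordinates (6 x n_coords, or 24 x n_coords
    with cues) feeds the discrete MI formula.  The standard error of the
    mean MI across neurons is bootstrapped over neurons.
    """
    n_coords, n_rep, n_neurons = samples.rates.shape
    states = bin_rates(samples.rates)
    cues = cue_states(samples.coordinates, samples.cmap.u_max, n_cues) if with_cues else None
    n_states = N_BINS * (n_cues if with_cues else 1)
    mi = np.empty(n_neurons)
    counts = np.zeros((n_states, n_coords))
    for j in range(n_neurons):
        counts[:] = 0.0
        st = states[:, :, j]
        for ci in range(n_coords):
            sel = st[ci][samples.valid[ci]]
            if sel.size == 0:
                raise InformationError(f"no valid replicates at coordinate index {ci}")
            full = sel + N_BINS * cues[ci] if with_cues else sel
            counts[:, ci] = np.bincount(full, minlength=n_states)
        mi[j] = mutual_information(counts)
    rng = np.random.default_rng(seed)
    boots = rng.integers(0, n_neurons, size=(n_boot, n_neurons))
    se = float(mi[boots].mean(axis=1).std(ddof=1))
    return MIResult(
        per_neuron_mi=mi,
        mean_mi=float(mi.mean()),
        se=se,
        with_cues=with_cues,
        n_coords=n_coords,
        n_replicates=n_rep,
    )


def cue_only_information(n_coords: int = 20, u_max: float = 200.0, n_cues: int = 4) -> float:
    """MI between the uniform coordinate variable and the cue state alone.

    With n_coords uniform coordinates split evenly over n_cues quadrants the
    cue refines U into n_cues equiprobable groups: I = log2(n_cues) bits.
    Computed from the counts table, not asserted.
    """
    coords = np.arange(1, n_coords + 1) * (u_max / n_coords)
    cues = cue_states(coords, u_max, n_cues)
    counts = np.zeros((n_cues, n_coords))
    counts[cues, np.arange(n_coords)] = 1.0
    return mutual_information(counts)
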