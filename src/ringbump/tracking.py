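"""Bump localization and trajectory assembly.

Positions are tracked from the firing rate summed across both populations,
S_i = s_L(i) + s_R(i).  A circular center of mass with periodicity N/M gives
a global phase; the ring is then partitioned into M near-equal segments,
circularly shifted so the phase sits at the middle of the first segment, and
a plain center of mass is taken inside each segment.  Identity labels are
assigned once and preserved across frames by nearest-neighbour matching on
the ring, which also drives the cumulative unwrapping used for displacement
statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np

PRESENCE_THRESHOLD = 1e-6  # relative to max(S): below this a site is "silent"


class TrackingError(RuntimeError):
    pass


def ring_difference(a, b, N: float):
    """Signed minimal displacement from b to a on a ring of circumference N."""
    return (np.asarray(a) - np.asarray(b) + N / 2.0) % N - N / 2.0


def global_phase(S: np.ndarray, M: int) -> float:
    """Circular center of mass of S with periodicity N/M, in [0, N/M).

    theta0 = (N / 2 pi M) atan2(sum S sin(2 pi i M / N), sum S cos(...)).
    """
    S = np.asarray(S, dtype=float)
    N = S.size
    if not np.any(S > 0):
        raise TrackingError("undefined phase: all rates are zero")
    ang = 2.0 * np.pi * np.arange(N) * M / N
    phase = np.arctan2((S * np.sin(ang)).sum(), (S * np.cos(ang)).sum())
    phase %= 2.0 * np.pi
    return float(N / (2.0 * np.pi * M) * phase)


def _segment_starts(N: int, M: int) -> np.ndarray:
    """Start indices of M segments of length floor(N/M), spread as evenly as possible."""
    return np.floor(np.arange(M) * N / M).astype(int)


def bump_positions(S: np.ndarray, M: int) -> np.ndarray:
    """Positions of the M bumps in a summed-rate snapshot, in [0, N).

    The snapshot is circularly shifted so the global phase lands at the
    middle of the first segment (both rounded to integers), a center of mass
    is taken per segment, and the shift is reversed.
    """
    S = np.asarray(S, dtype=float)
    N = S.size
    if M < 1:
        raise TrackingError("M must be >= 1")
    theta0 = global_phase(S, M)
    seg_len = N // M
    mid = int(round(N / (2.0 * M)))
    shift = mid - int(round(theta0))
    shifted = np.roll(S, shift)
    starts = _segment_starts(N, M)
    floor = PRESENCE_THRESHOLD * shifted.max()
    positions = np.empty(M)
    for m, start in enumerate(starts):
        seg = shifted[start : start + seg_len]
        seg = np.where(seg > floor, seg, 0.0)
        tot = seg.sum()
        if tot <= 0:
            raise TrackingError(f"missing bump: segment {m} has zero total rate")
        com = float((np.arange(start, start + seg_len) * seg).sum() / tot)
        positions[m] = (com - shift) % N
    return positions


def count_bumps(S: np.ndarray) -> int:
    """Number of maximal circular runs where S exceeds 1e-6 of its maximum."""
    S = np.asarray(S, dtype=float)
    if S.size == 0 or S.max() <= 0:
        return 0
    active = S > PRESENCE_THRESHOLD * S.max()
    if active.all():
        return 1
    # count rising edges on the ring
    prev = np.roll(active, 1)
    return int((active & ~prev).sum())


def bump_positions_batch(S: np.ndarray, M: int) -> np.ndarray:
    """Vectorized ``bump_positions`` for a batch of snapshots.

    ``S`` has shape (B, N); returns (B, M).  Used by the simulation engine,
    which tracks every timestep of large replicate ensembles.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    B, N = S.shape
    ang = 2.0 * np.pi * np.arange(N) * M / N
    phase = np.arctan2(S @ np.sin(ang), S @ np.cos(ang)) % (2.0 * np.pi)
    theta0 = N / (2.0 * np.pi * M) * phase
    seg_len = N // M
    mid = int(round(N / (2.0 * M)))
    shift = mid - np.rint(theta0).astype(int)
    idx = (np.arange(N)[None, :] - shift[:, None]) % N
    shifted = np.take_along_axis(S, idx, axis=1)
    floor = PRESENCE_THRESHOLD * shifted.max(axis=1, keepdims=True)
    shifted = np.where(shifted > floor, shifted, 0.0)
    starts = _segment_starts(N, M)
    positions = np.empty((B, M))
    for m, start in enumerate(starts):
        seg = shifted[:, start : start + seg_len]
        tot = seg.sum(axis=1)
        if np.any(tot <= 0):
            raise TrackingError(f"missing bump in segment {m}")
        com = (seg * np.arange(start, start + seg_len)).sum(axis=1) / tot
        positions[:, m] = (com - shift) % N
    return positions


def advance_positions(prev_wrapped: np.ndarray, candidates: np.ndarray, N: int):
    """Match new candidate positions to previous ones by minimal ring distance.

    ``prev_wrapped`` and ``candidates`` have shape (B, M).  Returns
    (matched, delta): candidates reordered to continue each bump, and the
    signed per-bump displacement.  Valid while per-step motion stays well
    below the bump spacing.
    """
    diff = ring_difference(candidates[:, None, :], prev_wrapped[:, :, None], N)
    pick = np.abs(diff).argmin(axis=2)  # (B, M)
    b_idx = np.arange(diff.shape[0])[:, None]
    delta = diff[b_idx, np.arange(diff.shape[1])[None, :], pick]
    matched = candidates[b_idx, pick]
    return matched, delta


@dataclasses.dataclass
class BumpTrajectory:
    """Unwrapped per-bump positions over time.

    ``positions`` has shape (n_frames, M); entry [t, m] is the cumulative
    (mod-N-unwrapped) position of bump m, so values may leave [0, N).
    """

    times: np.ndarray
    positions: np.ndarray
    N: int
    bump_ids: np.ndarray = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.bump_ids is None:
            self.bump_ids = np.arange(1, self.positions.shape[1] + 1)

    @property
    def M(self) -> int:
        return self.positions.shape[1]

    def wrapped(self) -> np.ndarray:
        return self.positions % self.N

    def save_tsv(self, path) -> None:
        """Delimited text: time_ms, bump_id, position_neurons, position_unwrapped."""
        wrapped = self.wrapped()
        with open(path, "w") as fh:
            fh.write("time_ms\tbump_id\tposition_neurons\tposition_unwrapped\n")
            for t, row, wrow in zip(self.times, self.positions, wrapped):
                for bid, p, wp in zip(self.bump_ids, row, wrow):
                    fh.write(f"{t}\t{bid}\t{wp:.6g}\t{p:.6g}\n")


def match_frame(prev: np.ndarray, current: np.ndarray, N: int) -> np.ndarray:
    """Order ``current`` positions so element m continues bump m of ``prev``.

    Bumps cannot pass each other, so the cyclic order is preserved: sort the
    candidates and test the M cyclic pairings against the previous frame,
    keeping the one with the smallest total ring distance.
    """
    prev = np.asarray(prev, dtype=float) % N
    current = np.sort(np.asarray(current, dtype=float) % N)
    M = prev.size
    if current.size != M:
        raise TrackingError(f"bump count changed: {M} -> {current.size}")
    if M > 1 and np.min(np.diff(np.concatenate([current, [current[0] + N]]))) < 1.0:
        raise TrackingError("ambiguous matching: two bumps within 1 neuron")
    order = np.argsort(prev)
    best, best_cost = None, np.inf
    for r in range(M):
        cand = np.empty(M)
        cand[order] = np.roll(current, -r)[np.arange(M)]
        cost = np.abs(ring_difference(cand, prev, N)).sum()
        if cost < best_cost:
            best, best_cost = cand, cost
    return best


def unwrap_trajectory(frames, N: int, times=None, dt: float = 1.0) -> BumpTrajectory:
    """Assemble an unwrapped trajectory from per-frame position lists.

    Per-frame displacements must stay below a quarter bump distance for the
    minimal-displacement rule to be valid; identity labels 1..M follow the
    first frame's sorted order.
    """
    frames = [np.atleast_1d(np.asarray(f, dtype=float)) for f in frames]
    if not frames:
        raise TrackingError("empty trajectory")
    M = frames[0].size
    out = np.empty((len(frames), M))
    out[0] = np.sort(frames[0] % N)
    prev_wrapped = out[0].copy()
    for t in range(1, len(frames)):
        matched = match_frame(prev_wrapped, frames[t], N)
        out[t] = out[t - 1] + ring_difference(matched, prev_wrapped, N)
        prev_wrapped = matched
    if times is None:
        times = np.arange(len(frames)) * dt
    return BumpTrajectory(times=times, positions=out, N=N)
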