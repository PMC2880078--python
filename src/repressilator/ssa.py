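"""Exact stochastic simulation (Gillespie direct method) of the ring.

The jump process runs on integer copy numbers for the 2n species
``[M_1..M_n, P_1..P_n]`` with the 4n birth/death reactions of
:func:`repressilator.model.reaction_system`; the copy-number scale ``omega``
links counts to ODE concentrations (count ~ omega * concentration).  The
inner loop is compiled with numba; the generator state is seeded once per
trace, so a given seed reproduces the trace exactly, including across the
chunked runs used by the closed-loop controller.

Period estimation for noisy traces uses smoothed autocorrelation rather than
peak counting, which is unreliable at low copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import DEFAULT_HILL, HillRepression, RingParameters

__all__ = [
    "StochasticTrace",
    "NonOscillatoryError",
    "gillespie",
    "counts_from_state",
    "estimate_period_stochastic",
    "detect_switching",
]


class NonOscillatoryError(RuntimeError):
    """No secondary autocorrelation peak: the trace is not oscillatory."""


@dataclass
class StochasticTrace:
    """Copy-number path sampled on a uniform time grid (piecewise constant)."""

    t: np.ndarray
    counts: np.ndarray  # (N, 2n) int64
    params: RingParameters
    omega: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.params.n

    @property
    def concentrations(self) -> np.ndarray:
        return self.counts / self.omega

    def protein_counts(self, gene: int) -> np.ndarray:
        if not 1 <= gene <= self.n:
            raise ValueError(f"gene index {gene} outside 1..{self.n}")
        return self.counts[:, self.n + gene - 1]


@njit(cache=True)
def _seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _ssa_core(c1, c2, c3, c4, h, K, omega, counts, t0, t1, drive, grid, out, cap):
    """Direct-method SSA from t0 to t1, recording onto grid times in [t0, t1).

    ``counts`` is modified in place and holds the final state on return.
    Returns 0 on success, 1 if any count exceeded ``cap``.
    """
    n = c1.size
    a = np.empty(4 * n)
    t = t0
    gi = 0
    while gi < grid.size and grid[gi] < t0:
        gi += 1
    while True:
        a0 = 0.0
        for j in range(n):
            pprev = counts[n + ((j - 1) % n)] / omega
            hill = 1.0 / (1.0 + (pprev / K) ** h)
            a[j] = omega * (c1[j] * hill + drive[j])
            a[n + j] = c2[j] * counts[j]
            a[2 * n + j] = c3[j] * counts[j]
            a[3 * n + j] = c4[j] * counts[n + j]
        for r in range(4 * n):
            a0 += a[r]
        if a0 <= 0.0:
            t = t1
        else:
            t += -np.log(np.random.random()) / a0
        while gi < grid.size and grid[gi] < min(t, t1):
            for s in range(2 * n):
                out[gi, s] = counts[s]
            gi += 1
        if t >= t1:
            break
        u = np.random.random() * a0
        acc = 0.0
        r = 4 * n - 1
        for k in range(4 * n):
            acc += a[k]
            if u < acc:
                r = k
                break
        j = r % n
        if r < n:
            counts[j] += 1
        elif r < 2 * n:
            counts[j] -= 1
        elif r < 3 * n:
            counts[n + j] += 1
        else:
            counts[n + j] -= 1
        if counts[j] > cap or counts[n + j] > cap:
            return 1
    return 0


def counts_from_state(y: np.ndarray, omega: float) -> np.ndarray:
    """Integer copy numbers nearest to a concentration state scaled by omega."""
    return np.rint(np.asarray(y, float) * omega).astype(np.int64)


def gillespie(
    params: RingParameters,
    omega: float,
    init_counts: np.ndarray,
    t_max: float,
    seed: int,
    hill: HillRepression = DEFAULT_HILL,
    record_dt: float | None = None,
    drive: np.ndarray | None = None,
    t_start: float = 0.0,
    cap: float = 1e9,
    _reseed: bool = True,
) -> StochasticTrace:
    """Exact SSA trace on [t_start, t_max], recorded every ``record_dt`` min.

    With ``_reseed`` False the global numba RNG stream continues from the
    previous call (used for chunked closed-loop simulation).
    """
    if t_max <= t_start:
        raise ValueError("t_max must exceed t_start")
    counts = np.asarray(init_counts, dtype=np.int64).copy()
    if counts.shape != (2 * params.n,) or np.any(counts < 0):
        raise ValueError("init_counts must be non-negative of length 2n")
    if record_dt is None:
        record_dt = (t_max - t_start) / 2000.0
    c1, c2, c3, c4 = params.rate_arrays()
    d = np.zeros(params.n) if drive is None else np.asarray(drive, dtype=float)
    grid = np.arange(t_start, t_max, record_dt)
    out = np.zeros((grid.size, 2 * params.n), dtype=np.int64)
    if _reseed:
        _seed_rng(seed)
    status = _ssa_core(
        c1, c2, c3, c4, float(hill.h), float(hill.threshold), float(omega),
        counts, float(t_start), float(t_max), d, grid, out, float(cap),
    )
    if status != 0:
        raise RuntimeError(f"copy number exceeded cap {cap:g}; check parameters")
    t = np.append(grid, t_max)
    out = np.vstack([out, counts[None, :]])
    return StochasticTrace(
        t=t, counts=out, params=params, omega=omega, seed=seed,
        meta={"record_dt": record_dt, "final_counts": counts},
    )


def estimate_period_stochastic(
    trace: StochasticTrace,
    gene: int = 1,
    smoothing_window: float | None = None,
    expected_period: float | None = None,
) -> float:
    """Oscillation period (min) from the smoothed autocorrelation of a protein.

    The count series is moving-average smoothed (default window: one tenth of
    ``expected_period`` if given, else 20 samples), demeaned, and the lag of
    the first positive-lag autocorrelation maximum above 0.1 is returned.
    Raises :class:`NonOscillatoryError` when no such peak exists.
    """
    from scipy.signal import find_peaks

    x = trace.protein_counts(gene).astype(float)
    dt = float(np.median(np.diff(trace.t[:-1]))) if trace.t.size > 2 else 1.0
    if smoothing_window is None:
        smoothing_window = expected_period / 10.0 if expected_period else 20 * dt
    w = max(1, int(round(smoothing_window / dt)))
    kernel = np.ones(w) / w
    z = np.convolve(x, kernel, mode="valid")
    z = z - z.mean()
    if np.allclose(z, 0):
        raise NonOscillatoryError("constant trace")
    ac = np.correlate(z, z, mode="full")[z.size - 1 :]
    ac = ac / ac[0]
    peaks, props = find_peaks(ac, height=0.1, prominence=0.05)
    if peaks.size == 0:
        raise NonOscillatoryError("no secondary autocorrelation peak")
    k = int(peaks[0])
    lag = float(k)
    if 0 < k < ac.size - 1:  # parabolic sub-grid refinement
        denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
        if denom < 0:
            lag += 0.5 * (ac[k - 1] - ac[k + 1]) / denom
    return float(lag * dt)


def detect_switching(
    trace: StochasticTrace,
    hill: HillRepression = DEFAULT_HILL,
    neutral_band: float = 0.3,
) -> list[tuple[str, float, float]]:
    """Dwell intervals in the two dimerized basins of an even ring.

    Each sample's protein vector (in concentration units) is classified by
    its distance to the two alternating fixed-point patterns, relative to the
    distance between the patterns; samples closer than ``neutral_band`` to
    neither (travelling-wave episodes, switching transits) stay unclassified.
    Consecutive same-basin samples merge into ``(basin, t_start, t_end)``
    intervals with basin "odd_up" or "even_up".
    """
    from .equilibria import dimerized_fixed_points

    fps = dimerized_fixed_points(trace.params, hill)
    if not fps:
        raise ValueError("dimerized fixed points undefined (c < 2)")
    n = trace.n
    patterns = {fp.assignment: fp.state(n)[n:] for fp in fps}
    gap = float(np.linalg.norm(patterns["odd_up"] - patterns["even_up"]))
    P = trace.counts[:, n:] / trace.omega
    d_odd = np.linalg.norm(P - patterns["odd_up"], axis=1) / gap
    d_even = np.linalg.norm(P - patterns["even_up"], axis=1) / gap
    label = np.where(
        np.minimum(d_odd, d_even) > neutral_band,
        -1,
        np.where(d_odd <= d_even, 0, 1),
    )
    names = {0: "odd_up", 1: "even_up"}
    intervals: list[tuple[str, float, float]] = []
    start = None
    cur = -1
    for i, lab in enumerate(label):
        if lab != cur:
            if cur in names and start is not None:
                intervals.append((names[cur], start, float(trace.t[i])))
            start = float(trace.t[i]) if lab in names else None
            cur = lab
    if cur in names and start is not None:
        intervals.append((names[cur], start, float(trace.t[-1])))
    return intervals
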