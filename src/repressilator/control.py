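"""STOP/KICK induction signals and switchable-oscillation protocols.

Interventions model light-activated transcription: a signal adds a constant
extra mRNA production rate to one gene for a finite window (never a state
clamp, so the flow stays smooth between switching events).

* A **STOP** on gene j, held longer than the oscillation period, drives an
  even ring into the dimerized fixed point with gene j up — a known rest
  state, whatever the previous history.
* A **KICK** on gene j+1 — a step of width and amplitude comparable to the
  oscillatory pattern — launches the travelling-wave quasi-stable orbit from
  that rest state.
* The closed-loop controller watches two successive proteins and fires a
  KICK on a readout gene whenever its protein falls below threshold (with a
  refractory time), sustaining the oscillation indefinitely; a STOP
  terminates it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DEFAULT_HILL, HillRepression, RingParameters
from .simulate import OscillationSummary, Trajectory, integrate, summarize_oscillation

__all__ = [
    "Signal",
    "StopKickSettings",
    "ControllerConfig",
    "SignalSchedule",
    "apply_signals",
    "stop_kick",
    "closed_loop",
]


@dataclass(frozen=True)
class Signal:
    """One timed induction pulse on a single gene (1-based index)."""

    kind: str  # "STOP" | "KICK"
    gene: int
    t_start: float
    duration: float
    amplitude: float  # added mRNA production rate, min^-1

    def __post_init__(self) -> None:
        if self.kind not in ("STOP", "KICK"):
            raise ValueError(f"signal kind must be STOP or KICK, got {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("signal duration must be positive")
        if self.amplitude < 0:
            raise ValueError("signal amplitude must be non-negative")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


class SignalSchedule:
    """Piecewise-constant drive built from non-overlapping per-gene signals."""

    def __init__(self, n: int, signals: list[Signal]):
        for s in signals:
            if not 1 <= s.gene <= n:
                raise ValueError(f"signal gene {s.gene} outside 1..{n}")
        by_gene: dict[int, list[Signal]] = {}
        for s in sorted(signals, key=lambda s: s.t_start):
            prev = by_gene.setdefault(s.gene, [])
            if prev and s.t_start < prev[-1].t_end:
                raise ValueError(
                    f"overlapping signals on gene {s.gene} at t = {s.t_start:g}"
                )
            prev.append(s)
        self.n = n
        self.signals = sorted(signals, key=lambda s: s.t_start)

    @property
    def boundaries(self) -> list[float]:
        return sorted({t for s in self.signals for t in (s.t_start, s.t_end)})

    def drive(self, t: float) -> np.ndarray:
        d = np.zeros(self.n)
        for s in self.signals:
            if s.t_start <= t < s.t_end:
                d[s.gene - 1] += s.amplitude
        return d


def apply_signals(params: RingParameters, signals: list[Signal]) -> SignalSchedule:
    """Validate signals against the ring and return the drive schedule."""
    return SignalSchedule(params.n, list(signals))


def _base_c1(params: RingParameters) -> float:
    return float(np.mean(params.rate_arrays()[0]))


@dataclass
class StopKickSettings:
    """Open-loop STOP-KICK protocol timing, in units of a reference period.

    The reference period is that of the quasi-stable orbit at the reference
    parameter set; amplitudes default to the reference c1 (an induction of
    the same order as the endogenous production), widths to the fractions
    the oscillatory pattern suggests: STOP 1.5 periods ("longer than the
    period"), KICK half a period.
    """

    reference_period: float
    stop_factor: float = 1.5
    settle_factor: float = 0.5
    kick_width_factor: float = 0.5
    post_periods: float = 10.0
    stop_amplitude: float | None = None  # default: reference c1
    kick_amplitude: float | None = None  # default: reference c1
    tol: float = 1e-8

    def build_signals(
        self, params: RingParameters, stop_gene: int, final_stop: bool = False
    ) -> list[Signal]:
        T = self.reference_period
        amp_stop = self.stop_amplitude if self.stop_amplitude is not None else _base_c1(params)
        amp_kick = self.kick_amplitude if self.kick_amplitude is not None else _base_c1(params)
        kick_gene = stop_gene % params.n + 1
        t_kick = self.stop_factor * T + self.settle_factor * T
        sigs = [
            Signal("STOP", stop_gene, 0.0, self.stop_factor * T, amp_stop),
            Signal("KICK", kick_gene, t_kick, self.kick_width_factor * T, amp_kick),
        ]
        if final_stop:
            sigs.append(
                Signal(
                    "STOP",
                    stop_gene,
                    t_kick + self.kick_width_factor * T + self.post_periods * T,
                    self.stop_factor * T,
                    amp_stop,
                )
            )
        return sigs

    def horizon(self, final_stop: bool = False) -> float:
        T = self.reference_period
        h = (self.stop_factor + self.settle_factor + self.kick_width_factor + self.post_periods) * T
        if final_stop:
            h += (self.stop_factor + 2.0) * T  # trailing STOP plus settling margin
        return h


def stop_kick(
    params: RingParameters,
    stop_gene: int,
    settings: StopKickSettings,
    hill: HillRepression = DEFAULT_HILL,
    init: np.ndarray | None = None,
    seed: int = 0,
    observed_genes=None,
    min_peaks: int = 5,
    final_stop: bool = False,
) -> tuple[Trajectory, OscillationSummary]:
    """Run the STOP-KICK(-STOP) protocol and summarize the induced response.

    The initial state defaults to a seeded random prior (uniform on
    ``[0, p_u]`` per coordinate) — the STOP stage is what initializes the
    ring, so induction must not depend on history.  The oscillation summary
    is computed on the window from the KICK to the final STOP (or the end).
    """
    if params.n % 2 == 1:
        raise ValueError("STOP-KICK induction targets even rings")
    if init is None:
        c = params.c
        hi = max(c - 1.0 / c, 1.0)
        init = np.random.default_rng(seed).uniform(0.0, hi, 2 * params.n)
    signals = settings.build_signals(params, stop_gene, final_stop=final_stop)
    schedule = apply_signals(params, signals)
    horizon = settings.horizon(final_stop=final_stop)
    traj = integrate(
        params,
        init,
        (0.0, horizon),
        tol=settings.tol,
        hill=hill,
        drive=schedule.drive,
        drive_boundaries=schedule.boundaries,
    )
    t_kick = signals[1].t_start
    t_end = signals[2].t_start if final_stop else traj.t[-1]
    window = traj.after(t_kick)
    window = Trajectory(
        window.t[window.t <= t_end], window.y[window.t <= t_end], params, traj.tol
    )
    summary = summarize_oscillation(
        window, observed_genes=observed_genes, min_peaks=min_peaks
    )
    return traj, summary


@dataclass
class ControllerConfig:
    """Threshold-based readout controller for two successive genes.

    Whenever a readout protein falls below its threshold (default
    ``threshold_frac * p_u``) and the refractory time has elapsed, a KICK of
    ``kick_width`` minutes fires on that protein's gene.  ``readout_delay``
    models fluorophore maturation as a constant lag.
    """

    readout_genes: tuple[int, int] = (1, 2)
    kick_width: float = 30.0
    kick_amplitude: float | None = None  # default: c1
    thresholds: tuple[float, float] | None = None  # default: threshold_frac * p_u
    threshold_frac: float = 0.1
    refractory: float | None = None  # default: kick_width
    check_dt: float = 2.0
    readout_delay: float = 0.0
    mode: str = "on"

    def __post_init__(self) -> None:
        a, b = self.readout_genes
        if self.refractory is not None and self.refractory < self.kick_width:
            raise ValueError("refractory time must be at least the kick width")

    @classmethod
    def for_period(
        cls, reference_period: float, readout_genes: tuple[int, int] = (1, 2), **kw
    ) -> "ControllerConfig":
        """Defaults scaled to a reference oscillation period.

        KICK width of a quarter period with a full-period refractory fires at
        most one KICK per readout gene per cycle, which sustains the wave
        without entraining it away from its natural period (measured period
        shift under on-phase kicking stays below ~5%).
        """
        kw.setdefault("kick_width", 0.25 * reference_period)
        kw.setdefault("refractory", reference_period)
        return cls(readout_genes=readout_genes, **kw)


def _resolve_controller(config: ControllerConfig, params: RingParameters, hill):
    from .equilibria import dimerized_fixed_points

    a, b = config.readout_genes
    if b != a % params.n + 1:
        raise ValueError("readout genes must be adjacent in ring order")
    thresholds = config.thresholds
    if thresholds is None:
        fps = dimerized_fixed_points(params, hill)
        if not fps:
            raise ValueError("default thresholds need c > 2 (dimerized levels)")
        thr = config.threshold_frac * fps[0].p_u
        thresholds = (thr, thr)
    amp = config.kick_amplitude if config.kick_amplitude is not None else _base_c1(params)
    refr = config.refractory if config.refractory is not None else config.kick_width
    return thresholds, amp, refr


def closed_loop(
    params: RingParameters,
    config: ControllerConfig,
    t_max: float,
    simulator: str = "ssa",
    omega: float = 50.0,
    seed: int = 0,
    hill: HillRepression = DEFAULT_HILL,
    init: np.ndarray | None = None,
    extra_signals: list[Signal] | None = None,
    tol: float = 1e-8,
):
    """Event-driven threshold feedback loop over a chunked simulation.

    Returns ``(trace, events)`` where ``trace`` is a
    :class:`~repressilator.ssa.StochasticTrace` (simulator "ssa") or
    :class:`~repressilator.simulate.Trajectory` (simulator "ode") and
    ``events`` is a list of ``(time, kind, gene)`` tuples.  ``extra_signals``
    (e.g. an initial or terminating STOP) are merged into the drive; a STOP
    also disengages the threshold rule from its onset, since the controller's
    job is precisely to relaunch the wave from rest — termination means
    "STOP and switch the controller off".
    """
    from . import ssa as ssa_mod

    thresholds, amp, refr = _resolve_controller(config, params, hill)
    n = params.n
    extra = SignalSchedule(n, list(extra_signals or []))
    if init is None:
        from .equilibria import dimerized_fixed_points

        fps = dimerized_fixed_points(params, hill)
        if not fps:
            raise ValueError("default initial state needs c > 2")
        init = fps[0].state(n)

    events: list[tuple[float, str, int]] = []
    kick_until = {g: -np.inf for g in config.readout_genes}
    next_allowed = {g: -np.inf for g in config.readout_genes}

    if simulator == "ssa":
        state = ssa_mod.counts_from_state(init, omega)
        ssa_mod._seed_rng(seed)
    elif simulator == "ode":
        state = np.asarray(init, float).copy()
    else:
        raise ValueError("simulator must be 'ssa' or 'ode'")

    ts, xs = [], []
    t = 0.0
    delay_buffer: list[tuple[float, np.ndarray]] = []
    while t < t_max:
        t_next = min(t + config.check_dt, t_max)
        drive = np.zeros(n)
        for g in config.readout_genes:
            if t < kick_until[g]:
                drive[g - 1] += amp
        drive += extra.drive(t + 1e-9)
        if simulator == "ssa":
            chunk = ssa_mod.gillespie(
                params, omega, state, t_next, seed=seed, hill=hill,
                record_dt=config.check_dt, drive=drive, t_start=t, _reseed=False,
            )
            state = chunk.meta["final_counts"]
            readout_state = state / omega
            ts.append(t)
            xs.append(chunk.counts[0])
        else:
            traj = integrate(
                params, state, (t, t_next), tol=tol, hill=hill,
                drive=lambda _t: drive, drive_boundaries=(),
            )
            state = traj.final_state()
            readout_state = state
            ts.append(t)
            xs.append(traj.y[0])
        t = t_next
        delay_buffer.append((t, np.array(readout_state)))
        # readout honoring the maturation delay
        t_read = t - config.readout_delay
        obs = None
        for tb, sb in delay_buffer:
            if tb <= t_read:
                obs = sb
        stop_engaged = any(
            s.kind == "STOP" and t >= s.t_start for s in extra.signals
        )
        if obs is None or config.mode != "on" or stop_engaged:
            continue
        delay_buffer = [(tb, sb) for tb, sb in delay_buffer if tb >= t_read - config.check_dt]
        for g, thr in zip(config.readout_genes, thresholds):
            if obs[n + g - 1] < thr and t >= next_allowed[g]:
                kick_until[g] = t + config.kick_width
                next_allowed[g] = t + refr
                events.append((t, "KICK", g))

    ts.append(t_max)
    xs.append(state.copy())
    tarr = np.asarray(ts)
    xarr = np.asarray(xs)
    if simulator == "ssa":
        trace = ssa_mod.StochasticTrace(
            t=tarr, counts=xarr.astype(np.int64), params=params, omega=omega,
            seed=seed, meta={"closed_loop": True},
        )
    else:
        trace = Trajectory(tarr, xarr.astype(float), params, tol, meta={"closed_loop": True})
    return trace, events
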