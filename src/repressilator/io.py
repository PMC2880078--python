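"""CSV/JSON writers and readers for trajectories, traces, orbits and reports.

Conventions: '.' decimal, no thousands separators, UTF-8, LF line endings;
times in minutes, concentrations dimensionless, counts integer.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import RingParameters
from .orbits import PeriodicOrbit
from .simulate import Trajectory
from .ssa import StochasticTrace

__all__ = [
    "trajectory_to_csv",
    "trajectory_from_csv",
    "trace_to_csv",
    "orbit_report",
    "write_orbit_report",
    "write_manifest",
    "params_to_dict",
    "params_from_dict",
]


def params_to_dict(params: RingParameters, **extra) -> dict:
    def _val(v):
        return list(np.asarray(v, float)) if not np.isscalar(v) else float(v)

    d = {"n": params.n, **{k: _val(getattr(params, k)) for k in ("c1", "c2", "c3", "c4")}}
    d.update(extra)
    return d


def params_from_dict(d: dict) -> RingParameters:
    return RingParameters(
        n=int(d["n"]), c1=d["c1"], c2=d["c2"], c3=d["c3"], c4=d["c4"]
    )


def _state_columns(n: int) -> list[str]:
    return [f"m_{j}" for j in range(1, n + 1)] + [f"p_{j}" for j in range(1, n + 1)]


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a deterministic trajectory: header ``time,m_1..m_n,p_1..p_n``."""
    df = pd.DataFrame(traj.y, columns=_state_columns(traj.n))
    df.insert(0, "time", traj.t)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def trajectory_from_csv(path: str | Path, params: RingParameters, tol: float = np.nan) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time"].to_numpy(float)
    y = df[_state_columns(params.n)].to_numpy(float)
    return Trajectory(t, y, params, tol)


def trace_to_csv(trace: StochasticTrace, path: str | Path, thin: int = 1) -> None:
    """Write a stochastic trace; adds ``seed`` and ``omega`` columns.

    ``thin`` keeps every thin-th sample for output-size control.
    """
    sl = slice(None, None, max(1, int(thin)))
    df = pd.DataFrame(trace.counts[sl], columns=_state_columns(trace.n))
    df.insert(0, "time", trace.t[sl])
    df["seed"] = trace.seed
    df["omega"] = trace.omega
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def orbit_report(orbit: PeriodicOrbit) -> dict:
    from .orbits import floquet_classify

    cls = floquet_classify(orbit)
    return {
        "c": orbit.c,
        "period_min": orbit.period,
        "multipliers": [[float(m.real), float(m.imag)] for m in orbit.multipliers],
        "n_unstable": cls.n_unstable,
        "stability": cls.label,
        "anchor": list(map(float, orbit.anchor)),
        "closure_residual": orbit.closure_residual,
        "branch_id": orbit.branch_id,
        "params": params_to_dict(orbit.params),
    }


def write_orbit_report(orbit: PeriodicOrbit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(orbit_report(orbit), indent=2) + "\n", encoding="utf-8")


def write_manifest(path: str | Path, config: dict) -> None:
    """Echo the fully resolved run configuration (incl. seeds) next to outputs."""
    Path(path).write_text(json.dumps(config, indent=2, default=str) + "\n", encoding="utf-8")
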