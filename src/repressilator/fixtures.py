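"""Seeded fixture generation: initial conditions, protocols, hypercube specs.

Random initial conditions are drawn uniformly per coordinate on ``[0, p_u]``
(the biologically occupied box below the high dimerized level); everything
else is deterministic given the seed, so fixture files regenerate
byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .control import StopKickSettings
from .model import DEFAULT_HILL, HillRepression, RingParameters, preset
from .robustness import HypercubeSpec

__all__ = [
    "random_initial_conditions",
    "canonical_protocol",
    "canonical_hypercube_specs",
    "generate_fixtures",
]


def random_initial_conditions(
    params: RingParameters,
    n_samples: int,
    seed: int,
    hill: HillRepression = DEFAULT_HILL,
) -> np.ndarray:
    """(n_samples, 2n) array of uniform states on [0, p_u] per coordinate."""
    c = params.c
    hi = c - 1.0 / c if c > 2 else max(c, 1.0)
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, hi, size=(n_samples, 2 * params.n))


def canonical_protocol(reference_period: float) -> dict:
    """STOP-KICK-STOP timeline (STOP, settle gap, KICK, free run, STOP)."""
    settings = StopKickSettings(reference_period=reference_period)
    sigs = settings.build_signals(preset("fig3"), stop_gene=1, final_stop=True)
    return {
        "reference_period": reference_period,
        "signals": [
            {
                "kind": s.kind,
                "gene": s.gene,
                "t_start": s.t_start,
                "duration": s.duration,
                "amplitude": s.amplitude,
            }
            for s in sigs
        ],
    }


def canonical_hypercube_specs(params: RingParameters) -> list[HypercubeSpec]:
    """The 5/10/20 per-cent variation cubes around a reference set."""
    return [HypercubeSpec(reference=params, fraction=f) for f in (0.05, 0.10, 0.20)]


def generate_fixtures(seed: int, outdir: str | Path, reference_period: float = 577.0) -> dict:
    """Write the canonical fixture files; returns the manifest dictionary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = preset("fig3")
    ics = random_initial_conditions(params, 100, seed)
    np.savetxt(out / "initial_conditions.csv", ics, delimiter=",", fmt="%.17g")
    protocol = canonical_protocol(reference_period)
    (out / "protocol.json").write_text(json.dumps(protocol, indent=2) + "\n")
    cubes = [
        {"fraction": s.fraction, "dims": s.dims, "n": s.reference.n}
        for s in canonical_hypercube_specs(params)
    ]
    (out / "hypercubes.json").write_text(json.dumps(cubes, indent=2) + "\n")
    manifest = {
        "seed": seed,
        "preset": "fig3",
        "files": ["initial_conditions.csv", "protocol.json", "hypercubes.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
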