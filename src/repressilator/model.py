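"""Generalized repressilator ring: states, parameters, vector field, reactions.

The circuit is a cycle of ``n`` genes in which transcription of gene ``j`` is
repressed by the protein product of gene ``j-1`` (1-based, periodic:
``p_0 == p_n``).  Per gene the deterministic dynamics are

    dm_j/dt = c1 * H(p_{j-1}) - c2 * m_j
    dp_j/dt = c3 * m_j       - c4 * p_j

with a Hill-type repression ``H(p) = 1 / (1 + (p/K)^h)`` (defaults ``h=2``,
``K=1``).  Concentrations are dimensionless, rates are per minute.  The
dimensionless combination ``c = c1*c3/(c2*c4)`` controls the bifurcation
structure: even rings undergo a pitchfork at ``c = 2`` into two "dimerized"
(alternating high/low) fixed points, odd rings a Hopf bifurcation into a
globally attracting limit cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "HillRepression",
    "RingParameters",
    "RingState",
    "ReactionSystem",
    "DEFAULT_HILL",
    "repression",
    "lumped_parameter",
    "vector_field",
    "jacobian",
    "reaction_system",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class HillRepression:
    """Repressive Hill function ``H(p) = 1 / (1 + (p/threshold)**h)``.

    ``H(0) = 1``, strictly decreasing, ``H -> 0`` as ``p -> inf``.
    """

    h: float = 2.0
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError(f"Hill exponent must be >= 1, got {self.h}")
        if self.threshold <= 0:
            raise ValueError(f"Hill threshold must be > 0, got {self.threshold}")

    def __call__(self, p):
        p = np.asarray(p, dtype=float)
        if np.any(p < 0):
            raise ValueError("protein concentration must be non-negative")
        return 1.0 / (1.0 + (p / self.threshold) ** self.h)

    def derivative(self, p):
        """dH/dp, analytic."""
        p = np.asarray(p, dtype=float)
        if np.any(p < 0):
            raise ValueError("protein concentration must be non-negative")
        x = p / self.threshold
        return -(self.h / self.threshold) * x ** (self.h - 1.0) / (1.0 + x ** self.h) ** 2


DEFAULT_HILL = HillRepression()


def repression(p, hill: HillRepression = DEFAULT_HILL):
    """Transcriptional repression fraction in (0, 1]; 1/(1+p**2) by default."""
    return hill(p)


def _as_rate(value, name: str, n: int) -> np.ndarray:
    """Broadcast a scalar or length-n sequence of rates; enforce positivity.

    Degradation rates (c2, c4) must be strictly positive; production rates
    (c1, c3) may be zero, which gives the exactly solvable decay limit.
    """
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n, float(arr[0]))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be scalar or length-{n}, got shape {arr.shape}")
    strict = name in ("c2", "c4")
    if (strict and not np.all(arr > 0)) or np.any(arr < 0):
        raise ValueError(f"{name} must be {'strictly positive' if strict else 'non-negative'}")
    return arr


@dataclass(frozen=True)
class RingParameters:
    """Ring size and kinetic rates (min^-1).

    ``c1``/``c3`` are the mRNA/protein production rates, ``c2``/``c4`` the
    corresponding degradation rates.  Each may be a scalar (identical genes)
    or a length-``n`` vector (heterogeneous genes, as used by the robustness
    sampler in per-gene mode).
    """

    n: int
    c1: float | Sequence[float]
    c2: float | Sequence[float]
    c3: float | Sequence[float]
    c4: float | Sequence[float]

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"ring size n must be an integer >= 2, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        for name in ("c1", "c2", "c3", "c4"):
            arr = _as_rate(getattr(self, name), name, self.n)
            if np.ptp(arr) == 0:
                object.__setattr__(self, name, float(arr[0]))
            else:
                object.__setattr__(self, name, arr)

    # -- convenience -------------------------------------------------------
    @property
    def even(self) -> bool:
        return self.n % 2 == 0

    @property
    def homogeneous(self) -> bool:
        return all(np.isscalar(getattr(self, k)) for k in ("c1", "c2", "c3", "c4"))

    def rate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return tuple(_as_rate(getattr(self, k), k, self.n) for k in ("c1", "c2", "c3", "c4"))

    @property
    def c(self) -> float:
        """Lumped bifurcation parameter c = c1*c3/(c2*c4).

        For heterogeneous rings the gene-averaged rates are used; the lumped
        parameter is only exact for identical genes.
        """
        a1, a2, a3, a4 = (np.mean(r) for r in self.rate_arrays())
        if a1 * a3 == 0:
            raise ValueError("lumped parameter undefined when a production rate is zero")
        return float(a1 * a3 / (a2 * a4))

    def with_c(self, c: float) -> "RingParameters":
        """Return parameters with c1 adjusted so the lumped parameter equals c.

        The sweep convention keeps c2, c3, c4 fixed and varies c1.
        """
        if c <= 0:
            raise ValueError("lumped parameter c must be > 0")
        if not self.homogeneous:
            raise ValueError("c sweep requires homogeneous rates")
        return replace(self, c1=c * self.c2 * self.c4 / self.c3)


def lumped_parameter(params: RingParameters) -> float:
    """Dimensionless bifurcation parameter c = c1*c3/(c2*c4)."""
    return params.c


@dataclass
class RingState:
    """mRNA and protein concentrations around the ring."""

    m: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.m.shape != self.p.shape or self.m.ndim != 1:
            raise ValueError("m and p must be 1-d arrays of equal length")

    @property
    def n(self) -> int:
        return self.m.size

    @property
    def y(self) -> np.ndarray:
        """Flat state vector [m_1..m_n, p_1..p_n]."""
        return np.concatenate([self.m, self.p])

    @classmethod
    def from_y(cls, y: np.ndarray) -> "RingState":
        y = np.asarray(y, dtype=float)
        n = y.size // 2
        return cls(y[:n].copy(), y[n:].copy())


def _check_dim(y: np.ndarray, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (2 * n,):
        raise ValueError(f"state dimension {y.shape} does not match 2n = {2 * n}")
    return y


def vector_field(
    y: np.ndarray,
    params: RingParameters,
    hill: HillRepression = DEFAULT_HILL,
    drive: np.ndarray | None = None,
) -> np.ndarray:
    """Time derivative of the flat state [m, p] (min^-1).

    ``drive`` is an optional length-n vector of added mRNA production rates
    (light-induced transcription used by the control module).
    """
    n = params.n
    y = _check_dim(y, n)
    m, p = y[:n], y[n:]
    c1, c2, c3, c4 = params.rate_arrays()
    prod = c1 * hill(np.maximum(np.roll(p, 1), 0.0))
    if drive is not None:
        prod = prod + drive
    return np.concatenate([prod - c2 * m, c3 * m - c4 * p])


def jacobian(
    y: np.ndarray,
    params: RingParameters,
    hill: HillRepression = DEFAULT_HILL,
) -> np.ndarray:
    """Analytic 2n x 2n Jacobian of :func:`vector_field` (drive-independent)."""
    n = params.n
    y = _check_dim(y, n)
    p = y[n:]
    c1, c2, c3, c4 = params.rate_arrays()
    J = np.zeros((2 * n, 2 * n))
    rows = np.arange(n)
    prev = (rows - 1) % n
    J[rows, rows] = -c2
    J[rows, n + prev] = c1 * hill.derivative(np.maximum(np.roll(p, 1), 0.0))
    J[n + rows, rows] = c3
    J[n + rows, n + rows] = -c4
    return J


@dataclass
class ReactionSystem:
    """Elementary reaction scheme on integer copy numbers.

    Species are ordered ``[M_1..M_n, P_1..P_n]``; each of the 4n reactions
    changes exactly one species by +-1.  ``omega`` is the copy-number scale:
    an ODE concentration ``x`` corresponds to roughly ``omega * x`` copies.
    """

    params: RingParameters
    omega: float
    hill: HillRepression = field(default_factory=HillRepression)
    #: per reaction: index of the species it changes
    species: np.ndarray = field(init=False)
    #: per reaction: +1 (birth) or -1 (death)
    delta: np.ndarray = field(init=False)
    #: per reaction: kind code 0=mRNA birth, 1=mRNA death, 2=protein birth, 3=protein death
    kind: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("copy-number scale omega must be > 0")
        n = self.params.n
        g = np.arange(n)
        self.species = np.concatenate([g, g, n + g, n + g])
        self.delta = np.concatenate([np.ones(n), -np.ones(n), np.ones(n), -np.ones(n)]).astype(np.int64)
        self.kind = np.repeat(np.arange(4), n)

    @property
    def n_reactions(self) -> int:
        return 4 * self.params.n

    def propensities(self, counts: np.ndarray, drive: np.ndarray | None = None) -> np.ndarray:
        """Propensity vector (min^-1) at an integer count state.

        Order: [mRNA birth_1..n, mRNA death, protein birth, protein death].
        ``drive`` adds ``omega * drive_j`` to gene j's mRNA birth propensity.
        """
        n = self.params.n
        counts = np.asarray(counts)
        if counts.shape != (2 * n,) or np.any(counts < 0):
            raise ValueError("counts must be a non-negative vector of length 2n")
        M, P = counts[:n].astype(float), counts[n:].astype(float)
        c1, c2, c3, c4 = self.params.rate_arrays()
        birth_m = self.omega * c1 * self.hill(np.roll(P, 1) / self.omega)
        if drive is not None:
            birth_m = birth_m + self.omega * np.asarray(drive, dtype=float)
        return np.concatenate([birth_m, c2 * M, c3 * M, c4 * P])

    def stoichiometry(self) -> np.ndarray:
        """Dense (4n, 2n) stoichiometry matrix."""
        S = np.zeros((self.n_reactions, 2 * self.params.n), dtype=np.int64)
        S[np.arange(self.n_reactions), self.species] = self.delta
        return S


def reaction_system(
    params: RingParameters,
    omega: float,
    hill: HillRepression = DEFAULT_HILL,
) -> ReactionSystem:
    """Build the 4n-reaction birth/death scheme underlying the ODE model."""
    return ReactionSystem(params=params, omega=omega, hill=hill)


#: Named parameter presets.  "table1" is the bifurcation-sweep family
#: (c2=0.12, c3=0.16, c4=0.06; c1 set through the lumped parameter), "fig3"
#: the 18-gene reference ring used for induction and robustness studies.
PRESET_NAMES = ("table1", "fig3")


def preset(name: str, n: int | None = None, c: float | None = None) -> RingParameters:
    """Return a built-in parameter preset.

    Parameters
    ----------
    name:
        "table1" (requires ``n``; ``c`` defaults to 5.0) or "fig3"
        (n=18, c1=2.6, c2=0.12, c3=0.2, c4=0.06).
    n:
        ring size; required for "table1", optional override for "fig3".
    c:
        lumped-parameter value for "table1" (sets c1 = c*c2*c4/c3).
    """
    if name == "table1":
        if n is None:
            raise ValueError("preset 'table1' requires a ring size n")
        base = RingParameters(n=n, c1=1.0, c2=0.12, c3=0.16, c4=0.06)
        return base.with_c(5.0 if c is None else c)
    if name == "fig3":
        params = RingParameters(n=18 if n is None else n, c1=2.6, c2=0.12, c3=0.2, c4=0.06)
        if c is not None:
            params = params.with_c(c)
        return params
    raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
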