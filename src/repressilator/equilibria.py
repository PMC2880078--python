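"""Fixed points and bifurcations of the symmetric branch.

The ring's translational symmetry makes the Jacobian at the symmetric fixed
point a block circulant, so its 2n eigenvalues split into n decoupled modes:
for mode k (phase ``theta = 2*pi*k/n``) the two eigenvalues solve

    (lambda + c2) * (lambda + c4) = c1 * c3 * H'(p_m) * exp(-i*theta).

Mode ``k = n/2`` (even rings) is real and crosses zero at the pitchfork
(c = 2 for the default Hill form); complex modes cross the imaginary axis at
Hopf bifurcations, from which the unstable travelling-wave branches emerge.
Critical values are located by bisection in the lumped parameter c, swept by
varying c1 at fixed c2, c3, c4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import DEFAULT_HILL, HillRepression, RingParameters

__all__ = [
    "SymmetricFixedPoint",
    "DimerizedFixedPoint",
    "ModeEigenvalues",
    "BifurcationPoint",
    "ParityError",
    "symmetric_fixed_point",
    "dimerized_fixed_points",
    "mode_spectrum",
    "find_pitchfork",
    "find_hopf_points",
    "bifurcation_table",
]


class ParityError(ValueError):
    """Raised when an operation requires the other ring parity."""


@dataclass(frozen=True)
class SymmetricFixedPoint:
    """Equilibrium with one common mRNA and protein level for all genes."""

    p_m: float
    m_m: float
    c: float

    def state(self, n: int) -> np.ndarray:
        return np.concatenate([np.full(n, self.m_m), np.full(n, self.p_m)])


@dataclass(frozen=True)
class DimerizedFixedPoint:
    """Alternating high/low equilibrium of an even ring (c > 2).

    ``assignment`` is "odd_up" if genes with odd 1-based index carry the high
    protein level ``p_u``, "even_up" for the mirrored state.
    """

    p_u: float
    p_d: float
    m_u: float
    m_d: float
    assignment: str

    def state(self, n: int) -> np.ndarray:
        j = np.arange(1, n + 1)
        odd = j % 2 == 1
        up = odd if self.assignment == "odd_up" else ~odd
        m = np.where(up, self.m_u, self.m_d)
        p = np.where(up, self.p_u, self.p_d)
        return np.concatenate([m, p])


@dataclass(frozen=True)
class ModeEigenvalues:
    k: int
    theta: float
    lambdas: tuple[complex, complex]


@dataclass(frozen=True)
class BifurcationPoint:
    """Critical point of the symmetric branch: 'pitchfork' or 'hopf'."""

    type: str
    c_star: float
    mode_k: int
    omega: float | None = None  # angular frequency at a Hopf crossing, min^-1

    @property
    def period(self) -> float | None:
        """Period 2*pi/omega (min) of the emerging orbit (Hopf only)."""
        return None if not self.omega else 2.0 * np.pi / self.omega


def symmetric_fixed_point(
    params: RingParameters, hill: HillRepression = DEFAULT_HILL
) -> SymmetricFixedPoint:
    """Unique symmetric equilibrium: the positive root of ``p = c * H(p)``.

    With the default Hill form this is the monotone cubic ``p*(1+p^2) = c``;
    for any admissible Hill the residual ``p - c*H(p)`` is strictly
    increasing, so bracketed root-finding is safe.
    """
    c = params.c
    f = lambda p: p - c * hill(p)
    hi = max(c, 1.0)
    p_m = brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    c1, c2, c3, c4 = (np.mean(r) for r in params.rate_arrays())
    return SymmetricFixedPoint(p_m=p_m, m_m=(c4 / c3) * p_m, c=c)


def dimerized_fixed_points(
    params: RingParameters, hill: HillRepression = DEFAULT_HILL
) -> list[DimerizedFixedPoint]:
    """The two alternating equilibria of an even ring, or ``[]`` below c = 2.

    Solves ``p_u = c*H(p_d)``, ``p_d = c*H(p_u)``; for the default Hill these
    reduce to ``p_u * p_d = 1`` and ``p_u + p_d = c`` with closed form
    ``p_{u,d} = (c ± sqrt(c^2 - 4)) / 2``.
    """
    if params.n % 2 == 1:
        raise ParityError("dimerized fixed points exist only for even rings")
    c = params.c
    if c < 2.0:
        return []
    if hill.h == 2.0 and hill.threshold == 1.0:
        root = np.sqrt(max(c * c - 4.0, 0.0))
        p_u, p_d = (c + root) / 2.0, (c - root) / 2.0
    else:  # general Hill: solve g(p_d) = c*H(c*H(p_d)) - p_d = 0 below p_m
        sym = symmetric_fixed_point(params, hill)
        g = lambda p: c * hill(c * hill(p)) - p
        lo, hi = 0.0, sym.p_m
        if g(lo) * g(hi) > 0:
            return []
        p_d = brentq(g, lo, hi, xtol=1e-14)
        p_u = c * hill(p_d)
        if abs(p_u - p_d) < 1e-9:
            return []
    # residual check against the defining equations
    res = max(abs(p_u - c * hill(p_d)), abs(p_d - c * hill(p_u)))
    if res > 1e-10 * max(1.0, c):
        raise RuntimeError(f"dimerized fixed-point residual {res:.2e} too large")
    c1, c2, c3, c4 = (np.mean(r) for r in params.rate_arrays())
    m_u, m_d = (c4 / c3) * p_u, (c4 / c3) * p_d
    return [
        DimerizedFixedPoint(p_u, p_d, m_u, m_d, "odd_up"),
        DimerizedFixedPoint(p_u, p_d, m_u, m_d, "even_up"),
    ]


def _mode_rhs(params: RingParameters, hill: HillRepression, p_m: float) -> float:
    """The (negative) coupling strength c1*c3*H'(p_m)."""
    c1, c2, c3, c4 = (float(np.mean(r)) for r in params.rate_arrays())
    return c1 * c3 * float(hill.derivative(p_m))


def _mode_lambdas(params: RingParameters, theta: float, g: complex) -> tuple[complex, complex]:
    c1, c2, c3, c4 = (float(np.mean(r)) for r in params.rate_arrays())
    rhs = g * np.exp(-1j * theta)
    disc = np.sqrt(complex((c2 - c4) ** 2 + 4.0 * rhs))
    l1 = (-(c2 + c4) + disc) / 2.0
    l2 = (-(c2 + c4) - disc) / 2.0
    return complex(l1), complex(l2)


def mode_spectrum(
    params: RingParameters, hill: HillRepression = DEFAULT_HILL
) -> list[ModeEigenvalues]:
    """Per-mode eigenvalues of the symmetric fixed point, k = 0..n-1."""
    sym = symmetric_fixed_point(params, hill)
    g = _mode_rhs(params, hill, sym.p_m)
    out = []
    for k in range(params.n):
        theta = 2.0 * np.pi * k / params.n
        out.append(ModeEigenvalues(k=k, theta=theta, lambdas=_mode_lambdas(params, theta, g)))
    return out


def _max_re(params: RingParameters, c: float, theta: float, hill: HillRepression) -> tuple[float, float]:
    """(max real part, |imag| at that root) of the mode pair at lumped value c."""
    pc = params.with_c(c)
    sym = symmetric_fixed_point(pc, hill)
    g = _mode_rhs(pc, hill, sym.p_m)
    l1, l2 = _mode_lambdas(pc, theta, g)
    lam = l1 if l1.real >= l2.real else l2
    return lam.real, abs(lam.imag)


def find_pitchfork(
    params: RingParameters,
    hill: HillRepression = DEFAULT_HILL,
    c_range: tuple[float, float] = (1e-3, 30.0),
) -> BifurcationPoint:
    """Zero crossing of the real k = n/2 mode eigenvalue (even rings).

    Returns c* = 2 (to root-finding accuracy) for the default Hill form.
    """
    if params.n % 2 == 1:
        raise ParityError("the pitchfork mode k = n/2 requires an even ring")
    theta = np.pi
    f = lambda c: _max_re(params, c, theta, hill)[0]
    lo, hi = c_range
    if f(lo) >= 0 or f(hi) <= 0:
        raise ValueError(f"no pitchfork crossing inside c range {c_range}")
    c_star = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return BifurcationPoint(type="pitchfork", c_star=c_star, mode_k=params.n // 2)


def find_hopf_points(
    params: RingParameters,
    c_range: tuple[float, float] = (1e-3, 30.0),
    hill: HillRepression = DEFAULT_HILL,
    scan_points: int = 600,
) -> list[BifurcationPoint]:
    """All Hopf crossings of the symmetric branch in a lumped-parameter range.

    Each conjugate mode pair (k, n-k) is examined once, tagged with
    ``min(k, n-k)``; crossings are located by a scan plus bisection in c
    (tolerance 1e-6) and returned sorted by ascending c*.
    """
    lo, hi = c_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid c range {c_range}")
    n = params.n
    points: list[BifurcationPoint] = []
    grid = np.linspace(lo, hi, scan_points)
    for k in range(1, n // 2 + (n % 2)):  # exclude k=0 and (even n) k=n/2
        theta = 2.0 * np.pi * k / n
        f = lambda c: _max_re(params, c, theta, hill)[0]
        vals = np.array([f(c) for c in grid])
        for i in np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:])):
            c_star = brentq(f, grid[i], grid[i + 1], xtol=1e-6)
            omega = _max_re(params, c_star, theta, hill)[1]
            if omega > 1e-10:
                points.append(BifurcationPoint("hopf", c_star, k, omega))
    points.sort(key=lambda b: b.c_star)
    return points


def bifurcation_table(
    params: RingParameters,
    c_range: tuple[float, float] = (1e-3, 30.0),
    hill: HillRepression = DEFAULT_HILL,
):
    """Pitchfork + Hopf summary as a pandas DataFrame.

    Columns: n, type (P|HB), c, mode_k, omega, period_min.
    """
    import pandas as pd

    rows = []
    if params.n % 2 == 0:
        pf = find_pitchfork(params, hill, c_range)
        rows.append(
            dict(n=params.n, type="P", c=pf.c_star, mode_k=pf.mode_k, omega=np.nan, period_min=np.nan)
        )
    for hb in find_hopf_points(params, c_range, hill):
        rows.append(
            dict(
                n=params.n,
                type="HB",
                c=hb.c_star,
                mode_k=hb.mode_k,
                omega=hb.omega,
                period_min=hb.period,
            )
        )
    return pd.DataFrame(rows, columns=["n", "type", "c", "mode_k", "omega", "period_min"])
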