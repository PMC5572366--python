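"""Equilibrium points and their stability.

The origin P0 = (0, 0, 0, 0) is always an equilibrium.  Nonzero
equilibria are found by reducing the four equilibrium conditions to a
two-dimensional intersection problem in (y, z) = (x1, x2): setting the
x2- and x4-rates to zero gives

    x4 = tanh(y),     tanh(x3) = u = z/2.8 - (1.1/2.8)*tanh(y)

(requiring |u| < 1 for a real x3 = atanh(u)), and substituting into the
remaining two rates yields two residual curves h1(y, z), h2(y, z) whose
intersections are the nonzero equilibria.  Each root is classified from
the spectrum of the Jacobian there: a stable node-focus (all real parts
negative, at least one complex pair) coexisting with an unstable
saddle-focus underlies the multistability of the network.

At the origin the characteristic polynomial factors as

    (lambda + 1) * [lambda^3 + 0.4 lambda^2 + (7ka - 3.52) lambda
                    + 3.64ka - 5.2]

so the origin's stability depends only on the product k*a; by
Routh-Hurwitz the origin is stable iff k*a >= 5.2/3.64 (k >= 1.4286 for
a = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .hnn import HNNParams, jacobian, rhs

__all__ = [
    "Equilibrium",
    "RegimeRow",
    "curve_residuals",
    "find_equilibria",
    "origin_char_poly",
    "origin_critical_k",
    "classify",
    "regime_scan",
]

_DEDUP_TOL = 1e-6
_TIE_TOL = 1e-9


@dataclass
class Equilibrium:
    """A fixed point with its Jacobian spectrum and stability label."""

    coords: np.ndarray
    eigenvalues: np.ndarray  # ordered by descending real part, then imag
    label: str
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.label.startswith("stable")


@dataclass
class RegimeRow:
    """Equilibria present at one value of b, with per-point stability."""

    b: float
    equilibria: list  # list[Equilibrium]; origin first

    @property
    def n_nonzero(self) -> int:
        return len(self.equilibria) - 1


def _sorted_eigs(J: np.ndarray) -> np.ndarray:
    eigs = np.linalg.eigvals(J)
    order = np.lexsort((-eigs.imag, -eigs.real))
    return eigs[order]


def curve_residuals(y: float, z: float, p: HNNParams) -> tuple[float, float]:
    """Residuals of the two nullcline curves at (y, z) = (x1, x2).

    h1 is the x1-rate and h2 the x3-rate after eliminating x3 and x4
    through the x2- and x4-equilibrium conditions.  The memristive weight
    enters h2 as k*(a - b*tanh(tanh(y)))*tanh(y); at k = 0.8 this reduces
    to the printed reference curves.

    Raises ValueError when |u| >= 1 (no real x3 solves the x2-nullcline).
    """
    ty, tz = np.tanh(y), np.tanh(z)
    u = z / 2.8 - (1.1 / 2.8) * ty
    if abs(u) >= 1.0:
        raise ValueError(f"x2-nullcline has no real x3 solution: |u| = {abs(u)} >= 1")
    x3 = np.arctanh(u)
    h1 = -y - 1.4 * ty + 1.2 * tz - 7.0 * u
    h2 = -x3 + p.k * (p.a - p.b * np.tanh(ty)) * ty - 2.0 * tz + 4.0 * u
    return float(h1), float(h2)


def _residual_smooth(yx3, p: HNNParams):
    """Nullcline residuals in the smooth coordinates (y, x3).

    Substituting z = 1.1*tanh(y) + 2.8*tanh(x3) (the x2-nullcline solved
    for z) removes the atanh domain constraint, so the root refinement is
    smooth on all of R^2.  Works on scalars or broadcast arrays.
    """
    y, x3 = yx3
    ty, t3 = np.tanh(y), np.tanh(x3)
    z = 1.1 * ty + 2.8 * t3
    tz = np.tanh(z)
    h1 = -y - 1.4 * ty + 1.2 * tz - 7.0 * t3
    h2 = -x3 + p.k * (p.a - p.b * np.tanh(ty)) * ty - 2.0 * tz + 4.0 * t3
    return np.array([h1, h2])


def _reconstruct(y: float, x3: float) -> np.ndarray:
    ty = np.tanh(y)
    return np.array([y, 1.1 * ty + 2.8 * np.tanh(x3), x3, ty])


def _make_equilibrium(coords: np.ndarray, p: HNNParams) -> Equilibrium:
    eigs = _sorted_eigs(jacobian(coords, p))
    res = float(np.max(np.abs(rhs(coords, p))))
    eq = Equilibrium(coords=coords, eigenvalues=eigs, label="", residual=res)
    eq.label = classify(eq)
    return eq


def find_equilibria(p: HNNParams, box=((-6.0, 6.0), (-3.0, 3.0)),
                    grid: int = 200) -> list[Equilibrium]:
    """All equilibria of the network in the (y, z) search box.

    The origin is always included.  The search runs in the smooth
    coordinates (y, x3) — with z eliminated through the x2-nullcline —
    so roots arbitrarily close to the atanh domain edge of the (y, z)
    formulation are found reliably: both residuals are evaluated on a
    ``grid`` x ``grid`` lattice, a hybrid-Powell refinement starts from
    every cell whose corners change sign in both residuals, and converged
    roots are mapped back to (y, z), kept when z lies inside the box,
    de-duplicated at 1e-6 and classified from the Jacobian spectrum.
    """
    if grid < 40:
        raise ValueError("grid must be >= 40 per axis")
    (ylo, yhi), (zlo, zhi) = box
    ys = np.linspace(ylo, yhi, grid)
    # x3 range covering |tanh(x3)| up to ~1 - 2e-6; the z-box filter is
    # applied after reconstruction
    x3s = np.linspace(-6.5, 6.5, grid)
    Y, X3 = np.meshgrid(ys, x3s, indexing="ij")
    H1, H2 = _residual_smooth((Y, X3), p)

    def cell_has_sign_change(F, i, j):
        c = np.array([F[i, j], F[i + 1, j], F[i, j + 1], F[i + 1, j + 1]])
        return c.min() < 0 < c.max()

    # Seed refinements from every cell the h1 = 0 curve crosses where h2
    # is small, not only from cells where both residuals change sign: the
    # two curves can cross at a shallow angle (they are near-tangent for
    # large b), in which case the h2 sign change lands in a neighbouring
    # cell and a double-sign-change criterion misses the root.
    roots: list[np.ndarray] = [np.zeros(2)]
    for i in range(grid - 1):
        for j in range(grid - 1):
            if not cell_has_sign_change(H1, i, j):
                continue
            if min(abs(H2[i, j]), abs(H2[i + 1, j]), abs(H2[i, j + 1]),
                   abs(H2[i + 1, j + 1])) > 2.0:
                continue
            y0 = 0.5 * (ys[i] + ys[i + 1])
            x30 = 0.5 * (x3s[j] + x3s[j + 1])
            sol = root(_residual_smooth, np.array([y0, x30]), args=(p,),
                       method="hybr", tol=1e-14)
            if not sol.success:
                # neighbouring cells along the curve re-seed the same root
                continue
            yx = sol.x
            if np.max(np.abs(_residual_smooth(yx, p))) > 1e-10:
                continue
            z = 1.1 * np.tanh(yx[0]) + 2.8 * np.tanh(yx[1])
            if not (ylo <= yx[0] <= yhi and zlo <= z <= zhi):
                continue
            if any(np.linalg.norm(yx - r) < _DEDUP_TOL for r in roots):
                continue
            roots.append(yx)

    out = [_make_equilibrium(np.zeros(4), p)]
    for yx in roots[1:]:
        out.append(_make_equilibrium(_reconstruct(*yx), p))
    # deterministic order: origin first, then descending y
    out[1:] = sorted(out[1:], key=lambda e: -e.coords[0])
    return out


def origin_char_poly(k: float, a: float):
    """Characteristic polynomial at the origin, in factored form.

    Returns ``(linear_root, cubic_coeffs)`` where ``linear_root`` is the
    root of the (lambda + 1) factor (always -1) and ``cubic_coeffs`` are
    the monic cubic coefficients (1, 0.4, 7ka - 3.52, 3.64ka - 5.2).
    """
    ka = k * a
    return -1.0, (1.0, 0.4, 7.0 * ka - 3.52, 3.64 * ka - 5.2)


def origin_critical_k(a: float) -> float:
    """Smallest coupling k stabilizing the origin (Routh-Hurwitz boundary).

    For the monic cubic l^3 + c2 l^2 + c1 l + c0 with c2 = 0.4,
    c1 = 7ka - 3.52, c0 = 3.64ka - 5.2, the binding Routh-Hurwitz
    condition is c0 > 0 (c2 > 0 always and c2*c1 - c0 > 0 wherever
    c0 >= 0), giving k = 5.2/(3.64 a).
    """
    if not a > 0:
        raise ValueError("a must be > 0")
    return 5.2 / (3.64 * a)


def classify(eq: Equilibrium) -> str:
    """Stability label from the eigenvalue spectrum.

    stable node-focus / stable node when all real parts are negative
    (with / without a complex pair); with mixed signs, an unstable
    saddle-focus when the unstable eigenvalues include a complex pair,
    an unstable saddle point when they are all real.  Real parts within
    1e-9 of zero make the classification degenerate ("other").
    """
    eigs = np.asarray(eq.eigenvalues)
    re = eigs.real
    if np.any(np.abs(re) < _TIE_TOL):
        return "other"
    has_complex = np.any(np.abs(eigs.imag) > _TIE_TOL)
    if np.all(re < 0):
        return "stable node-focus" if has_complex else "stable node"
    if np.all(re > 0):
        return "other"
    unstable = eigs[re > 0]
    if np.any(np.abs(unstable.imag) > _TIE_TOL):
        return "unstable saddle-focus"
    return "unstable saddle point"


def _p1(equilibria: list) -> "Equilibrium | None":
    """The nonzero equilibrium on the positive-x1 branch (P1), if present."""
    pos = [e for e in equilibria[1:] if e.coords[0] > _DEDUP_TOL]
    if not pos:
        return None
    return pos[0]


def regime_scan(p: HNNParams, b_grid: np.ndarray,
                box=((-6.0, 6.0), (-3.0, 3.0)), grid: int = 200) -> dict:
    """Stability regimes of the positive nonzero equilibrium P1 over b.

    For each b in ``b_grid`` (sorted ascending) the equilibria are
    located and classified.  Two boundaries are then refined by bisection
    to 1e-3 in b: the onset of P1 stability (largest eigenvalue real
    part crossing zero) and the b at which P1 ceases to exist.

    Returns a dict with keys ``rows`` (list of RegimeRow),
    ``stability_onset`` and ``existence_boundary`` (None when the scan
    grid does not bracket them).
    """
    b_grid = np.asarray(b_grid, dtype=float)
    if np.any(np.diff(b_grid) <= 0):
        raise ValueError("b_grid must be sorted ascending")

    def at(b: float) -> list:
        q = HNNParams(k=p.k, a=p.a, b=b, weights=p.weights)
        return find_equilibria(q, box=box, grid=grid)

    rows = [RegimeRow(b=float(b), equilibria=at(float(b))) for b in b_grid]

    def p1_max_re(b: float) -> float:
        e = _p1(at(b))
        if e is None:
            raise ValueError(f"P1 absent at b = {b}")
        return float(e.eigenvalues[0].real)

    def p1_exists(b: float) -> bool:
        return _p1(at(b)) is not None

    stability_onset = None
    existence_boundary = None
    # bracket stability onset from the scanned rows
    for r0, r1 in zip(rows, rows[1:]):
        e0, e1 = _p1(r0.equilibria), _p1(r1.equilibria)
        if e0 is None or e1 is None:
            continue
        m0 = e0.eigenvalues[0].real
        m1 = e1.eigenvalues[0].real
        if m0 > 0 >= m1:
            stability_onset = brentq(p1_max_re, r0.b, r1.b, xtol=1e-3)
            break
    # bracket disappearance of P1
    for r0, r1 in zip(rows, rows[1:]):
        if p1_exists(r0.b) and not p1_exists(r1.b):
            lo, hi = r0.b, r1.b
            while hi - lo > 1e-3:
                mid = 0.5 * (lo + hi)
                if p1_exists(mid):
                    lo = mid
                else:
                    hi = mid
            existence_boundary = 0.5 * (lo + hi)
            break
    return {"rows": rows, "stability_onset": stability_onset,
            "existence_boundary": existence_boundary}
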