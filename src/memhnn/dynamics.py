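"""Trajectories, Lyapunov spectra, bifurcation scans, attractor labels.

Chaos diagnostics for the memristive Hopfield network.  The Lyapunov
spectrum is computed by the tangent-space variant of Wolf's algorithm:
four tangent vectors are co-integrated with the flow using the analytic
Jacobian, re-orthonormalized by Gram-Schmidt (QR) at a fixed interval,
and the logarithms of the stretch factors are averaged after a transient.
Attractors are labelled from the spectrum plus simple geometric features
of the post-transient orbit: a negative leading exponent marks a stable
point, a zero leading exponent a period-n limit cycle (n = number of
distinct x1-maxima), a positive one chaos; chaotic orbits visiting both
signs of x1 beyond a threshold are double-scroll, otherwise spiral with a
left/right handedness given by the sign of the mean of x1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import find_equilibria
from .hnn import HNNParams, jacobian, rhs

__all__ = [
    "Trajectory",
    "LyapunovSpectrum",
    "AttractorLabel",
    "BifurcationScan",
    "DEFAULT_X0_SET",
    "ZERO_EXPONENT_TOL",
    "DOUBLE_SCROLL_THRESHOLD",
    "integrate",
    "wolf_spectrum",
    "bifurcation_scan",
    "classify_attractor",
    "coexistence_table",
    "symmetry_check",
]

# Reference initial conditions used throughout the coexistence analysis.
DEFAULT_X0_SET = (
    (0.0, 0.1, 0.0, 0.0),
    (0.0, -0.1, 0.0, 0.0),
    (1.0, 0.0, 0.0, 0.0),
)

ZERO_EXPONENT_TOL = 5e-3       # epsilon separating zero from nonzero exponents
# A chaotic orbit is double-scroll when x1 exceeds +theta AND falls below
# -theta.  A double scroll wraps around both nonzero foci (|x1| ~ 1.3-1.7
# over the parameter ranges studied) and its lobes extend past |x1| = 2.5
# on both sides, while one-sided chaotic spirals overshoot the opposite
# side by at most ~1.35; theta = 2 separates the geometries with margin.
DOUBLE_SCROLL_THRESHOLD = 2.0
PERIOD_CLUSTER_TOL = 1e-3      # absolute tolerance when clustering x1 maxima
MAX_PERIOD = 8                 # beyond this many clusters: chaotic/unresolved


@dataclass
class Trajectory:
    """A sampled solution orbit with its provenance."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 4)
    params: HNNParams
    x0: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    def window(self, t_from: float) -> "Trajectory":
        """Sub-trajectory with t >= t_from."""
        m = self.t >= t_from
        return Trajectory(self.t[m], self.states[m], self.params,
                          self.x0, dict(self.meta))


@dataclass
class LyapunovSpectrum:
    """Four Lyapunov exponents (per unit time), largest first."""

    exponents: np.ndarray
    protocol: dict
    x0: np.ndarray
    params: HNNParams
    mean_divergence: float  # time-averaged trace of the Jacobian
    degenerate: bool = False  # L1 and L2 closer than the zero tolerance

    @property
    def L1(self) -> float:
        return float(self.exponents[0])


@dataclass(frozen=True)
class AttractorLabel:
    """Classification of an orbit's limit set."""

    kind: str            # stable-point | period-n | chaotic-spiral |
                         # double-scroll-chaotic | unresolved
    handedness: str      # left | right | both
    n: int = 0           # period count when kind == "period-n"

    def __str__(self) -> str:
        if self.kind == "period-n":
            return f"{self.handedness}-period-{self.n}"
        if self.kind == "double-scroll-chaotic":
            return "double-scroll-chaotic"
        if self.kind == "chaotic-spiral":
            return f"{self.handedness}-chaotic-spiral"
        if self.kind == "stable-point":
            return f"{self.handedness}-stable-point"
        return self.kind


@dataclass
class BifurcationScan:
    """Post-transient x1 local maxima per (b, initial condition) branch."""

    b_values: np.ndarray
    x0_list: tuple
    records: list  # tuples (b, branch_index, x1_max)
    protocol: dict

    def branch(self, branch_index: int) -> np.ndarray:
        return np.array([(b, m) for b, br, m in self.records
                         if br == branch_index])


def integrate(x0, p: HNNParams, t_end: float, dt_out: float = 0.05,
              t_start: float = 0.0, rtol: float = 1e-9, atol: float = 1e-12,
              method: str = "RK45") -> Trajectory:
    """Integrate the network from x0 and sample uniformly every dt_out."""
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    x0 = np.asarray(x0, dtype=float)
    t = np.arange(t_start, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(lambda tt, y: rhs(y, p), (t_start, t[-1]), x0,
                    t_eval=t, method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("trajectory blew up to non-finite values")
    return Trajectory(t=t, states=states, params=p, x0=x0,
                      meta={"method": method, "rtol": rtol, "atol": atol,
                            "dt_out": dt_out})


def _rk4_step(x: np.ndarray, Q: np.ndarray, p: HNNParams, dt: float):
    """One fixed-step RK4 update of the flow and the tangent matrix."""
    def f(xx, QQ):
        return rhs(xx, p), jacobian(xx, p) @ QQ

    k1x, k1q = f(x, Q)
    k2x, k2q = f(x + 0.5 * dt * k1x, Q + 0.5 * dt * k1q)
    k3x, k3q = f(x + 0.5 * dt * k2x, Q + 0.5 * dt * k2q)
    k4x, k4q = f(x + dt * k3x, Q + dt * k3q)
    x_new = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    Q_new = Q + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
    return x_new, Q_new


def wolf_spectrum(x0, p: HNNParams, dt: float = 0.1, t_end: float = 10000.0,
                  renorm_every: int = 1, transient: float = 1000.0) -> LyapunovSpectrum:
    """Lyapunov spectrum by tangent-space evolution with QR renormalization.

    The flow and four tangent vectors (columns of Q, initialized to the
    identity) are advanced with a fixed-step RK4 at step ``dt``.  Every
    ``renorm_every`` steps Q is re-orthonormalized (QR factorization with
    positive diagonal, equivalent to Gram-Schmidt) and the logs of the
    stretch factors are accumulated; accumulation starts after
    ``transient`` time units.  Exponents are returned largest first.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end <= transient:
        raise ValueError("t_end must exceed the transient")
    x = np.asarray(x0, dtype=float).copy()
    Q = np.eye(4)
    n_steps = int(round(t_end / dt))
    n_transient = int(round(transient / dt))
    log_sum = np.zeros(4)
    trace_sum = 0.0
    n_trace = 0
    accumulated_time = 0.0
    for step in range(1, n_steps + 1):
        x, Q = _rk4_step(x, Q, p, dt)
        if step % renorm_every == 0:
            Q, R = np.linalg.qr(Q)
            d = np.sign(np.diag(R))
            d[d == 0] = 1.0
            Q *= d
            growth = np.log(np.abs(np.diag(R)))
            if step > n_transient:
                log_sum += growth
                accumulated_time += renorm_every * dt
        if step > n_transient:
            trace_sum += np.trace(jacobian(x, p))
            n_trace += 1
    exps = np.sort(log_sum / accumulated_time)[::-1]
    degenerate = abs(exps[0] - exps[1]) < ZERO_EXPONENT_TOL and exps[0] > ZERO_EXPONENT_TOL
    if degenerate:
        warnings.warn("leading Lyapunov exponents are closer than the zero "
                      "tolerance; classification may be ambiguous", RuntimeWarning)
    return LyapunovSpectrum(
        exponents=exps,
        protocol={"dt": dt, "t_end": t_end, "renorm_every": renorm_every,
                  "transient": transient},
        x0=np.asarray(x0, dtype=float),
        params=p,
        mean_divergence=trace_sum / max(n_trace, 1),
        degenerate=degenerate,
    )


def _local_maxima(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Values of strict local maxima of x, refined by parabolic interpolation."""
    idx = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]))[0] + 1
    vals = []
    for i in idx:
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            vals.append(y1 - (y0 - y2) ** 2 / (8 * denom))
        else:
            vals.append(y1)
    return np.asarray(vals)


def _cluster_count(vals: np.ndarray, tol: float = PERIOD_CLUSTER_TOL) -> int:
    """Number of distinct value clusters at absolute tolerance tol."""
    if len(vals) == 0:
        return 0
    sv = np.sort(vals)
    return int(1 + np.sum(np.diff(sv) > tol))


def classify_attractor(traj: Trajectory, spec: LyapunovSpectrum,
                       eps: float = ZERO_EXPONENT_TOL,
                       theta: float = DOUBLE_SCROLL_THRESHOLD,
                       window: float = 500.0) -> AttractorLabel:
    """Label the limit set of a trajectory from its Lyapunov spectrum.

    Uses the final ``window`` time units of the trajectory (the caller is
    responsible for having integrated past the transient).
    """
    if spec.degenerate:
        return AttractorLabel(kind="unresolved", handedness="both")
    w = traj.window(traj.t[-1] - window)
    x1 = w.x1
    mean_sign = "right" if float(np.mean(x1)) >= 0 else "left"
    L1 = spec.exponents[0]
    L2 = spec.exponents[1]

    if L1 < -eps:
        # verify convergence onto an equilibrium of the model
        end = w.states[-1]
        eqs = find_equilibria(traj.params)
        dists = [np.linalg.norm(end - e.coords) for e in eqs]
        if min(dists) < 1e-4:
            return AttractorLabel(kind="stable-point", handedness=mean_sign)
        return AttractorLabel(kind="unresolved", handedness=mean_sign)

    if L1 > eps:
        if np.max(x1) > theta and np.min(x1) < -theta:
            return AttractorLabel(kind="double-scroll-chaotic", handedness="both")
        return AttractorLabel(kind="chaotic-spiral", handedness=mean_sign)

    # |L1| <= eps: limit cycle.  L2 of a weakly stable cycle just past a
    # tangent bifurcation can sit inside (-eps, 0), so the periodicity is
    # confirmed by the maxima clustering rather than by the sign of L2: a
    # quasi-periodic or unconverged orbit produces an unbounded number of
    # distinct maxima and falls through to "unresolved".
    n = _cluster_count(_local_maxima(w.t, x1))
    if 1 <= n <= MAX_PERIOD and L2 <= eps:
        return AttractorLabel(kind="period-n", handedness=mean_sign, n=n)
    return AttractorLabel(kind="unresolved", handedness=mean_sign)


# Transient integration protocol mirroring the source experiments
# (Dormand-Prince 4(5) at the solver's standard loose tolerances, output
# step 0.1).  Multistable basins are finely interleaved and the attractor
# an initial condition selects depends on the integration protocol; the
# reference assignments were produced under this one.  Measurements on
# the selected attractor are then taken with the tight-tolerance solver.
SETTLE_PROTOCOL = {"rtol": 1e-3, "atol": 1e-6, "max_step": 0.1}


def settle(x0, p: HNNParams, transient: float = 1500.0,
           window: float = 500.0, dt_out: float = 0.05) -> Trajectory:
    """Basin-faithful transient, then a tight measurement window.

    Integrates the transient with the loose reference protocol (which
    decides the coexisting attractor reached from x0), then re-integrates
    the final ``window`` time units from the settled state with the
    tight-tolerance solver.  Returns the window trajectory.
    """
    x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(lambda tt, y: rhs(y, p), (0.0, transient), x0,
                    method="RK45", **SETTLE_PROTOCOL)
    if not sol.success:
        raise RuntimeError(f"transient integration failed: {sol.message}")
    w = integrate(sol.y[:, -1], p, t_start=transient,
                  t_end=transient + window, dt_out=dt_out)
    w.x0 = x0
    w.meta["transient"] = transient
    w.meta["settle_protocol"] = dict(SETTLE_PROTOCOL)
    return w


def bifurcation_scan(p_base: HNNParams, b_grid, x0_list=DEFAULT_X0_SET,
                     transient: float = 900.0, window: float = 300.0,
                     dt_out: float = 0.05) -> BifurcationScan:
    """Post-transient x1 local maxima over a grid of b, per initial condition.

    Every grid point restarts from the fixed initial conditions (no
    continuation between points), so each branch traces the attractor
    selected by its initial condition under the reference transient
    protocol.
    """
    b_grid = np.asarray(b_grid, dtype=float)
    records = []
    for b in b_grid:
        p = HNNParams(k=p_base.k, a=p_base.a, b=float(b), weights=p_base.weights)
        for br, x0 in enumerate(x0_list):
            w = settle(x0, p, transient=transient, window=window,
                       dt_out=dt_out)
            for m in _local_maxima(w.t, w.x1):
                records.append((float(b), br, float(m)))
    return BifurcationScan(
        b_values=b_grid, x0_list=tuple(tuple(x) for x in x0_list),
        records=records,
        protocol={"transient": transient, "window": window, "dt_out": dt_out,
                  **SETTLE_PROTOCOL})


def coexistence_table(p_base: HNNParams, b_list, x0_list=DEFAULT_X0_SET,
                      transient: float = 1500.0, window: float = 500.0,
                      spectrum_dt: float = 0.1,
                      spectrum_t_end: float = 1500.0,
                      spectrum_transient: float = 200.0) -> list[dict]:
    """Attractor label and spectrum for every (b, initial condition) cell.

    The transient is integrated with the loose reference protocol (which
    decides the coexisting attractor each initial condition selects);
    geometry is then measured on a tight-tolerance window and the
    Lyapunov spectrum is computed *from the settled state*, so the
    spectrum describes the same attractor the orbit settled on.
    (Coexisting basins are interleaved: a tangent integration restarted
    from the raw initial condition can land on a different coexisting
    attractor.)

    Returns a list of dict rows with keys b, x0, label (AttractorLabel),
    spectrum (LyapunovSpectrum).  Cells whose label is unresolved are kept
    and flagged by the label itself.
    """
    rows = []
    for b in np.asarray(b_list, dtype=float):
        p = HNNParams(k=p_base.k, a=p_base.a, b=float(b), weights=p_base.weights)
        for x0 in x0_list:
            w = settle(x0, p, transient=transient, window=window)
            spec = wolf_spectrum(w.states[0], p, dt=spectrum_dt,
                                 t_end=spectrum_t_end,
                                 transient=spectrum_transient)
            label = classify_attractor(w, spec, window=window)
            rows.append({"b": float(b), "x0": tuple(x0), "label": label,
                         "spectrum": spec})
    return rows


def symmetry_check(x0, p: HNNParams, t_end: float = 100.0,
                   dt_out: float = 0.05) -> float:
    """Max deviation from the (x, b) -> (-x, -b) equivariance.

    Integrates the model from x0 with parameter b and from -x0 with -b
    and returns max_t ||x(t) + x_mirror(t)||; an exact symmetry gives 0.
    """
    x0 = np.asarray(x0, dtype=float)
    traj = integrate(x0, p, t_end=t_end, dt_out=dt_out)
    mirror = integrate(-x0, p.mirrored(), t_end=t_end, dt_out=dt_out)
    return float(np.max(np.linalg.norm(traj.states + mirror.states, axis=1)))
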