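"""Memristive 3-neuron Hopfield network: vector field, Jacobian, bounds.

The network couples three Hopfield neurons (unit membrane constants, zero
bias currents, tanh activation) through a fixed synaptic weight matrix in
which one connection — the weight from neuron 1 into neuron 3 — is
replaced by a memristive synapse k*W with W = a - b*tanh(x4), where x4 is
the memristor inner state driven by the activation of neuron 1.  The
resulting four-dimensional autonomous system is

    x1' = -x1 - 1.4*tanh(x1) + 1.2*tanh(x2) - 7*tanh(x3)
    x2' = -x2 + 1.1*tanh(x1) + 2.8*tanh(x3)
    x3' = -x3 + k*(a - b*tanh(x4))*tanh(x1) - 2*tanh(x2) + 4*tanh(x3)
    x4' = -x4 + tanh(x1)

The system is dissipative and all orbits are bounded; it is equivariant
under (x1, x2, x3, x4, b) -> (-x1, -x2, -x3, -x4, -b), so attractors at
parameter b have mirror images at -b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_WEIGHTS",
    "MEMRISTIVE_SLOT",
    "HNNParams",
    "BoundConstants",
    "rhs",
    "general_hnn_rhs",
    "jacobian",
    "bound_constants",
]

# Fixed synaptic weights; the memristive synapse occupies the (3,1) slot
# (row i = 3 receives k*W * tanh(x1)).  Its placeholder value is nan.
MEMRISTIVE_SLOT = (2, 0)
DEFAULT_WEIGHTS = np.array([
    [-1.4, 1.2, -7.0],
    [1.1, 0.0, 2.8],
    [np.nan, -2.0, 4.0],
])


def _default_weights() -> np.ndarray:
    return DEFAULT_WEIGHTS.copy()


@dataclass
class HNNParams:
    """Parameters of the memristive Hopfield network.

    Parameters
    ----------
    k : float
        Memristor coupling strength (> 0).
    a : float
        Memductance offset (> 0).
    b : float
        Memductance modulation depth (>= 0 for all physical experiments;
        negative values arise only through :meth:`mirrored`, used to
        exercise the parameter-symmetry of the model).
    weights : (3, 3) ndarray
        Synaptic weight matrix; the entry at ``MEMRISTIVE_SLOT`` is a
        placeholder (nan) standing for the memristive weight k*W.
    """

    k: float = 0.8
    a: float = 1.0
    b: float = 0.26
    weights: np.ndarray = field(default_factory=_default_weights)

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"coupling strength k must be > 0, got {self.k}")
        if not self.a > 0:
            raise ValueError(f"memductance offset a must be > 0, got {self.a}")
        if self.b < 0:
            raise ValueError(
                f"modulation depth b must be >= 0, got {self.b}; "
                "use HNNParams.mirrored() for the b -> -b symmetry image")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (3, 3):
            raise ValueError("weights must be a 3x3 matrix")

    def mirrored(self) -> "HNNParams":
        """Parameter set with b negated (symmetry image of the model).

        The vector field with (x, b) maps to the negated field at
        (-x, -b); this constructor is the only sanctioned way to obtain
        a negative modulation depth.
        """
        out = HNNParams(k=self.k, a=self.a, b=0.0, weights=self.weights)
        out.b = -self.b
        return out

    def memductance(self, x4):
        """Synaptic memductance W(x4) = a - b*tanh(x4)."""
        return self.a - self.b * np.tanh(x4)

    def to_dict(self) -> dict:
        return {"k": self.k, "a": self.a, "b": self.b,
                "weights": self.weights.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "HNNParams":
        kw = {k: d[k] for k in ("k", "a", "b") if k in d}
        if "weights" in d and d["weights"] is not None:
            w = np.asarray([[np.nan if v is None else v for v in row]
                            for row in d["weights"]], dtype=float)
            kw["weights"] = w
        b = kw.pop("b", 0.26)
        p = cls(b=abs(b), **kw)
        p.b = b
        return p

    @classmethod
    def default(cls) -> "HNNParams":
        """Reference parameters shipped with the package."""
        import json
        from importlib.resources import files
        d = json.loads(files("memhnn.data").joinpath(
            "default_model.json").read_text())
        return cls.from_dict(d)


@dataclass(frozen=True)
class BoundConstants:
    """Constants of the dissipativity bound.

    M bounds the memductance magnitude, M = max{|a-b|, |a+b|}; c are the
    coefficients of the linear form that dominates the cross terms of
    dV/dt for the quadratic Lyapunov function V = ||x||^2 / 2, namely
    9.6|x1| + 3.9|x2| + (kM+6)|x3| + |x4|.  Outside a large enough ball
    this form is beaten by -2V, so dV/dt < 0 and all orbits are trapped.
    """

    M: float
    c: tuple[float, float, float, float]


def bound_constants(p: HNNParams) -> BoundConstants:
    """Memductance bound M and linear coefficients of the trapping estimate."""
    M = max(abs(p.a - p.b), abs(p.a + p.b))
    return BoundConstants(M=M, c=(9.6, 3.9, p.k * M + 6.0, 1.0))


def rhs(x, p: HNNParams) -> np.ndarray:
    """Vector field of the memristive network.

    ``x`` may be shape (4,) or (4, n) for batched evaluation.  The
    synaptic weights come from ``p.weights`` with the memristive slot
    evaluated as k*(a - b*tanh(x4)).
    """
    x = np.asarray(x, dtype=float)
    t = np.tanh(x)
    A = p.weights.copy()
    A[MEMRISTIVE_SLOT] = 0.0
    W = p.a - p.b * t[3]
    syn = A @ t[:3]
    syn[MEMRISTIVE_SLOT[0]] = (syn[MEMRISTIVE_SLOT[0]]
                               + p.k * W * t[MEMRISTIVE_SLOT[1]])
    return np.concatenate([
        -x[:3] + syn,
        np.reshape(-x[3] + t[0], (1,) + np.shape(x[3])),
    ])


def general_hnn_rhs(x, C, R, W, I) -> np.ndarray:
    """Generic n-neuron Hopfield vector field.

    x_i' = (-x_i/R_i + sum_j w_ij*tanh(x_j) + I_i) / C_i

    with membrane capacitances C, membrane resistances R, synaptic weight
    matrix W (w_ij couples the activation of neuron j into neuron i), and
    bias currents I.
    """
    x = np.asarray(x, dtype=float)
    C = np.broadcast_to(np.asarray(C, dtype=float), x.shape).copy()
    R = np.broadcast_to(np.asarray(R, dtype=float), x.shape)
    I = np.broadcast_to(np.asarray(I, dtype=float), x.shape)
    W = np.asarray(W, dtype=float)
    n = x.shape[0]
    if W.shape != (n, n):
        raise ValueError(f"weight matrix must be {n}x{n}, got {W.shape}")
    if np.any(C <= 0):
        raise ValueError("capacitances must be strictly positive")
    return (-x / R + W @ np.tanh(x) + I) / C


def jacobian(x, p: HNNParams) -> np.ndarray:
    """Jacobian of the vector field at state x (any state, not only equilibria).

    With h_i = sech^2(x_i) and W = a - b*tanh(x4):

        [ -1-1.4h1   1.2h2   -7h3        0              ]
        [ 1.1h1      -1      2.8h3       0              ]
        [ kWh1       -2h2    -1+4h3      -kb tanh(x1)h4 ]
        [ h1         0       0           -1             ]
    """
    x = np.asarray(x, dtype=float)
    h = 1.0 / np.cosh(x) ** 2
    t1, t4 = np.tanh(x[0]), np.tanh(x[3])
    W = p.a - p.b * t4
    A = p.weights.copy()
    A[MEMRISTIVE_SLOT] = p.k * W
    J = np.zeros((4, 4))
    J[:3, :3] = -np.eye(3) + A * h[:3]       # entry (i,j) = a_ij * h_j
    J[MEMRISTIVE_SLOT[0], 3] = -p.k * p.b * t1 * h[3]
    J[3, 0] = h[0]
    J[3, 3] = -1.0
    return J
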