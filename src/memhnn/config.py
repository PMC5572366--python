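"""Run configuration and result serialization.

A :class:`RunConfig` captures everything needed to reproduce a run: the
model parameters, the numerical protocol (steps, horizons, transients,
tolerances, classification thresholds), the scan grids and initial
conditions, output paths and the seed.  Configs round-trip losslessly
through JSON or YAML, and every result bundle embeds the config snapshot
that produced it.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hnn import HNNParams
from .dynamics import (DEFAULT_X0_SET, DOUBLE_SCROLL_THRESHOLD,
                       ZERO_EXPONENT_TOL)

log = logging.getLogger("memhnn")

RUN_KINDS = ("memristor-loop", "equilibria", "regime-scan", "lyapunov",
             "bifurcation", "coexistence")

#: Parameter sets of the three reference coexistence studies.
PRESETS = {
    "paper-case1": {"k": 0.8, "a": 1.0, "b_min": 0.0, "b_max": 0.6},
    "paper-case2": {"k": 0.95, "a": 1.0, "b_min": 0.0, "b_max": 0.6},
    "paper-case3": {"k": 1.0, "a": 1.0, "b_min": 0.0, "b_max": 0.6},
}


def _default_protocol() -> dict:
    return {
        "dt": 0.1,              # Lyapunov fixed step
        "t_end": 10000.0,       # Lyapunov horizon
        "lyap_transient": 1000.0,
        "transient": 1500.0,    # classification transient
        "window": 500.0,        # classification window
        "dt_out": 0.05,
        "rtol": 1e-9,
        "atol": 1e-12,
        "eps": ZERO_EXPONENT_TOL,
        "theta": DOUBLE_SCROLL_THRESHOLD,
    }


def _default_scan() -> dict:
    return {
        "b_min": 0.0,
        "b_max": 0.6,
        "b_steps": 61,
        "b_list": None,          # explicit list overrides min/max/steps
        "x0_list": [list(x) for x in DEFAULT_X0_SET],
    }


def _default_drive() -> dict:
    return {"Vm": 4.0, "f": 400.0, "cycles": 4, "samples_per_cycle": 512,
            "R": 10e3, "C": 100e-9, "Ra": 10e3, "Rb": 2e3, "g": 0.1}


@dataclass
class RunConfig:
    kind: str = "coexistence"
    model: dict = field(default_factory=lambda: {"k": 0.8, "a": 1.0,
                                                 "b": 0.26, "weights": None})
    protocol: dict = field(default_factory=_default_protocol)
    scan: dict = field(default_factory=_default_scan)
    drive: dict = field(default_factory=_default_drive)
    out: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in RUN_KINDS:
            raise ValueError(f"unknown run kind {self.kind!r}; "
                             f"expected one of {RUN_KINDS}")
        base = _default_protocol()
        unknown = set(self.protocol) - set(base)
        if unknown:
            raise ValueError(f"unknown protocol fields: {sorted(unknown)}")
        base.update(self.protocol)
        self.protocol = base
        base = _default_scan()
        unknown = set(self.scan) - set(base)
        if unknown:
            raise ValueError(f"unknown scan fields: {sorted(unknown)}")
        base.update(self.scan)
        self.scan = base

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_file(self, path: str) -> None:
        d = self.to_dict()
        text = (json.dumps(d, indent=2) if path.endswith(".json")
                else yaml.safe_dump(d, sort_keys=False))
        _atomic_write(path, text)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = (json.load(fh) if path.endswith(".json")
                 else yaml.safe_load(fh))
        return cls.from_dict(d)

    # -- derived objects ---------------------------------------------------
    def hnn_params(self, b: float | None = None) -> HNNParams:
        m = self.model
        kw = {"k": m.get("k", 0.8), "a": m.get("a", 1.0),
              "b": m.get("b", 0.26) if b is None else b}
        if m.get("weights") is not None:
            kw["weights"] = np.asarray(m["weights"], dtype=float)
        return HNNParams(**kw)

    def b_values(self) -> np.ndarray:
        s = self.scan
        if s.get("b_list") is not None:
            vals = np.asarray(s["b_list"], dtype=float)
        else:
            vals = np.linspace(s["b_min"], s["b_max"], int(s["b_steps"]))
        if vals.size == 0:
            raise ValueError("empty scan grid")
        return vals

    def x0_list(self) -> tuple:
        return tuple(tuple(float(v) for v in x) for x in self.scan["x0_list"])


@dataclass
class ResultBundle:
    """A run's tabular payload plus the provenance needed to re-run it."""

    kind: str
    config: RunConfig
    payload: pd.DataFrame
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def write(self, path: str) -> None:
        """Write the payload (CSV for tables, JSON otherwise) atomically.

        Numeric output keeps full double precision; a header block
        documents the run kind, software version and config.
        """
        if path.endswith(".csv"):
            header = "".join(
                f"# {line}\n" for line in (
                    f"memhnn {self.version} :: {self.kind} :: {self.timestamp}",
                    "config: " + json.dumps(self.config.to_dict()),
                ))
            text = header + self.payload.to_csv(index=False,
                                                float_format="%.17g")
            _atomic_write(path, text)
        else:
            doc = {"kind": self.kind, "version": self.version,
                   "timestamp": self.timestamp,
                   "config": self.config.to_dict(),
                   "payload": self.payload.to_dict(orient="records")}
            _atomic_write(path, json.dumps(doc, indent=2, default=_jsonify))
        log.info("wrote %s result to %s (%d rows)", self.kind, path,
                 len(self.payload))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def run(config: RunConfig) -> ResultBundle:
    """Execute the run a config describes and return its result bundle.

    Dispatches on ``config.kind``; writes the payload to ``config.out``
    when set.  Numerical warnings raised by the underlying operations are
    logged, not swallowed.
    """
    from . import dynamics, equilibria, memristor

    prot = config.protocol
    t0 = time.time()
    log.info("run kind=%s seed=%d", config.kind, config.seed)

    if config.kind == "memristor-loop":
        d = config.drive
        cv = memristor.CircuitValues(R=d["R"], C=d["C"], Ra=d["Ra"],
                                     Rb=d["Rb"], g=d["g"])
        loop = memristor.simulate_loop(
            cv, memristor.DriveSignal(Vm=d["Vm"], f=d["f"]),
            n_cycles=int(d["cycles"]),
            samples_per_cycle=int(d["samples_per_cycle"]))
        payload = pd.DataFrame({"t": loop.t, "v": loop.v, "i": loop.i,
                                "v0": loop.v0})

    elif config.kind == "equilibria":
        eqs = equilibria.find_equilibria(config.hnn_params())
        payload = pd.DataFrame([_eq_row(e) for e in eqs])

    elif config.kind == "regime-scan":
        res = equilibria.regime_scan(config.hnn_params(b=0.0),
                                     config.b_values())
        recs = []
        for row in res["rows"]:
            for e in row.equilibria:
                recs.append({"b": row.b, **_eq_row(e)})
        payload = pd.DataFrame(recs)
        payload.attrs["stability_onset"] = res["stability_onset"]
        payload.attrs["existence_boundary"] = res["existence_boundary"]

    elif config.kind == "lyapunov":
        # cap the transient at a fifth of the horizon for short runs
        transient = min(prot["lyap_transient"], 0.2 * prot["t_end"])
        spec = dynamics.wolf_spectrum(
            config.x0_list()[0], config.hnn_params(), dt=prot["dt"],
            t_end=prot["t_end"], transient=transient)
        payload = pd.DataFrame([{
            **{f"L{i+1}": spec.exponents[i] for i in range(4)},
            "sum": float(spec.exponents.sum()),
            "mean_divergence": spec.mean_divergence,
            "degenerate": spec.degenerate}])

    elif config.kind == "bifurcation":
        scan = dynamics.bifurcation_scan(
            config.hnn_params(b=0.0), config.b_values(),
            x0_list=config.x0_list())
        payload = pd.DataFrame(scan.records,
                               columns=["b", "branch", "x1_max"])
        payload["maximum_index"] = payload.groupby(
            ["b", "branch"]).cumcount()
        payload = payload[["b", "branch", "maximum_index", "x1_max"]]

    elif config.kind == "coexistence":
        rows = dynamics.coexistence_table(
            config.hnn_params(b=0.0), config.b_values(),
            x0_list=config.x0_list(),
            transient=prot["transient"], window=prot["window"])
        recs = []
        unresolved = 0
        for r in rows:
            lab = r["label"]
            unresolved += lab.kind == "unresolved"
            recs.append({"b": r["b"], "x0_label": str(tuple(r["x0"])),
                         "kind": lab.kind, "handedness": lab.handedness,
                         "n": lab.n,
                         **{f"L{i+1}": r["spectrum"].exponents[i]
                            for i in range(4)}})
        payload = pd.DataFrame(recs)
        if unresolved:
            log.warning("%d unresolved cells in coexistence table", unresolved)
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(config.kind)

    bundle = ResultBundle(kind=config.kind, config=config, payload=payload)
    if config.out:
        bundle.write(config.out)
    log.info("run finished in %.1f s", time.time() - t0)
    return bundle


def _eq_row(e) -> dict:
    d = {f"x{i+1}": e.coords[i] for i in range(4)}
    for i, lam in enumerate(e.eigenvalues):
        d[f"eig{i+1}_re"] = float(lam.real)
        d[f"eig{i+1}_im"] = float(lam.imag)
    d["label"] = e.label
    d["residual"] = e.residual
    return d
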