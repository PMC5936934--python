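"""Run configurations: schema, Fourier-string grammar and model building.

Model configs are YAML or JSON (auto-detected).  Time dependence of rates
is expressed in a small closed grammar rather than arbitrary code::

    "0.5"                      constant
    "1 + 1*cos(1*t + 0)"       offset plus cosine terms
    "2 - 2*sin(1*t + 0.75)"    sine terms (rewritten as cosines)

Each term is either a number or ``a*cos(w*t + phi)`` / ``a*sin(w*t + phi)``
with numeric coefficients (``pi`` is accepted as a literal).  State
dependence enters only through named built-in forms (the migration model's
exponential coupling), never through embedded user code.

A top-level config looks like::

    model:
      type: tasep            # tasep | sis | two_state | migration | generic
      n: 3
      period: 6.283185307179586
      rates: {alpha: "1+1*cos(1*t+0)", beta: "1+1*cos(1*t+3.141592653589793)",
              h: ["0.5", "0.25"]}
    initial: uniform         # uniform | {basis: i} | [x1, ..., xN]  (1-based basis)
    horizon_periods: 20
    solver: {rtol: 1.0e-9, atol: 1.0e-12}
    sampling: {n_time: 25, n_state: 200}
    seed: 1
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from ._errors import ConfigurationError
from .models import build_migration, build_sis, build_tasep, build_two_state
from .rates import ConstantRate, FourierRate
from .system import MasterSystem

__all__ = ["RunConfig", "parse_config", "parse_fourier", "build_model", "config_hash"]

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?|pi"

_TERM_RE = re.compile(
    rf"^(?:(?P<coef>{_NUM})\s*\*\s*)?(?P<fn>cos|sin)\s*\(\s*"
    rf"(?:(?P<freq>{_NUM})\s*\*\s*)?t\s*(?:(?P<sign>[-+])\s*(?P<phase>{_NUM})\s*)?\)$"
)


def _num(s: str) -> float:
    s = s.strip()
    if s in ("pi", "+pi"):
        return math.pi
    if s == "-pi":
        return -math.pi
    return float(s)


def _split_terms(expr: str):
    """Split on top-level + and -, keeping signs (no parens nesting needed)."""
    terms, depth, cur, sign = [], 0, "", 1.0
    for ch in expr:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch in "+-" and depth == 0 and cur.strip():
            terms.append((sign, cur.strip()))
            sign = 1.0 if ch == "+" else -1.0
            cur = ""
        elif ch in "+-" and depth == 0 and not cur.strip():
            sign *= 1.0 if ch == "+" else -1.0
        else:
            cur += ch
    if cur.strip():
        terms.append((sign, cur.strip()))
    return terms


def parse_fourier(expr: str, period: Optional[float] = None,
                  clip: bool = False) -> FourierRate:
    """Parse the restricted Fourier grammar into a :class:`FourierRate`.

    ``sin(theta)`` terms are rewritten as ``cos(theta - pi/2)``.
    """
    if not isinstance(expr, str):
        expr = str(expr)
    c0 = 0.0
    terms = []
    for sign, term in _split_terms(expr):
        m = _TERM_RE.match(term)
        if m:
            coef = sign * (_num(m.group("coef")) if m.group("coef") else 1.0)
            freq = _num(m.group("freq")) if m.group("freq") else 1.0
            phase = _num(m.group("phase") or "0")
            if m.group("sign") == "-":
                phase = -phase
            if m.group("fn") == "sin":
                phase -= math.pi / 2.0
            terms.append((coef, freq, phase))
        else:
            try:
                c0 += sign * _num(term)
            except ValueError:
                raise ConfigurationError(
                    f"cannot parse rate term {term!r} in {expr!r}"
                ) from None
    return FourierRate(c0=c0, terms=tuple(terms), period=period, clip=clip)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    model: dict
    initial: object = "uniform"
    horizon_periods: int = 20
    solver: dict = field(default_factory=lambda: {"rtol": 1e-9, "atol": 1e-12})
    sampling: dict = field(default_factory=lambda: {"n_time": 25, "n_state": 200})
    seed: int = 0
    output: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "initial": self.initial,
            "horizon_periods": self.horizon_periods,
            "solver": self.solver,
            "sampling": self.sampling,
            "seed": self.seed,
            "output": self.output,
        }


def parse_config(path) -> RunConfig:
    """Load a YAML/JSON run config and validate its schema."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "model" not in raw:
        raise ConfigurationError("config must be a mapping with a 'model' section")
    model = raw["model"]
    if "type" not in model:
        raise ConfigurationError("config field 'model.type' is missing")
    known = {"tasep", "sis", "two_state", "migration", "generic"}
    if model["type"] not in known:
        raise ConfigurationError(
            f"unknown model type {model['type']!r}; expected one of {sorted(known)}"
        )
    cfg = RunConfig(
        model=model,
        initial=raw.get("initial", "uniform"),
        horizon_periods=int(raw.get("horizon_periods", 20)),
        solver={**{"rtol": 1e-9, "atol": 1e-12}, **raw.get("solver", {})},
        sampling={**{"n_time": 25, "n_state": 200}, **raw.get("sampling", {})},
        seed=int(raw.get("seed", 0)),
        output=raw.get("output", {}),
    )
    build_model(cfg)  # validate eagerly so schema errors name the field
    return cfg


def _rate_from_spec(spec, period, name: str):
    if isinstance(spec, (int, float)):
        if spec < 0:
            raise ConfigurationError(f"rate {name!r} must be non-negative, got {spec}")
        return ConstantRate(float(spec))
    rate = parse_fourier(spec, period=period)
    # reject specs whose series dips negative anywhere over one period
    T = period if period else 2.0 * math.pi
    ts = np.linspace(0.0, T, 512, endpoint=False)
    vals = [rate(t) for t in ts]
    if min(vals) < 0:
        raise ConfigurationError(
            f"rate {name!r} = {spec!r} takes negative values (min {min(vals):.3g})"
        )
    return rate


def build_model(cfg: RunConfig):
    """Instantiate the model a config describes.

    Returns the model object (``TASEPModel``/``SISModel``) or the bare
    :class:`MasterSystem` for two-state, migration and generic models.
    """
    m = cfg.model
    mtype = m["type"]
    period = m.get("period")
    rates = m.get("rates", {})
    try:
        if mtype == "tasep":
            n = int(m["n"])
            alpha = _rate_from_spec(rates["alpha"], period, "alpha")
            beta = _rate_from_spec(rates["beta"], period, "beta")
            hs = [_rate_from_spec(h, period, f"h{k + 1}")
                  for k, h in enumerate(rates.get("h", []))]
            return build_tasep(n, alpha, beta, hs, period=period)
        if mtype == "sis":
            N = int(m["N"])
            a = _rate_from_spec(rates["a"], period, "a")
            b = _rate_from_spec(rates["b"], period, "b")
            c = _rate_from_spec(rates["c"], period, "c")
            return build_sis(N, a, b, c, period=period)
        if mtype == "two_state":
            p12 = _rate_from_spec(rates["p12"], period, "p12")
            p21 = _rate_from_spec(rates["p21"], period, "p21")
            return build_two_state(p12, p21, period=period)
        if mtype == "migration":
            K = int(m["K"])
            k = m["k"]
            if isinstance(k, list):
                k = np.asarray(k, dtype=float)
            return build_migration(K, k, period=period)
        # generic: explicit rate table, 1-based indices in the file
        n = int(m["n_states"])
        if period is None:
            raise ConfigurationError("generic models must declare 'model.period'")
        table = {}
        for entry in m.get("rates", []):
            i, j = int(entry["from"]) - 1, int(entry["to"]) - 1
            table[(i, j)] = _rate_from_spec(
                entry["rate"], period, f"p{i + 1},{j + 1}"
            )
        return MasterSystem(n, table, period, label=m.get("label", "generic"))
    except KeyError as e:
        raise ConfigurationError(f"config field {e.args[0]!r} is missing for "
                                 f"model type {mtype!r}") from None


def initial_state(cfg: RunConfig, n: int) -> np.ndarray:
    """Resolve the initial-condition spec into a probability vector."""
    init = cfg.initial
    if init == "uniform":
        return np.full(n, 1.0 / n)
    if isinstance(init, dict) and "basis" in init:
        i = int(init["basis"]) - 1  # 1-based in configs
        if not 0 <= i < n:
            raise ConfigurationError(f"basis index {i + 1} out of range 1..{n}")
        e = np.zeros(n)
        e[i] = 1.0
        return e
    x = np.asarray(init, dtype=float)
    if x.shape != (n,):
        raise ConfigurationError(f"initial vector has shape {x.shape}, expected ({n},)")
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
        raise ConfigurationError("initial vector must be a probability vector")
    return x


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the serialized config (embedded in reports)."""
    import hashlib

    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
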