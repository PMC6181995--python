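"""Mechanochemical negative-feedback control of membrane tension.

The model couples three variables:

- ``gamma``: instantaneous (apparent) membrane tension, dimensionless with
  the passive baseline gamma_p = 1;
- ``v``: active membrane-bound vinculin fraction in [0, 1] — the *fast*
  tension sensor (activation time tau_v ~ 1 s);
- ``g``: activated membrane-bound GBF1 — the *slow* arm regulating
  CLIC/GEEC (CG) endocytic capacity (relaxation time tau_g ~ 30 s).

Dynamics::

    dgamma/dt = k_a (J_endo - J_exo) + (gamma_p - gamma) / tau_m
    dv/dt     = (v_inf(gamma) - v) / tau_v,   v_inf = gamma^n / (gamma_v^n + gamma^n)
    dg/dt     = (g_inf(v) - g) / tau_g,       g_inf = g_max K^m / (K^m + v^m)

with fluxes::

    J_endo = k_e g / (1 + (gamma/gamma_e)^h)      (CG endocytosis)
    J_exo  = J_x gamma / (gamma_x + gamma)        (exocytosis)

Endocytosis removes membrane area and so *raises* tension; tension
activates vinculin, vinculin displaces GBF1 from the membrane, and GBF1
drives endocytosis — a negative feedback loop (signs + . - . + . + = -)
whose stable fixed point is the emergent tension set point gamma_s.
Slow activation (GBF1) with fast inhibition (vinculin) gives the
characteristic transient: a sudden tension drop de-activates vinculin
immediately, GBF1 then accumulates over tens of seconds, endocytic flux
overshoots, and tension is pulled back to the set point within ~90 s.

Functional forms are monotone Hill terms — the minimal realization
consistent with the component list, dependency structure and timescale
separation of the biological circuit; they are this package's own
concrete choice, not a published parameterization.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .errors import IntegrationError, ModelConfigurationError, ParameterError

__all__ = [
    "ModelParams",
    "FeedbackState",
    "Protocol",
    "ModelTrajectory",
    "tension_step",
    "clamp_v",
    "clamp_g",
    "scale",
    "release",
    "fluxes",
    "rhs",
    "steady_state",
    "stability",
    "simulate",
    "protocol_preset",
    "uptake_proxy",
    "response_gain",
    "qssa_reduce",
    "ReducedModel",
    "PRESET_NAMES",
]

_PARAM_FIELDS = (
    "gamma_p",
    "tau_m",
    "k_a",
    "k_e",
    "gamma_e",
    "h",
    "J_x",
    "gamma_x",
    "tau_v",
    "gamma_v",
    "n",
    "tau_g",
    "g_max",
    "K",
    "m",
)


@dataclass(frozen=True)
class ModelParams:
    """Feedback-model parameters. Use :meth:`default` for the shipped set."""

    gamma_p: float
    tau_m: float
    k_a: float
    k_e: float
    gamma_e: float
    h: float
    J_x: float
    gamma_x: float
    tau_v: float
    gamma_v: float
    n: float
    tau_g: float
    g_max: float
    K: float
    m: float

    def __post_init__(self):
        for name in _PARAM_FIELDS:
            if not (getattr(self, name) > 0):
                raise ParameterError(f"parameter {name} must be > 0")
        if self.tau_v / self.tau_g > 1.0 / 20.0:
            warnings.warn(
                "timescale separation tau_v << tau_g violated "
                f"(tau_v/tau_g = {self.tau_v / self.tau_g:.3g} > 1/20); "
                "the fast-sensing / slow-regulation structure is degraded",
                stacklevel=2,
            )

    @classmethod
    def default(cls) -> "ModelParams":
        """Load the shipped default parameter set (data/default_params.yaml)."""
        return cls(**_default_config()["params"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg["params"])

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return asdict(self)


def _default_config() -> dict:
    res = importlib.resources.files("cgtension").joinpath("data/default_params.yaml")
    return yaml.safe_load(res.read_text())


@dataclass
class FeedbackState:
    """Instantaneous model state (tension, vinculin, GBF1)."""

    gamma: float
    v: float
    g: float

    def __post_init__(self):
        if not (0.0 <= self.v <= 1.0):
            raise ParameterError("v must lie in [0, 1]")
        if self.g < 0 or self.gamma < 0:
            raise ParameterError("g and gamma must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma, self.v, self.g])


# ---------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class Action:
    kind: str  # tension_step | clamp_v | clamp_g | scale | release
    value: float | None = None
    param: str | None = None

    def __repr__(self):
        inner = self.param if self.kind in ("scale", "release") and self.param else ""
        if self.value is not None:
            inner += ("," if inner else "") + f"{self.value:g}"
        return f"{self.kind}({inner})"


def tension_step(factor: float) -> Action:
    """Multiply the instantaneous tension by ``factor`` (strain step)."""
    if factor <= 0:
        raise ParameterError("tension_step factor must be > 0")
    return Action("tension_step", value=factor)


def clamp_v(value: float) -> Action:
    """Freeze vinculin at ``value`` (null/suspension: mechanosensing off)."""
    return Action("clamp_v", value=value)


def clamp_g(value: float) -> Action:
    """Freeze GBF1 at ``value`` (GBF1 inhibition: clamp_g(0))."""
    return Action("clamp_g", value=value)


def scale(param: str, factor: float) -> Action:
    """Multiply a model parameter by ``factor`` from the event time on."""
    if param not in _PARAM_FIELDS:
        raise ParameterError(f"unknown parameter {param!r}")
    return Action("scale", value=factor, param=param)


def release(which: str) -> Action:
    """Remove a standing clamp ('v' or 'g')."""
    if which not in ("v", "g"):
        raise ParameterError("release target must be 'v' or 'g'")
    return Action("release", param=which)


@dataclass
class Protocol:
    """Timed perturbations applied during a simulation.

    ``events`` is an ordered list of (time_s, Action); ``marks`` names
    notable times (e.g. the relaxation instant) for window bookkeeping.
    """

    events: list[tuple[float, Action]] = field(default_factory=list)
    t_end: float = 300.0
    marks: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ParameterError("event times must be nondecreasing")
        if any(t < 0 or t > self.t_end for t in times):
            raise ParameterError("event times must lie in [0, t_end]")


@dataclass
class ModelTrajectory:
    """Time course of the model with recorded fluxes and set point."""

    time_s: np.ndarray
    gamma: np.ndarray
    v: np.ndarray
    g: np.ndarray
    J_endo: np.ndarray
    J_exo: np.ndarray
    gamma_s: float  # unperturbed fixed-point tension (emergent set point)
    params: "ModelParams" = None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time_s,
                "gamma": self.gamma,
                "v": self.v,
                "g": self.g,
                "J_endo": self.J_endo,
                "J_exo": self.J_exo,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model core


def _v_inf(gamma: float, p: ModelParams) -> float:
    gn = gamma**p.n
    return gn / (p.gamma_v**p.n + gn)


def _g_inf(v: float, p: ModelParams) -> float:
    km = p.K**p.m
    return p.g_max * km / (km + v**p.m)


def fluxes(state: FeedbackState, params: ModelParams) -> tuple[float, float]:
    """(J_endo, J_exo): CG endocytic and exocytic membrane fluxes."""
    j_endo = params.k_e * state.g / (1.0 + (state.gamma / params.gamma_e) ** params.h)
    j_exo = params.J_x * state.gamma / (params.gamma_x + state.gamma)
    return j_endo, j_exo


def rhs(
    state: FeedbackState, params: ModelParams, clamps: dict[str, float] | None = None
) -> np.ndarray:
    """Time derivative (dgamma/dt, dv/dt, dg/dt); clamped variables get 0."""
    clamps = clamps or {}
    j_endo, j_exo = fluxes(state, params)
    dgamma = params.k_a * (j_endo - j_exo) + (params.gamma_p - state.gamma) / params.tau_m
    dv = (_v_inf(state.gamma, params) - state.v) / params.tau_v
    dg = (_g_inf(state.v, params) - state.g) / params.tau_g
    if "v" in clamps:
        dv = 0.0
    if "g" in clamps:
        dg = 0.0
    return np.array([dgamma, dv, dg])


def _scalar_residual(
    gamma: float, params: ModelParams, clamps: dict[str, float]
) -> float:
    """dgamma/dt with v and g eliminated through their nullclines/clamps."""
    v = clamps.get("v", _v_inf(gamma, params))
    g = clamps.get("g", _g_inf(v, params))
    j_endo = params.k_e * g / (1.0 + (gamma / params.gamma_e) ** params.h)
    j_exo = params.J_x * gamma / (params.gamma_x + gamma)
    return params.k_a * (j_endo - j_exo) + (params.gamma_p - gamma) / params.tau_m


def steady_state(
    params: ModelParams, clamps: dict[str, float] | None = None
) -> FeedbackState:
    """Fixed point of the (possibly clamped) model.

    The 3-D root problem reduces to a scalar equation in gamma because the
    v and g equations pin v = v_inf(gamma) and g = g_inf(v) at any fixed
    point (or to their clamped values). The scalar equation is bracketed
    on a dense grid over (0, 10 gamma_p] and solved by bisection/Brent.
    """
    from scipy.optimize import brentq

    clamps = clamps or {}
    lo, hi = 1e-9 * params.gamma_p, 10.0 * params.gamma_p
    grid = np.linspace(lo, hi, 4001)
    vals = np.array([_scalar_residual(x, params, clamps) for x in grid])
    sign_change = np.nonzero(np.diff(np.signbit(vals)))[0]
    if sign_change.size == 0:
        raise ModelConfigurationError(
            f"no tension fixed point found in ({lo:.3g}, {hi:.3g}) "
            f"with clamps {clamps!r}"
        )
    i = sign_change[0]
    gamma = brentq(
        _scalar_residual, grid[i], grid[i + 1], args=(params, clamps), xtol=1e-14
    )
    v = clamps.get("v", _v_inf(gamma, params))
    g = clamps.get("g", _g_inf(v, params))
    st = FeedbackState(gamma=gamma, v=v, g=g)
    res = rhs(st, params, clamps)
    if np.linalg.norm(res) >= 1e-10:
        raise ModelConfigurationError(f"fixed-point residual {res!r} too large")
    return st


def jacobian(
    state: FeedbackState, params: ModelParams, clamps: dict[str, float] | None = None
) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`rhs`; clamped rows are zeroed."""
    clamps = clamps or {}
    p = params
    gamma, v, g = state.gamma, state.v, state.g
    phi = 1.0 + (gamma / p.gamma_e) ** p.h
    dphi = p.h * gamma ** (p.h - 1.0) / p.gamma_e**p.h
    dJendo_dgamma = -p.k_e * g * dphi / phi**2
    dJendo_dg = p.k_e / phi
    dJexo_dgamma = p.J_x * p.gamma_x / (p.gamma_x + gamma) ** 2
    gvn = p.gamma_v**p.n
    dvinf = p.n * gvn * gamma ** (p.n - 1.0) / (gvn + gamma**p.n) ** 2
    km = p.K**p.m
    dginf = -p.g_max * km * p.m * v ** (p.m - 1.0) / (km + v**p.m) ** 2
    J = np.array(
        [
            [
                p.k_a * (dJendo_dgamma - dJexo_dgamma) - 1.0 / p.tau_m,
                0.0,
                p.k_a * dJendo_dg,
            ],
            [dvinf / p.tau_v, -1.0 / p.tau_v, 0.0],
            [0.0, dginf / p.tau_g, -1.0 / p.tau_g],
        ]
    )
    if "v" in clamps:
        J[1, :] = 0.0
    if "g" in clamps:
        J[2, :] = 0.0
    return J


def stability(
    params: ModelParams, clamps: dict[str, float] | None = None
) -> np.ndarray:
    """Real parts of the Jacobian eigenvalues at the fixed point.

    Clamped variables are removed from the system before the eigen-solve,
    so a doubly clamped model returns the single eigenvalue
    d(dgamma/dt)/dgamma. All real parts negative = stable set point.
    """
    clamps = clamps or {}
    st = steady_state(params, clamps)
    J = jacobian(st, params, clamps)
    free = [i for i, name in enumerate(("gamma", "v", "g")) if name not in clamps]
    sub = J[np.ix_(free, free)]
    return np.sort(np.linalg.eigvals(sub).real)


# ---------------------------------------------------------------------------
# simulation


def _rk4_step(
    x: np.ndarray,
    h: float,
    params: ModelParams,
    clamps: dict[str, float],
) -> np.ndarray:
    def f(y: np.ndarray) -> np.ndarray:
        st = FeedbackState.__new__(FeedbackState)  # skip validation in hot loop
        st.gamma, st.v, st.g = y
        return rhs(st, params, clamps)

    k1 = f(x)
    k2 = f(x + 0.5 * h * k1)
    k3 = f(x + 0.5 * h * k2)
    k4 = f(x + h * k3)
    return x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate(
    params: ModelParams,
    protocol: Protocol | None = None,
    dt: float = 0.05,
    x0: FeedbackState | None = None,
) -> ModelTrajectory:
    """Integrate the model with fixed-step RK4 under a protocol.

    Starts from the unperturbed fixed point unless ``x0`` is given.
    Events are applied left-continuously at their times (a tension_step
    multiplies gamma instantaneously; clamps freeze a variable at a value;
    ``scale`` modifies a parameter from that time on); simultaneous events
    apply in listed order. Fluxes are recorded at every step.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    protocol = protocol or Protocol(events=[], t_end=300.0)
    gamma_s = steady_state(params).gamma
    state = (x0 or steady_state(params)).as_array().astype(float)
    clamps: dict[str, float] = {}
    p = params

    times = [0.0]
    hist = [state.copy()]
    # segment boundaries: event times + t_end
    ev_times = sorted({t for t, _ in protocol.events} | {protocol.t_end})
    pending = list(protocol.events)
    t_now = 0.0
    for t_next in ev_times:
        if t_next > t_now:
            n_steps = max(1, int(round((t_next - t_now) / dt)))
            h = (t_next - t_now) / n_steps
            for _ in range(n_steps):
                state = _rk4_step(state, h, p, clamps)
                if not np.all(np.isfinite(state)):
                    raise IntegrationError(
                        f"non-finite state at t={t_now:.3f}s with clamps "
                        f"{clamps!r}"
                    )
                t_now += h
                times.append(t_now)
                hist.append(state.copy())
            t_now = t_next
        # apply all events scheduled at t_next, in listed order
        while pending and pending[0][0] <= t_next + 1e-12:
            _, action = pending.pop(0)
            if action.kind == "tension_step":
                state[0] *= action.value
            elif action.kind == "clamp_v":
                val = state[1] if action.value is None else action.value
                clamps["v"] = val
                state[1] = val
            elif action.kind == "clamp_g":
                val = state[2] if action.value is None else action.value
                clamps["g"] = val
                state[2] = val
            elif action.kind == "scale":
                p = p.replace(**{action.param: getattr(p, action.param) * action.value})
            elif action.kind == "release":
                clamps.pop(action.param, None)
            times[-1] = t_next
            hist[-1] = state.copy()

    arr = np.array(hist)
    t_arr = np.array(times)
    # fluxes along the trajectory (parameter scalings are piecewise; recompute
    # with the final params is wrong if scale events occur — track per segment)
    j_endo, j_exo = _fluxes_along(t_arr, arr, params, protocol)
    return ModelTrajectory(
        time_s=t_arr,
        gamma=arr[:, 0],
        v=arr[:, 1],
        g=arr[:, 2],
        J_endo=j_endo,
        J_exo=j_exo,
        gamma_s=gamma_s,
        params=params,
    )


def _fluxes_along(
    t: np.ndarray, arr: np.ndarray, params: ModelParams, protocol: Protocol
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fluxes, honoring piecewise parameter scalings."""
    # build the piecewise parameter timeline
    segs: list[tuple[float, ModelParams]] = [(0.0, params)]
    p = params
    for tt, action in protocol.events:
        if action.kind == "scale":
            p = p.replace(**{action.param: getattr(p, action.param) * action.value})
            segs.append((tt, p))
    j_endo = np.empty(t.size)
    j_exo = np.empty(t.size)
    for i, (t0, pi) in enumerate(segs):
        t1 = segs[i + 1][0] if i + 1 < len(segs) else np.inf
        sel = (t >= t0) & (t < t1) if np.isfinite(t1) else (t >= t0)
        gam, g = arr[sel, 0], arr[sel, 2]
        j_endo[sel] = pi.k_e * g / (1.0 + (gam / pi.gamma_e) ** pi.h)
        j_exo[sel] = pi.J_x * gam / (pi.gamma_x + gam)
    return j_endo, j_exo


# ---------------------------------------------------------------------------
# protocol presets (in-silico replicas of the experimental manipulations)

PRESET_NAMES = (
    "stretch_relax",
    "hypo_iso",
    "lg186",
    "bfa",
    "vinculin_null",
    "dyn_tko",
    "suspension",
)


def protocol_preset(
    name: str,
    magnitude: float | None = None,
    t_end: float | None = None,
) -> Protocol:
    """Build the protocol replicating a named experimental perturbation.

    - ``stretch_relax``: tension up by ``magnitude`` (areal strain held
      90 s), then a step to below the set point on relaxation (excess
      membrane: factor 1/magnitude^2);
    - ``hypo_iso``: hypotonic tension rise for 60 s, then return below set
      point on the shift back to isotonic medium;
    - ``lg186``: GBF1 inhibitor — clamp g at 0;
    - ``bfa``: Brefeldin A frees ARF1/GBF1 for the plasma membrane —
      scale g_max by ``magnitude`` (> 1);
    - ``vinculin_null``: clamp v at 0 (no mechanotransduction);
    - ``dyn_tko``: dynamin triple knockout upregulates CG capacity —
      scale k_e by ``magnitude`` (> 1);
    - ``suspension``: de-adhered cells keep vinculin frozen at its current
      (set-point) value — clamp v with no value (freeze-in-place).
    """
    defaults = _default_config()["presets"]
    if name == "stretch_relax":
        mag = magnitude if magnitude is not None else defaults["stretch_relax"]
        t_on, hold = 20.0, 90.0
        t_relax = t_on + hold
        return Protocol(
            events=[
                (t_on, tension_step(mag)),
                (t_relax, tension_step(1.0 / mag**2)),
            ],
            t_end=t_end or t_relax + 300.0,
            marks={"stretch": t_on, "relax": t_relax},
        )
    if name == "hypo_iso":
        mag = magnitude if magnitude is not None else defaults["hypo_iso"]
        t_on, hold = 20.0, 60.0
        t_iso = t_on + hold
        return Protocol(
            events=[
                (t_on, tension_step(mag)),
                (t_iso, tension_step(1.0 / mag**2)),
            ],
            t_end=t_end or t_iso + 300.0,
            marks={"hypo": t_on, "iso": t_iso},
        )
    if name == "lg186":
        return Protocol(
            events=[(0.0, clamp_g(0.0))], t_end=t_end or 300.0, marks={"drug": 0.0}
        )
    if name == "bfa":
        mag = magnitude if magnitude is not None else defaults["bfa"]
        if mag <= 1:
            raise ParameterError("bfa magnitude must be > 1 (upregulation)")
        return Protocol(
            events=[(0.0, scale("g_max", mag))], t_end=t_end or 300.0, marks={"drug": 0.0}
        )
    if name == "vinculin_null":
        return Protocol(events=[(0.0, clamp_v(0.0))], t_end=t_end or 300.0)
    if name == "dyn_tko":
        mag = magnitude if magnitude is not None else defaults["dyn_tko"]
        if mag <= 1:
            raise ParameterError("dyn_tko magnitude must be > 1 (upregulation)")
        return Protocol(events=[(0.0, scale("k_e", mag))], t_end=t_end or 300.0)
    if name == "suspension":
        return Protocol(events=[(0.0, clamp_v(None))], t_end=t_end or 300.0)
    raise ParameterError(
        f"unknown preset {name!r}; choose one of {', '.join(PRESET_NAMES)}"
    )


# ---------------------------------------------------------------------------
# read-outs


def uptake_proxy(
    traj: ModelTrajectory,
    window: tuple[float, float],
    reference: ModelTrajectory | None = None,
) -> float:
    """Fold-change endocytic uptake over a time window.

    Integrates J_endo over ``window`` and divides by the same integral for
    the reference trajectory (default: the unperturbed model, which sits at
    the fixed point, so the reference integral is J_endo(gamma_s) * width).
    This is the model analog of a timed fluid-phase dextran pulse.
    """
    t0, t1 = window
    if not (traj.time_s[0] <= t0 < t1 <= traj.time_s[-1] + 1e-9):
        raise ParameterError(f"window {window} outside trajectory span")
    num = _integrate_window(traj.time_s, traj.J_endo, t0, t1)
    if reference is None:
        st = steady_state(traj.params)
        j_ss, _ = fluxes(st, traj.params)
        den = j_ss * (t1 - t0)
    else:
        den = _integrate_window(reference.time_s, reference.J_endo, t0, t1)
    if den == 0.0:
        raise ParameterError("reference uptake integral is zero")
    return num / den


def _integrate_window(t: np.ndarray, y: np.ndarray, t0: float, t1: float) -> float:
    tt = np.clip(np.linspace(t0, t1, 2001), t[0], t[-1])
    return float(np.trapezoid(np.interp(tt, t, y), tt))


def response_gain(
    params: ModelParams,
    step_factor: float,
    clamps: dict[str, float] | None = None,
    t_end: float = 300.0,
) -> tuple[float, float]:
    """(transient_gain, steady_gain) of the endocytic flux to a tension step.

    transient_gain: signed peak relative excursion of J_endo after an
    instantaneous tension step by ``step_factor`` (negative for step-up:
    uptake suppressed). steady_gain: relative change of the steady
    endocytic flux when gamma is *held* at step_factor * gamma_s.
    """
    clamps = dict(clamps or {})
    st = steady_state(params, clamps)
    j_ss, _ = fluxes(st, params)
    proto = Protocol(events=[(0.0, tension_step(step_factor))], t_end=t_end)
    if "v" in clamps:
        proto.events.insert(0, (0.0, clamp_v(clamps["v"])))
    if "g" in clamps:
        proto.events.insert(0, (0.0, clamp_g(clamps["g"])))
    traj = simulate(params, proto, x0=st)
    if j_ss == 0.0:
        return 0.0, 0.0
    rel = (traj.J_endo - j_ss) / j_ss
    transient = float(rel[np.argmax(np.abs(rel))])
    # sustained gamma clamp: v, g relax to their nullclines at the held gamma
    gam_held = st.gamma * step_factor
    v_held = clamps.get("v", _v_inf(gam_held, params))
    g_held = clamps.get("g", _g_inf(v_held, params))
    j_held = params.k_e * g_held / (1.0 + (gam_held / params.gamma_e) ** params.h)
    steady = j_held / j_ss - 1.0
    return transient, steady


# ---------------------------------------------------------------------------
# quasi-steady-state reduction


@dataclass
class ReducedModel:
    """2-variable (gamma, g) model with vinculin slaved to v_inf(gamma)."""

    params: ModelParams

    def rhs(self, gamma: float, g: float) -> tuple[float, float]:
        p = self.params
        j_endo = p.k_e * g / (1.0 + (gamma / p.gamma_e) ** p.h)
        j_exo = p.J_x * gamma / (p.gamma_x + gamma)
        dgamma = p.k_a * (j_endo - j_exo) + (p.gamma_p - gamma) / p.tau_m
        dg = (_g_inf(_v_inf(gamma, p), p) - g) / p.tau_g
        return dgamma, dg

    def steady_state(self) -> tuple[float, float]:
        st = steady_state(self.params)  # same scalar equation
        return st.gamma, st.g

    def simulate(self, protocol: Protocol | None = None, dt: float = 0.05):
        """RK4 integration of the reduced system under tension-step events."""
        protocol = protocol or Protocol(events=[], t_end=300.0)
        for _, a in protocol.events:
            if a.kind != "tension_step":
                raise ParameterError(
                    "reduced model supports tension_step events only"
                )
        g0 = self.steady_state()
        x = np.array(g0)

        def f(y):
            return np.array(self.rhs(y[0], y[1]))

        ev_times = sorted({t for t, _ in protocol.events} | {protocol.t_end})
        pending = list(protocol.events)
        t_now = 0.0
        times, hist = [0.0], [x.copy()]
        for t_next in ev_times:
            if t_next > t_now:
                n_steps = max(1, int(round((t_next - t_now) / dt)))
                h = (t_next - t_now) / n_steps
                for _ in range(n_steps):
                    k1 = f(x)
                    k2 = f(x + 0.5 * h * k1)
                    k3 = f(x + 0.5 * h * k2)
                    k4 = f(x + h * k3)
                    x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                    t_now += h
                    times.append(t_now)
                    hist.append(x.copy())
                t_now = t_next
            while pending and pending[0][0] <= t_next + 1e-12:
                _, action = pending.pop(0)
                x[0] *= action.value
                times[-1] = t_next
                hist[-1] = x.copy()
        arr = np.array(hist)
        return np.array(times), arr[:, 0], arr[:, 1]


def qssa_reduce(params: ModelParams) -> ReducedModel:
    """Quasi-steady-state reduction: v follows v_inf(gamma) instantly.

    Valid when tau_v << tau_g (fast vinculin sensing, slow GBF1
    regulation); warns when tau_v/tau_g > 1/5. Fixed points of the
    reduced and full systems coincide exactly since v = v_inf holds at
    any fixed point of the full model.
    """
    if params.tau_v / params.tau_g > 1.0 / 5.0:
        warnings.warn(
            "QSSA dubious: tau_v/tau_g = "
            f"{params.tau_v / params.tau_g:.3g} > 1/5",
            stacklevel=2,
        )
    return ReducedModel(params=params)
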