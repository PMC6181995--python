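"""In-silico replica of the perturbation panel and validation suites.

``run_panel`` simulates every perturbation condition (GBF1 inhibition,
BFA, dynamin TKO, vinculin-null, suspension, stretch-relax) of the
feedback model, evaluates the directional checks the experiments
established, and emits a machine-readable report. ``run_recovery_suite``
re-measures every synthetic-truth recovery (trap stiffness, per-cell
uptake, punctae detection, decay rate, Mann-Whitney oracle) at fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np

from . import feedback as fb
from . import quantify as qt
from . import synthetic as syn
from . import tether as te
from .errors import ParameterError

__all__ = ["ConditionResult", "PanelResult", "run_panel", "run_recovery_suite",
           "PANEL_CONDITIONS"]

PANEL_CONDITIONS = (
    "wt",
    "lg186",
    "bfa",
    "dyn_tko",
    "vinculin_null",
    "suspension",
)

# standing modifications per condition, as protocol-event factories
_CONDITION_EVENTS = {
    "wt": lambda mag: [],
    "lg186": lambda mag: [(0.0, fb.clamp_g(0.0))],
    "bfa": lambda mag: [(0.0, fb.scale("g_max", mag or 2.0))],
    "dyn_tko": lambda mag: [(0.0, fb.scale("k_e", mag or 1.5))],
    "vinculin_null": lambda mag: [(0.0, fb.clamp_v(0.0))],
    "suspension": lambda mag: [(0.0, fb.clamp_v(None))],
}
_CONDITION_CLAMPS = {
    "wt": lambda p: {},
    "lg186": lambda p: {"g": 0.0},
    "vinculin_null": lambda p: {"v": 0.0},
    "suspension": lambda p: {"v": fb.steady_state(p).v},
}
_CONDITION_PARAMS = {
    "bfa": lambda p, mag: p.replace(g_max=p.g_max * (mag or 2.0)),
    "dyn_tko": lambda p, mag: p.replace(k_e=p.k_e * (mag or 1.5)),
}


@dataclass
class ConditionResult:
    name: str
    steady_gamma: float
    steady_J_endo: float
    uptake_fold: float  # pulse-window uptake / condition's own baseline
    transient_excursion: float  # uptake_fold - 1 (0 when flux identically 0)
    peak_time_s: float | None
    flux_abolished: bool = False


@dataclass
class PanelResult:
    conditions: dict[str, ConditionResult]
    checks: dict[str, bool]
    pulse_window_s: float
    stretch_magnitude: float

    @property
    def all_pass(self) -> bool:
        return all(self.checks.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "conditions": {k: asdict(v) for k, v in self.conditions.items()},
            "checks": self.checks,
            "pulse_window_s": self.pulse_window_s,
            "stretch_magnitude": self.stretch_magnitude,
            "all_pass": self.all_pass,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _condition_steady(
    params: fb.ModelParams, name: str, magnitude: float | None
) -> tuple[fb.FeedbackState, fb.ModelParams, dict]:
    p = _CONDITION_PARAMS.get(name, lambda p, mag: p)(params, magnitude)
    clamps = _CONDITION_CLAMPS.get(name, lambda p: {})(params)
    return fb.steady_state(p, clamps), p, clamps


def run_panel(
    params: fb.ModelParams | None = None,
    conditions: tuple[str, ...] = PANEL_CONDITIONS,
    pulse_window: float = 90.0,
    stretch_magnitude: float | None = None,
    magnitudes: dict[str, float] | None = None,
    dt: float = 0.05,
) -> PanelResult:
    """Simulate the perturbation panel and evaluate directional checks.

    For every condition: compute the steady state under the condition's
    standing modification, then overlay the stretch-relax protocol and
    integrate the endocytic flux over ``pulse_window`` seconds after
    relaxation, normalized to the condition's own unstretched flux
    (the in-silico analog of a timed dextran pulse).

    Directional checks evaluated (WT must be among the conditions):
    ordering of steady tensions, higher basal endocytic flux without
    vinculin, transient suppression by GBF1 inhibition / vinculin loss /
    suspension, and the stretch-relax transient itself.
    """
    params = params or fb.ModelParams.default()
    magnitudes = magnitudes or {}
    unknown = set(conditions) - set(PANEL_CONDITIONS)
    if unknown:
        raise ParameterError(f"unknown conditions: {sorted(unknown)}")
    if "wt" not in conditions:
        raise ParameterError("the WT reference condition is required")
    stretch = fb.protocol_preset("stretch_relax", magnitude=stretch_magnitude)
    mag = stretch_magnitude or stretch.events[0][1].value
    t_relax = stretch.marks["relax"]
    window = (t_relax, t_relax + pulse_window)

    results: dict[str, ConditionResult] = {}
    for name in conditions:
        cmag = magnitudes.get(name)
        st, p_cond, clamps = _condition_steady(params, name, cmag)
        j_ss, _ = fb.fluxes(st, p_cond)
        pre_events = _CONDITION_EVENTS[name](cmag)
        proto = fb.Protocol(
            events=pre_events + list(stretch.events),
            t_end=stretch.t_end,
            marks=dict(stretch.marks),
        )
        # start each condition at its own steady state so the pulse window
        # measures the stretch response, not equilibration into the condition
        traj = fb.simulate(params, proto, dt=dt, x0=st)
        base = fb.simulate(
            params, fb.Protocol(events=pre_events, t_end=stretch.t_end), dt=dt, x0=st
        )
        num = fb._integrate_window(traj.time_s, traj.J_endo, *window)
        den = fb._integrate_window(base.time_s, base.J_endo, *window)
        if den <= 1e-12:
            fold, excursion, abolished = 1.0, 0.0, True
            peak_t = None
        else:
            fold = num / den
            excursion = fold - 1.0
            abolished = False
            post = traj.time_s >= t_relax
            peak_t = float(
                traj.time_s[post][np.argmax(traj.J_endo[post])] - t_relax
            )
        results[name] = ConditionResult(
            name=name,
            steady_gamma=st.gamma,
            steady_J_endo=j_ss,
            uptake_fold=fold,
            transient_excursion=excursion,
            peak_time_s=peak_t,
            flux_abolished=abolished,
        )

    checks: dict[str, bool] = {}
    wt = results["wt"]
    checks["stretch_relax_transient_uptake_gt_1"] = wt.uptake_fold > 1.0
    wt_exc = wt.transient_excursion
    if "lg186" in results:
        checks["lg186_lowers_steady_tension"] = (
            results["lg186"].steady_gamma < wt.steady_gamma
        )
        checks["lg186_abolishes_transient"] = (
            abs(results["lg186"].transient_excursion) < 0.05 * abs(wt_exc)
        )
    if "bfa" in results:
        checks["bfa_raises_steady_tension"] = (
            results["bfa"].steady_gamma > wt.steady_gamma
        )
    if "dyn_tko" in results:
        checks["dyn_tko_raises_steady_tension"] = (
            results["dyn_tko"].steady_gamma > wt.steady_gamma
        )
    if "vinculin_null" in results:
        vn = results["vinculin_null"]
        checks["vinculin_null_raises_steady_tension"] = (
            vn.steady_gamma > wt.steady_gamma
        )
        checks["vinculin_null_higher_basal_uptake"] = (
            vn.steady_J_endo > wt.steady_J_endo
        )
        checks["vinculin_null_suppressed_transient"] = (
            abs(vn.transient_excursion) < 0.2 * abs(wt_exc)
        )
    if "suspension" in results:
        checks["suspension_suppressed_transient"] = (
            abs(results["suspension"].transient_excursion) < 0.2 * abs(wt_exc)
        )
    return PanelResult(
        conditions=results,
        checks=checks,
        pulse_window_s=pulse_window,
        stretch_magnitude=mag,
    )


# ---------------------------------------------------------------------------
# recovery suite


def run_recovery_suite(
    seed: int = 0,
    n_trap: int = 20,
    trap_duration_s: float = 60.0,
    trap_fs_hz: float = 20_000.0,
    n_punctae_frames: int = 20,
    n_decay: int = 20,
    n_mw_cases: int = 100,
) -> dict:
    """Parameter-recovery and oracle checks on synthetic ground truth.

    Returns a report dict with measured errors and pass/fail against the
    package's stated tolerances; failures are recorded, never raised.
    """
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed, "checks": {}}

    # 1. trap-stiffness recovery from OU bead trajectories
    k_true, zeta = 0.05, te.zeta_from_stokes(500.0, 1.0)
    errs = []
    for i in range(n_trap):
        traj = syn.gen_bead_trajectory(
            k=k_true, zeta=zeta, kBT=4.28, fs=trap_fs_hz,
            duration=trap_duration_s, seed=int(rng.integers(2**31)),
        )
        cal = te.fit_lorentzian(te.compute_psd(traj), zeta=zeta)
        errs.append(abs(cal.k_trap - k_true) / k_true)
    med_err = float(np.median(errs))
    report["trap_k_median_rel_err"] = med_err
    report["checks"]["trap_k_recovery_lt_10pct"] = med_err < 0.10

    # 2. per-cell uptake recovery
    fieldt = syn.gen_cell_field(
        n_cells=12, mean_uptake=5e4, cv=0.3, noise_sd=2.0,
        shape=(384, 384), seed=int(rng.integers(2**31)),
    )
    recs = qt.measure_uptake(fieldt.image, fieldt.labels)
    truth = dict(
        zip(fieldt.true_intensity["cell_id"], fieldt.true_intensity["true_total"])
    )
    rel = [
        abs(r.integrated_intensity - truth[r.cell_id]) / truth[r.cell_id]
        for r in recs
    ]
    report["uptake_median_rel_err"] = float(np.median(rel))
    report["checks"]["uptake_recovery_lt_5pct"] = max(rel) < 0.05

    # 3. punctae recall/precision at SNR 5
    tp = fp = fn = 0
    for _ in range(n_punctae_frames):
        stk = syn.gen_punctae_stack(
            [8], psf_sigma_px=1.5, snr=5.0, shape=(128, 128),
            seed=int(rng.integers(2**31)),
        )
        det = qt.detect_punctae(stk.frames[0], sigma_px=1.5)
        m, extra, miss = _match_spots(stk.true_coords[0], det, tol_px=3.0)
        tp += m
        fp += extra
        fn += miss
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    report["punctae_recall"] = recall
    report["punctae_precision"] = precision
    report["checks"]["punctae_recall_ge_0.9"] = recall >= 0.9
    report["checks"]["punctae_precision_ge_0.9"] = precision >= 0.9

    # 4. decay-rate recovery at 5% noise
    traces = syn.gen_decay_traces(
        I0=100.0, rate=0.02, noise_sd=5.0, n=n_decay, t_end=150.0,
        seed=int(rng.integers(2**31)),
    )
    rerr = [abs(qt.fit_decay(tr).rate - 0.02) / 0.02 for tr in traces]
    report["decay_rate_median_rel_err"] = float(np.median(rerr))
    report["checks"]["decay_rate_recovery_lt_10pct"] = float(np.median(rerr)) < 0.10

    # 5. exact Mann-Whitney vs brute-force enumeration
    mismatches = 0
    for _ in range(n_mw_cases):
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 6))
        vals = rng.integers(0, 6, size=n1 + n2).astype(float)  # ties likely
        res = qt.mann_whitney(vals[:n1], vals[n1:], method="exact")
        p_oracle = _mw_enumeration_oracle(vals[:n1], vals[n1:])
        if res.all_tied:
            ok = res.p_two_sided == 1.0
        else:
            ok = abs(res.p_two_sided - p_oracle) < 1e-12
        mismatches += 0 if ok else 1
    report["mw_exact_mismatches"] = mismatches
    report["checks"]["mw_exact_equals_enumeration"] = mismatches == 0
    return report


def _match_spots(
    truth: np.ndarray, detected: np.ndarray, tol_px: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (tp, fp, fn)."""
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    used = np.zeros(detected.shape[0], dtype=bool)
    tp = 0
    for t in truth:
        if detected.size == 0:
            break
        d = np.hypot(detected[:, 0] - t[0], detected[:, 1] - t[1])
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_px:
            used[j] = True
            tp += 1
    fp = int((~used).sum())
    fn = truth.shape[0] - tp
    return tp, fp, fn


def _mw_enumeration_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Independent brute-force two-sided Mann-Whitney p-value.

    Counts, for every way of assigning the pooled values to the two
    groups, the pairwise-comparison statistic U = #(a_i > b_j) +
    0.5 #(a_i == b_j) — a definition route independent of midranks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    n = pooled.size
    mu = n1 * (n - n1) / 2.0

    def u_pairs(x, y):
        diff = x[:, None] - y[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_pairs(a, b)
    dev = abs(u_obs - mu)
    total = extreme = 0
    for comb in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        u = u_pairs(pooled[sel], pooled[~sel])
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total
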