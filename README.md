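# cgtension

Adherent cells hold their plasma-membrane tension near a set point. One
circuit that can do this couples the CLIC/GEEC (CG) endocytic pathway — a
clathrin- and dynamin-independent route that internalizes fluid phase and
GPI-anchored proteins — to tension through two regulators: **vinculin**, a
focal-adhesion mechanotransducer that senses tension quickly (~1 s), and
**GBF1**, the ARF1 exchange factor whose plasma-membrane punctae set CG
endocytic capacity slowly (~30 s). Tension activates vinculin, vinculin
displaces GBF1 from the membrane, GBF1 drives CG endocytosis, and
endocytosis removes membrane area and raises tension — a negative-feedback
loop with *fast inhibition and slow activation*, whose stable fixed point
is the emergent tension set point γ_s.

`cgtension` packages the three computational layers needed to study this
circuit quantitatively, each exercisable end-to-end on synthetic data with
known ground truth:

1. **Feedback model** (`cgtension.feedback`) — the ODE system

   ```
   dγ/dt = k_a (J_endo − J_exo) + (γ_p − γ)/τ_m
   dv/dt = (v∞(γ) − v)/τ_v,   v∞(γ) = γⁿ/(γ_vⁿ + γⁿ)
   dg/dt = (g∞(v) − g)/τ_g,   g∞(v) = g_max·Kᵐ/(Kᵐ + vᵐ)

   J_endo = k_e g / (1 + (γ/γ_e)ʰ),   J_exo = J_x γ/(γ_x + γ)
   ```

   with fixed-point/stability analysis, a quasi-steady-state reduction,
   and protocol presets for every classical perturbation (stretch–relax,
   hypo→iso shift, GBF1 inhibition, BFA, dynamin TKO, vinculin-null,
   suspension).

2. **Tether mechanics** (`cgtension.tether`) — optical-trap calibration by
   the power-spectrum method (Lorentzian fit `S(f) = D/(f_c² + f²)`,
   `k = 2π ζ f_c`, Stokes drag `ζ = 6π η r`) and the tether-force/tension
   relation `T = F₀²/(8π²B)` with its inverse. "Apparent" tension is kept
   in the naming: in cells the number conflates in-plane tension with
   membrane–cytoskeleton adhesion.

3. **Uptake quantification** (`cgtension.quantify`) — per-cell integrated
   uptake over label masks, fold-change normalization to the control mean,
   box summaries (median, quartiles, s.d. whiskers), an exact/approximate
   Mann–Whitney U test, difference-of-Gaussians punctae detection with
   first-frame normalization, exponential reservoir-decay fitting, and
   26-connected 3-D object counting.

`cgtension.synthetic` generates every input with recorded truth (an
exactly discretized Ornstein–Uhlenbeck bead in a harmonic trap, cell
fields with log-normal per-cell uptake, TIRF-like punctae frames,
exponential decay traces), and `cgtension.panel` orchestrates the
in-silico perturbation panel and the truth-recovery suites.

## Worked example

```bash
python examples/trap_calibration.py
```

```
Stokes drag zeta = 9.425e-06 pN s/nm
corner frequency fc = 862 Hz  (true: 845 Hz)
trap stiffness k   = 0.0511 pN/nm  (true: 0.0500)
tether force F0    = 20.4 pN
apparent tension T = 0.0652 pN/nm (B = 81 pN nm)
```

A simulated 60 s, 20 kHz recording of a 500 nm bead is calibrated to ~2%
of the true stiffness; a 400 nm tether displacement then maps to a 20 pN
tether force and, with a conventional bending stiffness B = 81 pN·nm, an
apparent tension of 0.065 pN/nm.

```bash
python examples/feedback_simulation.py
```

```
set point gamma_s       = 1.0207
eigenvalue real parts   = [-1.0033 -0.0256 -0.0256]
uptake fold during stretch      = 0.888  (< 1: suppressed)
uptake fold 0-90 s after relax  = 1.174  (> 1: transient burst)
uptake fold 90-180 s after relax= 0.994  (~1: reset complete)
vinculin-null uptake fold       = 1.006  (no mechano-response)
```

The set point is stable (all eigenvalue real parts negative). A 1.3×
stretch suppresses endocytic uptake; releasing it triggers a transient
uptake burst that is over within ~90 s, and the burst disappears when
vinculin is clamped — mechanotransduction, not membrane mechanics alone,
couples tension to the CG pathway. `examples/perturbation_panel.py` prints
the full condition table: steady tension orders as
γ(GBF1-inhibited) < γ(WT) < γ(dynamin-TKO), γ(BFA), γ(vinculin-null).

Other examples: `uptake_quantification.py` (per-cell uptake, fold changes,
Mann–Whitney) and `punctae_and_decay.py` (punctae series, decay fit, 3-D
objects). A thin CLI mirrors the library
(`cgtension generate|calibrate|tether|simulate|quantify|panel|recover`).

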