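# Methods

## The feedback model

The model is a deterministic three-variable ODE for membrane tension γ
(dimensionless, passive baseline γ_p = 1), active membrane-bound vinculin
fraction v ∈ [0, 1], and activated membrane-bound GBF1 g ≥ 0:

```
dγ/dt = k_a (J_endo − J_exo) + (γ_p − γ)/τ_m
dv/dt = (v∞(γ) − v)/τ_v        v∞(γ) = γⁿ/(γ_vⁿ + γⁿ)
dg/dt = (g∞(v) − g)/τ_g        g∞(v) = g_max Kᵐ/(Kᵐ + vᵐ)

J_endo = k_e g / (1 + (γ/γ_e)ʰ)        J_exo = J_x γ/(γ_x + γ)
```

Assumptions, and what each term encodes:

- **Tension balance.** Endocytosis removes membrane area and raises
  tension; exocytosis adds area and lowers it. `k_a` converts net flux to
  tension rate. The passive term `(γ_p − γ)/τ_m` stands for slow buffering
  by membrane reservoirs and vacuole-like dilations; it also guarantees a
  bounded fixed point when the fluxes cannot balance (e.g. with GBF1
  clamped to zero).
- **Fast sensing, slow regulation.** Vinculin activation follows tension
  with τ_v = 1 s; the GBF1 membrane pool relaxes with τ_g = 30 s. The
  constructor warns when τ_v/τ_g > 1/20. This ordering is what produces
  the transient: a sudden tension drop de-activates vinculin within
  seconds, GBF1 then accumulates over tens of seconds, and the endocytic
  flux overshoots before tension returns to the set point.
- **Monotone Hill forms.** Only the signs and saturations of the
  interactions are constrained by the biology (γ→v activating, v→g
  inhibitory, g→J_endo activating); Hill terms are the minimal smooth
  realization. The loop sign is (+)(−)(+)(+) = negative for all positive
  parameters. These functional forms, and the tension-dependent
  saturating exocytosis, are this package's own modeling choices.
- **Deterministic only.** Flux noise and spatial membrane mechanics are
  out of scope.

The set point γ_s is *emergent*: the root of the scalar equation obtained
by eliminating v and g through their nullclines, bracketed on a dense grid
over (0, 10 γ_p] and polished by Brent's method (residual < 1e-10).
Stability comes from the analytic 3×3 Jacobian (validated against central
finite differences at 1e-6 in the tests); clamped variables are removed
from the system before the eigen-solve.

### Default parameters

Shipped in `src/cgtension/data/default_params.yaml` (not hard-coded):
γ_p = 1, τ_m = 100 s, k_a = 0.05, k_e = 1, γ_e = 20, h = 2, J_x = 0.9,
γ_x = 1, τ_v = 1 s, γ_v = 1, n = 4, τ_g = 30 s, g_max = 1, K = 0.5, m = 4.

The defaults were calibrated once, against the qualitative property suite,
not against any measured data: a unique stable set point near γ = 1; a
stretch–relax uptake transient that is clearly present in WT (pulse fold
≈ 1.17) and decays on the ~90 s scale; set-point restoration within 2%
for instantaneous tension steps between 0.5× and 2×; and the steady-state
ordering γ(GBF1-inhibited) < γ(WT) < γ(dyn-TKO), γ(BFA), γ(vinculin-null).
The calibration deliberately keeps the *direct* tension-inhibition of
endocytosis weak (γ_e = 20, so the term is nearly flat over the operating
range): if that passive arm is steep, a vinculin-null model — which sits
at a higher set point where the Hill term has more leverage — responds to
tension steps more strongly than WT, inverting the defining experimental
contrast (vinculin-null cells do not mount the uptake transient). With a
weak passive arm the response routes through the vinculin→GBF1 arm, the
vinculin-null excursion falls to ~3% of WT, and a small residual passive
responsiveness remains, as observed. The coupling k_a = 0.05 sets the
recovery timescale (dominant eigenvalues ≈ −0.026 s⁻¹, i.e. ~40 s), slow
enough for GBF1 to engage and fast enough that the transient is over
within the 90 s pulse window. These numbers are model units; mapping γ to
pN/nm is left to the user, since no absolute tension values constrain it.

### Protocols and read-outs

Events apply left-continuously at their times; simultaneous events apply
in listed order. `tension_step(f)` multiplies γ instantaneously (an areal
strain step); clamps freeze a variable; `scale` rescales a parameter from
that time on. The stretch–relax preset applies `tension_step(m)` (default
m = 1.3), holds 90 s, then `tension_step(1/m²)` so tension lands below the
set point even after partial homeostatic recovery during the hold —
mimicking the excess membrane handed back to the cell on relaxation. The
hypo→iso preset is the same shape with a 60 s hold.

`uptake_proxy` integrates J_endo over a window and divides by the same
integral for a reference trajectory — the model analog of a timed
fluid-phase dextran pulse. The default reference is the unperturbed
fixed-point flux; the perturbation panel normalizes each condition to its
*own* unstretched baseline, so the transient is measured relative to the
condition's basal uptake (as the experimental box plots are). When a
condition's flux is identically zero (GBF1 clamped at 0) the fold is
reported as 1 with an `flux_abolished` flag instead of dividing 0/0.

Integration is fixed-step RK4 (default dt = 0.05 s), segment-aligned to
event times; step-halving in the tests confirms ~4th-order convergence.
The QSSA reduction slaves v to v∞(γ) and keeps (γ, g); its fixed points
coincide with the full model's exactly, and at τ_v/τ_g = 1/1000 the γ
trajectories agree to <0.5% sup-norm (~0.02% measured).

## Trap calibration and tether mechanics

The bead generator draws from the exact discretization of the
Ornstein–Uhlenbeck process, `x[n+1] = x[n]·e^(−Δt/τ) +
σ√(1−e^(−2Δt/τ))·η[n]` with τ = ζ/k and σ² = kBT/k, so its spectrum is
exactly the sampled Lorentzian the calibration assumes. Bead defaults
(r = 500 nm, η = 1 mPa·s, kBT = 4.28 pN·nm i.e. 37 °C, k = 0.05 pN/nm)
are conventional tweezer values, all overridable.

The PSD is a block-averaged one-sided periodogram (default 32
non-overlapping boxcar blocks, per-block mean removed, DC bin excluded);
Parseval (integral ≈ variance within 5%) is asserted in the tests. The
Lorentzian is fitted by least squares on log S(f) — block-averaged
periodogram noise is multiplicative, so log-domain residuals are
approximately homoscedastic. The default fit band runs from 10 Hz to 3×
a moment-based corner guess (fc ≈ 2·power/(π·plateau), exact for a
Lorentzian): extending the band closer to Nyquist inflates the recovered
corner because aliasing (not corrected here) lifts the high-frequency
tail; at 3 fc the residual bias is ~2.5%, well inside the 10% recovery
tolerance. Hydrodynamic corrections are likewise omitted. A fitted corner
within 5% of either band edge raises `FitQualityError` with diagnostics —
the symptom of a band that excludes the true corner.

Tension conversion uses `T = F₀²/(8π²B)` and its inverse
`F₀ = 2π√(2BT)`. B is always a user input (default 81 pN·nm ≈ 19 kBT, a
conventional plasma-membrane bending stiffness) and is reported alongside
any tension output. Outputs are named *apparent* membrane tension because
a tether pull on a cell conflates in-plane tension with
membrane–cytoskeleton adhesion.

## Synthetic images and quantification

The cell-field generator paints non-overlapping ellipses; per-cell totals
are log-normal (uptake per cell is positive and right-skewed) with the
requested mean and CV, spread over intra-cell puncta plus a diffuse
component and renormalized so each cell's pixel sum equals its drawn truth
exactly before noise. Camera noise is additive Gaussian on a constant
background offset (shot noise is out of scope). The punctae generator
places isotropic Gaussian spots with pairwise separation ≥ 4σ and sets the
noise s.d. to amplitude/SNR. What these do *not* emulate — segmentation
ambiguity, uneven illumination, bleaching, overlapping cells, clustered
spots — bounds what passing recoveries show about real microscopy: they
validate the measurement operators, not a segmentation pipeline.

Quantification conventions:

- background = median of unlabeled pixels, subtracted per pixel before
  summing over each label (masks are supplied explicitly; an Otsu +
  connected-components helper exists but is marked non-canonical, since
  the reference workflow outlines cells by hand);
- percentiles by linear interpolation between order statistics; s.d. with
  n−1; both stated because box values shift at small n under other
  conventions;
- Mann–Whitney U from midranks; exact two-sided p by the subset-sum
  recursion (no ties) or full enumeration of group assignments (with
  ties, n₁+n₂ ≤ 14), otherwise a normal approximation with tie and
  continuity corrections; all-tied input returns p = 1 with a flag.
  Significance thresholds are never hard-coded into logic;
- spot detection: difference of Gaussians at (σ, 3σ), local maxima above
  `min_prominence` × robust noise (1.4826·MAD of the band-passed image),
  minimum peak distance 2σ, plateau ties to the lowest (row, col);
  coordinates are 0-based (row, col). Chosen as the simplest auditable
  standard operator;
- decay fitting: nonlinear least squares of `I₀e^(−rate·t) + offset`;
  rate ≈ 0 flags an infinite half-time; a residual-resampling bootstrap
  CI helper quantifies rate uncertainty;
- 3-D objects: 26-connectivity, components below `min_voxels` discarded.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 20 bead trajectories of
60 s at 20 kHz for trap recovery (median |Δk|/k ≈ 2.5%); 12-cell fields of
384×384 px at noise σ = 2 (uptake errors ≪ 5%); 20 punctae frames of 8
spots at SNR 5 (recall/precision ≈ 1.0/0.98); 20 decay traces at 5% noise
(median rate error ≈ 4%); 100 random Mann–Whitney partitions with
n₁+n₂ ≤ 10 against the brute-force enumeration oracle (0 mismatches);
panel simulations at dt = 0.05 s and QSSA comparison at dt = 0.01 s.
These sizes keep every stage's sampling error an order of magnitude inside
its tolerance.

## Known limitations

- The feedback model is a minimal realization: parameter values are
  calibrated to qualitative directions and timescales, not fitted to
  measurements; absolute γ has no physical unit attached.
- Exocytosis is modeled as tension-dependent and saturating; whether the
  biological exocytic arm is itself tension-regulated is not settled, and
  only the net balance matters for the qualitative behavior reproduced
  here.
- Trap calibration omits aliasing and hydrodynamic corrections (bias
  ~2.5% at the default band, inside tolerance); active-calibration and
  equipartition variants are not provided.
- Quantitative agreement with published punctae counts or reservoir decay
  rates is not claimable — the original counting operators are not
  specified — so only directions and synthetic-truth recovery are
  asserted.
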