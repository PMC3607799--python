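# Methods

## Models

**Conductance-based burster.** The single neuron is a Morris–Lecar type-I
fast subsystem (membrane potential `V`, K⁺ gate `w`) with two slow
variables on the scale `ε = 5·10⁻⁴`: calcium `Ca`, which gates an
outward K⁺ current through `z = Ca/(Ca + Ca₀)`, and a slow inward gate
`n` feeding the Ca²⁺ current. Fixed constants (mV, mS-like conductance
units, `c = 20`): `V_K = −84`, `V_Ca = 120`, `g_K = 8`, `g_l = 2`,
`g_Ca = 4`, `g_KCa = g_sCa = 1`, `v₂ = 18`, `v₃ = 12`, `v₄ = 17.4`,
`v₅ = 12`, `v₆ = 24`, `φ = 1/15`, `τ_n = 0.05`, `μ = 0.025`, `Ca₀ = 1`.

Two parameter variants are exposed. The default `ml_canonical` uses
`v₁ = −1.2`, `V_l = −60` and `τ_w(V) = 1/cosh((V − v₃)/(2 v₄))` — the
canonical type-I Morris–Lecar values, under which the resting potential
sits below −40 mV and the drive ladder is: steady state destabilizes into
multi-spike firing at `I = 60`, clean parabolic bursting near `I = 68`
(three 39-spike bursts per 15000 time units), tonic spiking from
`I = 70`. The `paper_literal` variant keeps the alternative printed signs
(`v₁ = +1.2`, `V_l = +60`) and a sigmoidal `τ_w`; with a +60 mV leak
reversal it cannot reach the sub-(−40 mV) resting regime, so it exists
for audit only.

**Generative phase burster.** `θ̇ = I − cos θ − cos(θ/n)` on the extended
circle `[−nπ, nπ)`. The slow term is read as `cos(θ/n)`: only this
reading makes the threshold `I_c = max[cos θ + cos(θ/n)] = 2` independent
of `n` (both cosines peak together at θ = 0) and yields exactly `n`
spikes — passages of the maxima of `V = −cos θ`, i.e. odd multiples of π
— per full cycle. `I_c` is exactly 2; a drive of 2.01 is the canonical
"just above threshold" operating point, not the threshold itself.

**Synapse and mean field.** Gate kinetics `ṡ = a(V)(1 − s) − s/β`,
`a(V) = 1/(1 + e^{−V/2})`. The printed decay term is read as `−s/β` so
that the quasi-static formula `s* = β/(1 + β + e^{−V/2})` is the exact
equilibrium of the gate ODE and `β` is a decay time. The phase-model
field evaluates the same transfer at `cos θ_l` with the exponent
`e^{−cos θ_l/2}` (the `gamma_sign="voltage"` switch selects the
`V = −cos θ` substitution `e^{+cos θ_l/2}` instead; it is a monotone
reparameterization and empirically less stable for the synchronous
orbit). Self-exclusion (`l ≠ i`) is honored by total-sum-minus-own-term;
a toggle enables the `O(1/N)` full-sum simplification.

## Calibration choices

**Synaptic time constant.** The transfer `β/(1+β+e^{∓cosθ/2})` caps the
phase-model mean field at `K β/(1+β)`. With `β = 0.1` that is ≈ 0.09 K —
measured against the flow this is too weak to lock even nearly identical
bursters (the two-neuron Floquet exponent of the synchronous orbit is
≈ −7·10⁻⁴ per time unit, smaller than the frequency spread at
`ΔI = 0.001`), and no synchronized cell appears anywhere in the unit
sweep square. The phase network therefore defaults to `β = 1.5` — the
AMPA decay time the synapse model is built around — which reproduces the
reference regimes: SR at `(K, ΔI) = (0.8, 0.001)` for both `n = 1` and
`n = 5`, IN at `(0.01, 0.1)`, PO with a seed-dependent silent fraction
strictly inside `(0, 1)` at `(0.8, 0.5, N = 10)`, and PO at `(0.6, 0.3)`.
The synapse module itself defaults to `β = 0.1`, the center of the range
in which the quasi-static reduction is quantitatively valid (below).

**Coupling sign (voltage network).** Two forms of the synaptic current
are implemented: `as_printed` adds `+K S (V − v_th)` to the membrane
equation; `conductance` uses the standard excitatory conductance form
`−K S (V − v_th)`, which drives `V` toward the reversal `v_th = 0`. Only
the conductance form synchronizes the burster network at the reference
point `(K, ΔI) = (0.7, 0.001)` (χ ≈ 0.69 vs ≈ 0.45), so it is the
default; the choice is recorded in every trajectory's metadata. The
voltage network keeps `β = 0.1`: with the conductance form that
synchronizes robustly, and `β = 1.5` there does not.

**Drive rescaling.** Voltage-network drives are `b·Iᵢ` with `b = 32.4`,
mapping the drive center 2.1 onto ≈ 68, the bursting current.

## Order parameters and classification

On the post-transient window: `R` = mean squared fluctuation of
`V_mean(t)`; `R_θ(t) = ⟨cos θᵢ⟩` (bounded by 1); rotation numbers
`ρᵢ = Δθᵢ/Δt` on unwrapped phases (phase nets) or `2π·spikes/window`
(voltage nets, 0 mV upward crossings, 2-time-unit refractory); and the
normalized coherence `χ = std_t(V_mean) / ⟨std_t(Vᵢ)⟩ᵢ`, which is 1 for
identical oscillators, `O(1/√N)` for independent ones, and 0 by
convention for an all-flat population.

Classifier (thresholds frozen, never tuned per run): silent fraction
(`|ρ| < 0.01` rad/time) `= 1` → PO with QD (quiescent/oscillator-death)
sublabel; `≥ 0.05` → PO; else `χ ≥ 0.5` → SR; else IN. In-phase and
anti-phase clustered synchrony both land in SR.

**Sweep.** One simulation per `(K, ΔI)` cell, with a per-cell seed
derived from `(master seed, i, j)` via `SeedSequence`, so the table is
reproducible under any execution order and trivially parallelizable. The
desk-scale grid is 11×11: `K ∈ {0.01, 0.1, …, 1.0}`,
`ΔI ∈ {0.001, 0.1, …, 1.0}` with `N = 200`, `n = 5`, 2000 time units
analysed after a 500-unit transient. The smallest dispersion column sits
at 0.001 — the dispersion of the reference synchronized runs — because
under the printed mean-field normalization the SR region is confined to
near-zero dispersion (χ ≥ 0.5 requires `ΔI ≲ 0.002`); a grid starting at
0.01 would contain no SR cell. The full-resolution preset is the
100-point axis 0.01…1.00. The resulting diagram has the expected
topology: SR at strong coupling and near-zero dispersion, IN at weak
coupling and small dispersion, PO (silenced subpopulations) elsewhere.

## Stability layer

All analytics use the drift `v₀(θ) = F(θ) − Γ sin θ (cos θ − v_th)` —
verbatim the per-neuron vector field (for `v_th = 0`,
`sin θ cos θ = sin 2θ / 2`, so Γ here absorbs the factor-2 convention of
a `sin 2θ` notation). Fixed points are found by dense sampling (4096
intervals) plus Brent bisection; stability is the sign of the exact
derivative `F′(θ) − Γ(cos 2θ − v_th cos θ)`. The continuum stationary
density in the rotating case is `f₀ = L/v₀` with `L = 1/∮ dθ/v₀`
(adaptive quadrature split at the bottleneck θ = 0), normalized over the
extended circle, so `2πn·L` is the predicted rotation number; in the
pinned case the stable fixed point is returned as a point mass. The
critical lines are `|K| = εm (ΔI − ΔI_c)` (PO/IN, saddle-node; defaults
`εm = 1`, `ΔI_c = 0.1`, `p = 1` are calibration hooks refittable to a
sweep table by least squares) and `|K| = a₀ΔI + a₁ΔI² + a₂ΔI³` (IN/SR,
Hopf; `a₀ = 8/π`, `a₁ = 0`, `a₂ = 128/π³`). The numerically detected
IN→SR coupling (bisection on χ) increases with ΔI inside the coherent
sliver, consistent with the Hopf line's sign; its absolute scale is not
comparable, since the empirical coefficients describe a far wider SR
region than the printed mean-field normalization produces.

## Numerical choices

- Fixed-step integration, default `dt = 0.05`; Heun (two-stage
  trapezoidal predictor–corrector, i.e. second-order Runge–Kutta) by
  default, forward Euler selectable. There is no noise in either model,
  so no stochastic integrator exists.
- Transients are specified in model time units (default 200; 5000 for
  the slow voltage network, 500 for phase networks) and marked on the
  trajectory rather than discarded.
- Gating variables are clipped to [0, 1] and `Ca` to `≥ 0` after each
  step; the clip is inactive on resolved trajectories.
- The synaptic gate ODE is stiff for very fast synapses: explicit
  integration needs `dt < 2β`. The `β = 0.01` validity check therefore
  runs at `dt = 0.005`; at `dt = 0.05` that gate is a clipped numerical
  oscillation, not dynamics.
- Spike detection: upward threshold crossings (0 mV) with a 2-unit
  refractory window; burst grouping splits a train wherever an ISI
  exceeds 3× the median ISI. Phase-model spikes are the crossings of odd
  multiples of π, counted through the running maximum of the crossed
  threshold index so a non-monotone wiggle never double-counts, with
  crossing times interpolated linearly inside a step.
- Global-cycle phase uses strict local minima of `V_mean` with a
  prominence floor of 1% of the series range to suppress integration
  ripple, and linear 0→π→2π interpolation across each minimum–maximum–
  minimum cycle.
- Per-cell sweep seeds come from `SeedSequence((master, i, j))`, kept
  below 2³¹.

## Quasi-static validity

On a tonically spiking trace at drive 80, the sup-norm gap between the
integrated gate and `s*(V)` is ≈ 10⁻⁴ at `β = 0.01`, ≈ 0.008 at
`β = 0.1`, ≈ 0.099 at `β = 0.5` and ≈ 0.54 at `β = 5`. The `β = 0.5`
excess is carried entirely by the spike upstrokes (≈ 3% of samples),
where any finite-β gate lags the instantaneous map; the population-mean
field `S` — the quantity the coupling actually uses — averages those
lags out and stays within 0.05 of its adiabatic value at `β = 0.5`
(sup ≈ 0.009 on a 50-neuron population) while breaking down at `β = 5`
(sup ≈ 0.18). So the adiabatic reduction is quantitatively safe for the
mean field up to `β ≈ 0.5` and qualitatively wrong by `β = 5`.

## What the synthetic conditions do and do not show

All inputs are parameter records; drive heterogeneity is the only
randomness (uniform, seeded), plus random initial states. The simulated
conditions reproduce the studied mechanism — SNIC bursting, mean-field
locking, heterogeneity-induced incoherence, mean-field-induced oscillator
death — under all-to-all instantaneous coupling with identical synapses.
They do not emulate sparse or delayed connectivity, synaptic noise,
inhibition, or parameter heterogeneity beyond the drive, so passing tests
say nothing about those regimes.

## Known limitations

- The SR region of the phase diagram is much thinner in ΔI than the
  empirical Hopf coefficients suggest; see the calibration section. The
  mean-field normalization, not the bifurcation structure, sets this
  scale.
- The time-dependent continuum continuity equation is not integrated;
  only its stationary solutions are computed.
- `scan_firing_onset` defines onset operationally (≥ 3 post-transient
  spikes in the analysis window); pathological windows shorter than one
  burst period will misreport.
- The `v_th ≠ 0` sign convention of the phase-model coupling response is
  untestable within the studied conditions (all runs use `v_th = 0`).
- The inhibitory continuum reduction and neural-mass comparisons are out
  of scope.
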