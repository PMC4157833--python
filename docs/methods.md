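# Methods

## Model

The cell is a one-dimensional Kelvin–Voigt rod spanning the scaled
interval x ∈ [−1/2, +1/2] (lengths in units of the spread cell length),
coupled to an elastic substrate through a continuum density ρ(x, t) of
breakable bond springs. Contractility is imposed as a pre-stretch: the
relaxed rod is stretched by a displacement field u₀(x) (the default
builder is linear and antisymmetric, u₀ = 2εx, with edge magnitude ε)
and then attached to the substrate. Writing u(x, t) for the displacement
away from the stretched, just-attached state, the scaled force balance
is

```
η ∂t(∂²u/∂x²) + ∂²u/∂x² − β ρ(x,t) u = −u₀″(x),
(u₀ + u)′ + η (∂t u)′ = 0   at x = ±1/2   (stress-free ends),
u(x, 0) = static equilibrium solution.
```

Three dimensionless parameters control the dynamics:

| parameter | meaning | default |
|---|---|---|
| β (`stiffness_ratio`) | effective substrate-to-cell stiffness, k_bond·ρ₀·L²/(E_c·h·b); swept 0.1–100 | 10 |
| γ (`breakage_rate`) | first-order bond-severing rate in units of the reference time | 1 |
| η (`viscosity`) | internal relaxation time η_c/E_c in reference-time units | 0.1 |

plus the Bell coupling α (`force_coupling`), which multiplies the scaled
per-bond force in the breakage law. The per-bond spring constant is the
elastic half-space result for a force spread over the bond-contact
circle, k_bond = C·a·E_s with C = π/(1−ν²) and ν = 0.5 by default; any
other convention for C only rescales the swept β. The reference time
entering the non-dimensionalization is an explicit argument (default
1 s), which keeps γ and η independent parameters and the mapping to
physical units invertible.

The default η = 0.1 (relaxation ten times faster than breakage at γ = 1)
puts the baseline in the sigmoidal regime, which is the shape the
trypsin experiments show; η·γ ≳ 1 would instead produce the
single-exponential curves seen only at very high breakage rates. The
default pre-stretch edge magnitude ε = 0.01 keeps the linear
(small-strain) description self-consistent and, combined with Bell
couplings of order 100–5000, spans per-bond Bell exponents from ~1
(mild acceleration) to far beyond the clamp (instant rupture), the
range over which the stiffness ordering of de-adhesion reverses.

Bond kinetics are irreversible first-order decay, ∂ρ/∂t = −γρ, or the
Bell form ∂ρ/∂t = −γ·exp(α|f|)·ρ with per-bond force f = β·u (the
traction per unit length divided by the local density). With α = 0 the
model is linear in u₀, so normalized de-adhesion curves are exactly
independent of the contractility magnitude; any α > 0 breaks that
degeneracy and, for large α, reverses the stiffness ordering because
stiffer substrates load each bond harder (f ~ s·√(β/ρ) at the cell edge).

## Numerics

Space is discretized with second-order central differences on a uniform
grid (default 1001 nodes), the stress-free ends with ghost nodes. Each
time step (default dt = 10⁻³) is operator-split: (1) the bond field
decays by an exact frozen-force exponential — sub-stepped, capped at 25
sub-steps, whenever the largest per-node log-decay would exceed 0.2 —
then (2) the viscoelastic operator is advanced by one backward-Euler
tridiagonal solve (unconditionally stable). The Bell exponent is clamped
at 50 with a warning; such bonds are effectively instantly broken. Once
the bond term underflows relative to the discrete second-derivative
scale the operator is pure-Neumann, and the rigid-translation nullspace
is removed by pinning the centre node (stationary for symmetric cells);
the static solver uses the same convention for β·ρ → 0. Runs terminate
when the normalized length reaches 0.999 (or at t_end, recorded in the
result). At the defaults, halving dt and doubling the grid moves the
half-saturation time by well under 0.5%.

The edge-adhesion (Dirac) limit keeps the displacement profile exactly
linear, reducing the PDE to 2η·da/dt = −s − (2 + βN(t))·a with
N(t) = N₀e^(−γt); it is integrated with an adaptive stiff solver at
rtol 10⁻¹⁰ and bounds every distributed-bond run from the right.

## Timescales

For model curves τ₁ is the interpolated first crossing of 0.5 and τ₂ is
the 0.5→0.9 crossing interval divided by ln 9, so an exact Boltzmann
sigmoid returns its own width parameter and the threshold and fitted
definitions agree to ~10% wherever the model output is near-sigmoidal
(high β; at low β the curve is exponential-like and the two width
notions genuinely differ). Experimental traces are normalized as
(v(0) − v(t))/(v(0) − v∞) with v∞ the median of the final 10% of
samples, then fitted with the rising logistic 1/(1 + exp((τ₁ − t)/τ₂))
with asymptotes pinned at 0 and 1 (free amplitude/offset available
behind a flag for raw traces). Fits use trust-region least squares;
failures are reported through a `converged` flag, never raised.

## Analytic estimates

For uniform bonds the static solution gives the end-to-end contraction
factor g(k) = 2·tanh(k/2)/k with k² = βρ. When breakage is slow
compared with relaxation (γη ≪ 1, "quasistatic") the cell tracks its
equilibrium while k(t) = k₀e^(−γt/2) shrinks, so threshold crossings
solve g(k*) = g(k₀) + q(1 − g(k₀)); the root is bracketed and solved by
Brent's method, and for k₀ ≥ 8 the large-k asymptote yields the explicit
form τ₁ ≈ (2/γ)·ln(k₀/4) — a dependence on the logarithm of stiffness,
which is why even a 26-fold substrate-stiffness step changes τ₁ only by
an O(1) fraction. In the opposite fast-breakage regime (γη ≫ 1) bonds
vanish before the rod moves and the curve is the free Kelvin–Voigt
exponential: τ₁ = η·ln 2 and τ₂ = η·ln 5/ln 9, independent of stiffness.
The two mechanisms act in series, so the estimates combine additively
with the quasistatic term attenuated by exp(−(γη)²), making the
composite smooth across the switch; the relaxation term doubles as the
viscous lag correction inside the quasistatic regime. `validity` is
True for γη ≤ 0.1 or γη ≥ 3; on a 3×5 grid spanning the quasistatic
regime the estimates agree with the solver within 9% (15% is asserted,
leaving safety margin), and between the regimes they are only
indicative and flagged invalid.

## Synthetic assay

The generator emulates the trypsin de-adhesion experiments: three gel
conditions (1.5/2.5/40 kPa) whose ground-truth Boltzmann constants are
the published per-condition values (τ₁ = 80/30/30 s, τ₂ = 30/15/8 s),
15 cells per condition, 1 s frames over 300 s, additive Gaussian noise
(σ = 0.02) on the normalized signal, and raw areas A₀·(1 − r·signal)
with per-cell A₀ ∈ [500, 2500] µm² and retraction fraction
r ∈ [0.6, 0.9]. Per-cell constants are lognormal with mean equal to the
condition value and total cv 0.25; 78% of the log-variance sits in a
shared per-cell "speed" factor (a more contractile cell is faster in
both constants), which keeps the per-cell τ₁/τ₂ ratio away from 1 where
a trace stops being sigmoidal (the rare ratio < 1.4 draws are redrawn).
Draws are antithetic within a condition, so the 15-cell condition means
are centred on the ground truth (residual dispersion ~2%) and the
round trip measures the fidelity of the fitting stage rather than the
sampling luck of one cohort; each cell's marginal variability keeps the
designed cv. Everything is bit-reproducible from (design, seed) via a
counter-based generator.

Because the printed constants are themselves outputs of the
normalize-and-fit analysis, the default construction is fit-consistent:
each trace is the logistic in slightly adjusted constants, found by a
damped fixed-point inversion of the deterministic normalize+fit map, so
the pipeline recovers the drawn ground truth exactly in the noise-free
limit. (The literal logistic in the drawn constants, available with
`fit_consistent=False`, carries a deterministic round-trip bias of up
to ~15% when τ₁/τ₂ is small, because re-normalizing by the nonzero
t = 0 value of a wide logistic distorts it.) The quadratic length→area
map used to turn model trajectories into area curves is an isotropic
retraction assumption, not a claim about real cell geometry.

What passing the round trip shows: the normalization and fitting stages
recover condition-level constants through realistic noise and per-cell
variability. What it does not show: anything about segmentation or
tracking errors, non-sigmoidal retraction, photobleaching-like drifts,
or cells that detach or divide mid-assay — none of which the generator
emulates.

## Known limitations

The model is 1-D and linear: no rebinding, no active stress generation,
no translation/rotation modes, and the substrate enters only through a
local spring constant. The distribution-insensitivity check documents a
sup-norm threshold of 0.15 between uniform and end-concentrated bond
layouts at matched totals; the curves are close but not identical, the
residual difference growing with β. In the saturated force-dependent
regime (α ≥ ~10³ at the default ε) the stiffer conditions all collapse
onto free relaxation, so ordering assertions there admit ties within 1%.
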