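# Methods

This note records the models implemented in `fluctuodyn`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would want to know.

## Pair correlations and the structure factor

`compute_rdf` histograms minimum-image pair distances of the heavy atoms
(species label "H" excluded by default — hydrogens contribute negligibly
to the X-ray cross-section) on bins of width 0.02 Å out to
r_max = min(box)/2, normalized by ideal-gas shell counts at the density of
the filtered set. The 0.02 Å default resolves the first O-O peak without
amplifying counting noise. All heavy atoms are treated as one
indistinguishable set: no per-element form-factor weighting is applied,
which is a dilute-limit approximation appropriate for solutions of a few
mol% organic solute; it is a documented choice, not a claim about how any
particular experiment normalized its data.

`rdf_to_structure_factor` evaluates

    S(q) = 1 + 4πρ̄ ∫₀^{r_max} w(r) r [g(r) − 1] sin(qr)/q dr

by trapezoidal quadrature on the bin centers. The window

    w(r) = 1 − 3(r/r_max)²                   r < r_max/3
         = (3/2)(1 − 2r/r_max + (r/r_max)²)  r_max/3 ≤ r ≤ r_max
         = 0                                 r > r_max

is continuous (value 2/3 at the branch join) and suppresses truncation
ripples from the finite integration range. q = 0 is deliberately not
evaluated here; S(0) comes from the SAXS decomposition's extrapolation,
which is how the low-q limit is obtained in practice.

The transform is linear in g(r) − 1, and a homogeneous (Poisson)
configuration yields S ≡ 1; both are enforced by tests.

## SAXS decomposition

The total small-angle structure factor is modelled as

    S(q) = S_PY(q; R, η) + S_A(0)/(1 + ξ²q²).

S_PY is the Wertheim/Thiele closed-form Percus-Yevick hard-sphere
structure factor, implemented at equation level (S = 1/(1 − ρc(q)) with
the analytic direct-correlation function). The three bracket functions of
x = 2qR cancel catastrophically at small x — the third is an O(x⁶) residue
of O(1) terms — so below x = 0.2 they are replaced by their Taylor series
through x⁶, accurate there to ~1e-12 relative while the closed form has
recovered full precision; a smoothness test spans the switchover. The
q → 0 limit equals the compressibility-route value (1−η)⁴/(1+2η)².

`fit_saxs` is weighted nonlinear least squares over (η, S_A(0), ξ), with
the hard-sphere radius fixed at R = 1.78 Å by default (temperature
independent) and the window (0.15, 0.7) Å⁻¹. Bounds: η ∈ [0, 0.74),
S_A(0) ∈ [0, 5], ξ ∈ [0, 100] Å. ξ is multi-started at {1, 3, 10} Å
because the objective has a flat valley along ξ when S_A(0) → 0. The
non-negativity constraint on S_A(0) is a package choice. After the free
fit, a constrained fit with S_A(0) pinned to zero is run; if it matches
the free fit (chi-square within 0.1%), ξ is unidentifiable and the
decomposition is flagged `anomalous_component_absent`. Parameter standard
errors come from the fit covariance; `extrapolate_S0` propagates them
through S(0) = S_A(0) + S_PY(0; R, η) neglecting the (η, S_A(0))
covariance. The noiseless synthetic generator and the fit model are the
same function, so noiseless round trips are exact.

## Response functions and power laws

Two κ_T routes, both stored in SI (Pa⁻¹, displayed as 10⁻⁶ bar⁻¹):

* κ_T = S(0)/(n k_B T), with n = ρ N_A / M̄ the molecular number density
  from the mass density and the mole-fraction-weighted mean molar mass;
* κ_T = ⟨δV²⟩/(k_B ⟨V⟩⟨T⟩) from an NPT volume series, using the
  population (1/N) variance to match ensemble-average semantics.

On matched synthetic inputs the two agree within the χ² sampling error of
the variance (~√(2/n) relative).

`fit_powerlaw` fits value(T) = A ε^{-exponent}, ε = (T − T_s)/T_s, by full
nonlinear least squares in linear space — log-log fitting is not linear
here because T_s is free — with T_s bounded below min(T) and multi-started
at min(T) − {5, 15, 30} K, since the objective is multimodal in T_s.
Constant series are flagged degenerate (T_s unidentifiable) instead of
being forced through the optimizer. R² is 1 − SS_res/SS_tot over the
included points only.

`exclusion_scan` refits while dropping the 0…k lowest-temperature points
and flags a deviation when R² improves by more than a margin
(default 0.02). This is the diagnostic for a bend away from the power law
at the cold end — the behavior expected when a response function
approaches its maximum (Widom-line crossing) rather than diverging.
`exponent_ratio` reports ν/γ with propagated uncertainty at full
precision (0.6/1.2 = 0.5 for Ising exponents).

## WAXS observables

The first diffraction peak is fitted with a Gaussian plus constant
baseline (initialization: center at the window argmax with ties broken
toward lower q, width a quarter of the window, baseline at the window
minimum); the center's standard error is reported, and a window without a
peak — the fitted center leaving the window — is a fit failure, not a
silent extrapolation. dq₁/dT uses a smoothing spline with the parameter
chosen by generalized cross-validation (overridable); the derivative is
scanned on a dense grid and a flat derivative (linear q₁(T)) is flagged
non-unique. The isosbestic point is the q minimizing the
across-temperature variance of S(q) after linear interpolation onto the
overlap section of the first curve's grid; identical curves are flagged
non-unique.

## Local structure index

For oxygen i, neighbor distances are sorted under the minimum image (ties
broken by particle index for determinism); n_i counts neighbors inside
the 3.7 Å O-O cutoff, and the gap list Δ_j = r_{j+1} − r_j for j = 1…n_i
includes the gap spanning the cutoff, i.e. the first neighbor beyond
3.7 Å participates — the convention of the LSI literature, switchable in
`lsi_from_distances` by supplying the shell directly. LSI_i is the
variance of the gaps. Molecules with no neighbor inside the cutoff, or
whose first outside neighbor would exceed half the box (minimum image
ambiguous), are excluded and reported. HDL-like means LSI ≤ 0.114 Å²
(boundary inclusive), LDL-like above. The population crossing is the root
of the smoothing-spline LDL fraction minus 1/2, the root nearest the
median temperature being chosen (with a warning) if several exist.

No energy minimization is performed: the module evaluates supplied
coordinates as-is. Quenched (inherent-structure) configurations give
sharply bimodal LSI distributions; thermal configurations give broader
ones, so threshold-based populations from thermal frames are less crisp.
Population summaries pool all supplied molecules/frames.

## Synthetic generators

All generators take an explicit seed and draw from an independent
`numpy.random.default_rng`; fixed seed ⇒ byte-identical output. Noise is
additive Gaussian on curves and multiplicative relative Gaussian on
power-law series.

* *Ideal gas*: uniform positions — the g ≡ 1, S ≡ 1 reference.
* *Hard spheres*: random sequential insertion followed by 30 Metropolis
  displacement sweeps (step half a radius, moves rejected on overlap),
  relaxing toward the equilibrium hard-sphere fluid so the small-q limit
  is PY-like; insertion is pre-checked to η ≤ 0.45 and fails loudly past
  its attempt budget.
* *Water-like*: a geometric stand-in for the two local environments, not
  a water model. The LDL-like population sits on a diamond-cubic oxygen
  lattice (nearest neighbor 2.75 Å, second shell 4.49 Å — the wide gap
  that makes LSI large) with user-set Gaussian jitter; the HDL-like
  population is a denser disordered slab (face-centered sites, nearest
  neighbor 3.0 Å, built-in 0.25 Å disorder combined in quadrature with
  the user jitter) whose quasi-continuous neighbor distances through the
  interstitial region keep LSI small. The two slabs share one box split
  along x; molecules at the slab interfaces inherit mixed environments,
  which is why endpoint guarantees (≥90% correct classification) are
  stated for interior molecules and the mixed-fraction dial tracks the
  request to within a few percent. It reproduces the interstitial-shell
  mechanism the LSI detects and nothing else — no hydrogen bonding, no
  dynamics, no thermal-equilibrium pair correlations.
* *SAXS curves*: evaluated by the same model function the fitter uses.
* *Power-law series*: the amplitude is the prefactor (the value at ε = 1,
  T = 2T_s), the documented convention.
* *Volume series*: i.i.d. Gaussian volumes with variance κ k_B T ⟨V⟩;
  the i.i.d. choice means sampling error follows χ² exactly, unlike
  correlated MD series where the effective sample count is smaller.

Because the generators are geometric/statistical stand-ins, passing tests
demonstrate that the estimators and fitters are correct and
well-conditioned at realistic noise levels — not that any particular
force field or instrument would reproduce the published observables.

## Droplet cooling

Lumped Knudsen evaporation of a binary droplet in vacuum:
J = α p_vap(T) a_w √(M_w/(2πRT)) with α = 1 by default and Raoult water
activity a_w = 1 − χ_g; glycerol is non-volatile, so χ_g rises as water
leaves. dm_w/dt = −4πr²J and dT/dt = −J L 4πr²/(m c_p), integrated by
fixed-step classical RK4 (default 1 μs). Correlations: Murphy-Koop (2005)
vapor pressure and molar vaporization enthalpy for supercooled liquid
water (enforced validity window 150–320 K); liquid-water heat capacity as
an empirical fit rising toward deep supercooling (≈75 J mol⁻¹K⁻¹ at
273 K, ≈103 at 228 K); glycerol c_p 2430 J kg⁻¹K⁻¹ with mass-weighted
mixing; densities 1000/1261 kg m⁻³ with ideal volume mixing. Radiative
exchange and residual-gas conduction are neglected (Pa-level chamber
pressures). With these choices an 18.7 μm droplet at 3.2 mol% glycerol
cools from 293 K to ≈236 K in 2 ms — tens of kelvin on millisecond
flight times, the regime reported for evaporatively cooled microdroplet
experiments. The model targets this qualitative regime; absolute endpoint
temperatures depend on the exact thermophysical parameterization and are
not a validated output.

## Problem sizes and numerical conventions

Configurational tests use N ≈ 200–1000 particles and 8–20 frames, enough
to pin S(q→0) of hard spheres at η = 0.2 to well inside 15% of the PY
closed form while keeping the full suite under half a minute. The
synthetic recovery experiments use 100 seeds at 1% relative noise on an
8-point 232–295 K grid. Lengths are Å, wavevectors Å⁻¹, temperatures K
everywhere; positions are wrapped into the primary cell on construction;
particle indexing is 0-based; κ_T is SI internally with a display
conversion to 10⁻⁶ bar⁻¹.

## Known limitations

* No per-element form factors or electron-unit normalization of I(q); the
  pipeline starts from S(q) or configurations.
* The PY identification of the normal liquid is literal: no
  polydispersity, no alternative closures.
* The LSI module does not minimize energy; feeding thermal frames blurs
  the bimodality.
* The cooling model is lumped and ignores internal gradients, freezing
  kinetics and droplet-train aerodynamics.
* GRO output is quantized to the format's 3 decimals in nm (0.01 Å);
  XYZ round trips are exact to 1e-6 Å.
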