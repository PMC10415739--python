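# Methods

## The reaction model

The displacement reaction is reduced to a single bimolecular step,
I + R →(k) F, with

    d[I]/dt = d[R]/dt = −k[I][R],    d[F]/dt = +k[I][R].

[I] is the *total* invader concentration (free plus pool-bound); all pool
effects are folded into an effective rate constant k_eff = f·k₀ with
f ∈ (0, 1].  This is the standard coarse-graining for toehold-mediated
displacement with a short (5 nt) toehold, where toehold binding is fast and
reversible and branch migration is not resolved.  The closed-form solution

    [F](t) = A₀B₀ (e^x − 1)/(A₀e^x − B₀),    x = k(A₀−B₀)t

(equal-concentration branch [F] = A₀²kt/(1+A₀kt)) is implemented alongside a
numerical integrator; the integrator solves only d[F]/dt (with [I], [R]
recovered by conservation, which therefore holds to machine precision) with
LSODA at rtol 1e-13 / atol 1e-22 M, and the two routes are cross-checked to
better than 1e-8 relative in the tests.  Trace synthesis uses the closed
form (vectorized over droplets and frames); the slope-parabola model curve
uses the ODE integrator.

Fluorescence is linear in product: f = background + 200·[F]/200 nM (n.u.),
i.e. complete conversion of a 200 nM reporter reads 200 normalized units,
and a non-zero background models imperfect quenching of the intact reporter
(default 10 n.u., our choice; the measured background is an instrument
property with no published value).

Reference rate constants are k = 3.2×10⁴ M⁻¹s⁻¹ for the clean system and
2.7×10⁴ M⁻¹s⁻¹ with a 10× N25 pool.  We use their ratio 2.7/3.2 = 0.84375 as
the population-mean rate factor in pool simulations rather than the looser
"≈20% slowdown" rounding of the same measurement.

## Pool thermodynamics

The interaction of the invader with pool strand n is summarized by
ΔΔG_n = ΔG_AB − (ΔG_A + ΔG_B).  The default backend scores ΔG_AB as the best
ungapped antiparallel alignment under the unified nearest-neighbor stack
table (ΔG°37, 16 dinucleotide stacks shipped as a plain-text resource) plus
a constant duplex-initiation penalty of 1.96 kcal/mol, with ΔG_A = ΔG_B = 0
(isolated strands treated as unstructured) and ΔΔG clamped at ≤ 0.  One
initiation penalty is charged per alignment, and alignments with no stacked
(≥2 consecutive) base pairs score zero.  This reproduces the qualitative
shape of the ΔΔG spectrum of a random pool — a unimodal bulk with a long
strong-binding tail (skewness < 0) — with no external dependencies.  An
`external` backend slot accepts a user-supplied function returning all three
free energies for users with a full partition-function engine.

Boltzmann weights p(n) = exp(−ΔΔG_n/k_BT)/Q are evaluated at T = 302.15 K
(the experiments' 29 °C; k_BT as R·T ≈ 0.6005 kcal/mol), with the stack
table's 37 °C free energies used as constants — we do not resolve the
enthalpy/entropy split, so the temperature enters only through the Boltzmann
and equilibrium-constant exponents.  The two-state bound fraction θ for
A + R_j ⇌ C_j uses K_eq = exp(−ΔΔG/RT) M⁻¹ (1 M standard state) and the
exact mass-balance quadratic, evaluated in the cancellation-free form
C = 2AR/(b + √(b²−4AR)), b = A + R + 1/K; a root-bracketing solver on the
same mass balance serves as an independent oracle in the tests.  The
sequestration summary μ averages θ over the M = round(0.1·N) lowest-ΔΔG
strands (round half-up, stable tie-break by strand id).

Because our stack-table energies are shallower than a full
secondary-structure model, absolute μ values are smaller than a
partition-function calculation would give; μ is therefore treated as
model-relative, and pool rate factors are anchored by calibration (below),
not by absolute μ.

### Effective rate factor

Each droplet's sampled pool (per-sequence Poisson counts) is collapsed onto
a single effective ligand with total concentration R_tot = Σc_j and binding
constant K̄ = Σc_jK_j/R_tot; the droplet's invader bound fraction μ_droplet
follows from the same quadratic, and f = clip(1 − μ_droplet, 0.01, 1).  The
concentration-weighted collapse agrees with the linearized competitive
equilibrium (Σ K_jc_j ≪ per-species saturation) while remaining exact in the
single-ligand limit.  The floor 0.01 prevents zero-rate droplets in
pathological samples.  Since no quantitative k_eff(pool composition) mapping
has been measured, a `calibration` option rescales the population so its
*mean* f matches a measured rate-constant ratio (0.84375 by default usage),
leaving the droplet-to-droplet spread — the quantity of interest — untouched.
The rescale solves for a single multiplicative factor by bisection so the
clipped mean matches exactly.

## Droplet generation

Radii are truncated-normal (resampling at ≤ 0) with configurable mean
(default 15 µm, inside the experimental 10–30 µm range) and CV (default 3%,
inside the reported 1.3–5.9%); a plain normal is the standard model for
monodisperse emulsions, and only a CV was reported.  Mixing ratios follow
ξ_i = 0.5 + 0.5·a·sin(2πt_i/period + phase) at constant droplet production
rate (`droplet_interval`, default 10 ms — the pressure-oscillation periods
are known, 0.1–5 s, but droplet rates are not, so the interval is our
abstraction, as is the amplitude→ξ-range mapping).  An optional Gaussian
`xi_jitter_sd` models production noise in fixed-ratio runs.  In-droplet
concentrations obey [A] = ξ[A]_stock, [B] = (1−ξ)[B]_stock exactly.

Pool partitioning draws each distinct sequence independently Poisson with
mean ξ·(pool_stock/pool_size)·N_A·V — the low-occupancy limit of the
multinomial.  The real pool spans ~10¹⁵ sequences; the surrogate uses a
configurable finite pool (default 10⁴ distinct sequences, ~600 copies each
in a 10 µm droplet), which preserves the undersampling mechanism (droplets
differ in how many copies of the few strongest binders they receive) at desk
scale.  Variability tests that probe the mechanism use 10 µm droplets, where
undersampling is strongest within the experimental size range.

All stochastic operations draw from named substreams (`pool`, `radii`, `xi`,
`partition`, `noise`, `artifacts`) fanned out from one base seed, so e.g.
changing the noise model never changes the sampled radii.

## Synthetic traces and what they do (not) emulate

Per droplet, the red (reporter) channel is the exact kinetic model converted
to n.u.; the green (reference) channel is constant and proportional to ξ
(the reference dye is supplied with the invader solution; 200 n.u. at
ξ = 1).  Noise: one multiplicative per-frame factor shared by both channels
(illumination/focus fluctuation, default SD 2%) plus independent additive
read noise (default SD 1 n.u.).  Acquisition defaults: 2 s frames from
t = 4 s (droplets stop within a few seconds of flow halt), 300 frames.

Injected artifacts carry ground-truth labels: negative-slope traces (red
mirrored about its first frame), intensity jumps (a multiplicative step of
`jump_magnitude` at a random frame in the middle 60% of the acquisition),
and an out-of-focus proxy (both channels attenuated to 30% with extra
noise — a static stand-in; image formation is out of scope).  Ground truth
is written to a sidecar CSV that analysis functions never read.

The generator does **not** emulate: droplet motion and tracking failures,
spatial image formation, Ostwald ripening, photobleaching, or diffusive
mixing transients inside fresh droplets.  Passing tests therefore
demonstrate the correctness and statistical behaviour of the *analysis
chain* under the stated noise model, not robustness to every failure mode of
real microscopy data.

## Analysis choices

* **QC order**: negative slope → low reference signal → intensity jump; the
  jump metric is max |Δred| divided by max(local intensity, 25% of the trace
  maximum), so additive noise near the dim start of a trace does not trip
  the 25% threshold ("significant jump" was never quantified; 25% is our
  default).  The low-signal threshold defaults to half the population median
  of mean green.  QC is deterministic.
* **Normalization paths**: fixed-stoichiometry runs divide red by green per
  frame (rescaled by the trace's mean green to stay in n.u.); mixing sweeps
  analyse raw red, since droplets at low ξ legitimately carry ≈ 0 reference
  dye — synthetic droplets are motionless, so the raw path is exact there.
* **Slopes**: two-point estimator s = (f₂−f₁)/(t₂−t₁) on the frames nearest
  t₁, t₂ (default (10, 50) s; (10, 90) s for sweeps), or least-squares
  regression over the window as a robustness option; slopes are then
  mean-normalized.
* **Dispersion**: CV = sample SD (n−1)/mean and IQR (linear-interpolation
  percentiles) on normalized slopes; MAD = mean |s−⟨s⟩| on raw slopes (the
  two scales differ by the mean slope magnitude, which is why MAD values are
  ~10⁻⁴ when CVs are ~0.2).
* **Central peak**: nonlinear least-squares Gaussian on a 30-bin histogram of
  normalized slopes below 1.5 (the outlier cut; both configurable), avoiding
  any distributional likelihood assumption beyond the fit itself.
* **Concentration map**: per-droplet invader concentration from mean green
  intensity, anchored by the mean of the 10 lowest (→ 0) and 10 highest
  (→ stock) intensities, linear in between, clipped to [0, stock].
* **Rate fits**: least squares of the closed form (k on a log scale,
  background fitted unless supplied), requiring ≥ 25% conversion of the
  limiting reagent for identifiability.
* **Parabola overlay**: model finite-window slopes by ODE integration on a ξ
  grid (step 0.01); the single fitted quantity is a multiplicative scale
  (n.u. per molar), obtained in closed form.  On a 0.05 grid the model peaks
  at ξ = 0.5; on the fine grid the unequal stocks shift the finite-window
  (not the v₀-level) optimum by ~0.01 toward the side with more limiting
  reagent — a real property of finite-window slopes, not a bug.
* **Error budget**: Δv₀/v₀ ≈ Δk/k + Δ[A]₀/[A]₀ + Δ[B]₀/[B]₀ is a first-order
  *linear* budget: exact for common-mode variation, an upper bound when the
  three sources vary independently (where quadrature applies); the tests
  check both regimes.
* **Plateau criterion**: "time to a stable end value" is operationalized as
  99.7% conversion of the limiting reagent, which lands at ≈ 44 min
  (≈ 45 min to the nearest 5) for the clean system — the threshold is our
  choice; no explicit criterion was published.

## Problem sizes

Default test and acceptance workloads are desk-scale by design: 10⁴-strand
surrogate pools, 200–2000-droplet ensembles, 300-frame traces, 2700 s fit
horizons.  These sizes put every Monte-Carlo tolerance (e.g. CV recovered to
±0.01 at n = 2000, sampling error σ/√(2n) ≈ 0.004) comfortably inside the
asserted bands while keeping the full suite under a minute.

## Known limitations

* The nearest-neighbor backend ignores intramolecular structure, interior
  loops/bulges and salt corrections; absolute ΔΔG and μ values are
  model-relative (the invader/reporter sequences of the original experiments
  were never published in machine-readable form, so sequence-exact
  reproduction is impossible anyway).
* The effective-rate-factor mapping f = 1 − μ_droplet is a hypothesis-level
  model; only its calibrated mean is anchored to measurement.
* The bimolecular reduction has no toehold-length dependence and no
  temperature dependence of k.
* Artifact injection produces idealized, cleanly-labelled failure modes;
  real QC rejection rates will differ.
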