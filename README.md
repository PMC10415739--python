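# tmsdrop

Simulation and analysis of **toehold-mediated strand displacement (TMSD)
kinetics in water-in-oil emulsion droplets**, with an optional
random-sequence oligonucleotide pool that transiently sequesters the invader
strand.

TMSD is the workhorse reaction of dynamic DNA nanotechnology: an invader
strand binds a short single-stranded toehold on a fluorophore-labelled
reporter duplex and displaces the quencher-labelled incumbent, so reaction
progress reads out as rising fluorescence.  When thousands of copies of this
reaction are compartmentalized into picolitre droplets — each droplet mixing
an invader stock (≈500 nM, optionally pre-equilibrated with a 10-fold excess
of random 25-mers) and a reporter stock (≈400 nM) at a volume ratio ξ — the
observed per-droplet kinetics scatter around the bulk behaviour.  This
package exists to ask, at desk scale, *where that scatter comes from*: droplet
geometry, mixing-ratio fluctuations, or undersampling of the random pool.

## What it models

* **Pool thermodynamics** (`tmsdrop.pool_thermo`) — hybridization free-energy
  differences ΔΔG = ΔG_AB − (ΔG_A + ΔG_B) between the invader and each pool
  member (unified nearest-neighbor stack model, or an external backend),
  Boltzmann binding probabilities p(n) = exp(−ΔΔG_n/k_BT)/Q, two-state bound
  fractions θ from the exact mass-balance quadratic, and the sequestration
  statistic μ = M⁻¹ Σ θ(C_j) over the top decile of binders.  Per-droplet
  sampled pool compositions map to effective rate factors, k_eff = f·k₀.
* **Compartments** (`tmsdrop.compartments`) — droplet radii (truncated
  normal, CV up to ~6%), volumes V = (4π/3)r³, copy numbers
  N = N_A·c·V, mixing ratios from sinusoidal pressure programs
  ([A] = ξ[A]_stock, [B] = (1−ξ)[B]_stock), and Poisson partitioning of pool
  molecules into droplets.
* **Kinetics** (`tmsdrop.kinetics`) — the bimolecular reduction
  I + R →(k) F with d[I]/dt = d[R]/dt = −k[I][R]; numerical ODE integration,
  the analytic closed form, initial velocities v₀ = k[A]₀[B]₀, finite-window
  slopes, the stoichiometry parabola v = kξ(1−ξ)[A]_s[B]_s, and conversion to
  normalized fluorescence (200 n.u. ≡ 200 nM unquenched reporter).
  Reference rate constants: 3.2×10⁴ M⁻¹s⁻¹ (clean), 2.7×10⁴ M⁻¹s⁻¹ (pool).
* **Synthetic traces** (`tmsdrop.synthetic_traces`) — two-channel per-droplet
  trace tables (green reference dye ∝ ξ, red reporter), shared multiplicative
  plus independent additive noise, and labelled QC artifacts (negative
  slopes, intensity jumps, out-of-focus droplets).
* **Analysis** (`tmsdrop.analysis`) — QC filtering, reference normalization,
  two-point/regression slope estimation over a (10, 50) s or (10, 90) s
  window, mean-normalization, CV/IQR/MAD and central-peak Gaussian
  statistics, per-droplet invader-concentration estimation from reference
  intensity anchors, rate-constant fitting, the first-order error budget
  Δv₀/v₀ ≈ Δk/k + Δ[A]₀/[A]₀ + Δ[B]₀/[B]₀, and the scaled parabola overlay.

## Worked example

```python
import tmsdrop as td
from tmsdrop.pool_thermo import generate_random_pool, pool_ddGs

# surrogate pool energetics against a fixed 25-mer invader
invader = td.DNAStrand("invader", "GTCAGTTGAGGATCCACGTATGCTT")
pool = generate_random_pool(n=10_000, length=25, seed=3)
ddgs = pool_ddGs(invader, pool)
print(f"ddG range: {ddgs.min():.1f} to {ddgs.max():.1f} kcal/mol")

base = dict(n_droplets=400, radius_mean=10.0, radius_cv=0.03,
            xi_jitter_sd=0.01)
em_clean = td.generate_emulsion(td.EmulsionConfig(**base), seed=1)
em_pool = td.generate_emulsion(
    td.EmulsionConfig(**base, pool_stock=5e-6, pool_size=10_000),
    pool=ddgs, seed=1, calibration=td.K_POOL / td.K_CLEAN)

acq = td.AcquisitionConfig()
noise = td.NoiseModel(additive_sd=1.0, multiplicative_sd=0.02)
window = td.SlopeWindow(10.0, 50.0)
for label, em in [("clean", em_clean), ("pool", em_pool)]:
    traces = td.simulate_trace_set(em, td.RateParameters(td.K_CLEAN),
                                   acq, noise, seed=1)
    kept = td.qc_filter(traces)
    slopes = td.estimate_slopes(traces, window, normalize="ref")
    stats = td.variability_stats(slopes)
    times, mean_red = td.mean_trace(traces)
    fit = td.fit_rate_constant(times, mean_red, 250e-9, 200e-9, 200e-9)
    print(f"{label:5s}  kept {kept.n_kept}/{len(traces)}  "
          f"CV={stats.cv:.3f}  IQR={stats.iqr:.3f}  "
          f"k_hat={fit.k_hat:.3g} /M/s")
```

prints

```
ddG range: -12.9 to -0.8 kcal/mol
clean  kept 400/400  CV=0.035  IQR=0.048  k_hat=3.2e+04 /M/s
pool   kept 400/400  CV=0.040  IQR=0.057  k_hat=2.7e+04 /M/s
```

Both ensembles were generated with identical droplet geometry, mixing jitter
and measurement noise; the pool ensemble's larger slope CV/IQR is driven
entirely by droplet-to-droplet variation in the effective rate factor, i.e.
by each droplet sampling a different subset of the strongest pool binders,
and the mean kinetics fit recovers the calibrated pool rate constant.

A CLI mirrors the pipeline for shell use:

```
tmsdrop pool-thermo --invader invader.fasta --n 10000 --out pool.csv
tmsdrop simulate --config config.json --seed 1 --out run
tmsdrop analyze --traces run_traces.csv --out report.json
tmsdrop map-stoichiometry --traces sweep_traces.csv --out map.csv
```

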