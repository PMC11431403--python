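# Methods

## Model and assumptions

The simulator treats electron transfer between a donor and an acceptor
orbital as a mixed quantum–classical problem: the electronic amplitudes
`φ_D, φ_A` evolve unitarily under the 2×2 Hamiltonian

```
[[E_D − k_z u_z,  ε_x + k_x u_x],
 [ε_x + k_x u_x,  E_A + k_z u_z]]
```

while the two mode coordinates follow classical Newton/Langevin equations
driven by the electronic mean-field forces (an Ehrenfest-type closure).
Working units are ħ = 1 (time in 1/ħ, energies in ħ) with unit oscillator
masses, so mode momenta equal velocities. The two baths are assumed
independent — the antisymmetric bath couples only to `u_z`, the symmetric
bath only to `u_x` — which is the natural split for a nearly symmetric
donor–acceptor pair.

Two textual ambiguities in the Hamiltonian's usual presentation are
resolved the only way consistent with normalisation and with the equations
of motion: the acceptor on-site term is `E_A|φ_A|²`, and the ionic force
term is the modulus form `|φ_A|² − |φ_D|²` (the gradient of the coupling
term in H). Likewise the transfer term of the reduced potential carries
the amplitude `√(ρ(1−ρ))`, which is required for `F(ρ)` to be the
phase-minimised expectation value of the anti-adiabatic Hamiltonian; the
phase minimiser is `Δ = 0` for `ε_x < 0` and `Δ = π` for `ε_x > 0`.

The linear transfer integral `ε_x + k_x u_x` is an expansion of an
exponentially distance-dependent overlap; it is physically meaningful only
while it keeps its sign. The integrator counts sign changes and warns (or,
with `strict_transfer_sign`, raises). Runs in the TET neighbourhood with
`|ε_x|` tiny flip sign freely — there the warning indicates that the bare
integral is essentially zero, not that the run is invalid.

## Integration and noise

The propagator is the Dormand–Prince RK 5(4) pair at a **fixed** step
(default `dt = 0.001`). Adaptive control is deliberately disabled: the
Langevin forces are drawn once per macro-step with variance `2γ·kBT/dt`
(one ordered pair `(η_z, η_x)` per step, frozen across the internal
stages), and changing the step would change the noise variance. The
embedded 4th-order solution is kept only as an accuracy diagnostic
(`max_embedded_error` in the trajectory metadata). How white noise should
interact with the internal stages of a high-order scheme is not uniquely
defined; the frozen-force convention is the simplest one consistent with
the stated per-step variance, and the fluctuation–dissipation test (a
decoupled damped mode equilibrating to `½Ω²⟨u²⟩ = kBT/2`) validates it to
a few percent.

At `kBT = 0` no random numbers are drawn, so noiseless runs are exactly
deterministic; for `kBT > 0` each run's generator is seeded explicitly
(`numpy` PCG64), making ensembles bitwise reproducible. Electronic-norm
drift is monitored every step; exceeding `norm_tol` (default 1e−6) is a
hard error rather than a silent renormalisation, because renormalising
would mask integrator failure (a `renormalize` option exists for very long
noisy runs). In practice the drift over 2×10⁵ steps is ~1e−13.

The compiled kernel is cross-checked in the test suite against an
independent adaptive integration (scipy DOP853 at rtol 1e−12) of the
Python-level equations of motion; they agree to ~1e−11 over a horizon of
20 time units.

## Presets

All presets use `Ω_z = Ω_x = 1` and `γ_z = γ_x = 0.1` — the damping sits in
the crossover between underdamped (long-lived donor–acceptor oscillation)
and overdamped (friction-limited) transfer, where TET is fastest. The
exact damping used for the regime phenomenology is a repository choice;
the qualitative regime structure is insensitive to it.

| preset | E_D | E_A | k_z | k_x | ε_x | character |
|---|---|---|---|---|---|---|
| `tet` | 0 | 0 | 1 | 1 | 0 | exact degeneracy; flat F; cylindrical conical intersection |
| `near_tet` | 0.5 | 0 | 1 | 1 | −0.001 | TET kinetics: downhill groove, irreversible at T = 0 |
| `marcus_normal` | 0.5 | 0 | 2 | 0.1 | −0.02 | double-well F, crossing between the diabatic minima |
| `marcus_inverted` | 3 | 0 | 1 | 0.1 | −0.02 | driving force exceeds the reorganisation energy |
| `away` | 0.5 | 0 | 2.5 | 0.5 | −0.1 | ionic/covalent ratio 25; barrier ≈ 3; Arrhenius kinetics near kBT ≈ 1 |

Two preset-design points deserve note. First, the donor-localised
equilibrium state is an *exact stationary point* of the deterministic flow
whenever `ε_x = 0` (the transfer coupling vanishes at `u_x = 0`), so the
pure `tet` preset shows no zero-temperature dynamics at all; irreversible
zero-temperature TET requires a small positive reaction energy and a seed
transfer integral, which is what `near_tet` provides and why it is the
preset used for kinetic contrasts. Second, the `away` preset keeps the
25× imbalance in `k²/Ω²` but at couplings (`k_z = 2.5`) chosen so that its
activation barrier (≈ 3 energy units) places the Arrhenius window at
kBT ≈ 0.8–2, the temperature range where thermally assisted transfer is
observable at practical horizons; a much larger `k_z` pushes the barrier
to ~12 and freezes transfer entirely below kBT ≈ 3.

## Regime classification

`classify_regime` tests, in order: the exact TET residuals (tolerance
1e−9); the near-TET windows (|E_A−E_D| ≤ 1, |k_z²/Ω_z² − k_x²/Ω_x²| ≤
0.05, |ε_x| ≤ 0.05 — matching the parameter region the kinetics
experiments use); a coarse "away" cut at ionic/covalent imbalance ≥ 5;
then the Marcus construction. The Marcus discrimination is done on the
diabatic parabolas `V_D/A(u_z) = ½Ω_z²u_z² + E_{D/A} ∓ k_z u_z` restricted
to `u_x = 0`: the landscape is barrier-forming when the ionic coupling
dominates (concave quadratic part of F), and the regime is *normal* when
the parabola crossing lies between the two minima (driving force below the
reorganisation energy `2k_z²/Ω_z²`) and *inverted* otherwise. A strict
"two sampled minima of F" test was rejected: because the `√(ρ(1−ρ))`
transfer term creates unresolvable boundary layers and because the
double-well condition is strictly stronger than the normal-regime
condition, it can never label an inverted case. Covalent-dominated
landscapes (convex F — a single hybridised well, no reaction in the
chemical sense) fall to "away".

## Transfer kinetics

Per trajectory the package reports `p_max = max_t P_A(t)`, the transfer
time `τ` (earliest time attaining `p_max`, ties to the earliest sample) and
the first-passage time `t_first` across a completion threshold (default
P_A = 0.9). Sweep statistics use the population standard deviation, and
transfer-time averages include only completed runs (`p_max` above the
threshold) so blocked trajectories cannot contribute spurious finite rates.

The Arrhenius rate surrogate is `k = 1/⟨t_first⟩` by default. The
`1/⟨τ⟩` alternative is provided but is not rate-sensitive in long noisy
runs: after a completed transfer the occupation keeps fluctuating near 1,
so the time of the *global* maximum is spread roughly uniformly over the
post-transfer window and `⟨τ⟩` saturates at about half the horizon at
every temperature. First passage is the standard activated-kinetics
estimator and recovers a clean Arrhenius line (r² ≈ 0.95 with 4
temperatures × 30 runs on the `away` preset).

## Problem sizes and numerical choices

Default horizons: 200 time units for generic runs; 300 for thermal
ensembles of the symmetric dimer (its equilibration time at kBT = 1.5 is
~20); 500 for zero-temperature kinetic contrasts (the TET-regime transfer
completes at τ ≈ 400); 1000 for the Arrhenius sweep (so that first
passages at the coldest usable temperature, kBT = 0.8, are only mildly
censored). Ensembles use 50 runs for equilibrium averages and 30 per
temperature for rate fits. Trajectories are sampled every `stride` steps
(auto-chosen to keep ≈ 2000 samples); the step count is trimmed to a
multiple of the stride so sampled times stay uniform.

PES grids default to 201 points per axis on [−3, 3], which brackets the
stationary points `±k_z/Ω_z²` of every preset. TET degeneracy checks use
a 1001-point ρ grid (flatness holds to < 1e−12 by exact term
cancellation). The conical-point gap is zero to machine precision rather
than exactly zero because `(E_D−E_A)/2 − k_z·u_z*` involves one rounding.

## What the synthetic conditions do and do not show

All inputs are parameter sets; there is no external data. The presets
emulate regime phenomenology — degenerate groove, activated double well,
inverted ordering — in rescaled units with a single effective mode per
symmetry channel and white (memoryless) baths. Passing tests therefore
demonstrate the internal consistency of the model and its kinetic
signatures, not quantitative rates for any real molecule: real systems
have many modes, coloured baths, quantised vibrations near crossings, and
exponentially varying transfer integrals, none of which are modelled. The
geometric (Berry) phase around the conical intersection is likewise
outside scope: the electronic amplitudes are propagated, not the nuclear
wavefunction.

## Known limitations

- Ehrenfest mean-field closure: no surface hopping, no detailed balance
  for the *electronic* populations at low temperature (the modes, by
  contrast, thermalise correctly by construction).
- Fixed-step noise convention: the per-step frozen force is first-order
  accurate in the noise; deterministic parts retain 5th-order accuracy.
- `τ` from the occupation maximum is a faithful descriptive statistic but
  a poor rate estimator under noise (see above); rate work should use the
  first-passage definition.
- The linear transfer integral loses meaning if `ε_x + k_x u_x` changes
  sign; only a guard is provided, not the exponential variant.
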