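# alchemti

Thermodynamic-integration (TI) analysis of alchemical charge-change
transformations, built around the question of how much a ligand's formal
charge contributes to binding **selectivity** between two closely related
receptors — the textbook case being an ATP-competitive kinase inhibitor
that binds one CDK four orders of magnitude more tightly than its close
homolog.

## Who this is for

Computational chemists and structural bioinformaticians who have per-λ
∂V/∂λ output from alchemical MD (or want to prototype the analysis before
burning cluster time) and need:

* potency ↔ free-energy arithmetic: ΔG⁰ = −RT ln K_D (K_D approximated by
  IC50), selectivity gaps ΔΔG = RT ln(IC50_a/IC50_b), and the equivalent
  K_D fold-change exp(ΔΔG/RT);
* the TI quadrature for a uniform λ grid that stops short of the end
  points: trapezoid rule on the sampled interval plus constant
  extrapolation of the terminal ⟨∂V/∂λ⟩ to λ = 0 and λ = 1 (19 windows on
  [0.05, 0.95] → interior weights 0.05, terminal weights 0.075);
* honest error bars from batch (block) averaging of correlated series,
  propagated through the quadrature as σ(ΔG) = √(Σ wᵢ² SEMᵢ²), and
  quadrature-combined across the two legs of a thermodynamic cycle;
* trajectory metrics used to interpret the result: hydrogen-bond
  occupancy (donor–acceptor ≤ 3.0 Å and donor−H···acceptor ≥ 135°,
  inclusive), inter-atom distance series, Kabsch-superposed RMSD, and
  per-atom RMSF;
* a desk-scale **toy alchemical simulator** — Langevin (BAOAB) dynamics on
  a harmonic environment linearly coupled to the mutating charge — whose
  charging free energy is known in closed form (−Δq²E²/2k), so the entire
  estimator chain can be validated end to end in seconds.

Synthetic-data generators produce every input the pipeline consumes
(∂V/∂λ window sets with a known mean-curve integral and AR(1) noise;
trajectories with planted H-bond occupancies and fluctuation profiles),
each returning its exact ground truth.

## Worked example

```python
from alchemti import (AffinityMeasurement, SimParams, ToySystem,
                      build_schedule, ddG_to_kd_fold, run_ti_experiment,
                      selectivity_ddG)

# measured potencies: one inhibitor against two kinases
cdk2 = AffinityMeasurement.from_value("FAS", "CDK2", 500, "uM")
cdk4 = AffinityMeasurement.from_value("FAS", "CDK4", 0.4, "uM")
gap = selectivity_ddG(cdk2, cdk4)
print(f"selectivity gap: {gap.value:.1f} kcal/mol")
print(f"K_D fold-change: {ddG_to_kd_fold(gap, 298.15):.0f}")

# toy charging cycle: the same 0 → +1 e mutation in two environments
schedule = build_schedule(19, 0.05, 0.95)
pocket  = ToySystem(charges_state0=[0.0], charges_state1=[1.0], field_strength=1.0)
solvent = ToySystem(charges_state0=[0.0], charges_state1=[1.0], field_strength=0.5)
cycle = run_ti_experiment(pocket, solvent, schedule, SimParams(seed=42))
print(f"toy cycle ddG = {cycle.ddG.value:.3f} +/- {cycle.ddG.uncertainty:.3f} kcal/mol")
```

prints

```
selectivity gap: 4.2 kcal/mol
K_D fold-change: 1250
toy cycle ddG = -0.394 +/- 0.019 kcal/mol
```

The 4.2 kcal/mol is the binding free-energy difference implied by the two
IC50s (a 1250-fold K_D ratio). The toy cycle ΔΔG is the sampled estimate
of the exact Gaussian answer −Δq²(E_A² − E_B²)/2k = −0.375 kcal/mol; the
reported ±0.019 is the quadrature-combined batch-mean standard error, and
the estimate sits within ~1σ of the exact value.

The same workflows are scriptable from the shell via the `alchemti`
command (`generate`, `ti`, `simulate`, `analyze`, `affinity` subcommands);
every report embeds a provenance block and identical seeds reproduce
byte-identical outputs.

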