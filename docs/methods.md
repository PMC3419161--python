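# Methods

## Potency → free energy

`ic50_to_dG` implements ΔG⁰ = −RT ln(K_D/c⁰) with the gas constant fixed
at R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹, concentrations converted to mol/L and
referenced to the standard state c⁰ = 1 mol/L. K_D is approximated by IC50
directly: no Hill-slope fitting and no Cheng–Prusoff correction are
applied, so the numbers are comparative, not absolute. The default
temperature is 298.15 K; the selectivity gap printed for the 500 µM vs
0.4 µM pair is 4.22 kcal/mol at 298.15 K and 4.25 kcal/mol at 300 K —
identical at one decimal, so the conversion is insensitive to the choice
within the physiological range. The sign convention makes the gap
positive: `selectivity_ddG(a, b) = RT ln(IC50_a/IC50_b)` is how much
binding free energy the weaker complex `a` is missing, and equals
`ic50_to_dG(b) − ic50_to_dG(a)` exactly.

## TI quadrature

The λ grid is uniform with spacing h on [λ_min, λ_max] ⊂ (0, 1). The
integral ∫₀¹⟨∂V/∂λ⟩dλ is evaluated by the trapezoid rule on the sampled
interval plus constant extrapolation of the terminal window means to the
interval ends: interior weights h, terminal weights h/2 + λ_min (left) and
h/2 + (1 − λ_max) (right). This is the unique simple construction that
reproduces both the interior weight 0.05 and the terminal weight 0.075 on
the canonical 19-window grid, and the weights sum to 1 for *every* uniform
grid, making the quadrature exact for constant integrands; symmetry makes
it exact for linear ones as well (∫λ dλ = 0.5 to machine precision).
Soft-core λ paths and MBAR/BAR estimators are out of scope — for a purely
electrostatic mutation the linear mixture is well behaved at both ends.

## Error model

Per-window ∂V/∂λ series from MD are autocorrelated, so naive standard
errors are overconfident. Each window is cut into contiguous,
non-overlapping batches of equal duration (canonically a 5 ns window into
25 batches of 200 ps); the window mean is the mean of batch means and the
window SEM is their standard deviation over √n_batches. We chose the SEM
(not the SD) of batch means as the per-window uncertainty — the standard
choice when batches are longer than the correlation time — and the code is
structured so the alternative is a one-line change. ΔG's uncertainty is
√(Σ wᵢ² SEMᵢ²); two legs combine in quadrature. With a single batch the
uncertainty is reported as absent rather than zero. No equilibration is
discarded by default (`equilibration_fraction = 0`), matching a protocol
that reports all batches per window; the fraction is configurable. NaNs or
non-uniform time stamps in a window are hard errors — corrupted tables
must never silently shift ΔG. The convergence trace re-evaluates ΔG using
only the first b batches of every window, which is the standard
running-estimate plot for judging whether the transformation has
converged.

## Toy alchemical system

The simulator is a Gaussian linear-response surrogate for an
electrostatics-dominated mutation: each particle has one 1-D harmonic
coordinate (force constant k, default 1 kcal mol⁻¹ Å⁻²) linearly coupled
to its charge through a field E (kcal mol⁻¹ Å⁻¹ e⁻¹), V_s = ½kΣx² −
ΣqₛEx. It is *not* a reduced protein model — it is the minimal system for
which the charging free energy of the linear λ-mixture is exact
(−Δq²E²/2k for a neutral initial state), which is precisely what makes it
the right validation target for the estimator chain. Matching common
practice for charge-change transformations, no counter-ion is created
within a leg; the net-charge change cancels in the two-leg cycle.

Sampling uses the BAOAB Langevin splitting with stability guards
dt·γ < 1 and dt·√(k/m) < 2 (defaults dt = 0.05 ps, γ = 1 ps⁻¹, mass
1 kcal mol⁻¹ ps² Å⁻², T = 300 K). Positions are initialised from the exact
Boltzmann distribution of V(λ) (Gaussian about the λ-dependent minimum),
so no burn-in is needed and every recorded sample is production data. All
randomness flows from `numpy` generators seeded per window via a
`SeedSequence` spawned from the experiment seed: runs are bit-reproducible
and windows are mutually independent.

Default experiment size — 19 windows × 4000 steps, recording every 5
steps, 25 batches per window — was chosen so a full two-leg cycle takes
about a second while the position correlation time (≈ 2/γ = 2 ps) is
several times shorter than a batch (8 ps), keeping the batch-mean error
bars calibrated: across repeated seeds the exact answer falls within 3
reported σ in ≥ 95% of runs.

## Trajectory metrics

Hydrogen bonds use the ptraj-style geometric criterion: donor-heavy to
acceptor-heavy distance ≤ 3.0 Å **and** donor−H···acceptor angle (vertex
at the hydrogen) ≥ 135°, both inclusive; a 10⁻⁹ guard keeps the inclusive
boundary inclusive under floating-point round-off. Occupancy is the
percentage of frames passing. Distances are computed on raw coordinates
with no prior fitting — the alignment question only matters for metrics
that compare frames, and a raw inter-atom distance is frame-local; this is
noted because published distance plots do not always state their fitting
choice. RMSD uses Kabsch superposition (proper rotations only, via
`scipy.spatial.transform.Rotation.align_vectors`) of the selection onto
the reference; the backbone selection when reading a PDB is the N/CA/C/O
atom names. RMSF aligns all frames to the time-averaged structure
iteratively (2 passes by default), then reports per-atom √⟨|Δx|²⟩. Note
that rigid-body fitting removes 6 degrees of freedom: with N selected
atoms the measured RMSF is deflated by roughly √(1 − 2/N), so σ√3
recovery tests use N ≳ 50. Atom-count mismatches always raise; nothing is
truncated silently.

## Synthetic data

The ∂V/∂λ generator plants a polynomial mean curve m(λ) (default 2 − 3λ,
exact integral 0.5) plus stationary AR(1) noise, default marginal SD
1 kcal/mol and φ = 0.9 (≈ 19-sample correlation time) — white noise would
make batch averaging pointless, so the autocorrelation is the feature
under test. Default 2500 samples per window at 2 ps spacing emulate a 5 ns
window logged every 2 ps. The H-bond generator places the
donor/H/acceptor triple deterministically — bonded frames at 2.8 Å / 170°,
broken frames at 3.5 Å — so the planted occupancy is exact by
construction, and jitters only scaffold atoms. The fluctuation generator
jitters atoms isotropically about an ideal α-helical Cα arrangement
(deliberately non-collinear: a straight-line reference makes the Kabsch
rotation degenerate and biases RMSF). Expected RMSF is σ√3 per atom.

What the generators do **not** emulate: force-field energetics, solvent,
protein topology beyond the minimal atom template, conformational
transitions, or non-stationary drift in ∂V/∂λ. Passing tests therefore
demonstrate the correctness and calibration of the *estimators*, not the
convergence of any particular protein system.

## Numerical choices and edge cases

* λ window matching between a manifest and a schedule uses a 10⁻⁹
  absolute tolerance; a missing window fails naming its λ.
* Batch durations must be a whole multiple of the sampling interval;
  trailing samples short of a full batch are dropped.
* Quadrature weight sums are enforced to 10⁻¹²; schedules that violate it
  cannot be constructed.
* Free-energy uncertainties are 1-σ standard errors and must be
  non-negative; absence (no estimate) is distinct from zero.
* Reports write full precision to JSON and one decimal (kcal/mol) to the
  human-readable tables.

## Known limitations

The toy model's linear response means ⟨∂V/∂λ⟩ is linear in λ, which the
quadrature integrates exactly — so the toy cycle validates sampling and
error calibration, not quadrature bias on curved integrands (that is
covered separately by polynomial-mean synthetic windows). Cluster-scale
protein results (tens of kcal/mol legs from explicit-solvent MD) are out
of scope by design: this package is the analysis layer, not the sampler.
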