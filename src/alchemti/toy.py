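"""Desk-scale alchemical charge-mutation simulator with exact free energies.

The model is a Gaussian (linear-response) surrogate for an
electrostatics-dominated alchemical mutation: each particle carries one
1-D harmonic environment coordinate x (force constant k) linearly coupled
to its charge through a constant field E,

    V_s(x) = ½ k Σᵢ xᵢ²  −  Σᵢ q_s,ᵢ E xᵢ,        s ∈ {0, 1},

where the two end states differ only in their charges (an iso-electronic
mutation, e.g. a neutral carbon turning into a positively charged
nitrogen). Linear λ-mixing V(λ) = (1−λ)V₀ + λV₁ makes ∂V/∂λ = V₁ − V₀
exactly, independent of λ. Because the model is Gaussian, everything is
closed-form:

    ⟨xᵢ⟩_λ = (q₀,ᵢ + λΔqᵢ) E / k
    ⟨∂V/∂λ⟩_λ = −(E²/k) Σᵢ Δqᵢ (q₀,ᵢ + λΔqᵢ)
    ΔG = −(E²/k) Σᵢ (q₀,ᵢΔqᵢ + Δqᵢ²/2)       (= −Δq²E²/2k from q₀ = 0)

so the TI estimator can be validated end to end against exact answers.
Sampling uses the BAOAB Langevin splitting, which targets the Boltzmann
distribution of V(λ) at the set temperature with O(dt²) configurational
bias. No counter-ion is created during the transformation: the net system
charge changes within each leg and cancels only in the two-leg cycle
difference, mirroring standard practice for charge-change mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .constants import KB_KCAL
from .errors import InvalidInputError
from .ti import CycleResult, DvdlSeries, LambdaSchedule, cycle_ddG, estimate_dG

__all__ = [
    "ToySystem",
    "SimParams",
    "mixed_potential",
    "dvdl",
    "langevin_run",
    "run_ti_experiment",
    "analytic_dvdl_mean",
    "analytic_charging_free_energy",
]


@dataclass(frozen=True)
class ToySystem:
    """Particles with dual-state charges in a harmonic environment.

    Units: Å, kcal/mol, ps, K, elementary charges. ``mass`` is expressed
    in kcal mol⁻¹ ps² Å⁻² so the equations of motion need no conversion
    factor; with k = mass = 1 the oscillator period is 2π ps.
    """

    charges_state0: np.ndarray  # e, the neutral end state
    charges_state1: np.ndarray  # e, the charged end state
    spring_constant: float = 1.0  # kcal mol^-1 Å^-2
    field_strength: float = 1.0  # kcal mol^-1 Å^-1 e^-1
    temperature: float = 300.0  # K
    friction: float = 1.0  # ps^-1
    mass: float = 1.0  # kcal mol^-1 ps^2 Å^-2
    positions: Optional[np.ndarray] = None  # Å, initial coordinates

    def __post_init__(self) -> None:
        q0 = np.atleast_1d(np.asarray(self.charges_state0, dtype=float))
        q1 = np.atleast_1d(np.asarray(self.charges_state1, dtype=float))
        object.__setattr__(self, "charges_state0", q0)
        object.__setattr__(self, "charges_state1", q1)
        if q0.shape != q1.shape or q0.ndim != 1:
            raise InvalidInputError("end-state charge arrays must be 1-D and equal length")
        if not (np.all(np.isfinite(q0)) and np.all(np.isfinite(q1))):
            raise InvalidInputError("charges must be finite")
        if self.spring_constant <= 0:
            raise InvalidInputError(f"spring constant must be > 0, got {self.spring_constant}")
        if self.temperature <= 0:
            raise InvalidInputError(f"temperature must be > 0, got {self.temperature}")
        if self.friction <= 0 or self.mass <= 0:
            raise InvalidInputError("friction and mass must be > 0")
        if self.positions is not None:
            x = np.atleast_1d(np.asarray(self.positions, dtype=float))
            if x.shape != q0.shape:
                raise InvalidInputError("positions must match the number of particles")
            object.__setattr__(self, "positions", x)

    @property
    def n_particles(self) -> int:
        return len(self.charges_state0)

    @property
    def delta_q(self) -> np.ndarray:
        """Per-particle charge change Δq = q₁ − q₀ in e."""
        return self.charges_state1 - self.charges_state0

    def charges_at(self, lam: float) -> np.ndarray:
        """λ-mixed charges (1−λ)q₀ + λq₁."""
        return (1.0 - lam) * self.charges_state0 + lam * self.charges_state1


@dataclass(frozen=True)
class SimParams:
    """Langevin sampling parameters."""

    dt: float = 0.05  # ps
    n_steps: int = 4000
    seed: int = 0
    record_interval: int = 5  # steps between recorded ∂V/∂λ samples

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidInputError(f"dt must be > 0, got {self.dt}")
        if self.n_steps < 1:
            raise InvalidInputError(f"n_steps must be ≥ 1, got {self.n_steps}")
        if self.record_interval < 1:
            raise InvalidInputError("record_interval must be ≥ 1")


def _state_potential(system: ToySystem, coords: np.ndarray, charges: np.ndarray) -> float:
    x = np.atleast_1d(np.asarray(coords, dtype=float))
    if x.shape != system.charges_state0.shape:
        raise InvalidInputError(
            f"coords shape {x.shape} does not match {system.n_particles} particles"
        )
    k, E = system.spring_constant, system.field_strength
    return float(0.5 * k * np.sum(x**2) - E * np.sum(charges * x))


def mixed_potential(system: ToySystem, coords: np.ndarray, lam: float) -> float:
    """λ-mixed potential (1−λ)V₀ + λV₁ in kcal/mol."""
    if not (0.0 <= lam <= 1.0):
        raise InvalidInputError(f"λ must lie in [0, 1], got {lam}")
    v0 = _state_potential(system, coords, system.charges_state0)
    v1 = _state_potential(system, coords, system.charges_state1)
    return (1.0 - lam) * v0 + lam * v1


def dvdl(system: ToySystem, coords: np.ndarray) -> float:
    """∂V/∂λ = V₁ − V₀ = −Σᵢ Δqᵢ E xᵢ; exact and λ-independent for the
    linear mixture."""
    x = np.atleast_1d(np.asarray(coords, dtype=float))
    if x.shape != system.charges_state0.shape:
        raise InvalidInputError(
            f"coords shape {x.shape} does not match {system.n_particles} particles"
        )
    return float(-system.field_strength * np.sum(system.delta_q * x))


def analytic_dvdl_mean(system: ToySystem, lam: float) -> float:
    """Exact ⟨∂V/∂λ⟩ at λ: −(E²/k) Σᵢ Δqᵢ(q₀,ᵢ + λΔqᵢ)."""
    k, E = system.spring_constant, system.field_strength
    dq, q0 = system.delta_q, system.charges_state0
    return float(-(E**2) / k * np.sum(dq * (q0 + lam * dq)))


def analytic_charging_free_energy(system: ToySystem) -> float:
    """Exact ΔG of the charge mutation, ∫₀¹⟨∂V/∂λ⟩dλ =
    −(E²/k) Σᵢ (q₀,ᵢΔqᵢ + Δqᵢ²/2); reduces to −Δq²E²/(2k) when the initial
    state is neutral."""
    k, E = system.spring_constant, system.field_strength
    dq, q0 = system.delta_q, system.charges_state0
    return float(-(E**2) / k * np.sum(q0 * dq + 0.5 * dq**2))


def langevin_run(system: ToySystem, lam: float, params: SimParams) -> DvdlSeries:
    """Sample ∂V/∂λ from BAOAB Langevin dynamics on V(λ).

    Stability requires dt·γ < 1 and dt·√(k/m) < 2; violating either raises
    with the bound in the message. Positions start from the exact Boltzmann
    distribution of V(λ) (a Gaussian centred on the λ-dependent minimum
    with variance k_BT/k) and velocities from Maxwell–Boltzmann, so no
    burn-in is required. Identical seeds give bit-identical series.
    """
    if not (0.0 <= lam <= 1.0):
        raise InvalidInputError(f"λ must lie in [0, 1], got {lam}")
    k, E, m, gamma = (
        system.spring_constant,
        system.field_strength,
        system.mass,
        system.friction,
    )
    dt = params.dt
    if dt * gamma >= 1.0:
        raise InvalidInputError(
            f"unstable step: require dt·friction < 1, got {dt * gamma:.3g}"
        )
    omega_dt = dt * math.sqrt(k / m)
    if omega_dt >= 2.0:
        raise InvalidInputError(
            f"unstable step: require dt·sqrt(k/m) < 2, got {omega_dt:.3g}"
        )

    kbt = KB_KCAL * system.temperature
    q_lam = system.charges_at(lam)
    rng = np.random.default_rng(params.seed)

    n = system.n_particles
    x = q_lam * E / k + math.sqrt(kbt / k) * rng.standard_normal(n)
    v = math.sqrt(kbt / m) * rng.standard_normal(n)

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * kbt / m)
    noise = rng.standard_normal((params.n_steps, n))

    force_scale = E * q_lam  # constant part of the force; −kx is the rest
    half_dt = 0.5 * dt
    dq_E = system.delta_q * E

    n_rec = params.n_steps // params.record_interval
    times = np.empty(n_rec)
    values = np.empty(n_rec)
    rec = 0
    for step in range(params.n_steps):
        v += half_dt / m * (force_scale - k * x)
        x += half_dt * v
        v = c1 * v + c2 * noise[step]
        x += half_dt * v
        v += half_dt / m * (force_scale - k * x)
        if (step + 1) % params.record_interval == 0:
            times[rec] = (step + 1) * dt
            values[rec] = -np.dot(dq_E, x)
            rec += 1
    if n_rec == 0:
        raise InvalidInputError(
            "record_interval exceeds n_steps; no ∂V/∂λ samples recorded"
        )
    return DvdlSeries(lambda_value=lam, times=times, values=values)


def _derive_window_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-window child seeds from one experiment seed."""
    return np.random.SeedSequence(seed).generate_state(n).astype(np.int64)


def run_ti_experiment(
    sys_envA: ToySystem,
    sys_envB: ToySystem,
    schedule: LambdaSchedule,
    params: SimParams,
    batch_duration: Optional[float] = None,
    n_batches: int = 25,
) -> CycleResult:
    """Run the full two-leg TI cycle on two toy environments.

    Every schedule λ is sampled in both environments with independent,
    seed-derived streams; each leg is integrated with batch-mean errors
    and the legs combine into ΔΔG = ΔG_A − ΔG_B. By default each window is
    cut into 25 equal batches. The exact answer is
    ``analytic_charging_free_energy(sys_envA) − analytic_charging_free_energy(sys_envB)``.
    """
    if sys_envA.charges_state0.shape != sys_envB.charges_state0.shape or not (
        np.array_equal(sys_envA.charges_state0, sys_envB.charges_state0)
        and np.array_equal(sys_envA.charges_state1, sys_envB.charges_state1)
    ):
        raise InvalidInputError(
            "both environments must share the same end-state charge definitions"
        )
    nw = len(schedule)
    seeds = _derive_window_seeds(params.seed, 2 * nw)
    legs = []
    for env_idx, system in enumerate((sys_envA, sys_envB)):
        windows = [
            langevin_run(
                system,
                float(lam),
                replace(params, seed=int(seeds[env_idx * nw + i])),
            )
            for i, lam in enumerate(schedule.points)
        ]
        if batch_duration is None:
            per_batch = len(windows[0].values) // n_batches
            if per_batch < 1:
                raise InvalidInputError(
                    f"too few recorded samples ({len(windows[0].values)}) for "
                    f"{n_batches} batches"
                )
            bd = per_batch * windows[0].dt
        else:
            bd = batch_duration
        legs.append(
            estimate_dG(
                windows,
                schedule,
                batch_duration=bd,
                label=f"dG(toy leg {'AB'[env_idx]})",
            )
        )
    return cycle_ddG(legs[0].dG, legs[1].dG)
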