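"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* per-λ ∂V/∂λ window sets whose mean is a chosen polynomial in λ with
  stationary AR(1) noise on top — the autocorrelation emulates what makes
  batch-mean error estimation necessary for MD output, and the exact
  integral of the mean curve is returned as ground truth;
* trajectories with a planted hydrogen-bond occupancy fraction (bonded
  frames placed at 2.8 Å / 170°, broken frames at 3.5 Å), returned with
  the exact frame mask;
* trajectories of atoms jittering isotropically about fixed sites with a
  prescribed per-atom σ, for which the expected RMSF is σ√3.

Every generator is seed-deterministic and returns its truth alongside the
data, so recovery tests never rely on re-estimated quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import InvalidInputError
from .ti import DvdlSeries, LambdaSchedule
from .trajectory import Atom, Trajectory

__all__ = [
    "DvdlGeneratorSpec",
    "TrajGeneratorSpec",
    "generate_windows",
    "generate_hbond_traj",
    "generate_fluct_traj",
]


@dataclass(frozen=True)
class DvdlGeneratorSpec:
    """Recipe for one set of ∂V/∂λ windows.

    ``mean_coefficients`` are polynomial coefficients in ascending powers
    of λ (kcal/mol): m(λ) = Σⱼ cⱼ λʲ. The noise is stationary AR(1) with
    marginal standard deviation ``noise_sd`` and lag-1 correlation
    ``ar1_phi`` (default 0.9, i.e. a correlation time of ~19 samples, so
    naive i.i.d. error bars would be badly overconfident).
    """

    mean_coefficients: tuple[float, ...] = (2.0, -3.0)
    noise_sd: float = 1.0
    ar1_phi: float = 0.9
    n_samples: int = 2500
    dt: float = 2.0  # ps between samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_coefficients:
            raise InvalidInputError("mean_coefficients must be non-empty")
        if self.noise_sd < 0:
            raise InvalidInputError(f"noise_sd must be ≥ 0, got {self.noise_sd}")
        if not (-1.0 < self.ar1_phi < 1.0):
            raise InvalidInputError(f"|ar1_phi| must be < 1, got {self.ar1_phi}")
        if self.n_samples < 1 or self.dt <= 0:
            raise InvalidInputError("n_samples must be ≥ 1 and dt > 0")

    def mean_at(self, lam: float) -> float:
        return float(
            sum(c * lam**j for j, c in enumerate(self.mean_coefficients))
        )

    @property
    def true_integral(self) -> float:
        """Exact ∫₀¹ m(λ) dλ = Σⱼ cⱼ/(j+1)."""
        return float(
            sum(c / (j + 1) for j, c in enumerate(self.mean_coefficients))
        )


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) path of marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    x0 = rng.normal(0.0, sd)
    if n == 1:
        return np.array([x0])
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    rest, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return np.concatenate(([x0], rest))


def generate_windows(
    spec: DvdlGeneratorSpec, schedule: LambdaSchedule
) -> tuple[list[DvdlSeries], float]:
    """One ∂V/∂λ series per schedule point plus the exact mean-curve
    integral.

    Each window draws from an independent, deterministically derived
    stream, so adding windows never perturbs existing ones.
    """
    children = np.random.SeedSequence(spec.seed).spawn(len(schedule))
    times = spec.dt * np.arange(1, spec.n_samples + 1)
    series = []
    for lam, child in zip(schedule.points, children):
        rng = np.random.default_rng(child)
        noise = _ar1(rng, spec.n_samples, spec.noise_sd, spec.ar1_phi)
        series.append(
            DvdlSeries(
                lambda_value=float(lam),
                times=times,
                values=spec.mean_at(float(lam)) + noise,
            )
        )
    return series, spec.true_integral


@dataclass(frozen=True)
class TrajGeneratorSpec:
    """Recipe for a trajectory with a planted H-bond occupancy."""

    n_frames: int = 100
    target_occupancy: float = 0.46
    jitter_sd: float = 0.1  # Å, applied to scaffold atoms only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise InvalidInputError(f"n_frames must be ≥ 1, got {self.n_frames}")
        if not (0.0 <= self.target_occupancy <= 1.0):
            raise InvalidInputError(
                f"target_occupancy must be in [0, 1], got {self.target_occupancy}"
            )
        if self.jitter_sd < 0:
            raise InvalidInputError(f"jitter_sd must be ≥ 0, got {self.jitter_sd}")


#: Geometry of a clearly-formed hydrogen bond: D–A distance 2.8 Å, angle 170°.
_BONDED_DA = 2.8
_BONDED_ANGLE = 170.0
#: Broken geometry: the acceptor pulled out to 3.5 Å (angle unchanged).
_BROKEN_DA = 3.5


def _hbond_frame_coords(da_distance: float) -> np.ndarray:
    """Donor N at the origin, H at 1 Å along +x, acceptor O placed so the
    D−H···A angle is 170° and |D−A| equals ``da_distance``."""
    theta = math.radians(180.0 - _BONDED_ANGLE)  # deviation of H→A from +x
    c = math.cos(theta)
    # |D−A|² = 1 + 2 r c + r², solve for the H→A length r > 0
    r = -c + math.sqrt(c * c + da_distance**2 - 1.0)
    h = np.array([1.0, 0.0, 0.0])
    a = h + r * np.array([math.cos(theta), math.sin(theta), 0.0])
    return np.array([[0.0, 0.0, 0.0], h, a])


def generate_hbond_traj(spec: TrajGeneratorSpec) -> tuple[Trajectory, np.ndarray]:
    """Trajectory with exactly ``round(target_occupancy · n_frames)``
    bonded frames, plus the boolean frame mask as ground truth.

    The donor/hydrogen/acceptor triple (a ligand indole N−H donating to a
    hinge backbone carbonyl O) is placed deterministically — bonded frames
    at 2.8 Å / 170°, broken frames at 3.5 Å — so the planted occupancy is
    exact by construction. Two scaffold carbons carry Gaussian jitter so
    the file is not fully static. Which frames are bonded is a seeded
    permutation.
    """
    n = spec.n_frames
    n_present = int(round(spec.target_occupancy * n))
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:n_present]] = True

    atoms = [
        Atom(id=0, name="N1", element="N", res_id=1, res_name="LIG"),
        Atom(id=1, name="H1", element="H", res_id=1, res_name="LIG"),
        Atom(id=2, name="O", element="O", res_id=2, res_name="VAL"),
        Atom(id=3, name="C1", element="C", res_id=1, res_name="LIG"),
        Atom(id=4, name="C2", element="C", res_id=1, res_name="LIG"),
    ]
    bonded = _hbond_frame_coords(_BONDED_DA)
    broken = _hbond_frame_coords(_BROKEN_DA)
    scaffold_sites = np.array([[-1.4, 0.5, 0.0], [-2.5, -0.3, 0.4]])

    coords = np.empty((n, len(atoms), 3))
    for f in range(n):
        coords[f, :3] = bonded if mask[f] else broken
        coords[f, 3:] = scaffold_sites + rng.normal(0.0, spec.jitter_sd, (2, 3))
    return Trajectory(coords=coords, atoms=atoms), mask


def generate_fluct_traj(
    n_frames: int, sigma_profile: Sequence[float], seed: int
) -> Trajectory:
    """Atoms jittering isotropically about a Cα-like helix with per-atom σ.

    Sites follow ideal α-helix Cα geometry (2.3 Å radius, 1.5 Å rise and
    100° turn per residue) — deliberately non-collinear so rigid-body
    superposition is well conditioned. Each atom's displacement in every
    frame is an independent 3-D Gaussian of per-axis standard deviation
    σᵢ, so its expected RMSF is σᵢ√3.
    """
    sigma = np.asarray(sigma_profile, dtype=float)
    if sigma.ndim != 1 or len(sigma) < 1:
        raise InvalidInputError("sigma_profile must be a non-empty 1-D sequence")
    if np.any(sigma < 0):
        raise InvalidInputError("sigma_profile must be non-negative")
    if n_frames < 1:
        raise InvalidInputError(f"n_frames must be ≥ 1, got {n_frames}")
    rng = np.random.default_rng(seed)
    n_atoms = len(sigma)
    turn = np.radians(100.0) * np.arange(n_atoms)
    sites = np.column_stack(
        [1.5 * np.arange(n_atoms), 2.3 * np.cos(turn), 2.3 * np.sin(turn)]
    )
    coords = sites + rng.standard_normal((n_frames, n_atoms, 3)) * sigma[None, :, None]
    atoms = [
        Atom(id=i, name="CA", element="C", res_id=i + 1, res_name="GLY")
        for i in range(n_atoms)
    ]
    return Trajectory(coords=coords, atoms=atoms)
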