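"""Thermodynamic-integration estimator: λ schedules, quadrature, batch-mean
errors, and the thermodynamic-cycle ΔΔG.

The free energy of an alchemical transformation with linearly mixed end
states, V(λ) = (1−λ)V₀ + λV₁, is

    ΔG = ∫₀¹ ⟨∂V/∂λ⟩_λ dλ,

estimated here on a uniform λ grid that stops short of the end points
(e.g. 19 windows at λ = 0.05, 0.10, …, 0.95). The quadrature is the
trapezoid rule on the sampled interval plus constant extrapolation of the
terminal ⟨∂V/∂λ⟩ values out to λ = 0 and λ = 1, which on the 19-point grid
gives interior weights of 0.05 and terminal weights of 0.075
(= 0.05/2 + 0.05). Statistical errors come from batch (block) averaging of
the correlated per-window time series: each window is cut into contiguous
equal-duration batches (e.g. a 5 ns window into 25 batches of 200 ps) and
the standard error of the batch means propagates through the quadrature.

Two transformation legs run in different environments (e.g. the same
charge mutation inside two kinase binding pockets) combine into a
thermodynamic-cycle difference ΔΔG = ΔG_a − ΔG_b; the net-charge change of
a single leg cancels in this difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .affinity import FreeEnergy
from .errors import InvalidInputError

__all__ = [
    "LambdaSchedule",
    "DvdlSeries",
    "TIResult",
    "CycleResult",
    "build_schedule",
    "integrate_dvdl",
    "batch_means",
    "estimate_dG",
    "cycle_ddG",
    "write_window",
    "read_window",
    "read_manifest",
    "write_manifest",
]

_WEIGHT_SUM_TOL = 1e-12


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered λ grid with quadrature weights.

    Invariants: points strictly increasing inside (0, 1), weights positive
    and summing to 1 (within 1e-12), uniform spacing.
    """

    points: np.ndarray
    weights: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts)
        if pts.ndim != 1 or pts.shape != wts.shape:
            raise InvalidInputError("points and weights must be 1-D and equal length")
        if len(pts) < 2:
            raise InvalidInputError("schedule needs at least two λ points")
        if not (np.all(pts > 0) and np.all(pts < 1)):
            raise InvalidInputError("λ points must lie strictly inside (0, 1)")
        if not np.all(np.diff(pts) > 0):
            raise InvalidInputError("λ points must be strictly increasing")
        if not np.all(wts > 0):
            raise InvalidInputError("quadrature weights must be positive")
        if abs(wts.sum() - 1.0) > _WEIGHT_SUM_TOL:
            raise InvalidInputError(
                f"quadrature weights must sum to 1, got {wts.sum():.16f}"
            )

    def __len__(self) -> int:
        return len(self.points)


def build_schedule(n_windows: int, lambda_min: float, lambda_max: float) -> LambdaSchedule:
    """Uniform λ schedule with trapezoid + constant-extrapolation weights.

    Interior points carry weight h (the grid spacing); each terminal point
    carries h/2 from the trapezoid rule on [λ_min, λ_max] plus the distance
    to the nearest interval end (λ_min to the left, 1 − λ_max to the
    right), i.e. the terminal ⟨∂V/∂λ⟩ is extended as a constant to λ = 0
    and λ = 1. The weights always sum to 1. For 19 windows on
    [0.05, 0.95] this yields interior weights 0.05 and terminal weights
    0.075.
    """
    if n_windows < 2:
        raise InvalidInputError(f"need at least 2 λ windows, got {n_windows}")
    if not (0.0 < lambda_min < lambda_max < 1.0):
        raise InvalidInputError(
            f"require 0 < lambda_min < lambda_max < 1, got [{lambda_min}, {lambda_max}]"
        )
    h = (lambda_max - lambda_min) / (n_windows - 1)
    points = lambda_min + h * np.arange(n_windows)
    weights = np.full(n_windows, h)
    weights[0] = h / 2 + lambda_min
    weights[-1] = h / 2 + (1.0 - lambda_max)
    return LambdaSchedule(points=points, weights=weights, spacing=h)


def integrate_dvdl(means: Sequence[float], schedule: LambdaSchedule) -> float:
    """Weighted quadrature Σᵢ wᵢ·⟨∂V/∂λ⟩ᵢ over the schedule, in kcal/mol.

    Exact for integrands constant or linear in λ on a symmetric grid.
    """
    m = np.asarray(means, dtype=float)
    if m.shape != schedule.points.shape:
        raise InvalidInputError(
            f"got {m.size} means for a {len(schedule)}-point schedule"
        )
    if not np.all(np.isfinite(m)):
        raise InvalidInputError("per-λ means contain non-finite values")
    return float(np.dot(schedule.weights, m))


@dataclass(frozen=True)
class DvdlSeries:
    """∂V/∂λ sampled at uniform time intervals within one λ window."""

    lambda_value: float
    times: np.ndarray  # ps, strictly increasing, uniform
    values: np.ndarray  # kcal/mol

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if not (0.0 < self.lambda_value < 1.0):
            raise InvalidInputError(f"λ must be in (0, 1), got {self.lambda_value}")
        if t.ndim != 1 or t.shape != v.shape or len(t) < 1:
            raise InvalidInputError("times and values must be equal-length 1-D, length ≥ 1")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError(
                f"∂V/∂λ series at λ={self.lambda_value} contains NaN/inf"
            )
        if len(t) > 1:
            dt = np.diff(t)
            if not np.all(dt > 0):
                raise InvalidInputError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InvalidInputError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        """Sampling interval in ps (defined for length ≥ 2)."""
        if len(self.times) < 2:
            raise InvalidInputError("sampling interval undefined for a single sample")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Total sampled duration in ps, counting one interval per sample."""
        return len(self.values) * self.dt


def batch_means(series: DvdlSeries, batch_duration: float) -> np.ndarray:
    """Means of contiguous non-overlapping batches of ``batch_duration`` ps.

    The batch duration must be a whole number of sampling intervals; any
    trailing samples short of a full batch are dropped.
    """
    if batch_duration <= 0:
        raise InvalidInputError(f"batch duration must be positive, got {batch_duration}")
    dt = series.dt
    per_batch = int(round(batch_duration / dt))
    if per_batch < 1 or abs(per_batch * dt - batch_duration) > dt * 1e-6:
        raise InvalidInputError(
            f"batch duration {batch_duration} ps is not a multiple of the "
            f"sampling interval {dt} ps"
        )
    n_batches = len(series.values) // per_batch
    if n_batches < 1:
        raise InvalidInputError(
            f"batch of {batch_duration} ps exceeds the series duration "
            f"{series.duration} ps at λ={series.lambda_value}"
        )
    trimmed = series.values[: n_batches * per_batch]
    return trimmed.reshape(n_batches, per_batch).mean(axis=1)


@dataclass(frozen=True)
class TIResult:
    """Per-window statistics, the integrated ΔG, and its convergence trace."""

    per_lambda_means: np.ndarray  # kcal/mol
    per_lambda_sems: Optional[np.ndarray]  # kcal/mol; None if inestimable
    dG: FreeEnergy
    #: (cumulative sampling time ps, ΔG estimate) at every batch boundary.
    convergence: list[tuple[float, float]] = field(default_factory=list)


def estimate_dG(
    window_series: Sequence[DvdlSeries],
    schedule: LambdaSchedule,
    batch_duration: float,
    equilibration_fraction: float = 0.0,
    label: str = "",
) -> TIResult:
    """Assemble per-window series into a TI free energy with batch errors.

    For each λ window the post-equilibration samples are cut into batches;
    the window mean is the mean of batch means and the window SEM is their
    standard deviation over √n_batches. ΔG is the quadrature of the window
    means and its uncertainty is √(Σ wᵢ² SEMᵢ²). The convergence trace
    re-evaluates ΔG using only the first b batches of every window, for
    b = 1 … n_batches.

    With a single batch per window the uncertainty is reported as absent.
    """
    if not (0.0 <= equilibration_fraction < 1.0):
        raise InvalidInputError(
            f"equilibration fraction must be in [0, 1), got {equilibration_fraction}"
        )
    by_lambda = {s.lambda_value: s for s in window_series}
    if len(by_lambda) != len(window_series):
        raise InvalidInputError("duplicate λ windows supplied")

    per_window_batches: list[np.ndarray] = []
    for lam in schedule.points:
        matches = [s for lv, s in by_lambda.items() if abs(lv - lam) <= 1e-9]
        if not matches:
            raise InvalidInputError(f"missing ∂V/∂λ window for λ={lam:.4f}")
        s = matches[0]
        n_skip = int(math.floor(equilibration_fraction * len(s.values)))
        if n_skip:
            s = DvdlSeries(s.lambda_value, s.times[n_skip:], s.values[n_skip:])
        per_window_batches.append(batch_means(s, batch_duration))

    n_batches = {len(b) for b in per_window_batches}
    if len(n_batches) != 1:
        raise InvalidInputError(
            f"windows disagree on batch count: {sorted(n_batches)}"
        )
    nb = n_batches.pop()
    bm = np.vstack(per_window_batches)  # (n_windows, n_batches)

    means = bm.mean(axis=1)
    if nb >= 2:
        sems = bm.std(axis=1, ddof=1) / math.sqrt(nb)
        sigma = float(np.sqrt(np.sum(schedule.weights**2 * sems**2)))
    else:
        sems = None
        sigma = None

    value = integrate_dvdl(means, schedule)
    convergence = [
        (b * batch_duration, integrate_dvdl(bm[:, :b].mean(axis=1), schedule))
        for b in range(1, nb + 1)
    ]
    return TIResult(
        per_lambda_means=means,
        per_lambda_sems=sems,
        dG=FreeEnergy(value, sigma, label=label or "dG(TI)"),
        convergence=convergence,
    )


@dataclass(frozen=True)
class CycleResult:
    """Two transformation legs and their thermodynamic-cycle difference."""

    leg_a: FreeEnergy
    leg_b: FreeEnergy
    ddG: FreeEnergy


def cycle_ddG(leg_a: FreeEnergy, leg_b: FreeEnergy) -> CycleResult:
    """Combine two legs of the thermodynamic cycle: ΔΔG = ΔG_a − ΔG_b.

    Uncertainties combine in quadrature when both legs carry one. The
    per-leg net-charge change of an alchemical charge mutation is identical
    in both legs and cancels in the difference; the result label records
    this bookkeeping.
    """
    value = leg_a.value - leg_b.value
    if leg_a.uncertainty is not None and leg_b.uncertainty is not None:
        sigma = math.sqrt(leg_a.uncertainty**2 + leg_b.uncertainty**2)
    else:
        sigma = None
    label = (
        f"ddG[{leg_a.label or 'leg_a'} - {leg_b.label or 'leg_b'}]; "
        "per-leg net-charge change cancels in the cycle difference"
    )
    return CycleResult(leg_a=leg_a, leg_b=leg_b, ddG=FreeEnergy(value, sigma, label))


# ---------------------------------------------------------------------------
# Plain-text window files and leg manifests

def write_window(series: DvdlSeries, path: str | Path) -> None:
    """Write one window as '# lambda=<value>' plus two columns
    (time_ps, dvdl_kcal_mol)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# lambda={series.lambda_value:.10g}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.10g} {v:.10g}\n")


def read_window(path: str | Path) -> DvdlSeries:
    """Read a window file written by :func:`write_window`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# lambda="):
            raise InvalidInputError(
                f"{path}: first line must be '# lambda=<value>', got {header!r}"
            )
        try:
            lam = float(header.split("=", 1)[1])
        except ValueError as exc:
            raise InvalidInputError(f"{path}: unparseable λ in header") from exc
        try:
            data = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise InvalidInputError(f"{path}: malformed data lines") from exc
    if data.size == 0 or data.shape[1] != 2:
        raise InvalidInputError(f"{path}: expected two columns time_ps dvdl_kcal_mol")
    return DvdlSeries(lambda_value=lam, times=data[:, 0], values=data[:, 1])


def write_manifest(paths: Sequence[str | Path], manifest_path: str | Path) -> None:
    """Write a leg manifest: one window-file path per line, relative to the
    manifest's directory when possible."""
    manifest_path = Path(manifest_path)
    lines = []
    for p in paths:
        p = Path(p)
        try:
            lines.append(str(p.relative_to(manifest_path.parent)))
        except ValueError:
            lines.append(str(p))
    manifest_path.write_text("\n".join(lines) + "\n")


def read_manifest(manifest_path: str | Path) -> list[DvdlSeries]:
    """Read every window listed in a leg manifest (paths resolved relative
    to the manifest's directory)."""
    manifest_path = Path(manifest_path)
    series = []
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p = Path(line)
        if not p.is_absolute():
            p = manifest_path.parent / p
        series.append(read_window(p))
    if not series:
        raise InvalidInputError(f"manifest {manifest_path} lists no windows")
    return series
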