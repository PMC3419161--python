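"""Conversions between measured inhibitor potencies and binding free energies.

A dissociation constant K_D (approximated here by IC50, with no Hill-slope
or Cheng–Prusoff correction) maps to a standard binding free energy through

    ΔG⁰ = −RT ln(K_D / c⁰),    c⁰ = 1 mol/L.

The difference of two such free energies — e.g. one inhibitor measured
against two kinases — quantifies selectivity, and exponentiating it back,
exp(ΔΔG/RT), gives the equivalent fold-change in K_D.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .constants import C_STANDARD, R_KCAL
from .errors import InvalidInputError, UnitError

__all__ = [
    "AffinityMeasurement",
    "FreeEnergy",
    "ic50_to_dG",
    "selectivity_ddG",
    "ddG_to_kd_fold",
    "read_affinity_table",
    "affinity_report",
]

#: Recognised concentration units and their value in mol/L.
_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,  # greek mu, distinct codepoint from micro sign
    "nM": 1e-9,
    "pM": 1e-12,
}


@dataclass(frozen=True)
class FreeEnergy:
    """A free energy in kcal/mol with an optional 1-σ uncertainty.

    Parameters
    ----------
    value
        Free energy in kcal/mol.
    uncertainty
        One standard error in kcal/mol, or ``None`` when no uncertainty
        estimate exists (e.g. a single converted potency).
    label
        Free-text provenance, e.g. ``"dG(FAS@CDK4)"``.
    """

    value: float
    uncertainty: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise InvalidInputError(f"free energy value must be finite, got {self.value}")
        if self.uncertainty is not None:
            if not math.isfinite(self.uncertainty) or self.uncertainty < 0:
                raise InvalidInputError(
                    f"uncertainty must be a finite non-negative number, got {self.uncertainty}"
                )


@dataclass(frozen=True)
class AffinityMeasurement:
    """A measured potency (IC50 standing in for K_D) at a given temperature.

    ``ic50`` is stored in mol/L; use :meth:`from_value` to construct from a
    value with an explicit unit string.
    """

    compound_id: str
    target_id: str
    ic50: float  # mol/L
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ic50) and self.ic50 > 0):
            raise InvalidInputError(f"ic50 must be positive and finite, got {self.ic50}")
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise InvalidInputError(
                f"temperature must be positive and finite, got {self.temperature}"
            )

    @classmethod
    def from_value(
        cls,
        compound_id: str,
        target_id: str,
        value: float,
        unit: str,
        temperature: float = 298.15,
    ) -> "AffinityMeasurement":
        """Build a measurement from a value carrying an explicit unit.

        Raises :class:`UnitError` if the unit is missing or unrecognised.
        """
        if unit is None or str(unit).strip() == "":
            raise UnitError("concentration requires an explicit unit (M, mM, uM, nM, pM)")
        factor = _UNIT_TO_MOLAR.get(str(unit).strip())
        if factor is None:
            raise UnitError(
                f"unrecognised concentration unit {unit!r}; "
                f"expected one of {sorted(set(_UNIT_TO_MOLAR))}"
            )
        return cls(compound_id, target_id, float(value) * factor, temperature)


def ic50_to_dG(m: AffinityMeasurement) -> FreeEnergy:
    """Convert a potency to a standard binding free energy, ΔG⁰ = −RT ln K_D.

    The concentration is referenced to c⁰ = 1 mol/L, so a sub-molar IC50
    yields a positive number on this sign convention (the magnitude of the
    binding free energy). No uncertainty is attached.
    """
    dg = -R_KCAL * m.temperature * math.log(m.ic50 / C_STANDARD)
    return FreeEnergy(dg, None, label=f"dG({m.compound_id}@{m.target_id})")


def selectivity_ddG(a: AffinityMeasurement, b: AffinityMeasurement) -> FreeEnergy:
    """Free-energy gap between two potencies: RT ln(ic50_a / ic50_b).

    Positive when ``a`` is the weaker binder. Both measurements must be at
    the same temperature. Algebraically this is exactly
    ``ic50_to_dG(b).value − ic50_to_dG(a).value``: on the −RT ln K_D
    convention the stronger binder has the larger ΔG⁰ magnitude, and the
    gap is how much binding free energy the weaker complex is missing.
    """
    if a.temperature != b.temperature:
        raise InvalidInputError(
            f"temperature mismatch: {a.temperature} K vs {b.temperature} K"
        )
    ddg = R_KCAL * a.temperature * math.log(a.ic50 / b.ic50)
    return FreeEnergy(
        ddg,
        None,
        label=f"ddG({a.compound_id}@{a.target_id} vs {b.compound_id}@{b.target_id})",
    )


def ddG_to_kd_fold(ddG: FreeEnergy, temperature: float) -> float:
    """Fold-change in K_D equivalent to a free-energy difference.

    Returns ``exp(ΔΔG / RT)`` — 1 for ΔΔG = 0, monotone increasing.
    """
    if not (math.isfinite(temperature) and temperature > 0):
        raise InvalidInputError(f"temperature must be positive, got {temperature}")
    return math.exp(ddG.value / (R_KCAL * temperature))


# ---------------------------------------------------------------------------
# Tabular interface

_TABLE_COLUMNS = ["compound_id", "target_id", "ic50_value", "ic50_unit", "temperature_K"]


def read_affinity_table(path: str | Path) -> list[AffinityMeasurement]:
    """Read a TSV with columns compound_id, target_id, ic50_value, ic50_unit,
    temperature_K into measurements."""
    df = pd.read_csv(path, sep="\t", dtype={"ic50_unit": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"affinity table {path} lacks columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        if pd.isna(row.ic50_unit):
            raise UnitError(
                f"row for {row.compound_id}/{row.target_id} has no ic50_unit"
            )
        out.append(
            AffinityMeasurement.from_value(
                str(row.compound_id),
                str(row.target_id),
                float(row.ic50_value),
                str(row.ic50_unit),
                float(row.temperature_K),
            )
        )
    return out


def affinity_report(measurements: Iterable[AffinityMeasurement]) -> dict:
    """Per-measurement ΔG plus all pairwise ΔΔG / K_D-fold entries.

    Pairs are ordered so that ΔΔG ≥ 0 (weaker binder first); only pairs at
    equal temperature are formed.
    """
    ms = list(measurements)
    rows = [
        {
            "compound_id": m.compound_id,
            "target_id": m.target_id,
            "ic50_molar": m.ic50,
            "temperature_K": m.temperature,
            "dG_kcal_mol": ic50_to_dG(m).value,
        }
        for m in ms
    ]
    pairs = []
    for i, a in enumerate(ms):
        for b in ms[i + 1 :]:
            if a.temperature != b.temperature:
                continue
            weak, strong = (a, b) if a.ic50 >= b.ic50 else (b, a)
            ddg = selectivity_ddG(weak, strong)
            pairs.append(
                {
                    "weaker": f"{weak.compound_id}@{weak.target_id}",
                    "stronger": f"{strong.compound_id}@{strong.target_id}",
                    "ddG_kcal_mol": ddg.value,
                    "kd_fold": ddG_to_kd_fold(ddg, weak.temperature),
                }
            )
    return {"measurements": rows, "pairs": pairs}


def write_affinity_report(report: dict, out_dir: str | Path) -> None:
    """Write the report as machine-precision JSON plus human-readable TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "affinity_report.json").write_text(json.dumps(report, indent=2) + "\n")
    pd.DataFrame(report["measurements"]).to_csv(
        out / "affinity_dG.tsv", sep="\t", index=False, float_format="%.4g"
    )
    if report["pairs"]:
        df = pd.DataFrame(report["pairs"])
        df["ddG_kcal_mol"] = df["ddG_kcal_mol"].map(lambda v: f"{v:.1f}")
        df["kd_fold"] = df["kd_fold"].map(lambda v: f"{v:.3g}")
        df.to_csv(out / "affinity_ddG.tsv", sep="\t", index=False)
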