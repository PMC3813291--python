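"""Ligand-efficiency indices from binding free energies.

Two indices are computed for each fragment:

* ligand efficiency, ``LE = −ΔGb / HAC`` — binding free energy per heavy
  atom, in kcal·mol⁻¹ per atom;
* binding efficiency index, ``BEI = pKi / MW(kDa)`` — with pKi obtained
  from the (docked) free energy through ``ΔG = −RT ln Ki``, i.e.
  ``pKi = −ΔG / (ln 10 · R · T)``.

LE charges every heavy atom equally; BEI weights by mass, so fragments
bearing heavy heteroatoms (sulfur, phosphorus) score differently under the
two indices while C/N/O-only fragments rank nearly identically.

Series are min–max normalized to [0, 1] for joint plotting; binding
energies are normalized on their magnitude so that stronger binding is
larger in every series, and ΔE = BEI_norm − LE_norm highlights where the
two efficiency views disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Gas constant in kcal·mol⁻¹·K⁻¹ (1.987 cal rounding, which reproduces
#: tabulated BEI values computed at 298.15 K to their printed precision).
GAS_CONSTANT_KCAL = 0.001987
STANDARD_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class ThermoConstants:
    """R, T and the derived ΔG→pKi conversion factor c = ln(10)·R·T
    (≈ 1.364 kcal/mol at 298.15 K)."""

    R: float = GAS_CONSTANT_KCAL
    T: float = STANDARD_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def c(self) -> float:
        return math.log(10.0) * self.R * self.T


@dataclass(frozen=True)
class BindingRecord:
    """One binding measurement: id, free energy (kcal/mol, negative =
    favourable), optional experimental IC50 in nM."""

    id: str
    delta_g: float
    ic50_nM: float | tuple[float, float] | None = None
    source: str = "docked"

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise ValueError(f"{self.id}: non-finite binding energy")
        if self.ic50_nM is not None:
            lo, hi = self.ic50_interval()
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{self.id}: IC50 must be positive")

    def ic50_interval(self) -> tuple[float, float]:
        if isinstance(self.ic50_nM, tuple):
            return self.ic50_nM
        return (self.ic50_nM, self.ic50_nM)


@dataclass(frozen=True)
class EfficiencyScores:
    pki: float
    le: float
    bei: float


class DegenerateRangeError(ValueError):
    """Raised when a series cannot be min–max normalized."""


def delta_g_to_pki(delta_g: float, constants: ThermoConstants | None = None) -> float:
    """pKi = −ΔG / (ln 10 · R · T)."""
    constants = constants or ThermoConstants()
    return -delta_g / constants.c


def ligand_efficiency(delta_g: float, hac: int) -> float:
    """LE = −ΔG / HAC, in kcal/mol per heavy atom."""
    if hac < 1:
        raise ValueError(f"heavy atom count must be >= 1, got {hac}")
    return -delta_g / hac


def binding_efficiency_index(pki: float, mw: float) -> float:
    """BEI = pKi / MW with MW expressed in kDa."""
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return pki / (mw / 1000.0)


def score_fragments(
    records: list[BindingRecord],
    descriptors: dict[str, "object"],
    constants: ThermoConstants | None = None,
) -> dict[str, EfficiencyScores]:
    """pKi, LE and BEI for every binding record.

    ``descriptors`` maps record id to any object exposing ``hac`` and ``mw``
    attributes.  Records without a descriptor set are an error.
    """
    constants = constants or ThermoConstants()
    missing = [r.id for r in records if r.id not in descriptors]
    if missing:
        raise KeyError(f"missing descriptors for: {', '.join(missing)}")
    out: dict[str, EfficiencyScores] = {}
    for r in records:
        d = descriptors[r.id]
        pki = delta_g_to_pki(r.delta_g, constants)
        out[r.id] = EfficiencyScores(
            pki=pki,
            le=ligand_efficiency(r.delta_g, d.hac),
            bei=binding_efficiency_index(pki, d.mw),
        )
    return out


def normalize_series(values: list[float], magnitude: bool = False) -> list[float]:
    """Min–max scale a series to [0, 1].

    With ``magnitude=True`` the absolute values are scaled (used for binding
    energies, so that stronger binding maps to 1).  A constant series has no
    range and raises :class:`DegenerateRangeError`.
    """
    if len(values) < 2:
        raise DegenerateRangeError("need at least 2 values to normalize")
    vals = [abs(v) for v in values] if magnitude else list(values)
    lo, hi = min(vals), max(vals)
    if hi == lo:
        raise DegenerateRangeError("constant series cannot be normalized")
    return [(v - lo) / (hi - lo) for v in vals]


def delta_e_series(norm_bei: list[float], norm_le: list[float]) -> list[float]:
    """Elementwise BEI_norm − LE_norm for id-paired series."""
    if len(norm_bei) != len(norm_le):
        raise ValueError(
            f"series length mismatch: {len(norm_bei)} vs {len(norm_le)}"
        )
    return [b - l for b, l in zip(norm_bei, norm_le)]
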