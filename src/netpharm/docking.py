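"""Docking-record post-processing: binding energy to inhibition constant.

Binding free energies ΔG (kcal/mol, as reported by AutoDock-family
scorers) are converted to inhibition constants via

    Ki = exp(ΔG / (R T)),

with R = 1.98720 cal mol⁻¹ K⁻¹ and T = 298.15 K by default, reported in
µmol/L.  ΔG below -5 kcal/mol is flagged as stable docking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT_CAL",
    "STANDARD_TEMPERATURE_K",
    "STABLE_DOCKING_CUTOFF",
    "DockingRecord",
    "DockingSummary",
    "ki_from_energy",
    "summarize_docking",
]

GAS_CONSTANT_CAL = 1.98720  # cal / (mol K)
STANDARD_TEMPERATURE_K = 298.15
STABLE_DOCKING_CUTOFF = -5.0  # kcal/mol


@dataclass(frozen=True)
class DockingRecord:
    """One receptor-ligand docking outcome.

    ``delta_g`` is the binding free energy in kcal/mol (negative for
    binders); ``ki`` the inhibition constant in µmol/L, computed from
    ``delta_g`` when not supplied.
    """

    receptor: str
    ligand: str
    delta_g: float
    ki: float | None = None

    def __post_init__(self) -> None:
        if self.ki is None:
            object.__setattr__(self, "ki", ki_from_energy(self.delta_g))
        if self.ki <= 0:
            raise ValueError("inhibition constant must be positive")

    @property
    def stable(self) -> bool:
        return self.delta_g < STABLE_DOCKING_CUTOFF


@dataclass(frozen=True)
class DockingSummary:
    min_delta_g: float
    max_delta_g: float
    min_ki: float
    max_ki: float
    best_ligand_per_receptor: dict[str, str]
    n_stable: int
    n_records: int


def ki_from_energy(
    delta_g: float, temperature: float = STANDARD_TEMPERATURE_K
) -> float:
    """Ki in µmol/L from ΔG in kcal/mol: 1e6 · exp(1000·ΔG / (R·T)).

    Strictly increasing in ΔG; ΔG = 0 gives 1 mol/L (1e6 µmol/L).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1e6 * math.exp(delta_g * 1000.0 / (GAS_CONSTANT_CAL * temperature))


def summarize_docking(records: list[DockingRecord]) -> DockingSummary:
    """Exact ΔG and Ki extrema, the lowest-energy ligand per receptor and
    the count of stable (ΔG < -5 kcal/mol) dockings."""
    if not records:
        raise ValueError("no docking records to summarize")
    best: dict[str, DockingRecord] = {}
    for record in records:
        incumbent = best.get(record.receptor)
        if incumbent is None or record.delta_g < incumbent.delta_g:
            best[record.receptor] = record
    return DockingSummary(
        min_delta_g=min(r.delta_g for r in records),
        max_delta_g=max(r.delta_g for r in records),
        min_ki=min(r.ki for r in records),
        max_ki=max(r.ki for r in records),
        best_ligand_per_receptor={rec: r.ligand for rec, r in sorted(best.items())},
        n_stable=sum(r.stable for r in records),
        n_records=len(records),
    )
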