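"""Small bundled example datasets.

``djd_docking_table`` holds published AutoDock Vina binding free energies
(kcal/mol) for 14 receptor-ligand pairs from the Duhuo Jisheng Decoction /
intervertebral disc degeneration study system: key disease targets docked
against the formula's principal flavonoids and terpenoids.  Only the
energies are data; inhibition constants are always recomputed from them.
"""

from __future__ import annotations

from .docking import DockingRecord

__all__ = ["djd_docking_table"]

_DJD_DOCKING_ROWS: tuple[tuple[str, str, float], ...] = (
    ("AKT1", "Kaempferol", -7.04),
    ("AKT1", "Quercetin", -7.23),
    ("PIK3R1", "Quercetin", -6.12),
    ("ESR1", "Myricanone", -8.16),
    ("MYC", "Quercetin", -5.96),
    ("NR3C1", "Wallichilide", -10.44),
    ("IL1B", "Quercetin", -8.28),
    ("TP53", "Quercetin", -6.67),
    ("ERRB2", "Quercetin", -5.12),
    ("CAV1", "Quercetin", -5.5),
    ("AR", "Kaempferol", -8.26),
    ("IGF2", "Quercetin", -5.15),
    ("ALB", "Beta-Carotene", -12.61),
    ("CTNNB1", "Beta-Carotene", -8.43),
)


def djd_docking_table() -> list[DockingRecord]:
    """The 14 bundled receptor-ligand docking energies, Ki recomputed."""
    return [
        DockingRecord(receptor=r, ligand=l, delta_g=dg)
        for r, l, dg in _DJD_DOCKING_ROWS
    ]
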