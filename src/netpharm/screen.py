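"""ADMET screening of herbal compounds.

The oral-potential / drug-likeness filter keeps a compound when it has
either oral bioavailability (OB) above 30% or an acceptable Lipinski
rule-of-five profile, and additionally Caco-2 permeability > 0.4,
drug-likeness (DL) > 0.18 and half-life > 3 h.  All thresholds are strict
inequalities and all are overridable.

Toxicity endpoint labels (hepatotoxicity, carcinogenicity, immunotoxicity,
mutagenicity, cytotoxicity, cardiotoxicity) arrive as predictions in the
input table and are only summarized, never filtered on; the same holds for
acute oral toxicity (LD50).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "TOXICITY_ENDPOINTS",
    "ToxicityCall",
    "CompoundRecord",
    "ScreenThresholds",
    "COMPOUND_SCHEMA",
    "passes_ro5",
    "passes_screen",
    "screen_compounds",
    "summarize_toxicity",
    "compound_to_row",
    "compound_from_row",
]

TOXICITY_ENDPOINTS = (
    "hepatotoxicity",
    "carcinogenicity",
    "immunotoxicity",
    "mutagenicity",
    "cytotoxicity",
    "cardiotoxicity",
)


@dataclass(frozen=True)
class ToxicityCall:
    """A predicted toxicity endpoint label with its confidence."""

    label: str  # "active" | "inactive"
    probability: float

    def __post_init__(self) -> None:
        if self.label not in ("active", "inactive"):
            raise ValueError(f"unknown toxicity label {self.label!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("toxicity probability outside [0, 1]")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with its structural and ADMET descriptors.

    ``mw`` is the molecular weight in Da, ``alogp`` the computed
    octanol-water partition coefficient, ``h_donors``/``h_acceptors`` the
    hydrogen-bond donor/acceptor counts, ``ob`` the oral bioavailability in
    percent, ``caco2`` the Caco-2 permeability index, ``dl`` the
    drug-likeness index on [0, 1] and ``half_life`` hours.  ``ld50`` is the
    predicted acute oral toxicity in mg/kg (optional).
    """

    compound_id: str
    name: str
    herb_ids: frozenset[str]
    mw: float
    alogp: float
    h_donors: int
    h_acceptors: int
    ob: float
    caco2: float
    dl: float
    half_life: float
    toxicity: dict[str, ToxicityCall] = field(default_factory=dict)
    ld50: float | None = None

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.compound_id}: molecular weight must be positive")
        if self.h_donors < 0 or self.h_acceptors < 0:
            raise ValueError(f"{self.compound_id}: H-bond counts must be >= 0")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.compound_id}: drug-likeness outside [0, 1]")
        if not self.herb_ids:
            raise ValueError(f"{self.compound_id}: herb membership must be non-empty")
        for endpoint in self.toxicity:
            if endpoint not in TOXICITY_ENDPOINTS:
                raise ValueError(f"{self.compound_id}: unknown toxicity endpoint {endpoint!r}")


@dataclass(frozen=True)
class ScreenThresholds:
    """Strict lower bounds of the ADMET filter (defaults: 30 / 0.4 / 0.18 / 3)."""

    ob: float = 30.0
    caco2: float = 0.4
    dl: float = 0.18
    half_life: float = 3.0
    max_ro5_violations: int = 1


def passes_ro5(compound: CompoundRecord, max_violations: int = 1) -> bool:
    """Lipinski rule of five: count violations among MW > 500, AlogP > 5,
    H-donors > 5, H-acceptors > 10; pass iff violations <= ``max_violations``.

    The conventional rule tolerates one violation; set ``max_violations=0``
    for the strict variant.
    """
    violations = sum(
        (
            compound.mw > 500,
            compound.alogp > 5,
            compound.h_donors > 5,
            compound.h_acceptors > 10,
        )
    )
    return violations <= max_violations


def passes_screen(
    compound: CompoundRecord, thresholds: ScreenThresholds = ScreenThresholds()
) -> bool:
    """True iff (OB > 30 or RO5-compliant) and Caco-2 > 0.4 and DL > 0.18
    and half-life > 3 h (all strict, all overridable)."""
    oral_potential = compound.ob > thresholds.ob or passes_ro5(
        compound, thresholds.max_ro5_violations
    )
    return (
        oral_potential
        and compound.caco2 > thresholds.caco2
        and compound.dl > thresholds.dl
        and compound.half_life > thresholds.half_life
    )


def screen_compounds(
    compounds: list[CompoundRecord], thresholds: ScreenThresholds = ScreenThresholds()
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Apply the filter, preserving input order.

    Returns the kept compounds and a per-criterion failure count; a compound
    failing several criteria is counted once under each.
    """
    kept: list[CompoundRecord] = []
    report: Counter[str] = Counter(
        {"oral_potential": 0, "caco2": 0, "dl": 0, "half_life": 0}
    )
    for compound in compounds:
        ok = True
        if not (
            compound.ob > thresholds.ob
            or passes_ro5(compound, thresholds.max_ro5_violations)
        ):
            report["oral_potential"] += 1
            ok = False
        if not compound.caco2 > thresholds.caco2:
            report["caco2"] += 1
            ok = False
        if not compound.dl > thresholds.dl:
            report["dl"] += 1
            ok = False
        if not compound.half_life > thresholds.half_life:
            report["half_life"] += 1
            ok = False
        if ok:
            kept.append(compound)
    return kept, dict(report)


def _compound_schema():
    from .io import TableSchema  # local import to avoid a cycle at module load

    columns: list[tuple[str, str]] = [
        ("compound_id", "text"),
        ("name", "text"),
        ("herbs", "text"),
        ("mw", "number"),
        ("alogp", "number"),
        ("h_donors", "integer"),
        ("h_acceptors", "integer"),
        ("ob", "number"),
        ("caco2", "number"),
        ("dl", "number"),
        ("half_life", "number"),
    ]
    for endpoint in TOXICITY_ENDPOINTS:
        columns.append((f"tox_{endpoint}", "text"))
        columns.append((f"tox_{endpoint}_p", "probability"))
    columns.append(("ld50", "number"))
    return TableSchema(name="compounds", required_columns=tuple(columns))


COMPOUND_SCHEMA = _compound_schema()


def compound_to_row(compound: CompoundRecord) -> dict:
    """Flatten a compound record into one table row (herbs comma-joined)."""
    row = {
        "compound_id": compound.compound_id,
        "name": compound.name,
        "herbs": ",".join(sorted(compound.herb_ids)),
        "mw": compound.mw,
        "alogp": compound.alogp,
        "h_donors": compound.h_donors,
        "h_acceptors": compound.h_acceptors,
        "ob": compound.ob,
        "caco2": compound.caco2,
        "dl": compound.dl,
        "half_life": compound.half_life,
        "ld50": compound.ld50 if compound.ld50 is not None else float("nan"),
    }
    for endpoint in TOXICITY_ENDPOINTS:
        call = compound.toxicity.get(endpoint)
        row[f"tox_{endpoint}"] = call.label if call else "inactive"
        row[f"tox_{endpoint}_p"] = call.probability if call else 0.0
    return row


def compound_from_row(row: dict) -> CompoundRecord:
    """Rebuild a compound record from a table row parsed with COMPOUND_SCHEMA."""
    toxicity = {
        endpoint: ToxicityCall(
            label=row[f"tox_{endpoint}"], probability=row[f"tox_{endpoint}_p"]
        )
        for endpoint in TOXICITY_ENDPOINTS
    }
    ld50 = row["ld50"]
    return CompoundRecord(
        compound_id=row["compound_id"],
        name=row["name"],
        herb_ids=frozenset(h for h in row["herbs"].split(",") if h),
        mw=row["mw"],
        alogp=row["alogp"],
        h_donors=row["h_donors"],
        h_acceptors=row["h_acceptors"],
        ob=row["ob"],
        caco2=row["caco2"],
        dl=row["dl"],
        half_life=row["half_life"],
        toxicity=toxicity,
        ld50=None if ld50 != ld50 else ld50,  # NaN round-trips to None
    )


def summarize_toxicity(compounds: list[CompoundRecord]) -> dict[str, int]:
    """Count compounds with an *active* call per endpoint; every known
    endpoint appears in the output, with 0 when no compound is active."""
    counts = {endpoint: 0 for endpoint in TOXICITY_ENDPOINTS}
    for compound in compounds:
        for endpoint, call in compound.toxicity.items():
            if call.label == "active":
                counts[endpoint] += 1
    return counts
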