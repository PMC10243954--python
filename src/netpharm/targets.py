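"""Assembly of drug targets, disease targets and their intersection.

Drug targets come from compound-target association tables filtered on a
prediction probability; disease targets from two score-ranked sources, the
first (GeneCards-style) truncated to its top fraction by relevance score,
the second (DisGeNET-style) taken whole.  The common-target set feeds every
downstream network stage.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from .io import GeneSet, canonical_gene
from .screen import CompoundRecord

__all__ = [
    "TargetAssociation",
    "DiseaseGeneRecord",
    "CompoundAlias",
    "drug_targets",
    "disease_targets",
    "common_targets",
    "label_pathway_members",
    "assign_aliases",
]


@dataclass(frozen=True)
class TargetAssociation:
    """A predicted compound-target link with its prediction probability."""

    compound_id: str
    gene: str
    probability: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"{self.compound_id}->{self.gene}: probability outside [0, 1]"
            )


@dataclass(frozen=True)
class DiseaseGeneRecord:
    """A disease-associated gene with a relevance score from one source."""

    gene: str
    score: float
    source: Literal["genecards", "disgenet"]

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"{self.gene}: relevance score must be >= 0")
        if self.source not in ("genecards", "disgenet"):
            raise ValueError(f"{self.gene}: unknown source {self.source!r}")


@dataclass(frozen=True)
class CompoundAlias:
    """Display label for a compound: a single letter when the compound is
    shared by two or more herbs, otherwise herb abbreviation + index."""

    compound_id: str
    label: str


def drug_targets(
    assocs: Iterable[TargetAssociation], min_probability: float = 0.8
) -> set[str]:
    """Genes with at least one association probability strictly above
    ``min_probability`` (default 0.8), deduplicated."""
    return {
        canonical_gene(a.gene) for a in assocs if a.probability > min_probability
    }


def disease_targets(
    records: Iterable[DiseaseGeneRecord], genecards_top_fraction: float = 0.5
) -> set[str]:
    """Union of the top-fraction score-ranked GeneCards genes with all
    DisGeNET genes.

    GeneCards records are sorted by (score descending, gene ascending) and
    the first ``ceil(fraction * N)`` kept; the alphabetical tie-break makes
    the cut deterministic.
    """
    if not 0.0 < genecards_top_fraction <= 1.0:
        raise ValueError("genecards_top_fraction must be in (0, 1]")
    genecards = sorted(
        (r for r in records if r.source == "genecards"),
        key=lambda r: (-r.score, canonical_gene(r.gene)),
    )
    n_keep = math.ceil(genecards_top_fraction * len(genecards))
    kept = {canonical_gene(r.gene) for r in genecards[:n_keep]}
    kept |= {
        canonical_gene(r.gene) for r in records if r.source == "disgenet"
    }
    return kept


def common_targets(drug: set[str], disease: set[str]) -> list[str]:
    """Sorted intersection of drug and disease target sets; an empty
    intersection is returned with a warning (downstream stages refuse it)."""
    common = sorted({canonical_gene(g) for g in drug} & {canonical_gene(g) for g in disease})
    if not common:
        warnings.warn("drug and disease target sets are disjoint", stacklevel=2)
    return common


def label_pathway_members(
    common: Iterable[str], pathways: Iterable[GeneSet]
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Map every common gene to the pathway ids containing it (possibly
    empty) and report members per pathway."""
    pathways = list(pathways)
    labels: dict[str, list[str]] = {}
    for gene in common:
        gene = canonical_gene(gene)
        labels[gene] = [p.id for p in pathways if gene in p.genes]
    counts = {
        p.id: sum(1 for members in labels.values() if p.id in members) for p in pathways
    }
    return labels, counts


def assign_aliases(
    compounds: Iterable[CompoundRecord],
    herb_codes: Mapping[str, str],
    override: Mapping[str, str] | None = None,
    allow_double_letters: bool = False,
) -> list[CompoundAlias]:
    """Assign display labels following the shared/unique convention.

    Compounds occurring in >= 2 herbs receive letters A, B, C, ... in
    (descending herb count, compound_id ascending) order; herb-unique
    compounds receive ``<herb abbreviation><1-based index>`` in compound_id
    order within each herb.  ``override`` pins chosen compound_ids to
    published labels; remaining labels are assigned around it.
    """
    compounds = list(compounds)
    override = dict(override or {})
    for compound in compounds:
        for herb in compound.herb_ids:
            if herb not in herb_codes:
                raise ValueError(f"no abbreviation for herb {herb!r}")

    shared = sorted(
        (c for c in compounds if len(c.herb_ids) >= 2),
        key=lambda c: (-len(c.herb_ids), c.compound_id),
    )
    letters = list(string.ascii_uppercase)
    if allow_double_letters:
        letters += [a + b for a in string.ascii_uppercase for b in string.ascii_uppercase]
    available = [c for c in letters if c not in override.values()]
    aliases: dict[str, str] = {}
    cursor = 0
    for compound in shared:
        if compound.compound_id in override:
            aliases[compound.compound_id] = override[compound.compound_id]
            continue
        if cursor >= len(available):
            raise ValueError(
                "letter labels exhausted; enable allow_double_letters"
            )
        aliases[compound.compound_id] = available[cursor]
        cursor += 1

    unique = [c for c in compounds if len(c.herb_ids) == 1]
    per_herb_counter: dict[str, int] = {}
    for compound in sorted(unique, key=lambda c: c.compound_id):
        (herb,) = compound.herb_ids
        if compound.compound_id in override:
            aliases[compound.compound_id] = override[compound.compound_id]
            continue
        per_herb_counter[herb] = per_herb_counter.get(herb, 0) + 1
        aliases[compound.compound_id] = f"{herb_codes[herb]}{per_herb_counter[herb]}"

    labels = list(aliases.values())
    if len(set(labels)) != len(labels):
        raise ValueError("alias labels are not unique (check override map)")
    return [CompoundAlias(c.compound_id, aliases[c.compound_id]) for c in compounds]
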