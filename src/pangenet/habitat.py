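"""Habitat-level gene-set algebra and pathway-completeness screens.

Genomes are grouped by isolation habitat (groups with fewer than three
genomes are excluded by default, as is usual when a habitat needs enough
representatives to define a core).  On top of a family x genome
presence/absence matrix the module derives:

* the **habitat core** — families present in every genome of a habitat;
* **habitat-specific** families — a habitat's core minus the other habitats'
  cores (default), or minus *all* gene content of the other habitats'
  genomes (strict mode);
* the **cloud content** — families whose genome incidence spans at most
  ``max_habitats`` habitats (2 by default).

Pathway completeness is a symbol screen: a genome's annotated gene symbols
are compared case-insensitively against a pathway's required gene list.
Definitions for the three environmental sulfur-assimilation routes
(sulfate/thiosulfate via cysPAUW, alkanesulfonate via ssuABCD, taurine via
tauABCD) and for ectoine biosynthesis (ectABC, with ectD extending to
hydroxyectoine) are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class HabitatGrouping:
    """Habitat label -> genome ids, with a minimum group size."""

    groups: dict[str, list[str]]
    min_genomes: int = 3

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for habitat, members in self.groups.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"genomes assigned to more than one habitat: {sorted(overlap)}")
            seen |= set(members)
        self.groups = {
            h: list(m) for h, m in self.groups.items() if len(m) >= self.min_genomes
        }

    @classmethod
    def from_habitat_map(
        cls, habitat_map: Mapping[str, str | None], min_genomes: int = 3
    ) -> "HabitatGrouping":
        """Build from a genome_id -> habitat map; unassigned genomes are dropped."""
        groups: dict[str, list[str]] = {}
        for genome_id, habitat in habitat_map.items():
            if habitat:
                groups.setdefault(habitat, []).append(genome_id)
        return cls(groups, min_genomes=min_genomes)

    @property
    def habitats(self) -> list[str]:
        return sorted(self.groups)

    def genomes(self, habitat: str) -> list[str]:
        if habitat not in self.groups:
            raise KeyError(f"unknown or excluded habitat: {habitat!r}")
        return self.groups[habitat]


def habitat_core(matrix: pd.DataFrame, grouping: HabitatGrouping, habitat: str) -> set[str]:
    """Families present in every genome of ``habitat``."""
    members = grouping.genomes(habitat)
    sub = matrix[members]
    return set(matrix.index[sub.all(axis=1)])


def habitat_specific(
    matrix: pd.DataFrame, grouping: HabitatGrouping, mode: str = "core"
) -> dict[str, set[str]]:
    """Habitat-specific families for every habitat.

    ``mode="core"`` subtracts the union of the *cores* of the other habitats;
    ``mode="strict"`` subtracts the union of *all* gene content carried by
    any genome of the other habitats.  Strict sets are always subsets of the
    core-mode sets.
    """
    if len(grouping.habitats) < 2:
        raise ValueError("habitat specificity needs at least two habitats")
    cores = {h: habitat_core(matrix, grouping, h) for h in grouping.habitats}
    specific: dict[str, set[str]] = {}
    for habitat in grouping.habitats:
        others = [h for h in grouping.habitats if h != habitat]
        if mode == "core":
            exclude: set[str] = set().union(*(cores[h] for h in others))
        elif mode == "strict":
            other_genomes = [g for h in others for g in grouping.genomes(h)]
            sub = matrix[other_genomes]
            exclude = set(matrix.index[sub.any(axis=1)])
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        specific[habitat] = cores[habitat] - exclude
    return specific


def cloud_content(
    matrix: pd.DataFrame, grouping: HabitatGrouping, max_habitats: int = 2
) -> set[str]:
    """Families whose genome incidence spans at most ``max_habitats`` habitats."""
    habitat_of = {g: h for h in grouping.habitats for g in grouping.genomes(h)}
    cloud = set()
    for family in matrix.index:
        present = matrix.columns[matrix.loc[family].astype(bool)]
        spanned = {habitat_of[g] for g in present if g in habitat_of}
        if len(spanned) <= max_habitats:
            cloud.add(family)
    return cloud


# ---------------------------------------------------------------------------
# pathway completeness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    required_genes: tuple[str, ...]
    optional_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.required_genes:
            raise ValueError("a pathway needs at least one required gene")


@dataclass(frozen=True)
class PathwayStatus:
    status: str                    # "complete" | "partial" | "absent"
    missing: tuple[str, ...]       # required genes not found

    def __str__(self) -> str:
        if self.status == "partial":
            return f"partial (missing {', '.join(self.missing)})"
        return self.status


SULFATE_ASSIMILATION = PathwayDefinition(
    "sulfate_assimilation",
    required_genes=("cysP", "cysA", "cysU", "cysW", "cysD", "cysNC", "cysE", "cysK", "cysQ"),
)
ALKANESULFONATE_ASSIMILATION = PathwayDefinition(
    "alkanesulfonate_assimilation", required_genes=("ssuA", "ssuB", "ssuC", "ssuD"))
TAURINE_ASSIMILATION = PathwayDefinition(
    "taurine_assimilation", required_genes=("tauA", "tauB", "tauC", "tauD"))
ECTOINE_BIOSYNTHESIS = PathwayDefinition(
    "ectoine_biosynthesis", required_genes=("ectA", "ectB", "ectC"), optional_genes=("ectD",))

BUNDLED_PATHWAYS = (
    SULFATE_ASSIMILATION,
    ALKANESULFONATE_ASSIMILATION,
    TAURINE_ASSIMILATION,
    ECTOINE_BIOSYNTHESIS,
)


def pathway_completeness(
    genome_gene_symbols: Iterable[str], pathway: PathwayDefinition
) -> PathwayStatus:
    """Classify a genome's pathway as complete, partial or absent.

    Matching is exact and case-insensitive on gene symbols.  ``complete``
    means every required gene is present; ``partial`` some but not all (the
    missing ones are reported); ``absent`` none.
    """
    have = {s.lower() for s in genome_gene_symbols}
    missing = tuple(g for g in pathway.required_genes if g.lower() not in have)
    if not missing:
        return PathwayStatus("complete", ())
    if len(missing) == len(pathway.required_genes):
        return PathwayStatus("absent", missing)
    return PathwayStatus("partial", missing)


def pathway_report(
    symbols_by_genome: Mapping[str, Iterable[str]],
    pathways: Iterable[PathwayDefinition] = BUNDLED_PATHWAYS,
) -> pd.DataFrame:
    """Completeness status of each pathway in each genome, as a tidy table."""
    rows = []
    for genome_id, symbols in symbols_by_genome.items():
        symbols = list(symbols)
        for pathway in pathways:
            result = pathway_completeness(symbols, pathway)
            rows.append((genome_id, pathway.pathway_id, result.status, ";".join(result.missing)))
    return pd.DataFrame(rows, columns=["genome_id", "pathway_id", "status", "missing"])
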