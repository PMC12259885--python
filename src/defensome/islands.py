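"""Defense-island detection and island-level statistics.

A defense island is an array of defense genes on one contig in which
consecutive defense genes are separated by at most ``max_gap`` intervening
non-defense genes, containing at least ``min_def_genes`` defense genes from
at least ``min_families`` distinct defense families.  Chains are maximal: a
chain closes only when the next defense gene exceeds the gap limit or the
contig ends, so islands can never overlap and never cross contigs.

"Separated by 10 genes or less" is read as <= 10 intervening non-defense
genes (index difference <= 11).  The stricter alternative (index difference
<= 10) is available as ``gap_semantics="index-diff"`` for sensitivity
analysis.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .errors import DataError
from .io import DefenseSystemRecord, GenomeAnnotation


@dataclass(slots=True)
class DefenseIsland:
    genome_id: str
    contig_id: str
    first_index: int
    last_index: int
    defense_gene_ids: tuple[str, ...]
    families: frozenset[str]
    systems: frozenset[str]            # >= 1 member gene inside the span
    systems_contained: frozenset[str]  # all member genes inside the span

    @property
    def span_genes(self) -> int:
        return self.last_index - self.first_index + 1

    @property
    def n_defense(self) -> int:
        return len(self.defense_gene_ids)


def _gene_family_map(systems: list[DefenseSystemRecord]
                     ) -> dict[str, set[str]]:
    fams: dict[str, set[str]] = defaultdict(set)
    for s in systems:
        for g in s.gene_ids:
            fams[g].add(s.family)
    return fams


def detect_islands(genome: GenomeAnnotation, max_gap: int = 10,
                   min_def_genes: int = 5, min_families: int = 3,
                   gap_semantics: str = "intervening") -> list[DefenseIsland]:
    """Detect defense islands on every contig of one genome.

    Defense genes (system members) are chained greedily in index order while
    the gap criterion holds; maximal chains are kept iff they contain
    ``min_def_genes`` defense genes from ``min_families`` families.  Output
    is sorted by (contig, first_index).
    """
    if gap_semantics == "intervening":
        max_index_diff = max_gap + 1
    elif gap_semantics == "index-diff":
        max_index_diff = max_gap
    else:
        raise DataError(f"unknown gap_semantics {gap_semantics!r}")

    gene_families = _gene_family_map(genome.systems)
    if not gene_families:
        return []
    lookup = genome.genes_by_id()
    missing = [g for g in gene_families if g not in lookup]
    if missing:
        raise DataError(
            f"{genome.genome_id}: system member gene(s) without gene records: "
            f"{sorted(missing)[:5]}")

    # defense genes grouped by contig, in index order
    by_contig: dict[str, list] = defaultdict(list)
    for gid in gene_families:
        g = lookup[gid]
        by_contig[g.contig_id].append(g)

    # which systems touch which contig, with member index ranges
    sys_on_contig: dict[str, list[DefenseSystemRecord]] = defaultdict(list)
    for s in genome.systems:
        sys_on_contig[lookup[s.gene_ids[0]].contig_id].append(s)

    islands: list[DefenseIsland] = []
    for contig in sorted(by_contig):
        genes = sorted(by_contig[contig], key=lambda g: g.index)
        chains: list[list] = [[genes[0]]]
        for g in genes[1:]:
            if g.index - chains[-1][-1].index <= max_index_diff:
                chains[-1].append(g)
            else:
                chains.append([g])
        for chain in chains:
            fams = frozenset().union(*(gene_families[g.gene_id] for g in chain))
            if len(chain) < min_def_genes or len(fams) < min_families:
                continue
            first, last = chain[0].index, chain[-1].index
            touching, contained = set(), set()
            for s in sys_on_contig[contig]:
                idxs = [lookup[g].index for g in s.gene_ids]
                if any(first <= i <= last for i in idxs):
                    touching.add(s.system_id)
                    if all(first <= i <= last for i in idxs):
                        contained.add(s.system_id)
            islands.append(DefenseIsland(
                genome_id=genome.genome_id, contig_id=contig,
                first_index=first, last_index=last,
                defense_gene_ids=tuple(g.gene_id for g in chain),
                families=fams, systems=frozenset(touching),
                systems_contained=frozenset(contained)))
    islands.sort(key=lambda i: (i.contig_id, i.first_index))
    return islands


def detect_islands_cohort(cohort: list[GenomeAnnotation], **kwargs
                          ) -> list[DefenseIsland]:
    out: list[DefenseIsland] = []
    for ga in cohort:
        out.extend(detect_islands(ga, **kwargs))
    return out


@dataclass(slots=True)
class IslandCensus:
    """Cohort-level island tally.

    ``proportion_pct`` is the percentage of genes inside islands that are
    defense genes (sum n_defense / sum span_genes x 100), ``None`` when no
    islands exist.
    """

    n_islands: int
    total_span_genes: int
    total_defense_genes: int
    proportion_pct: float | None
    defense_per_island: list[int] = field(default_factory=list)
    span_per_island: list[int] = field(default_factory=list)


def island_census(islands: list[DefenseIsland]) -> IslandCensus:
    span = sum(i.span_genes for i in islands)
    ndef = sum(i.n_defense for i in islands)
    return IslandCensus(
        n_islands=len(islands),
        total_span_genes=span,
        total_defense_genes=ndef,
        proportion_pct=(100.0 * ndef / span) if islands else None,
        defense_per_island=[i.n_defense for i in islands],
        span_per_island=[i.span_genes for i in islands])


def island_family_composition(islands: list[DefenseIsland],
                              systems: list[DefenseSystemRecord],
                              first_line: set[str] | frozenset[str],
                              containment: str = "any"
                              ) -> tuple[float, float]:
    """Share of island-resident systems that are first-line vs accessory.

    ``containment="any"`` counts a system as island-resident when >= 1 of
    its member genes lies in an island span; ``"all"`` requires all of them.
    Shares sum to 1; raises when no systems lie in islands.
    """
    if containment == "any":
        resident = {sid for i in islands for sid in i.systems}
    elif containment == "all":
        resident = {sid for i in islands for sid in i.systems_contained}
    else:
        raise DataError(f"unknown containment {containment!r}")
    if not resident:
        raise DataError("no systems inside islands")
    fam_by_id = {s.system_id: s.family for s in systems}
    n_fl = sum(1 for sid in resident if fam_by_id[sid] in first_line)
    return n_fl / len(resident), 1 - n_fl / len(resident)
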