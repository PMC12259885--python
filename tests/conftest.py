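"""Shared fixtures and small cohort builders."""

from __future__ import annotations

import pytest

from defensome.io import (DefenseSystemRecord, GeneRecord, GenomeAnnotation,
                          GenomeQC, MGEInterval)


def make_genome(genome_id="G1", contigs=None, size_bp=None, mges=(),
                traits=None, slot_bp=1000, completeness=95.0,
                contamination=1.0):
    """Build a fully materialized genome from a compact description.

    ``contigs`` maps contig_id -> (n_genes, defense) where defense is a
    list of (index, family) or (index, family, system_id); genes at listed
    indices become members of single-gene systems (or of the shared
    system_id when given), everything else is filler.  Gene i occupies
    bp [i*slot_bp+1, i*slot_bp+900].
    """
    contigs = contigs or {"c1": (20, [])}
    genes, systems = [], []
    sys_members: dict[str, list] = {}
    sys_family: dict[str, str] = {}
    n_total_genes = 0
    for contig_id, (n_genes, defense) in contigs.items():
        n_total_genes += n_genes
        defense_map = {}
        for item in defense:
            idx, family = item[0], item[1]
            sys_id = (item[2] if len(item) > 2
                      else f"{genome_id}_{contig_id}_s{idx}")
            defense_map[idx] = (family, sys_id)
        for idx in range(n_genes):
            start = idx * slot_bp + 1
            gid = f"{genome_id}|{contig_id}|{idx:05d}"
            genes.append(GeneRecord(
                gene_id=gid, genome_id=genome_id, contig_id=contig_id,
                index=idx, start=start, end=start + 899, strand="+"))
            if idx in defense_map:
                family, sys_id = defense_map[idx]
                sys_members.setdefault(sys_id, []).append(gid)
                sys_family[sys_id] = family
    for sys_id, members in sys_members.items():
        systems.append(DefenseSystemRecord(
            system_id=sys_id, genome_id=genome_id,
            family=sys_family[sys_id], gene_ids=tuple(members)))
    size = size_bp if size_bp is not None else n_total_genes * slot_bp
    qc = GenomeQC(genome_id=genome_id, size_bp=size, n50_bp=size,
                  completeness=completeness, contamination=contamination)
    return GenomeAnnotation(qc=qc, genes=genes, systems=systems,
                            mges=list(mges), traits=dict(traits or {}))


def make_mge(genome_id, contig_id, start, end, mge_class, mge_id=None):
    return MGEInterval(
        mge_id=mge_id or f"{contig_id}:{start}-{end}:{mge_class}",
        genome_id=genome_id, contig_id=contig_id, start=start, end=end,
        mge_class=mge_class)


@pytest.fixture
def toy_cohort():
    """Two consistent genomes with a few systems and one MGE."""
    g1 = make_genome("G1", contigs={
        "G1_c1": (40, [(5, "RM", "G1sys_rm"), (6, "RM", "G1sys_rm"),
                       (20, "CBASS")])},
        mges=[make_mge("G1", "G1_c1", 15001, 25000, "plasmid")],
        traits={"ARG": 3, "MRG": 1, "VFG": 0})
    g2 = make_genome("G2", contigs={
        "G2_c1": (30, [(2, "SoFIC")]), "G2_c2": (25, [])},
        traits={"ARG": 7, "MRG": 2, "VFG": 1})
    return [g1, g2]
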