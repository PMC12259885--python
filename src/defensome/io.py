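"""Cohort data model and tabular/sequence I/O.

The unit of analysis is an annotated genome (:class:`GenomeAnnotation`): an
ordered gene table per contig, the defense systems detected on it, mobile
genetic element (MGE) intervals, assembly QC, adaptive-trait counts
(ARG/MRG/VFG) and an optional virus-host abundance ratio.  A *cohort* is a
plain list of :class:`GenomeAnnotation`.

Conventions
-----------
* All tabular files are TSV with a header and ``.`` for missing values.
* Coordinates are 1-based inclusive everywhere in memory and in TSV files
  (GFF convention).  MGE intervals are read from and written to BED, which
  is 0-based half-open; the conversion happens on read/write.
* A gene is a *defense gene* iff it is a member of at least one
  :class:`DefenseSystemRecord`.  A gene may belong to several systems but is
  counted once as a defense gene.
* Family names are opaque, case-sensitive strings; no synonym folding.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import CrossRefError, DataError, RecordError, SchemaError

MGE_CLASSES = ("plasmid", "phage_prophage", "integron", "ice_ime")

_MISSING = "."


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class GeneRecord:
    """One ORF on a contig.

    ``index`` is the 0-based rank of the gene along its contig; island
    detection operates on these ranks, not on bp coordinates.  ``labels``
    holds trait tags such as ``ARG`` or ``anti_defense:<type>``.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    index: int
    start: int
    end: int
    strand: str
    labels: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.start > self.end:
            raise RecordError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise RecordError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(slots=True)
class DefenseSystemRecord:
    """A detected defense system: a family label plus its member genes."""

    system_id: str
    genome_id: str
    family: str
    gene_ids: tuple[str, ...]
    subtype: str | None = None
    effector_type: str | None = None

    def __post_init__(self):
        if not self.gene_ids:
            raise RecordError(f"system {self.system_id}: empty gene list")


@dataclass(slots=True)
class MGEInterval:
    """A mobile genetic element interval (1-based inclusive in memory)."""

    mge_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    mge_class: str

    def __post_init__(self):
        if self.start > self.end:
            raise RecordError(
                f"MGE {self.mge_id}: start {self.start} > end {self.end}")
        if self.mge_class not in MGE_CLASSES:
            raise RecordError(
                f"MGE {self.mge_id}: class {self.mge_class!r} not in {MGE_CLASSES}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(slots=True)
class GenomeQC:
    genome_id: str
    size_bp: int
    n50_bp: int
    completeness: float
    contamination: float
    domain: str | None = None
    phylum: str | None = None
    class_: str | None = None

    def __post_init__(self):
        if self.size_bp <= 0:
            raise RecordError(f"{self.genome_id}: size_bp must be positive")
        if not (0 <= self.completeness <= 100):
            raise RecordError(f"{self.genome_id}: completeness out of [0, 100]")
        if self.contamination < 0:
            raise RecordError(f"{self.genome_id}: negative contamination")


@dataclass(slots=True)
class GenomeAnnotation:
    """One genome's full annotation bundle.

    ``contig_genes`` maps contig id to the number of genes on that contig and
    is authoritative for index ranges.  ``gene_detail`` is ``"full"`` when
    every gene has a record, or ``"sparse"`` when only defense (system
    member) genes were materialized — a memory-saving mode for large
    simulated cohorts; downstream statistics that depend only on gene order
    gaps and counts behave identically in both modes.
    """

    qc: GenomeQC
    genes: list[GeneRecord] = field(default_factory=list)
    systems: list[DefenseSystemRecord] = field(default_factory=list)
    mges: list[MGEInterval] = field(default_factory=list)
    traits: dict[str, int] = field(default_factory=dict)
    vhr: float | None = None
    contig_genes: dict[str, int] = field(default_factory=dict)
    gene_detail: str = "full"

    def __post_init__(self):
        if not self.contig_genes and self.genes:
            counts: Counter[str] = Counter(g.contig_id for g in self.genes)
            self.contig_genes = dict(counts)

    @property
    def genome_id(self) -> str:
        return self.qc.genome_id

    @property
    def n_systems(self) -> int:
        return len(self.systems)

    def genes_by_id(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}

    def defense_gene_ids(self) -> set[str]:
        out: set[str] = set()
        for s in self.systems:
            out.update(s.gene_ids)
        return out


@dataclass(slots=True)
class SequenceRecord:
    """A nucleotide sequence over {A, C, G, T, N}."""

    seq_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise RecordError(f"sequence {self.seq_id}: empty")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise RecordError(
                f"sequence {self.seq_id}: illegal characters {sorted(bad)}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

_GENE_COLS = ("genome_id", "contig_id", "gene_id", "start", "end", "strand")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[_MISSING], comment="#")


def read_gene_table(path) -> list[GeneRecord]:
    """Read a gene table TSV into :class:`GeneRecord` objects.

    Required columns: genome_id, contig_id, gene_id, start, end, strand.
    Optional: index (0-based rank on contig; assigned by start order per
    contig when absent), labels (comma-joined tags).
    Records are returned sorted by (genome_id, contig_id, index).
    """
    df = _read_tsv(path)
    _require_columns(df, _GENE_COLS, f"gene table {path}")
    has_index = "index" in df.columns
    has_labels = "labels" in df.columns

    records: list[GeneRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        start, end = int(row["start"]), int(row["end"])
        if start > end:
            raise RecordError(
                f"gene {row['gene_id']}: start {start} > end {end}", line=i)
        labels: frozenset[str] = frozenset()
        if has_labels and isinstance(row["labels"], str) and row["labels"]:
            labels = frozenset(t for t in row["labels"].split(",") if t)
        idx = (int(row["index"]) if has_index and not pd.isna(row["index"])
               else -1)
        records.append(GeneRecord(
            gene_id=row["gene_id"], genome_id=row["genome_id"],
            contig_id=row["contig_id"], index=idx, start=start, end=end,
            strand=row["strand"], labels=labels))

    if not has_index:
        by_contig: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
        for g in records:
            by_contig[(g.genome_id, g.contig_id)].append(g)
        for genes in by_contig.values():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for k, g in enumerate(genes):
                g.index = k
    records.sort(key=lambda g: (g.genome_id, g.contig_id, g.index))
    return records


def write_gene_table(genes: Iterable[GeneRecord], path) -> None:
    rows = [{
        "genome_id": g.genome_id, "contig_id": g.contig_id,
        "gene_id": g.gene_id, "index": g.index, "start": g.start,
        "end": g.end, "strand": g.strand,
        "labels": ",".join(sorted(g.labels)) if g.labels else _MISSING,
    } for g in genes]
    cols = ["genome_id", "contig_id", "gene_id", "index", "start", "end",
            "strand", "labels"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_defense_systems(path, dialect: str = "native",
                         genome_id: str | None = None) -> list[DefenseSystemRecord]:
    """Read a defense-system table.

    ``dialect="native"`` expects columns system_id, genome_id, family,
    gene_ids (comma-joined), and optional subtype / effector_type.
    ``dialect="defensefinder"`` maps the DefenseFinder systems-table columns
    sys_id -> system_id, type -> family, subtype -> subtype and splits
    ``protein_in_syst`` into gene_ids; genome_id is taken from a genome_id
    column if present, else from the ``genome_id`` argument (DefenseFinder
    output is per-genome).
    """
    df = _read_tsv(path)
    if dialect == "defensefinder":
        _require_columns(df, ("sys_id", "type", "protein_in_syst"),
                         f"DefenseFinder systems table {path}")
        df = df.rename(columns={"sys_id": "system_id", "type": "family",
                                "protein_in_syst": "gene_ids"})
        if "genome_id" not in df.columns:
            if genome_id is None:
                raise SchemaError(
                    f"{path}: DefenseFinder dialect without genome_id column "
                    "requires the genome_id argument")
            df["genome_id"] = genome_id
    elif dialect == "native":
        _require_columns(df, ("system_id", "genome_id", "family", "gene_ids"),
                         f"systems table {path}")
    else:
        raise SchemaError(f"unknown systems-table dialect {dialect!r}")

    records: list[DefenseSystemRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=2):
        sid = row["system_id"]
        if sid in seen:
            raise RecordError(f"duplicate system_id {sid!r}", line=i)
        seen.add(sid)
        gene_ids = tuple(g for g in str(row["gene_ids"]).split(",") if g)
        if not gene_ids:
            raise RecordError(f"system {sid}: empty gene list", line=i)
        subtype = row.get("subtype")
        effector = row.get("effector_type")
        records.append(DefenseSystemRecord(
            system_id=sid, genome_id=row["genome_id"], family=row["family"],
            gene_ids=gene_ids,
            subtype=None if (subtype is None or pd.isna(subtype)) else subtype,
            effector_type=None if (effector is None or pd.isna(effector))
            else effector))
    return records


def write_defense_systems(systems: Iterable[DefenseSystemRecord], path) -> None:
    rows = [{
        "system_id": s.system_id, "genome_id": s.genome_id,
        "family": s.family, "subtype": s.subtype or _MISSING,
        "effector_type": s.effector_type or _MISSING,
        "gene_ids": ",".join(s.gene_ids),
    } for s in systems]
    cols = ["system_id", "genome_id", "family", "subtype", "effector_type",
            "gene_ids"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_mge_bed(path, contig_to_genome: Mapping[str, str]) -> list[MGEInterval]:
    """Read MGE intervals from BED (0-based half-open -> 1-based inclusive).

    The BED name field is either the bare MGE class or ``class|mge_id``.
    When no id is given, a deterministic one is derived from the interval.
    """
    records: list[MGEInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise RecordError("BED line needs >= 4 fields", line=i)
            contig, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if "|" in name:
                mge_class, mge_id = name.split("|", 1)
            else:
                mge_class = name
                mge_id = f"{contig}:{start0 + 1}-{end0}:{mge_class}"
            if contig not in contig_to_genome:
                raise CrossRefError(
                    f"BED line {i}: unknown contig {contig!r}")
            records.append(MGEInterval(
                mge_id=mge_id, genome_id=contig_to_genome[contig],
                contig_id=contig, start=start0 + 1, end=end0,
                mge_class=mge_class))
    return records


def write_mge_bed(mges: Iterable[MGEInterval], path) -> None:
    with open(path, "w") as fh:
        for m in mges:
            fh.write(f"{m.contig_id}\t{m.start - 1}\t{m.end}\t"
                     f"{m.mge_class}|{m.mge_id}\n")


_QC_COLS = ("genome_id", "size_bp", "n50_bp", "completeness", "contamination")


def read_qc_table(path) -> list[GenomeQC]:
    df = _read_tsv(path)
    _require_columns(df, _QC_COLS, f"QC table {path}")

    def _opt(row, key):
        v = row.get(key)
        return None if (v is None or pd.isna(v)) else v

    out = []
    for row in df.to_dict("records"):
        out.append(GenomeQC(
            genome_id=row["genome_id"], size_bp=int(row["size_bp"]),
            n50_bp=int(row["n50_bp"]), completeness=float(row["completeness"]),
            contamination=float(row["contamination"]),
            domain=_opt(row, "domain"), phylum=_opt(row, "phylum"),
            class_=_opt(row, "class_")))
    return out


def write_qc_table(qcs: Iterable[GenomeQC], path) -> None:
    rows = [{
        "genome_id": q.genome_id, "size_bp": q.size_bp, "n50_bp": q.n50_bp,
        "completeness": q.completeness, "contamination": q.contamination,
        "domain": q.domain or _MISSING, "phylum": q.phylum or _MISSING,
        "class_": q.class_ or _MISSING,
    } for q in qcs]
    pd.DataFrame(rows, columns=list(_QC_COLS) + ["domain", "phylum", "class_"]
                 ).to_csv(path, sep="\t", index=False)


def read_traits_table(path) -> dict[str, dict]:
    """Read per-genome trait counts (+ optional vhr) keyed by genome_id."""
    df = _read_tsv(path)
    _require_columns(df, ("genome_id",), f"traits table {path}")
    trait_cols = [c for c in df.columns if c not in ("genome_id", "vhr")]
    out: dict[str, dict] = {}
    for row in df.to_dict("records"):
        traits = {c: int(row[c]) for c in trait_cols}
        if any(v < 0 for v in traits.values()):
            raise RecordError(f"{row['genome_id']}: negative trait count")
        vhr = row.get("vhr")
        out[row["genome_id"]] = {
            "traits": traits,
            "vhr": None if (vhr is None or pd.isna(vhr)) else float(vhr),
        }
    return out


def write_traits_table(cohort: Iterable[GenomeAnnotation], path) -> None:
    trait_names = sorted({t for g in cohort for t in g.traits})
    rows = []
    for g in cohort:
        row = {"genome_id": g.genome_id}
        row.update({t: g.traits.get(t, 0) for t in trait_names})
        row["vhr"] = g.vhr if g.vhr is not None else _MISSING
        rows.append(row)
    pd.DataFrame(rows, columns=["genome_id"] + trait_names + ["vhr"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(seq_id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[SequenceRecord], path) -> None:
    SeqIO.write(
        (_BioSeqRecord(Seq(s.sequence), id=s.seq_id, description="")
         for s in seqs), str(path), "fasta")


# ---------------------------------------------------------------------------
# cohort directory bundle
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[GenomeAnnotation], directory) -> None:
    """Write a cohort as genes.tsv / systems.tsv / mges.bed / qc.tsv / traits.tsv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_gene_table((g for ga in cohort for g in ga.genes), d / "genes.tsv")
    write_defense_systems((s for ga in cohort for s in ga.systems),
                          d / "systems.tsv")
    write_mge_bed((m for ga in cohort for m in ga.mges), d / "mges.bed")
    write_qc_table((ga.qc for ga in cohort), d / "qc.tsv")
    write_traits_table(cohort, d / "traits.tsv")


def read_cohort(directory) -> list[GenomeAnnotation]:
    """Read a cohort directory written by :func:`write_cohort`."""
    d = Path(directory)
    genes = read_gene_table(d / "genes.tsv")
    systems = read_defense_systems(d / "systems.tsv")
    qcs = read_qc_table(d / "qc.tsv")
    traits = read_traits_table(d / "traits.tsv") if (d / "traits.tsv").exists() else {}
    contig_to_genome = {g.contig_id: g.genome_id for g in genes}
    mges = (read_mge_bed(d / "mges.bed", contig_to_genome)
            if (d / "mges.bed").exists() else [])

    genes_by_genome: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in genes:
        genes_by_genome[g.genome_id].append(g)
    systems_by_genome: dict[str, list[DefenseSystemRecord]] = defaultdict(list)
    for s in systems:
        systems_by_genome[s.genome_id].append(s)
    mges_by_genome: dict[str, list[MGEInterval]] = defaultdict(list)
    for m in mges:
        mges_by_genome[m.genome_id].append(m)

    cohort = []
    for qc in qcs:
        tr = traits.get(qc.genome_id, {"traits": {}, "vhr": None})
        cohort.append(GenomeAnnotation(
            qc=qc, genes=genes_by_genome.get(qc.genome_id, []),
            systems=systems_by_genome.get(qc.genome_id, []),
            mges=mges_by_genome.get(qc.genome_id, []),
            traits=tr["traits"], vhr=tr["vhr"]))
    return cohort


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class CohortDiagnostics:
    n_genomes: int
    n_genes: int
    n_systems: int
    n_mges: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort(cohort: list[GenomeAnnotation]) -> CohortDiagnostics:
    """Check cross-references and per-contig index invariants.

    Violations are collected and reported, never raised.  Index contiguity
    (0..n-1 per contig) is only checked on fully materialized genomes.
    """
    violations: list[str] = []
    n_genes = n_systems = n_mges = 0
    for ga in cohort:
        gid = ga.genome_id
        n_genes += len(ga.genes)
        n_systems += len(ga.systems)
        n_mges += len(ga.mges)
        gene_ids = {g.gene_id for g in ga.genes}
        contigs = set(ga.contig_genes) | {g.contig_id for g in ga.genes}

        by_contig: dict[str, list[GeneRecord]] = defaultdict(list)
        for g in ga.genes:
            by_contig[g.contig_id].append(g)
        if ga.gene_detail == "full":
            for contig, genes in by_contig.items():
                idx = sorted(g.index for g in genes)
                if idx != list(range(len(genes))):
                    violations.append(
                        f"{gid}/{contig}: gene indices not 0..{len(genes)-1}")
                in_order = sorted(genes, key=lambda g: g.index)
                if any(a.start > b.start for a, b in zip(in_order, in_order[1:])):
                    violations.append(
                        f"{gid}/{contig}: gene index order disagrees with start order")

        lookup = ga.genes_by_id()
        for s in ga.systems:
            missing = [g for g in s.gene_ids if g not in gene_ids]
            if missing:
                violations.append(
                    f"{gid}: system {s.system_id} references unknown gene(s) "
                    f"{missing}")
                continue
            sys_contigs = {lookup[g].contig_id for g in s.gene_ids}
            if len(sys_contigs) > 1:
                violations.append(
                    f"{gid}: system {s.system_id} spans multiple contigs "
                    f"{sorted(sys_contigs)}")
        for m in ga.mges:
            if m.contig_id not in contigs:
                violations.append(
                    f"{gid}: MGE {m.mge_id} on unknown contig {m.contig_id}")
        for t, v in ga.traits.items():
            if v < 0:
                violations.append(f"{gid}: trait {t} negative ({v})")
    return CohortDiagnostics(
        n_genomes=len(cohort), n_genes=n_genes, n_systems=n_systems,
        n_mges=n_mges, violations=violations)


def cohort_as_dict(cohort: list[GenomeAnnotation]) -> list[dict]:
    """A plain-data view of a cohort (for determinism comparisons)."""
    return [dataclasses.asdict(ga) for ga in cohort]
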