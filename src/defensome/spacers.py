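"""CRISPR spacer-protospacer matching and anti-defense tabulation.

Spacers (25-45 bp) are matched against phage sequences under the filtering
rule *at most ``max_mm`` mismatches and query coverage >= ``min_cov``*.  At
those lengths and thresholds a qualifying alignment is necessarily ungapped
and near full length, so the search is implemented as an exact ungapped
scanner over every window on both strands, not as a wrapper around an
external aligner.  Coverage is computed over the spacer (query); an N in
either sequence never matches.

Overlapping alignments of one spacer at the same phage locus are collapsed
to the single best hit: fewest mismatches, then longest, then leftmost,
then forward strand first.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CrossRefError, DataError
from .io import GeneRecord, SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# spacer N and phage N get distinct codes so N never matches anything
_SPACER_CODE = {c: i for i, c in enumerate("ACGT")} | {"N": 4}
_PHAGE_CODE = {c: i for i, c in enumerate("ACGT")} | {"N": 5}


def _encode(seq: str, table: dict[str, int]) -> np.ndarray:
    return np.frombuffer(
        bytes(table[c] for c in seq), dtype=np.uint8)


@dataclass(slots=True)
class SpacerHit:
    spacer_id: str
    phage_id: str
    phage_start: int   # 1-based, forward strand, left end of the window
    strand: str        # '+' or '-'
    aligned_len: int
    mismatches: int
    coverage: float    # aligned_len / spacer length
    identity: float    # (aligned_len - mismatches) / aligned_len


def _scan_one(spacer: str, phage_fwd: np.ndarray, phage_len: int,
              max_mm: int, min_len: int) -> list[tuple]:
    """All qualifying ungapped alignments of one spacer against one phage.

    Returns raw candidate tuples (mm, -aligned_len, fwd_start0, strand_rank,
    strand, aligned_len) before locus collapse.  Coordinates are 0-based
    on the forward strand.
    """
    L = len(spacer)
    out: list[tuple] = []
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        q_full = _encode(query, _SPACER_CODE)
        for aligned_len in range(L, min_len - 1, -1):
            n_win = phage_len - aligned_len + 1
            if n_win <= 0:
                continue
            for off in range(0, L - aligned_len + 1):
                q = q_full[off:off + aligned_len]
                mm = np.zeros(n_win, dtype=np.int32)
                for j in range(aligned_len):
                    mm += phage_fwd[j:j + n_win] != q[j]
                    # early exit is not worth it at these sizes
                hits = np.flatnonzero(mm <= max_mm)
                for p0 in hits:
                    out.append((int(mm[p0]), -aligned_len, int(p0),
                                0 if strand == "+" else 1, strand,
                                aligned_len))
    return out


def _collapse(cands: list[tuple]) -> list[tuple]:
    """Greedy best-first collapse of overlapping candidate alignments."""
    cands.sort()
    accepted: list[tuple] = []
    taken: list[tuple[int, int]] = []  # [start0, end0) intervals
    for c in cands:
        p0, alen = c[2], c[5]
        if any(p0 < e and p0 + alen > s for s, e in taken):
            continue
        accepted.append(c)
        taken.append((p0, p0 + alen))
    return accepted


def find_protospacers(spacers: list[SequenceRecord],
                      phages: list[SequenceRecord],
                      max_mm: int = 1, min_cov: float = 0.95
                      ) -> list[SpacerHit]:
    """Match every spacer against every phage on both strands.

    A hit is an ungapped alignment of a spacer substring of length
    >= ceil(min_cov * L) with <= max_mm mismatches.  For a minus-strand hit
    ``phage_start`` is still the forward-strand coordinate of the window's
    left end.  Output is sorted by (spacer_id, phage_id, start, strand).
    """
    for sp in spacers:
        if len(sp.sequence) == 0:
            raise DataError(f"spacer {sp.seq_id}: empty sequence")
    hits: list[SpacerHit] = []
    encoded = [(ph, _encode(ph.sequence, _PHAGE_CODE)) for ph in phages]
    for sp in spacers:
        L = len(sp.sequence)
        min_len = int(np.ceil(min_cov * L))
        for ph, ph_arr in encoded:
            cands = _scan_one(sp.sequence, ph_arr, len(ph.sequence),
                              max_mm, min_len)
            for mm, _neg, p0, _rank, strand, alen in _collapse(cands):
                hits.append(SpacerHit(
                    spacer_id=sp.seq_id, phage_id=ph.seq_id,
                    phage_start=p0 + 1, strand=strand, aligned_len=alen,
                    mismatches=mm, coverage=alen / L,
                    identity=(alen - mm) / alen))
    hits.sort(key=lambda h: (h.spacer_id, h.phage_id, h.phage_start,
                             h.strand))
    return hits


def hits_table(hits: list[SpacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"spacer_id": h.spacer_id, "phage_id": h.phage_id,
          "start": h.phage_start, "strand": h.strand,
          "aligned_len": h.aligned_len, "mismatches": h.mismatches,
          "coverage": h.coverage, "identity": h.identity} for h in hits],
        columns=["spacer_id", "phage_id", "start", "strand", "aligned_len",
                 "mismatches", "coverage", "identity"])


def link_hosts(hits: list[SpacerHit],
               spacer_origin: dict[str, str]) -> pd.DataFrame:
    """Distinct (host genome, phage) links with supporting hit counts."""
    unknown = sorted({h.spacer_id for h in hits} - set(spacer_origin))
    if unknown:
        raise CrossRefError(f"spacer(s) without origin genome: {unknown}")
    support: Counter[tuple[str, str]] = Counter()
    for h in hits:
        support[(spacer_origin[h.spacer_id], h.phage_id)] += 1
    rows = [{"host_genome_id": host, "phage_id": phage, "n_hits": n}
            for (host, phage), n in sorted(support.items())]
    return pd.DataFrame(rows,
                        columns=["host_genome_id", "phage_id", "n_hits"])


def n_targeted_phages(links: pd.DataFrame) -> int:
    return int(links["phage_id"].nunique()) if len(links) else 0


ANTI_DEFENSE_PREFIX = "anti_defense:"


@dataclass(slots=True)
class AntiDefenseTally:
    """Anti-defense gene census over a set of phage annotations.

    ``prevalence_pct`` is 100 x (phages with >= 1 anti-defense gene) /
    phage universe size, rounded to one decimal for reporting.
    """

    per_type: dict[str, int] = field(default_factory=dict)
    n_genes: int = 0
    n_phages: int = 0
    universe: int = 0
    prevalence_pct: float = 0.0


def _anti_defense_types(gene: GeneRecord) -> list[str]:
    return [lab[len(ANTI_DEFENSE_PREFIX):] for lab in sorted(gene.labels)
            if lab.startswith(ANTI_DEFENSE_PREFIX)]


def tally_anti_defense(phage_genes: list[GeneRecord],
                       phage_universe_size: int) -> AntiDefenseTally:
    """Tally anti-defense genes (labels ``anti_defense:<type>``).

    ``genome_id`` of each gene record identifies its phage.  The universe
    size is the full phage set the prevalence is quoted against, which may
    exceed the number of annotated phages passed in.
    """
    per_type: Counter[str] = Counter()
    carriers: set[str] = set()
    n_genes = 0
    for g in phage_genes:
        types = _anti_defense_types(g)
        if types:
            n_genes += 1
            carriers.add(g.genome_id)
            per_type.update(types)
    if phage_universe_size < len(carriers):
        raise DataError(
            f"universe size {phage_universe_size} smaller than the "
            f"{len(carriers)} phages carrying anti-defense genes")
    prev = (100.0 * len(carriers) / phage_universe_size
            if phage_universe_size else 0.0)
    return AntiDefenseTally(
        per_type=dict(sorted(per_type.items())), n_genes=n_genes,
        n_phages=len(carriers), universe=phage_universe_size,
        prevalence_pct=round(prev, 1))


def colocalized_anti_defense(phage_genes: list[GeneRecord]
                             ) -> list[dict]:
    """Phages carrying >= 2 anti-defense genes with their gene contexts.

    Context is the ordered list of anti-defense type labels along the
    phage.  Sorted by gene count descending, then phage id.
    """
    by_phage: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in phage_genes:
        if _anti_defense_types(g):
            by_phage[g.genome_id].append(g)
    out = []
    for phage, genes in by_phage.items():
        if len(genes) < 2:
            continue
        genes.sort(key=lambda g: (g.index, g.start))
        context = [t for g in genes for t in _anti_defense_types(g)]
        out.append({"phage_id": phage, "n_anti_defense_genes": len(genes),
                    "context": context})
    out.sort(key=lambda r: (-r["n_anti_defense_genes"], r["phage_id"]))
    return out


def novelty_classify(hit_table: pd.DataFrame,
                     queries: list[str] | None = None,
                     min_cov: float = 0.80, min_id: float = 0.90,
                     rule: str = "and") -> dict[str, str]:
    """Classify queries as known vs novel from an alignment hit table.

    ``hit_table`` needs columns query, coverage, identity (fractions in
    [0, 1]).  Under the default ``rule="and"`` a query is *known* iff at
    least one hit has coverage >= min_cov AND identity >= min_id; under
    ``rule="or"`` one passing threshold suffices.  Queries without hits
    (including any extra ids in ``queries``) are novel.
    """
    if rule not in ("and", "or"):
        raise DataError(f"unknown novelty rule {rule!r}")
    for col in ("query", "coverage", "identity"):
        if col not in hit_table.columns:
            raise DataError(f"hit table missing column {col!r}")
    cov = hit_table["coverage"].to_numpy(dtype=float)
    ident = hit_table["identity"].to_numpy(dtype=float)
    if len(hit_table) and (cov.min() < 0 or cov.max() > 1
                           or ident.min() < 0 or ident.max() > 1):
        raise DataError("coverage/identity must be fractions in [0, 1]")
    if rule == "and":
        good = (cov >= min_cov) & (ident >= min_id)
    else:
        good = (cov >= min_cov) | (ident >= min_id)
    known = set(hit_table.loc[good, "query"])
    universe = set(hit_table["query"]) | set(queries or [])
    return {q: ("known" if q in known else "novel") for q in sorted(universe)}
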