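"""Compartment assignment and observed/expected enrichment.

Defense systems are assigned to genomic compartments — an MGE class
(plasmid, phage/prophage, integron, ICE/IME) or the chromosome; separately,
defense island (DI) versus non-DI.  Enrichment of a family in a compartment
is measured as the observed count over the count expected under independence
(E[f, c] = total_f x total_c / N), with a per-cell 2x2 chi-square test
(Yates-corrected by default, mirroring R's ``chisq.test``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import GenomeAnnotation, MGEInterval, MGE_CLASSES, DefenseSystemRecord
from .islands import DefenseIsland

#: Default resolution order when one system qualifies for several MGE
#: classes: smaller, more specific elements outrank larger ones.
DEFAULT_PRIORITY = ("ice_ime", "integron", "phage_prophage", "plasmid")


def assign_compartment(system: DefenseSystemRecord,
                       genes_by_id: dict,
                       mges: list[MGEInterval],
                       priority: tuple[str, ...] = DEFAULT_PRIORITY,
                       containment: str = "all") -> str:
    """Compartment label for one system.

    A system belongs to an MGE class iff a single interval of that class
    contains the midpoints of all member genes (``containment="all"``) or of
    a strict majority of them (``"majority"``).  Among qualifying classes
    the first in ``priority`` wins; otherwise the system is chromosomal.
    """
    if containment not in ("all", "majority"):
        raise DataError(f"unknown containment {containment!r}")
    mids = []
    contigs = set()
    for gid in system.gene_ids:
        g = genes_by_id[gid]
        mids.append(g.midpoint)
        contigs.add(g.contig_id)
    if len(contigs) != 1:
        return "chromosome"
    contig = contigs.pop()
    need = len(mids) if containment == "all" else len(mids) // 2 + 1
    qualifying = set()
    for m in mges:
        if m.contig_id != contig or m.mge_class in qualifying:
            continue
        inside = sum(1 for x in mids if m.start <= x <= m.end)
        if inside >= need:
            qualifying.add(m.mge_class)
    for cls in priority:
        if cls in qualifying:
            return cls
    return "chromosome"


def assign_compartments(genome: GenomeAnnotation,
                        priority: tuple[str, ...] = DEFAULT_PRIORITY,
                        containment: str = "all") -> dict[str, str]:
    """Map system_id -> compartment for every system of a genome."""
    lookup = genome.genes_by_id()
    return {s.system_id: assign_compartment(s, lookup, genome.mges,
                                            priority, containment)
            for s in genome.systems}


@dataclass
class OETable:
    """Family x compartment observed/expected table with per-cell tests.

    All frames share the same index (families) and columns (compartments).
    ``qvalue`` is the Benjamini-Hochberg adjustment of ``pvalue`` across all
    cells, provided for convenience; the per-cell p-values themselves are
    unadjusted.  Cells with E = 0 have ratio NaN.
    """

    observed: pd.DataFrame
    expected: pd.DataFrame
    ratio: pd.DataFrame
    chi2: pd.DataFrame
    pvalue: pd.DataFrame
    qvalue: pd.DataFrame
    family_totals: pd.Series
    compartment_totals: pd.Series
    grand_total: int

    def to_long(self) -> pd.DataFrame:
        rows = []
        for f in self.observed.index:
            for c in self.observed.columns:
                rows.append({
                    "family": f, "compartment": c,
                    "observed": self.observed.at[f, c],
                    "expected": self.expected.at[f, c],
                    "oe_ratio": self.ratio.at[f, c],
                    "chi2": self.chi2.at[f, c],
                    "pvalue": self.pvalue.at[f, c],
                    "qvalue": self.qvalue.at[f, c],
                })
        return pd.DataFrame(rows)


def _cell_chi2(o: int, rf: int, cf: int, n: int, correction: bool
               ) -> tuple[float, float]:
    """2x2 chi-square of one cell against the rest of the table."""
    table = np.array([[o, rf - o], [cf - o, n - rf - cf + o]], dtype=float)
    if table.min() < 0:
        return np.nan, np.nan
    if (table.sum(axis=0).min() == 0) or (table.sum(axis=1).min() == 0):
        return np.nan, np.nan
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def oe_table(assignments: list[tuple[str, str]],
             correction: bool = True) -> OETable:
    """Observed/expected enrichment from (family, compartment) pairs.

    E[f, c] = total_f x (total_c / N); ratio = O/E; per-cell chi-square on
    the 2x2 collapse of the table with Yates continuity correction by
    default.
    """
    if not assignments:
        raise DataError("oe_table of zero systems is undefined")
    df = pd.DataFrame(assignments, columns=["family", "compartment"])
    obs = (df.groupby(["family", "compartment"]).size()
             .unstack(fill_value=0).sort_index(axis=0).sort_index(axis=1))
    fam_tot = obs.sum(axis=1)
    comp_tot = obs.sum(axis=0)
    n = int(fam_tot.sum())
    expected = np.outer(fam_tot, comp_tot) / n
    expected = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = obs / expected
    chi2 = pd.DataFrame(np.nan, index=obs.index, columns=obs.columns)
    pval = pd.DataFrame(np.nan, index=obs.index, columns=obs.columns)
    for f in obs.index:
        for c in obs.columns:
            s, p = _cell_chi2(int(obs.at[f, c]), int(fam_tot[f]),
                              int(comp_tot[c]), n, correction)
            chi2.at[f, c] = s
            pval.at[f, c] = p
    flat = pval.to_numpy().ravel()
    q = np.full_like(flat, np.nan)
    ok = ~np.isnan(flat)
    if ok.any():
        q[ok] = stats.false_discovery_control(flat[ok], method="bh")
    qval = pd.DataFrame(q.reshape(pval.shape), index=pval.index,
                        columns=pval.columns)
    return OETable(observed=obs.astype(int), expected=expected, ratio=ratio,
                   chi2=chi2, pvalue=pval, qvalue=qval,
                   family_totals=fam_tot, compartment_totals=comp_tot,
                   grand_total=n)


def mge_oe_table(cohort: list[GenomeAnnotation],
                 priority: tuple[str, ...] = DEFAULT_PRIORITY,
                 containment: str = "all", correction: bool = True) -> OETable:
    """O/E of families across {chromosome} + MGE classes for a whole cohort."""
    pairs = []
    for ga in cohort:
        comp = assign_compartments(ga, priority, containment)
        for s in ga.systems:
            pairs.append((s.family, comp[s.system_id]))
    return oe_table(pairs, correction=correction)


def island_oe_table(cohort: list[GenomeAnnotation],
                    islands: list[DefenseIsland],
                    containment: str = "any",
                    correction: bool = True) -> OETable:
    """O/E of families across {DI, non-DI} compartments."""
    if containment == "any":
        resident = {sid for i in islands for sid in i.systems}
    elif containment == "all":
        resident = {sid for i in islands for sid in i.systems_contained}
    else:
        raise DataError(f"unknown containment {containment!r}")
    pairs = []
    for ga in cohort:
        for s in ga.systems:
            pairs.append((s.family,
                          "DI" if s.system_id in resident else "non-DI"))
    return oe_table(pairs, correction=correction)


def _merged_bp(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by 1-based inclusive intervals after merging."""
    total = 0
    prev_end: int | None = None
    for start, end in sorted(intervals):
        if prev_end is not None and start <= prev_end:
            if end > prev_end:
                total += end - prev_end
                prev_end = end
        else:
            total += end - start + 1
            prev_end = end
    return total


def compartment_density(cohort: list[GenomeAnnotation],
                        priority: tuple[str, ...] = DEFAULT_PRIORITY,
                        containment: str = "all") -> pd.Series:
    """Defense-system density (systems per kb) per compartment.

    Chromosome length = sum of genome sizes minus merged MGE bp.  Each MGE
    class contributes its merged interval length.  Classes with zero bp but
    observed systems raise; classes with zero bp and zero systems are
    omitted.
    """
    sys_counts: dict[str, int] = {c: 0 for c in ("chromosome", *MGE_CLASSES)}
    bp: dict[str, float] = {c: 0.0 for c in ("chromosome", *MGE_CLASSES)}
    for ga in cohort:
        comp = assign_compartments(ga, priority, containment)
        for label in comp.values():
            sys_counts[label] += 1
        all_iv, per_class = [], {c: [] for c in MGE_CLASSES}
        for m in ga.mges:
            all_iv.append((m.contig_id, m.start, m.end))
            per_class[m.mge_class].append((m.contig_id, m.start, m.end))

        def merged(ivs):
            by_contig: dict[str, list[tuple[int, int]]] = {}
            for contig, s, e in ivs:
                by_contig.setdefault(contig, []).append((s, e))
            return sum(_merged_bp(v) for v in by_contig.values())

        mge_bp = merged(all_iv)
        bp["chromosome"] += ga.qc.size_bp - mge_bp
        for c in MGE_CLASSES:
            bp[c] += merged(per_class[c])

    out = {}
    for c, n_sys in sys_counts.items():
        if bp[c] <= 0:
            if n_sys > 0:
                raise DataError(
                    f"compartment {c}: {n_sys} systems but zero length")
            continue
        out[c] = n_sys / (bp[c] / 1000.0)
    return pd.Series(out, name="systems_per_kb")
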