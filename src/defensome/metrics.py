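"""Per-genome and cohort-level defensome statistics.

Covers defense-system counts and densities, family prevalence, the
first-line/accessory partition (the few families present in more than 10% of
genomes versus the long tail), the high-quality MAG filter, the exponential
shape of the per-genome system-count distribution, and Spearman correlations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import GenomeAnnotation, GenomeQC

#: The five families the source cohort's >10% prevalence rule selects.
FIRST_LINE_NAMED = ("RM", "SoFIC", "CRISPR-Cas", "AbiE", "MazEF")


@dataclass(slots=True)
class DefensomeProfile:
    """Defense census of a single genome."""

    genome_id: str
    n_systems: int
    density_per_mb: float
    n_families: int
    families: Counter = field(default_factory=Counter)
    first_line_count: int = 0
    accessory_count: int = 0


def profile_genome(genome: GenomeAnnotation,
                   first_line: set[str] | frozenset[str] = frozenset()
                   ) -> DefensomeProfile:
    """Count systems and distinct families; density is systems per Mbp."""
    if genome.qc.size_bp <= 0:
        raise DataError(f"{genome.genome_id}: non-positive genome size")
    fams = Counter(s.family for s in genome.systems)
    n = len(genome.systems)
    fl = sum(c for f, c in fams.items() if f in first_line)
    return DefensomeProfile(
        genome_id=genome.genome_id,
        n_systems=n,
        density_per_mb=n / (genome.qc.size_bp / 1e6),
        n_families=len(fams),
        families=fams,
        first_line_count=fl,
        accessory_count=n - fl)


def profiles_table(cohort: list[GenomeAnnotation],
                   first_line: set[str] | frozenset[str] = frozenset()
                   ) -> pd.DataFrame:
    rows = []
    for ga in cohort:
        p = profile_genome(ga, first_line)
        rows.append({
            "genome_id": p.genome_id, "n_systems": p.n_systems,
            "density_per_mb": p.density_per_mb, "n_families": p.n_families,
            "first_line_count": p.first_line_count,
            "accessory_count": p.accessory_count,
            "size_bp": ga.qc.size_bp,
        })
    return pd.DataFrame(rows, columns=[
        "genome_id", "n_systems", "density_per_mb", "n_families",
        "first_line_count", "accessory_count", "size_bp"])


def prevalence(cohort: list[GenomeAnnotation]) -> pd.DataFrame:
    """Family prevalence across the cohort.

    One row per family observed at least once, sorted by prevalence
    descending (ties by name): ``n_genomes_with`` (genomes with >= 1 system
    of the family), ``prevalence`` (fraction of the cohort) and
    ``total_systems``.
    """
    if not cohort:
        raise DataError("prevalence of an empty cohort is undefined")
    n_genomes = len(cohort)
    with_family: Counter[str] = Counter()
    totals: Counter[str] = Counter()
    for ga in cohort:
        fams = Counter(s.family for s in ga.systems)
        totals.update(fams)
        with_family.update(fams.keys())
    rows = [{
        "family": f,
        "n_genomes_with": with_family[f],
        "prevalence": with_family[f] / n_genomes,
        "total_systems": totals[f],
    } for f in totals]
    df = pd.DataFrame(rows, columns=["family", "n_genomes_with", "prevalence",
                                     "total_systems"])
    return df.sort_values(["prevalence", "family"],
                          ascending=[False, True]).reset_index(drop=True)


def partition_first_line(prev: pd.DataFrame, threshold: float = 0.10
                         ) -> tuple[set[str], set[str]]:
    """Split families into first-line (prevalence strictly > threshold)
    and accessory (the rest)."""
    fl = set(prev.loc[prev["prevalence"] > threshold, "family"])
    acc = set(prev["family"]) - fl
    return fl, acc


def family_share(cohort: list[GenomeAnnotation],
                 family_set: set[str] | frozenset[str]) -> float:
    """Fraction of all systems whose family is in ``family_set``."""
    total = sum(len(ga.systems) for ga in cohort)
    if total == 0:
        raise DataError("family_share undefined: cohort has no systems")
    hit = sum(1 for ga in cohort for s in ga.systems if s.family in family_set)
    return hit / total


def hq_filter(qc: GenomeQC) -> bool:
    """High-quality MAG rule; all comparisons strict.

    completeness > 90, contamination < 5,
    completeness - 5 x contamination > 70, N50 > 100 kb.
    """
    return (qc.completeness > 90
            and qc.contamination < 5
            and qc.completeness - 5 * qc.contamination > 70
            and qc.n50_bp > 100_000)


def fit_exponential_decline(counts) -> tuple[float, float]:
    """Fit the exponential shape of the per-genome system-count histogram.

    Least-squares line through (k, log f_k) over occupied bins k (f_k > 0),
    weighted by f_k (the Poisson-noise variance of log f_k is ~1/f_k, so
    sparse tail bins do not dominate); returns (rate, r_squared) where
    rate = -slope and r_squared is the weighted R^2 of the regression.
    Zero-frequency bins are skipped, not imputed.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise DataError("no counts")
    freq = Counter(counts.tolist())
    ks = np.array(sorted(freq), dtype=float)
    fs = np.array([freq[k] for k in sorted(freq)], dtype=float)
    if ks.size < 3:
        raise DataError("need >= 3 occupied count bins for the exponential fit")
    y = np.log(fs)
    w = fs
    x_mat = np.vstack([np.ones_like(ks), ks]).T
    beta = np.linalg.solve((x_mat * w[:, None]).T @ x_mat,
                           (x_mat * w[:, None]).T @ y)
    y_hat = x_mat @ beta
    y_bar = np.average(y, weights=w)
    sst = np.sum(w * (y - y_bar) ** 2)
    r2 = 1.0 if sst == 0 else float(1 - np.sum(w * (y - y_hat) ** 2) / sst)
    return float(-beta[1]), r2


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Two-sided p-value from the t-approximation with n - 2 df.  Raises on
    constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("spearman: length mismatch")
    if x.size < 4:
        raise DataError("spearman: need >= 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("spearman: constant vector, coefficient undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def cohort_totals(cohort: list[GenomeAnnotation]) -> dict[str, int]:
    """Headline totals of one cohort: genomes, defense genes, systems, families."""
    families = {s.family for ga in cohort for s in ga.systems}
    return {
        "n_genomes": len(cohort),
        "n_defense_genes": sum(len(ga.defense_gene_ids()) for ga in cohort),
        "n_systems": sum(len(ga.systems) for ga in cohort),
        "n_families": len(families),
    }


def combine_totals(components: list[dict[str, float]]) -> dict[str, float]:
    """Sum per-domain (e.g. bacterial + archaeal) headline totals key-wise.

    Keys present in only some components are treated as 0 elsewhere; family
    counts are *not* additive across domains and must not be combined here.
    """
    out: dict[str, float] = {}
    for comp in components:
        for k, v in comp.items():
            if k == "n_families":
                raise DataError("family counts are not additive across domains")
            out[k] = out.get(k, 0) + v
    return out
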