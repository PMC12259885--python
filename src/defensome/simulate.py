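"""Seeded generator of annotated-genome cohorts with planted ground truth.

The generator emulates the structure of a metagenome-assembled-genome (MAG)
cohort annotated for defense systems: genomes with log-normal sizes split
into a few contigs, a Zipf-decaying family abundance structure (few dominant
"first-line" families, a long accessory tail), dispersed defense systems
plus planted defense islands, MGE intervals carrying accessory systems at a
calibrated enrichment, adaptive-trait counts bounded by a logistic ceiling
in the defense-system count, and CRISPR spacers copied from phage windows
with controlled mismatches.

Every quantity a downstream stage is meant to recover is recorded in
:class:`SyntheticTruth`.  All randomness flows through
``numpy.random.default_rng([seed, component, genome])`` so that adding a
component never reshuffles earlier draws and output is identical across
runs and platforms.

Constructive guarantees
-----------------------
* Planted islands satisfy the island rule (>= 5 defense genes, >= 3
  families, gaps <= max_gap) by construction; deliberate near-misses
  violate exactly one clause and are flagged with the reason.
* Every placed defense unit (island or dispersed system) keeps more than
  ``max_gap`` intervening genes to any other defense unit, so no accidental
  qualifying cluster can arise and island recall/precision against truth is
  exactly 1.
* Positive spacers place their substitutions at interior positions covered
  by every window passing the coverage threshold; negatives carry four such
  interior substitutions and are additionally screened against the whole
  phage set, so the matcher must recover all positives and no negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .io import (DefenseSystemRecord, GeneRecord, GenomeAnnotation, GenomeQC,
                 MGEInterval, MGE_CLASSES, SequenceRecord)
from .metrics import FIRST_LINE_NAMED
from .spacers import revcomp

DEFAULT_FAMILY_POOL = FIRST_LINE_NAMED + (
    "CBASS", "Wadjet", "Septu", "Thoeris", "Gabija", "Hachiman", "Lamassu",
    "Zorya", "Druantia", "PARIS", "Retron", "dGTPase", "BstA", "AVAST",
    "DISARM")

ANTI_DEFENSE_TYPES = (
    "anti-CRISPR", "anti-RM", "anti-Thoeris", "anti-CBASS", "anti-Dnd",
    "anti-Gabija", "anti-Pycsar", "anti-Hachiman", "anti-Septu")

_SYSTEM_SIZES = (1, 2, 3, 4, 5)
_SYSTEM_SIZE_P = (0.35, 0.35, 0.20, 0.07, 0.03)


def zipf_weights(n: int, exponent: float = 1.1) -> np.ndarray:
    """Zipf-like prevalence weights mimicking the few-dominant/many-rare
    family structure; the default exponent puts ~2/3 of the mass on the
    first five families."""
    w = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    return w / w.sum()


@dataclass(slots=True)
class IslandSpec:
    """How many islands to plant and what they look like.

    ``accessory_multiplier`` is the target observed/expected enrichment of
    accessory families inside islands; the within-island family distribution
    is tilted so each accessory family's O/E is approximately this factor.
    """

    n_islands: int | None = None        # None -> ~2.3% of genomes
    genes_range: tuple[int, int] = (5, 12)
    gap_range: tuple[int, int] = (0, 2)
    families_range: tuple[int, int] = (3, 6)
    accessory_multiplier: float = 3.0
    n_near_miss: int = 0


@dataclass(slots=True)
class MGESpec:
    """Per-class MGE rates (expected elements per genome), mean lengths and
    enrichment multipliers.

    ``density_multiplier`` is the target ratio of defense-system density
    (per kb) on MGEs versus chromosome; ``accessory_multiplier`` the target
    O/E of accessory families on MGEs.
    """

    rates: dict = field(default_factory=lambda: {
        "plasmid": 5.9, "phage_prophage": 1.46,
        "integron": 0.098, "ice_ime": 0.022})
    mean_len_kb: dict = field(default_factory=lambda: {
        "plasmid": 30.0, "phage_prophage": 35.0,
        "integron": 8.0, "ice_ime": 45.0})
    density_multiplier: float = 5.0
    accessory_multiplier: float = 3.0


@dataclass(slots=True)
class TradeoffSpec:
    """Logistic ceiling for trait counts: max trait = a / (1 + e^{b(x-c)})
    at defense-system count x, per-trait ceilings scaled by ``trait_scale``.

    Counts are uniform integers in [0, ceiling]; with probability
    ``touch_prob`` the ceiling itself is drawn, so that populated bins
    reliably realize the envelope.
    """

    a: float = 40.0
    b: float = 0.5
    c: float = 10.0
    trait_scale: dict = field(default_factory=lambda: {
        "ARG": 1.0, "MRG": 0.6, "VFG": 0.4})
    touch_prob: float = 0.15


@dataclass(slots=True)
class CohortParams:
    """Full parameterization of one synthetic cohort."""

    n_genomes: int
    size_log_mu: float = math.log(3e6)   # log-normal genome size, bp
    size_log_sigma: float = 0.35
    gene_density: float = 1.0            # genes per kbp (fixed gene layout)
    family_pool: tuple[str, ...] = DEFAULT_FAMILY_POOL
    family_exponent: float = 1.1
    n_first_line: int = 5
    mean_systems_per_genome: float = 3.2
    island_spec: IslandSpec = field(default_factory=IslandSpec)
    mge_spec: MGESpec = field(default_factory=MGESpec)
    tradeoff_spec: TradeoffSpec = field(default_factory=TradeoffSpec)
    island_max_gap: int = 10             # detection gap the islands must meet
    seed: int = 0
    gene_detail: str = "full"            # "full" | "sparse"

    def first_line_families(self) -> frozenset[str]:
        return frozenset(self.family_pool[:self.n_first_line])


@dataclass(slots=True)
class PlantedIsland:
    genome_id: str
    contig_id: str
    first_index: int
    last_index: int
    families: frozenset[str]
    n_defense: int
    system_ids: tuple[str, ...]
    near_miss: str | None = None   # violation reason, None for real islands


@dataclass(slots=True)
class PlantedProtospacer:
    spacer_id: str
    phage_id: str
    position: int       # 1-based forward-strand coordinate of the window
    strand: str
    n_mismatches: int
    length: int


@dataclass(slots=True)
class SyntheticTruth:
    planted_islands: list[PlantedIsland] = field(default_factory=list)
    planted_enrichment: dict = field(default_factory=dict)
    tradeoff_params: tuple[float, float, float] | None = None
    planted_protospacers: list[PlantedProtospacer] = field(default_factory=list)
    multi_anti_defense_phages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# placement helpers (gene-index slot allocation)
# ---------------------------------------------------------------------------

def _free_ranges(lo: int, hi: int, blocks: list[tuple[int, int]],
                 unit_len: int, margin: int) -> list[tuple[int, int]]:
    """Valid start positions in [lo, hi] for a unit of ``unit_len`` genes
    keeping ``margin`` genes clear of every blocked interval."""
    hi = hi - unit_len + 1
    if hi < lo:
        return []
    ranges = [(lo, hi)]
    for s, e in blocks:
        b_lo, b_hi = s - margin - unit_len + 1, e + margin
        nxt = []
        for r_lo, r_hi in ranges:
            if b_hi < r_lo or b_lo > r_hi:
                nxt.append((r_lo, r_hi))
                continue
            if r_lo < b_lo:
                nxt.append((r_lo, b_lo - 1))
            if r_hi > b_hi:
                nxt.append((b_hi + 1, r_hi))
        ranges = nxt
    return ranges


def _pick_start(rng, ranges: list[tuple[int, int]]) -> int | None:
    sizes = [hi - lo + 1 for lo, hi in ranges]
    total = sum(sizes)
    if total == 0:
        return None
    u = int(rng.integers(total))
    for (lo, _hi), size in zip(ranges, sizes):
        if u < size:
            return lo + u
        u -= size
    return None  # pragma: no cover


class _ContigState:
    """Mutable occupancy bookkeeping for one contig during generation."""

    __slots__ = ("contig_id", "n_genes", "mge_blocks", "def_blocks")

    def __init__(self, contig_id: str, n_genes: int):
        self.contig_id = contig_id
        self.n_genes = n_genes
        self.mge_blocks: list[tuple[int, int]] = []
        self.def_blocks: list[tuple[int, int]] = []


def _place_defense_unit(rng, contigs: list[_ContigState], unit_len: int,
                        margin: int,
                        within: tuple[_ContigState, int, int] | None = None
                        ) -> tuple[_ContigState, int] | None:
    """Place a defense unit clear of MGEs (chromosomal) or inside one MGE."""
    if within is not None:
        cs, lo, hi = within
        ranges = _free_ranges(lo, hi, cs.def_blocks, unit_len, margin)
        start = _pick_start(rng, ranges)
        if start is None:
            return None
        cs.def_blocks.append((start, start + unit_len - 1))
        return cs, start
    options = []
    for cs in contigs:
        blocks = cs.def_blocks + [(s, e) for s, e in cs.mge_blocks]
        ranges = _free_ranges(0, cs.n_genes - 1, blocks, unit_len, margin)
        n = sum(hi - lo + 1 for lo, hi in ranges)
        if n:
            options.append((cs, ranges, n))
    total = sum(n for _, _, n in options)
    if total == 0:
        return None
    u = int(rng.integers(total))
    for cs, ranges, n in options:
        if u < n:
            start = None
            for lo, hi in ranges:
                size = hi - lo + 1
                if u < size:
                    start = lo + u
                    break
                u -= size
            cs.def_blocks.append((start, start + unit_len - 1))
            return cs, start
        u -= n
    return None  # pragma: no cover


# ---------------------------------------------------------------------------
# island composition
# ---------------------------------------------------------------------------

def _tilted_family_probs(weights: np.ndarray, is_accessory: np.ndarray,
                         multiplier: float) -> np.ndarray:
    """Family distribution whose accessory O/E against ``weights`` is
    approximately ``multiplier``: accessory families get m x their overall
    probability, first-line families share the remainder pro rata."""
    acc_share = float(weights[is_accessory].sum())
    if multiplier * acc_share >= 1.0:
        raise ConfigError(
            f"accessory multiplier {multiplier} infeasible: accessory weight "
            f"share {acc_share:.3f} gives tilted mass >= 1")
    p = weights.copy()
    p[is_accessory] *= multiplier
    fl_mass = 1.0 - multiplier * acc_share
    fl = ~is_accessory
    p[fl] = weights[fl] / weights[fl].sum() * fl_mass
    return p / p.sum()


def _draw_island_layout(rng, spec: IslandSpec, families: np.ndarray,
                        probs: np.ndarray, near_miss: str | None,
                        max_gap: int):
    """Choose families, per-family gene counts and intra-island gaps.

    Returns (list of (family, n_genes), gaps between consecutive defense
    genes).  Near-miss layouts violate exactly the named clause.
    """
    f_lo, f_hi = spec.families_range
    g_lo, g_hi = spec.genes_range
    n_fam = int(rng.integers(f_lo, f_hi + 1))
    n_genes = int(rng.integers(max(g_lo, n_fam), g_hi + 1))
    if near_miss == "too_few_genes":
        n_fam, n_genes = 3, 4
    elif near_miss == "too_few_families":
        n_fam, n_genes = 2, max(6, g_lo)
    elif near_miss == "gap_exceeded":
        n_fam, n_genes = 3, max(6, g_lo)
    chosen = rng.choice(len(families), size=n_fam, replace=False, p=probs)
    counts = np.ones(n_fam, dtype=int)
    for _ in range(n_genes - n_fam):
        counts[int(rng.integers(n_fam))] += 1
    layout = [(str(families[i]), int(c)) for i, c in zip(chosen, counts)]
    gaps = rng.integers(spec.gap_range[0], spec.gap_range[1] + 1,
                        size=n_genes - 1).tolist()
    if near_miss == "gap_exceeded":
        gaps[len(gaps) // 2] = max_gap + 1
    return layout, gaps


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _validate(params: CohortParams) -> None:
    if params.n_genomes < 0:
        raise ConfigError("n_genomes must be >= 0")
    if params.gene_density <= 0 or params.gene_density > 1.05:
        raise ConfigError("gene_density must be in (0, 1.05] genes/kbp")
    if params.n_first_line > len(params.family_pool):
        raise ConfigError("n_first_line exceeds the family pool")
    isp = params.island_spec
    if isp.genes_range[0] < 1 or isp.genes_range[0] > isp.genes_range[1]:
        raise ConfigError("bad island genes_range")
    if not (0 <= isp.gap_range[0] <= isp.gap_range[1] <= params.island_max_gap):
        raise ConfigError(
            f"island gap_range must lie within [0, {params.island_max_gap}]")
    if any(v < 0 for v in params.mge_spec.rates.values()):
        raise ConfigError("MGE rates must be >= 0")
    if not (0 <= params.tradeoff_spec.touch_prob <= 1):
        raise ConfigError("touch_prob must be a probability")


def _rng(params: CohortParams, component: int, genome: int = 0):
    return np.random.default_rng([params.seed, component, genome])


_C_STRUCT, _C_COUNT, _C_MGE, _C_PLACE, _C_TRAIT, _C_STRAND, _C_QC = range(7)
_C_COHORT = 10
_C_FILLER = 11


def generate_cohort(params: CohortParams
                    ) -> tuple[list[GenomeAnnotation], SyntheticTruth]:
    """Generate a cohort and its planted ground truth.

    Deterministic given ``params`` (including the seed).  See the module
    docstring for the constructive guarantees.
    """
    _validate(params)
    truth = SyntheticTruth(
        tradeoff_params=(params.tradeoff_spec.a, params.tradeoff_spec.b,
                         params.tradeoff_spec.c),
        planted_enrichment={
            "island_accessory_multiplier":
                params.island_spec.accessory_multiplier,
            "mge_accessory_multiplier":
                params.mge_spec.accessory_multiplier,
            "mge_density_multiplier": params.mge_spec.density_multiplier,
        })
    if params.n_genomes == 0:
        return [], truth

    families = np.array(params.family_pool)
    weights = zipf_weights(len(families), params.family_exponent)
    is_acc = np.array([f not in params.first_line_families()
                       for f in params.family_pool])
    island_probs = _tilted_family_probs(
        weights, is_acc, params.island_spec.accessory_multiplier)
    # per-family probability factor of MGE residency (first-line damped,
    # accessory boosted so the accessory O/E on MGEs ~ accessory_multiplier)
    m_mge = params.mge_spec.accessory_multiplier
    acc_share = float(weights[is_acc].sum())
    if m_mge * acc_share >= 1.0:
        raise ConfigError("MGE accessory multiplier infeasible for this pool")
    t_factor = np.where(is_acc, m_mge, (1 - m_mge * acc_share) / (1 - acc_share))
    fam_t = dict(zip(params.family_pool, t_factor))

    # cohort-level island assignment
    isp = params.island_spec
    n_islands = (isp.n_islands if isp.n_islands is not None
                 else max(1, round(0.023 * params.n_genomes)))
    rng_c = _rng(params, _C_COHORT)
    n_units = n_islands + isp.n_near_miss
    if n_units > params.n_genomes:
        raise ConfigError(
            f"{n_units} islands requested for {params.n_genomes} genomes")
    hosts = rng_c.choice(params.n_genomes, size=n_units, replace=False)
    near_kinds = ("too_few_genes", "too_few_families", "gap_exceeded")
    island_plan: dict[int, list] = {}
    for k, host in enumerate(hosts):
        near = None if k < n_islands else near_kinds[(k - n_islands) % 3]
        layout, gaps = _draw_island_layout(
            rng_c, isp, families, island_probs, near, params.island_max_gap)
        island_plan.setdefault(int(host), []).append((layout, gaps, near))

    slot_bp = round(1000 / params.gene_density)
    mean_size = math.exp(params.size_log_mu + params.size_log_sigma ** 2 / 2)
    d_mult = params.mge_spec.density_multiplier
    margin = params.island_max_gap + 1

    cohort: list[GenomeAnnotation] = []
    for i in range(params.n_genomes):
        gid = f"G{i:05d}"
        rng_s = _rng(params, _C_STRUCT, i)
        size = float(np.clip(rng_s.lognormal(params.size_log_mu,
                                             params.size_log_sigma),
                             5e5, 1.5e7))
        n_contigs = int(rng_s.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1]))
        frac = rng_s.uniform(0.5, 1.0, size=n_contigs)
        frac /= frac.sum()
        contigs: list[_ContigState] = []
        for j in range(n_contigs):
            n_genes = max(40, int(size * frac[j] / slot_bp))
            contigs.append(_ContigState(f"{gid}_c{j}", n_genes))
        size_bp = sum(cs.n_genes for cs in contigs) * slot_bp

        # ---- MGE intervals -------------------------------------------------
        rng_m = _rng(params, _C_MGE, i)
        mges: list[MGEInterval] = []
        mge_spans: list[tuple[_ContigState, int, int, str]] = []
        for cls in MGE_CLASSES:
            n_cls = int(rng_m.poisson(params.mge_spec.rates[cls]))
            for k in range(n_cls):
                ln_bp = rng_m.lognormal(
                    math.log(params.mge_spec.mean_len_kb[cls] * 1000), 0.3)
                span = max(3, int(round(ln_bp / slot_bp)))
                options = []
                for cs in contigs:
                    ranges = _free_ranges(0, cs.n_genes - 1, cs.mge_blocks,
                                          span, 1)
                    n = sum(hi - lo + 1 for lo, hi in ranges)
                    if n:
                        options.append((cs, ranges, n))
                total = sum(n for _, _, n in options)
                if total == 0:
                    continue  # genome too crowded: drop this element
                u = int(rng_m.integers(total))
                for cs, ranges, n in options:
                    if u < n:
                        for lo, hi in ranges:
                            sz = hi - lo + 1
                            if u < sz:
                                start = lo + u
                                break
                            u -= sz
                        cs.mge_blocks.append((start, start + span - 1))
                        mges.append(MGEInterval(
                            mge_id=f"{gid}_mge{len(mges)}", genome_id=gid,
                            contig_id=cs.contig_id,
                            start=start * slot_bp + 1,
                            end=(start + span) * slot_bp, mge_class=cls))
                        mge_spans.append((cs, start, start + span - 1, cls))
                        break
                    u -= n
        mge_bp = sum(m.length_bp for m in mges)
        phi = mge_bp / size_bp
        # residency probability calibrated so the realized MGE/chromosome
        # density ratio matches density_multiplier; the chromosome side also
        # carries the planted-island systems (expected load rho per genome)
        rho = (n_islands * (isp.families_range[0] + isp.families_range[1]) / 2
               / max(1, params.n_genomes) / params.mean_systems_per_genome)
        if phi > 0:
            r = d_mult * phi / (1 - phi)
            psi = r * (1 + rho) / (1 + r * (1 + rho))
            # family probabilities are capped at 1; rescale so the expected
            # residency share still equals psi despite the truncation
            def _excess(alpha):
                return float(np.sum(weights * np.minimum(
                    1.0, alpha * t_factor * psi))) - psi
            lo_a, hi_a = 1.0, 2.0
            while _excess(hi_a) < 0 and hi_a < 1e6:
                hi_a *= 2
            for _ in range(50):
                mid = (lo_a + hi_a) / 2
                if _excess(mid) < 0:
                    lo_a = mid
                else:
                    hi_a = mid
            alpha = (lo_a + hi_a) / 2
        else:
            psi, alpha = 0.0, 1.0

        # ---- defense systems ----------------------------------------------
        systems: list[DefenseSystemRecord] = []
        defense_genes: dict[tuple[str, int], tuple[str, list[str]]] = {}
        # (contig_id, index) -> (gene_id, [system_ids])
        rng_p = _rng(params, _C_PLACE, i)
        rng_strand = _rng(params, _C_STRAND, i)

        def register_system(family: str, cs: _ContigState,
                            idxs: list[int]) -> str:
            sys_id = f"{gid}_S{len(systems)}"
            strand = "+" if rng_strand.random() < 0.5 else "-"
            gene_ids = []
            for idx in idxs:
                key = (cs.contig_id, idx)
                if key not in defense_genes:
                    defense_genes[key] = (f"{gid}|{cs.contig_id}|{idx:06d}",
                                          [])
                defense_genes[key][1].append(sys_id)
                gene_ids.append(defense_genes[key][0])
            systems.append(DefenseSystemRecord(
                system_id=sys_id, genome_id=gid, family=family,
                gene_ids=tuple(gene_ids)))
            # strand recorded via the gene records at materialization
            defense_strands[sys_id] = strand
            return sys_id

        defense_strands: dict[str, str] = {}

        # planted islands first (they need the most room)
        for layout, gaps, near in island_plan.get(i, []):
            offsets, pos = [], 0
            n_genes_island = sum(c for _, c in layout)
            for k in range(n_genes_island):
                offsets.append(pos)
                if k < len(gaps):
                    pos += 1 + gaps[k]
            span = offsets[-1] + 1
            placed = _place_defense_unit(rng_p, contigs, span, margin)
            if placed is None:
                raise ConfigError(
                    f"island of span {span} genes does not fit on any contig "
                    f"of genome {gid}")
            cs, start = placed
            # interleave families along the island so families mix
            fam_seq = [fam for fam, cnt in layout for _ in range(cnt)]
            order = rng_p.permutation(len(fam_seq))
            sys_idxs: dict[str, list[int]] = {fam: [] for fam, _ in layout}
            for slot, k in enumerate(order):
                sys_idxs[fam_seq[k]].append(start + offsets[slot])
            ids = [register_system(fam, cs, sorted(idxs))
                   for fam, idxs in sys_idxs.items()]
            truth.planted_islands.append(PlantedIsland(
                genome_id=gid, contig_id=cs.contig_id, first_index=start,
                last_index=start + span - 1,
                families=frozenset(fam for fam, _ in layout),
                n_defense=n_genes_island, system_ids=tuple(ids),
                near_miss=near))

        # dispersed systems
        rng_n = _rng(params, _C_COUNT, i)
        lam = params.mean_systems_per_genome * size / mean_size
        x = int(rng_n.geometric(1.0 / (1.0 + lam))) - 1
        for _ in range(x):
            fam = str(families[rng_p.choice(len(families), p=weights)])
            n_genes_sys = int(rng_p.choice(_SYSTEM_SIZES, p=_SYSTEM_SIZE_P))
            p_res = min(1.0, alpha * fam_t[fam] * psi)
            placed = None
            if mge_spans and rng_p.random() < p_res:
                # consider every MGE interval with free capacity, weighted
                # by its number of valid starts, so collisions inside a
                # single element do not push systems back to the chromosome
                options = []
                for cs, s, e, _cls in mge_spans:
                    ranges = _free_ranges(s, e, cs.def_blocks, n_genes_sys,
                                          margin)
                    n_free = sum(hi - lo + 1 for lo, hi in ranges)
                    if n_free:
                        options.append((cs, ranges, n_free))
                total = sum(n for _, _, n in options)
                if total:
                    u = int(rng_p.integers(total))
                    for cs, ranges, n_free in options:
                        if u < n_free:
                            for lo, hi in ranges:
                                sz = hi - lo + 1
                                if u < sz:
                                    start = lo + u
                                    break
                                u -= sz
                            cs.def_blocks.append(
                                (start, start + n_genes_sys - 1))
                            placed = (cs, start)
                            break
                        u -= n_free
            if placed is None:
                placed = _place_defense_unit(rng_p, contigs, n_genes_sys,
                                             margin)
            if placed is None:
                continue  # no room anywhere: drop (deterministic)
            cs, start = placed
            register_system(fam, cs, list(range(start, start + n_genes_sys)))

        # ---- traits --------------------------------------------------------
        rng_t = _rng(params, _C_TRAIT, i)
        ts = params.tradeoff_spec
        x_total = len(systems)
        traits = {}
        for trait, scale in ts.trait_scale.items():
            ceil = int(round((ts.a * scale)
                             / (1 + math.exp(np.clip(ts.b * (x_total - ts.c),
                                                     -500, 500)))))
            if rng_t.random() < ts.touch_prob:
                traits[trait] = ceil
            else:
                traits[trait] = int(rng_t.integers(0, ceil + 1))

        # ---- QC / VHR ------------------------------------------------------
        rng_q = _rng(params, _C_QC, i)
        qc = GenomeQC(
            genome_id=gid, size_bp=size_bp,
            n50_bp=max(cs.n_genes for cs in contigs) * slot_bp,
            completeness=float(rng_q.uniform(70, 100)),
            contamination=float(rng_q.uniform(0, 10)),
            domain="Bacteria")
        density = x_total / (size_bp / 1e6)
        vhr = float(rng_q.lognormal(math.log(0.2 + 0.1 * density), 0.4))

        # ---- materialize gene records -------------------------------------
        genes: list[GeneRecord] = []
        contig_genes = {cs.contig_id: cs.n_genes for cs in contigs}
        sys_strand_of_gene = {}
        for s in systems:
            for g in s.gene_ids:
                sys_strand_of_gene[g] = defense_strands[s.system_id]
        def_by_contig: dict[str, dict[int, str]] = {}
        for (contig_id, idx), (gene_id, _sids) in defense_genes.items():
            def_by_contig.setdefault(contig_id, {})[idx] = gene_id
        if params.gene_detail == "full":
            rng_f = _rng(params, _C_FILLER, i)
            for cs in contigs:
                strands = rng_f.choice(np.array(["+", "-"]), size=cs.n_genes)
                dmap = def_by_contig.get(cs.contig_id, {})
                for idx in range(cs.n_genes):
                    start = idx * slot_bp + 1
                    if idx in dmap:
                        gene_id = dmap[idx]
                        strand = sys_strand_of_gene[gene_id]
                    else:
                        gene_id = f"{gid}|{cs.contig_id}|{idx:06d}"
                        strand = str(strands[idx])
                    genes.append(GeneRecord(
                        gene_id=gene_id, genome_id=gid,
                        contig_id=cs.contig_id, index=idx, start=start,
                        end=start + 899, strand=strand))
        else:
            for cs in contigs:
                dmap = def_by_contig.get(cs.contig_id, {})
                for idx in sorted(dmap):
                    start = idx * slot_bp + 1
                    gene_id = dmap[idx]
                    genes.append(GeneRecord(
                        gene_id=gene_id, genome_id=gid,
                        contig_id=cs.contig_id, index=idx, start=start,
                        end=start + 899,
                        strand=sys_strand_of_gene[gene_id]))

        cohort.append(GenomeAnnotation(
            qc=qc, genes=genes, systems=systems, mges=mges, traits=traits,
            vhr=vhr, contig_genes=contig_genes,
            gene_detail=params.gene_detail))
    return cohort, truth


# ---------------------------------------------------------------------------
# phage / spacer generation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def generate_phages(n: int, length_range: tuple[int, int] = (3000, 8000),
                    seed: int = 0) -> list[SequenceRecord]:
    """Random phage sequences (uniform base composition)."""
    rng = np.random.default_rng([seed, 100])
    out = []
    for k in range(n):
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(_BASES, size=ln))
        out.append(SequenceRecord(seq_id=f"phage_{k:04d}", sequence=seq))
    return out


def _interior_positions(L: int, min_cov: float) -> tuple[int, int]:
    """Positions contained in every spacer substring passing coverage.

    With min aligned length Lmin = ceil(min_cov * L), a position p is inside
    every qualifying window iff L - Lmin <= p <= Lmin - 1.
    """
    lmin = math.ceil(min_cov * L)
    return L - lmin, lmin - 1


def _substitute(rng, seq: list[str], pos: int) -> None:
    old = seq[pos]
    choices = [b for b in "ACGT" if b != old]
    seq[pos] = choices[int(rng.integers(3))]


def generate_spacer_set(phages: list[SequenceRecord], n_pos: int, n_neg: int,
                        seed: int, min_cov: float = 0.95
                        ) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Plant ``n_pos`` recoverable spacers (0 or 1 interior substitution)
    and ``n_neg`` unrecoverable ones (4 interior substitutions, screened
    against the whole phage set)."""
    from .spacers import find_protospacers  # local import avoids cycle at import time

    for ph in phages:
        if len(ph) < 60:
            raise ConfigError(f"phage {ph.seq_id} shorter than 60 bp")
    max_l = 45
    available = sum(max(0, len(ph) - max_l + 1) for ph in phages)
    if n_pos > available:
        raise ConfigError(
            f"n_pos={n_pos} exceeds the {available} available phage windows")

    rng = np.random.default_rng([seed, 101])
    truth = SyntheticTruth()
    spacers: list[SequenceRecord] = []

    def draw_window():
        L = int(rng.integers(25, 46))
        ok = [ph for ph in phages if len(ph) >= L]
        ph = ok[int(rng.integers(len(ok)))]
        pos = int(rng.integers(0, len(ph) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        window = ph.sequence[pos:pos + L]
        return L, ph, pos, strand, window

    for k in range(n_pos):
        L, ph, pos, strand, window = draw_window()
        spacer = list(window if strand == "+" else revcomp(window))
        n_mm = int(rng.integers(0, 2))
        if n_mm:
            lo, hi = _interior_positions(L, min_cov)
            _substitute(rng, spacer, int(rng.integers(lo, hi + 1)))
        sid = f"spacer_pos_{k:04d}"
        spacers.append(SequenceRecord(seq_id=sid, sequence="".join(spacer)))
        truth.planted_protospacers.append(PlantedProtospacer(
            spacer_id=sid, phage_id=ph.seq_id, position=pos + 1,
            strand=strand, n_mismatches=n_mm, length=L))

    for k in range(n_neg):
        sid = f"spacer_neg_{k:04d}"
        for _attempt in range(50):
            L, ph, pos, strand, window = draw_window()
            spacer = list(window if strand == "+" else revcomp(window))
            lo, hi = _interior_positions(L, min_cov)
            sites = rng.choice(np.arange(lo, hi + 1), size=4, replace=False)
            for p in sites:
                _substitute(rng, spacer, int(p))
            rec = SequenceRecord(seq_id=sid, sequence="".join(spacer))
            # minimum-distance screen: the negative must hit nothing
            if not find_protospacers([rec], phages, max_mm=1,
                                     min_cov=min_cov):
                spacers.append(rec)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigError(f"could not construct negative spacer {sid}")
    return spacers, truth


def generate_phage_annotations(phage_ids: list[str], seed: int = 0,
                               carrier_frac: float = 0.1,
                               multi_frac: float = 0.3
                               ) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Gene records for phages, a fraction carrying anti-defense genes.

    Carriers get one anti-defense gene; with probability ``multi_frac``
    they carry 2-3 (the co-localization signal).  Truth lists the
    multi-carriers.
    """
    rng = np.random.default_rng([seed, 102])
    genes: list[GeneRecord] = []
    truth = SyntheticTruth()
    for pid in phage_ids:
        n_genes = int(rng.integers(8, 61))
        anti_at: dict[int, str] = {}
        if rng.random() < carrier_frac:
            n_anti = 1
            if rng.random() < multi_frac:
                n_anti = int(rng.integers(2, 4))
            idxs = rng.choice(n_genes, size=min(n_anti, n_genes),
                              replace=False)
            for idx in idxs:
                t = ANTI_DEFENSE_TYPES[int(rng.integers(
                    len(ANTI_DEFENSE_TYPES)))]
                anti_at[int(idx)] = t
            if len(anti_at) >= 2:
                truth.multi_anti_defense_phages.append(pid)
        for idx in range(n_genes):
            start = idx * 1000 + 1
            labels = (frozenset({f"anti_defense:{anti_at[idx]}"})
                      if idx in anti_at else frozenset())
            genes.append(GeneRecord(
                gene_id=f"{pid}|g{idx:04d}", genome_id=pid, contig_id=pid,
                index=idx, start=start, end=start + 899, strand="+",
                labels=labels))
    truth.multi_anti_defense_phages.sort()
    return genes, truth


def sparse_params(params: CohortParams) -> CohortParams:
    """Convenience: the same cohort conditions without filler gene records."""
    return replace(params, gene_detail="sparse")
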