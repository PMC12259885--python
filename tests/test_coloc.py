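"""Compartment assignment, O/E enrichment and compartment densities."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_genome, make_mge
from defensome.coloc import (assign_compartment, assign_compartments,
                             compartment_density, island_oe_table,
                             mge_oe_table, oe_table)
from defensome.errors import DataError
from defensome.islands import detect_islands_cohort
from defensome.metrics import FIRST_LINE_NAMED
from defensome.simulate import (CohortParams, IslandSpec, generate_cohort,
                                sparse_params)


def _two_gene_system_genome(mges):
    # system genes at indices 20, 21 -> bp midpoints 20450.5, 21450.5
    return make_genome("G1", contigs={
        "c1": (50, [(20, "RM", "sysA"), (21, "RM", "sysA")])}, mges=mges)


def test_no_mges_means_chromosome():
    g = _two_gene_system_genome([])
    assert assign_compartments(g) == {"sysA": "chromosome"}


def test_fully_contained_in_prophage():
    g = _two_gene_system_genome(
        [make_mge("G1", "c1", 15001, 25000, "phage_prophage")])
    assert assign_compartments(g) == {"sysA": "phage_prophage"}


def test_straddling_system_is_chromosomal():
    # second gene's midpoint (21450.5) outside the interval
    g = _two_gene_system_genome(
        [make_mge("G1", "c1", 15001, 21000, "phage_prophage")])
    assert assign_compartments(g) == {"sysA": "chromosome"}
    # but the majority rule keeps... 1 of 2 is not a strict majority
    assert assign_compartments(g, containment="majority") == {
        "sysA": "chromosome"}


def test_priority_resolves_nested_elements():
    mges = [make_mge("G1", "c1", 10001, 30000, "plasmid"),
            make_mge("G1", "c1", 15001, 25000, "integron")]
    g = _two_gene_system_genome(mges)
    assert assign_compartments(g) == {"sysA": "integron"}
    assert assign_compartments(
        g, priority=("plasmid", "integron", "phage_prophage", "ice_ime")
    ) == {"sysA": "plasmid"}


def test_priority_irrelevant_when_not_overlapping():
    g = _two_gene_system_genome(
        [make_mge("G1", "c1", 15001, 25000, "plasmid"),
         make_mge("G1", "c1", 30001, 40000, "integron")])
    for prio in (("ice_ime", "integron", "phage_prophage", "plasmid"),
                 ("plasmid", "phage_prophage", "integron", "ice_ime")):
        assert assign_compartments(g, priority=prio) == {"sysA": "plasmid"}


# ---------------------------------------------------------------------------
# O/E mathematics
# ---------------------------------------------------------------------------

def _toy_assignments():
    # A: 20 systems (10 plasmid / 10 chromosome); B: 80 (all chromosome)
    return ([("A", "plasmid")] * 10 + [("A", "chromosome")] * 10
            + [("B", "chromosome")] * 80)


def test_oe_expected_and_ratio_toy():
    t = oe_table(_toy_assignments())
    assert t.expected.at["A", "plasmid"] == pytest.approx(2.0)
    assert t.ratio.at["A", "plasmid"] == pytest.approx(5.0)


def test_oe_chi2_yates_hand_formula():
    """2x2 collapse [[10,10],[0,80]]: Yates statistic by the closed form
    N(|ad-bc|-N/2)^2 / (r1 r2 c1 c2) = 100*(800-50)^2/(20*80*10*90)."""
    t = oe_table(_toy_assignments())
    hand = 100 * (abs(10 * 80 - 10 * 0) - 50) ** 2 / (20 * 80 * 10 * 90)
    assert hand == pytest.approx(39.0625)
    assert t.chi2.at["A", "plasmid"] == pytest.approx(hand)
    assert t.pvalue.at["A", "plasmid"] < 1e-8
    # without continuity correction the statistic is larger
    t2 = oe_table(_toy_assignments(), correction=False)
    assert t2.chi2.at["A", "plasmid"] == pytest.approx(
        100 * (10 * 80) ** 2 / (20 * 80 * 10 * 90))


def test_oe_independence_gives_unit_ratios():
    pairs = []
    for fam, n_f in (("A", 40), ("B", 60)):
        for comp, frac in (("chromosome", 0.75), ("plasmid", 0.25)):
            pairs.extend([(fam, comp)] * int(n_f * frac))
    t = oe_table(pairs)
    assert np.allclose(t.ratio.to_numpy(), 1.0)


def test_oe_margin_conservation():
    rng = np.random.default_rng(3)
    fams = rng.choice(list("ABCDE"), size=500)
    comps = rng.choice(["chromosome", "plasmid", "phage_prophage"], size=500)
    t = oe_table(list(zip(fams, comps)))
    assert np.allclose(t.expected.sum(axis=1), t.family_totals, atol=1e-9)
    assert np.allclose(t.expected.sum(axis=0), t.compartment_totals,
                       atol=1e-9)
    assert t.grand_total == 500


def test_oe_empty_raises():
    with pytest.raises(DataError):
        oe_table([])


def test_permutation_null_brackets_unity():
    """Shuffling compartment labels gives O/E distributions around 1."""
    rng = np.random.default_rng(5)
    fams = np.array(["A"] * 120 + ["B"] * 60 + ["C"] * 20)
    comps = np.array(["x"] * 50 + ["y"] * 150)
    n = len(fams)
    ratios = {f: [] for f in "ABC"}
    for _ in range(1000):
        perm = rng.permutation(n)
        shuffled = comps[perm]
        for f in "ABC":
            o = np.sum((fams == f) & (shuffled == "x"))
            e = np.sum(fams == f) * np.sum(comps == "x") / n
            ratios[f].append(o / e)
    for f in "ABC":  # every family here has total >= 20
        lo, hi = np.quantile(ratios[f], [0.025, 0.975])
        assert lo <= 1.0 <= hi


def test_island_oe_no_islands_all_non_di(toy_cohort):
    t = island_oe_table(toy_cohort, [])
    assert list(t.observed.columns) == ["non-DI"]
    assert t.observed["non-DI"].sum() == t.grand_total


def test_island_oe_direction_forced():
    # all X systems in islands, X rare overall -> O/E > 1 for (X, DI)
    defense = [(10, "X"), (11, "Y"), (12, "X"), (13, "Z"), (14, "X")]
    g = make_genome("G1", contigs={"c1": (200, defense
                                          + [(100 + 13 * i, "RM")
                                             for i in range(6)])})
    islands = detect_islands_cohort([g])
    assert len(islands) == 1
    t = island_oe_table([g], islands)
    assert t.ratio.at["X", "DI"] > 1


def test_planted_island_enrichment_recovered():
    cohort, truth = generate_cohort(sparse_params(CohortParams(
        n_genomes=400, seed=17, island_spec=IslandSpec(n_islands=20))))
    t = island_oe_table(cohort, detect_islands_cohort(cohort))
    fl = set(FIRST_LINE_NAMED)
    acc = [f for f in t.ratio.index
           if f not in fl and t.family_totals[f] >= 5]
    med = float(t.ratio.loc[acc, "DI"].median())
    assert 2.0 <= med <= 4.0
    # first-line families are not enriched in islands
    fl_med = float(t.ratio.loc[[f for f in t.ratio.index if f in fl],
                               "DI"].median())
    assert fl_med < 1.0


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def test_density_simple_arithmetic():
    g = make_genome("G1", contigs={
        "c1": (100, [(20, "RM", "sysA"), (21, "RM", "sysA")])},
        mges=[make_mge("G1", "c1", 15001, 25000, "plasmid")])
    dens = compartment_density([g])
    assert dens["plasmid"] == pytest.approx(1 / 10.0)  # 1 system / 10 kb
    assert dens["chromosome"] == pytest.approx(0.0)


def test_density_zero_systems():
    g = make_genome("G1", contigs={"c1": (100, [])},
                    mges=[make_mge("G1", "c1", 1, 10000, "plasmid")])
    dens = compartment_density([g])
    assert (dens == 0).all()


def test_density_planted_multiplier_recovered():
    """Median pooled MGE/chromosome density ratio over seeds near the
    planted 5x multiplier."""
    ratios = []
    for seed in range(5):
        cohort, _ = generate_cohort(sparse_params(CohortParams(
            n_genomes=300, seed=seed, island_spec=IslandSpec(n_islands=10))))
        n_res = n_tot = 0
        bp_mge = bp_tot = 0
        for ga in cohort:
            comp = assign_compartments(ga)
            n_res += sum(1 for v in comp.values() if v != "chromosome")
            n_tot += len(comp)
            bp_mge += sum(m.length_bp for m in ga.mges)
            bp_tot += ga.qc.size_bp
        ratios.append((n_res / (bp_mge / 1000))
                      / ((n_tot - n_res) / ((bp_tot - bp_mge) / 1000)))
    assert 4.0 <= float(np.median(ratios)) <= 6.0


def test_mge_oe_on_generated_cohort_runs():
    cohort, _ = generate_cohort(sparse_params(CohortParams(
        n_genomes=60, seed=23)))
    t = mge_oe_table(cohort)
    assert "chromosome" in t.observed.columns
    long = t.to_long()
    assert {"family", "compartment", "oe_ratio"} <= set(long.columns)
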