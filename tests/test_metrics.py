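"""Defensome metrics: profiles, prevalence, partitions, filters, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genome
from defensome.errors import DataError
from defensome.io import GenomeQC
from defensome.metrics import (combine_totals, cohort_totals, family_share,
                               fit_exponential_decline, hq_filter,
                               partition_first_line, prevalence,
                               profile_genome, spearman)
from defensome.simulate import (CohortParams, IslandSpec, generate_cohort,
                                sparse_params)
import pandas as pd


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_profile_zero_systems():
    g = make_genome("G1", contigs={"c1": (10, [])}, size_bp=2_000_000)
    p = profile_genome(g)
    assert (p.n_systems, p.density_per_mb, p.n_families) == (0, 0.0, 0)


def test_profile_density_arithmetic():
    defense = [(i, f"F{i}") for i in range(0, 80, 10)]  # 8 systems
    g = make_genome("G1", contigs={"c1": (100, defense)}, size_bp=2_500_000)
    p = profile_genome(g)
    assert p.n_systems == 8
    assert p.density_per_mb == pytest.approx(3.2)


def test_profile_single_family():
    g = make_genome("G1", contigs={"c1": (60, [(0, "RM"), (20, "RM"),
                                              (40, "RM")])})
    assert profile_genome(g).n_families == 1


def test_profile_density_scales_with_size():
    defense = [(0, "RM"), (20, "AbiE")]
    g1 = make_genome("G1", contigs={"c1": (40, defense)}, size_bp=1_000_000)
    g2 = make_genome("G2", contigs={"c1": (40, defense)}, size_bp=2_000_000)
    assert profile_genome(g1).density_per_mb == pytest.approx(
        2 * profile_genome(g2).density_per_mb)


# ---------------------------------------------------------------------------
# prevalence & partition
# ---------------------------------------------------------------------------

def _cohort_with_rm_in_two_of_four():
    g1 = make_genome("G1", contigs={"c1": (40, [(0, "RM"), (10, "RM"),
                                               (20, "RM")])})
    g2 = make_genome("G2", contigs={"c1": (40, [(0, "RM")])})
    g3 = make_genome("G3", contigs={"c1": (40, [(0, "AbiE")])})
    g4 = make_genome("G4", contigs={"c1": (40, [])})
    return [g1, g2, g3, g4]


def test_prevalence_counts_genomes_once_but_totals_all():
    prev = prevalence(_cohort_with_rm_in_two_of_four())
    rm = prev.set_index("family").loc["RM"]
    assert rm["n_genomes_with"] == 2
    assert rm["prevalence"] == pytest.approx(0.5)
    assert rm["total_systems"] == 4
    assert "CBASS" not in set(prev["family"])  # absent families omitted


def test_prevalence_totals_conservation():
    cohort, _ = generate_cohort(sparse_params(CohortParams(
        n_genomes=60, seed=2)))
    prev = prevalence(cohort)
    assert prev["total_systems"].sum() == cohort_totals(cohort)["n_systems"]


def test_prevalence_empty_cohort_raises():
    with pytest.raises(DataError):
        prevalence([])


def test_partition_threshold_rule():
    prev = pd.DataFrame({"family": ["A", "B", "C"],
                         "prevalence": [0.5, 0.12, 0.09],
                         "n_genomes_with": [5, 2, 1],
                         "total_systems": [9, 2, 1]})
    fl, acc = partition_first_line(prev)
    assert fl == {"A", "B"} and acc == {"C"}


def test_partition_boundary_is_strict():
    prev = pd.DataFrame({"family": ["A", "B"], "prevalence": [0.10, 0.05],
                         "n_genomes_with": [1, 1], "total_systems": [1, 1]})
    fl, acc = partition_first_line(prev)
    assert fl == set() and acc == {"A", "B"}


def test_partition_disjoint_and_covering():
    cohort, _ = generate_cohort(sparse_params(CohortParams(
        n_genomes=80, seed=13)))
    prev = prevalence(cohort)
    fl, acc = partition_first_line(prev)
    assert fl & acc == set()
    assert fl | acc == set(prev["family"])


def test_top_weight_family_has_top_prevalence_across_seeds():
    # Zipf weights put RM first; rank agreement over 20 seeds
    wins = 0
    for seed in range(20):
        cohort, _ = generate_cohort(sparse_params(CohortParams(
            n_genomes=150, seed=seed, island_spec=IslandSpec(n_islands=0))))
        prev = prevalence(cohort)
        wins += prev.iloc[0]["family"] == "RM"
    assert wins == 20


# ---------------------------------------------------------------------------
# family share
# ---------------------------------------------------------------------------

def test_family_share():
    cohort = _cohort_with_rm_in_two_of_four()
    assert family_share(cohort, {"RM", "AbiE"}) == pytest.approx(1.0)
    assert family_share(cohort, set()) == 0.0
    assert family_share(cohort, {"RM"}) == pytest.approx(4 / 5)


def test_family_share_no_systems_raises():
    g = make_genome("G1", contigs={"c1": (10, [])})
    with pytest.raises(DataError):
        family_share([g], {"RM"})


# ---------------------------------------------------------------------------
# HQ filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("comp,cont,n50,expected", [
    (95.0, 2.0, 150_000, True),    # 95-10=85 > 70
    (91.0, 4.5, 200_000, False),   # 91-22.5=68.5 fails the penalty term
    (95.0, 2.0, 100_000, False),   # N50 boundary is strict
    (90.0, 1.0, 150_000, False),   # completeness boundary is strict
    (96.0, 5.0, 150_000, False),   # contamination boundary is strict
    (95.0, 4.9, 150_000, True),    # 95-24.5=70.5 > 70, all clauses pass
    (91.0, 0.0, 150_000, True),
])
def test_hq_filter_truth_table(comp, cont, n50, expected):
    qc = GenomeQC("G1", size_bp=3_000_000, n50_bp=n50, completeness=comp,
                  contamination=cont)
    assert hq_filter(qc) is expected


def test_hq_filter_penalty_boundary_strict():
    # completeness - 5*contamination == 70 exactly -> fail
    qc = GenomeQC("G1", 3_000_000, 150_000, completeness=95.0,
                  contamination=5.0)
    assert hq_filter(qc) is False
    qc2 = GenomeQC("G1", 3_000_000, 150_000, completeness=95.1,
                   contamination=4.98)
    assert hq_filter(qc2) is True  # 95.1 - 24.9 = 70.2 > 70


# ---------------------------------------------------------------------------
# exponential decline
# ---------------------------------------------------------------------------

def test_exponential_exact_generating_model():
    # frequencies 64,32,16,8,4,2,1 at k=0..6: rate = ln 2 exactly
    counts = []
    for k, f in enumerate([64, 32, 16, 8, 4, 2, 1]):
        counts.extend([k] * f)
    rate, r2 = fit_exponential_decline(counts)
    assert rate == pytest.approx(np.log(2), abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_exponential_uniform_gives_zero_rate():
    counts = [0] * 10 + [1] * 10 + [2] * 10 + [3] * 10
    rate, _ = fit_exponential_decline(counts)
    assert rate == pytest.approx(0.0, abs=1e-12)


def test_exponential_geometric_recovery():
    rng = np.random.default_rng(0)
    x = rng.geometric(0.4, size=5000) - 1
    rate, r2 = fit_exponential_decline(x)
    assert rate == pytest.approx(-np.log(0.6), abs=0.05)
    assert r2 > 0.9


def test_exponential_needs_three_bins():
    with pytest.raises(DataError):
        fit_exponential_decline([1, 1, 2, 2])


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------

def test_spearman_perfect_and_inverse():
    x = [1, 2, 3, 4, 5]
    rho, _ = spearman(x, x)
    assert rho == pytest.approx(1.0)
    rho, _ = spearman(x, [-v for v in x])
    assert rho == pytest.approx(-1.0)


def test_spearman_toy_hand_value():
    # d^2 = 6 over n=6: rho = 1 - 6*6/(6*35) = 0.828571...
    rho, p = spearman([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
    assert rho == pytest.approx(1 - 36 / 210, abs=1e-12)
    assert 0 < p < 0.05


def test_spearman_constant_raises():
    with pytest.raises(DataError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(-100, 100), min_size=4, max_size=30, unique=True))
def test_spearman_antisymmetric_under_negation(xs):
    ys = list(range(len(xs)))
    rho1, _ = spearman(xs, ys)
    rho2, _ = spearman([-v for v in xs], ys)
    assert rho1 == pytest.approx(-rho2)


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------

def test_combine_totals_sums_domains():
    bact = {"n_systems": 88_166, "n_defense_genes": 185_355}
    arch = {"n_systems": 2_658, "n_defense_genes": 5_455}
    tot = combine_totals([bact, arch])
    assert tot == {"n_systems": 90_824, "n_defense_genes": 190_810}


def test_combine_totals_rejects_family_counts():
    with pytest.raises(DataError):
        combine_totals([{"n_families": 139}, {"n_families": 81}])
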