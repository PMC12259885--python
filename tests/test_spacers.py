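"""Spacer-protospacer matching, host links, anti-defense tallies, novelty."""

import numpy as np
import pandas as pd
import pytest

from defensome.errors import CrossRefError, DataError
from defensome.io import GeneRecord, SequenceRecord
from defensome.simulate import (generate_phage_annotations, generate_phages,
                                generate_spacer_set)
from defensome.spacers import (find_protospacers, link_hosts,
                               n_targeted_phages, novelty_classify, revcomp,
                               tally_anti_defense, colocalized_anti_defense)
from oracles import oracle_protospacers, rc


def _seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_identity_hit():
    rng = np.random.default_rng(1)
    phage = SequenceRecord("P", _seq(rng, 400))
    spacer = SequenceRecord("S", phage.sequence[100:136])
    [hit] = find_protospacers([spacer], [phage])
    assert (hit.phage_start, hit.strand, hit.mismatches) == (101, "+", 0)
    assert hit.coverage == pytest.approx(1.0)
    assert hit.identity == pytest.approx(1.0)


def test_reverse_complement_hit_coordinates():
    rng = np.random.default_rng(2)
    phage = SequenceRecord("P", _seq(rng, 400))
    spacer = SequenceRecord("S", revcomp(phage.sequence[200:232]))
    [hit] = find_protospacers([spacer], [phage])
    assert hit.strand == "-"
    assert hit.phage_start == 201  # forward-strand coordinate of the window
    assert hit.aligned_len == 32


def test_two_substitutions_no_hit():
    rng = np.random.default_rng(3)
    phage = SequenceRecord("P", _seq(rng, 300))
    s = list(phage.sequence[50:86])
    for p in (10, 20):
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    assert find_protospacers([SequenceRecord("S", "".join(s))], [phage]) == []


def test_one_interior_substitution_full_length_hit():
    rng = np.random.default_rng(4)
    phage = SequenceRecord("P", _seq(rng, 300))
    s = list(phage.sequence[50:86])  # L = 36
    s[18] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[18]]
    [hit] = find_protospacers([SequenceRecord("S", "".join(s))], [phage])
    assert hit.mismatches == 1
    assert hit.coverage == pytest.approx(1.0)
    assert hit.phage_start == 51


def test_n_never_matches():
    phage = SequenceRecord("P", "ACGT" * 30)
    spacer = "ACGT" * 6 + "A"  # 25 bp, matches exactly
    assert find_protospacers([SequenceRecord("S", spacer)], [phage])
    with_n = spacer[:12] + "N" + spacer[13:]
    hits = find_protospacers([SequenceRecord("S", with_n)], [phage])
    assert all(h.mismatches >= 1 for h in hits)


def test_empty_spacer_rejected():
    with pytest.raises(Exception):
        SequenceRecord("S", "")


def test_oracle_equivalence_random_instances():
    """Optimized matcher equals the exhaustive scanner on 500 instances,
    half with a planted noisy copy, half pure random."""
    rng = np.random.default_rng(11)
    for case in range(500):
        phage = _seq(rng, int(rng.integers(120, 400)))
        L = int(rng.integers(25, 46))
        if case % 2 == 0:
            p0 = int(rng.integers(0, len(phage) - L + 1))
            s = list(phage[p0:p0 + L])
            for _ in range(int(rng.integers(0, 3))):  # 0-2 substitutions
                q = int(rng.integers(L))
                s[q] = "ACGT"[int(rng.integers(4))]
            spacer = "".join(s)
            if rng.random() < 0.5:
                spacer = rc(spacer)
        else:
            spacer = _seq(rng, L)
        got = find_protospacers([SequenceRecord("S", spacer)],
                                [SequenceRecord("P", phage)])
        got_t = sorted((h.phage_start, h.strand, h.aligned_len, h.mismatches)
                       for h in got)
        assert got_t == oracle_protospacers(spacer, phage, 1, 0.95)


def test_strand_involution():
    """Matching against reverse-complemented phages swaps strands and maps
    coordinates by pos' = len - (pos + aligned_len) + 2."""
    phages = generate_phages(4, (300, 600), seed=21)
    spacers, _ = generate_spacer_set(phages, n_pos=8, n_neg=0, seed=21)
    fwd = find_protospacers(spacers, phages)
    rev = find_protospacers(
        spacers, [SequenceRecord(p.seq_id, revcomp(p.sequence))
                  for p in phages])
    lens = {p.seq_id: len(p.sequence) for p in phages}

    def canon(hits, flip):
        out = set()
        for h in hits:
            if flip:
                pos = lens[h.phage_id] - (h.phage_start + h.aligned_len) + 2
                strand = "-" if h.strand == "+" else "+"
            else:
                pos, strand = h.phage_start, h.strand
            out.add((h.spacer_id, h.phage_id, pos, strand, h.aligned_len,
                     h.mismatches))
        return out

    assert canon(fwd, False) == canon(rev, True)


def test_planted_spacers_recovered_and_negatives_silent():
    phages = generate_phages(6, (500, 1500), seed=5)
    spacers, truth = generate_spacer_set(phages, n_pos=15, n_neg=15, seed=5)
    hits = find_protospacers(spacers, phages)
    by_spacer = {}
    for h in hits:
        by_spacer.setdefault(h.spacer_id, []).append(h)
    for p in truth.planted_protospacers:
        matches = [h for h in by_spacer.get(p.spacer_id, [])
                   if h.phage_id == p.phage_id
                   and h.phage_start == p.position
                   and h.strand == p.strand]
        assert matches, f"planted {p.spacer_id} not recovered"
        assert matches[0].mismatches == p.n_mismatches
    for h in hits:
        assert not h.spacer_id.startswith("spacer_neg")


# ---------------------------------------------------------------------------
# host links
# ---------------------------------------------------------------------------

def _hit(spacer, phage, start=10):
    from defensome.spacers import SpacerHit
    return SpacerHit(spacer, phage, start, "+", 30, 0, 1.0, 1.0)


def test_link_hosts_support_counts():
    hits = [_hit("s1", "P1", 5), _hit("s1", "P1", 50), _hit("s2", "P1", 99)]
    links = link_hosts(hits, {"s1": "G1", "s2": "G1"})
    assert len(links) == 1
    assert links.iloc[0]["n_hits"] == 3
    assert n_targeted_phages(links) == 1


def test_link_hosts_empty_and_unknown():
    assert len(link_hosts([], {})) == 0
    with pytest.raises(CrossRefError):
        link_hosts([_hit("sX", "P1")], {"s1": "G1"})


def test_targeted_phage_count_from_planted_truth():
    hits = [_hit("s1", "P1"), _hit("s2", "P1"), _hit("s3", "P2"),
            _hit("s4", "P2"), _hit("s5", "P2")]
    links = link_hosts(hits, {f"s{i}": f"G{i}" for i in range(1, 6)})
    assert n_targeted_phages(links) == 2


# ---------------------------------------------------------------------------
# anti-defense tallies
# ---------------------------------------------------------------------------

def _anti_gene(phage, idx, atype):
    return GeneRecord(f"{phage}|g{idx}", phage, phage, idx, idx * 1000 + 1,
                      idx * 1000 + 900, "+",
                      frozenset({f"anti_defense:{atype}"}))


def test_tally_printed_type_counts():
    counts = {"anti-CRISPR": 27, "anti-RM": 8, "anti-Thoeris": 8,
              "anti-CBASS": 6, "anti-Dnd": 5}
    genes, phage_i = [], 0
    for atype, n in counts.items():
        for k in range(n):
            genes.append(_anti_gene(f"P{phage_i % 43}", k, atype))
            phage_i += 1
    tally = tally_anti_defense(genes, phage_universe_size=601)
    assert tally.n_genes == 54
    assert tally.per_type == dict(sorted(counts.items()))


def test_tally_prevalence_printed_fraction():
    genes = [_anti_gene(f"P{i}", 0, "anti-RM") for i in range(625)]
    tally = tally_anti_defense(genes, phage_universe_size=40_302)
    assert tally.n_phages == 625
    assert tally.prevalence_pct == 1.6


def test_tally_empty_and_inconsistent():
    t = tally_anti_defense([], phage_universe_size=10)
    assert (t.n_genes, t.n_phages, t.prevalence_pct) == (0, 0, 0.0)
    with pytest.raises(DataError):
        tally_anti_defense([_anti_gene("P1", 0, "Acr"),
                            _anti_gene("P2", 0, "Acr")],
                           phage_universe_size=1)


def test_colocalized_anti_defense():
    genes = [_anti_gene("P1", 0, "anti-CRISPR"),
             _anti_gene("P1", 5, "anti-RM"),
             _anti_gene("P2", 3, "anti-Thoeris")]
    out = colocalized_anti_defense(genes)
    assert len(out) == 1
    assert out[0]["phage_id"] == "P1"
    assert out[0]["context"] == ["anti-CRISPR", "anti-RM"]


def test_colocalized_matches_planted_truth():
    ids = [f"P{i:03d}" for i in range(80)]
    genes, truth = generate_phage_annotations(ids, seed=9, carrier_frac=0.3,
                                              multi_frac=0.5)
    out = colocalized_anti_defense(genes)
    assert sorted(r["phage_id"] for r in out) == \
        truth.multi_anti_defense_phages


# ---------------------------------------------------------------------------
# novelty
# ---------------------------------------------------------------------------

def test_novelty_truth_table_and_rule():
    df = pd.DataFrame({
        "query": ["q1", "q2", "q3", "q4"],
        "coverage": [0.95, 0.85, 0.95, 0.70],
        "identity": [0.95, 0.85, 0.85, 0.95],
    })
    got = novelty_classify(df, queries=["q1", "q2", "q3", "q4", "q5"])
    assert got == {"q1": "known", "q2": "novel", "q3": "novel",
                   "q4": "novel", "q5": "novel"}
    # under the OR reading one passing threshold suffices for "known"
    got_or = novelty_classify(df, rule="or")
    assert got_or == {"q1": "known", "q2": "known", "q3": "known",
                      "q4": "known"}


def test_novelty_best_of_several_hits():
    df = pd.DataFrame({"query": ["q1", "q1"],
                       "coverage": [0.5, 0.9],
                       "identity": [0.99, 0.92]})
    assert novelty_classify(df) == {"q1": "known"}


def test_novelty_input_validation():
    with pytest.raises(DataError):
        novelty_classify(pd.DataFrame({"query": ["q"], "coverage": [1.5],
                                       "identity": [0.5]}))
    with pytest.raises(DataError):
        novelty_classify(pd.DataFrame({"query": ["q"]}))
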