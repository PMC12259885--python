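"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations of the two core algorithms
(maximal defense-gene chaining, ungapped spacer matching) written from the
rule statements alone; they share no code with the package implementations
they check.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_islands(defense, max_gap, min_def_genes, min_families,
                   semantics="intervening"):
    """Every maximal qualifying chain on one contig, by exhaustive check.

    ``defense`` is a list of (index, families-frozenset) sorted or not.
    A candidate run (i..j) of defense genes qualifies as a *maximal chain*
    iff every consecutive pair inside it respects the gap rule and the
    flanking defense genes (if any) do not.  Returns a list of
    (first_index, last_index, n_defense, families) tuples.
    """
    limit = max_gap + 1 if semantics == "intervening" else max_gap
    genes = sorted(defense)
    n = len(genes)
    out = []
    for i in range(n):
        for j in range(i, n):
            ok = all(genes[k + 1][0] - genes[k][0] <= limit
                     for k in range(i, j))
            if not ok:
                continue
            if i > 0 and genes[i][0] - genes[i - 1][0] <= limit:
                continue  # extendable left: not maximal
            if j < n - 1 and genes[j + 1][0] - genes[j][0] <= limit:
                continue  # extendable right: not maximal
            fams = frozenset().union(*(f for _, f in genes[i:j + 1]))
            if j - i + 1 >= min_def_genes and len(fams) >= min_families:
                out.append((genes[i][0], genes[j][0], j - i + 1, fams))
    return sorted(out)


def oracle_protospacers(spacer: str, phage: str, max_mm: int,
                        min_cov: float):
    """All collapsed hits of one spacer on one phage by exhaustive scan.

    Enumerates every substring of the spacer with length >= ceil(min_cov*L)
    on both strands against every phage window, collapses overlapping
    alignments keeping the best by (mismatches, -length, start, '+'-first).
    Returns a sorted list of (start_1based, strand, aligned_len, mismatches).
    """
    import math
    L = len(spacer)
    lmin = math.ceil(min_cov * L)
    cands = []
    for strand, query in (("+", spacer), ("-", rc(spacer))):
        for alen in range(lmin, L + 1):
            for off in range(0, L - alen + 1):
                sub = query[off:off + alen]
                for p0 in range(0, len(phage) - alen + 1):
                    mm = 0
                    for a, b in zip(sub, phage[p0:p0 + alen]):
                        if a != b or a == "N" or b == "N":
                            mm += 1
                            if mm > max_mm:
                                break
                    else:
                        cands.append((mm, -alen, p0,
                                      0 if strand == "+" else 1,
                                      strand, alen))
    cands.sort()
    taken = []
    hits = []
    for mm, _na, p0, _r, strand, alen in cands:
        if any(p0 < e and p0 + alen > s for s, e in taken):
            continue
        taken.append((p0, p0 + alen))
        hits.append((p0 + 1, strand, alen, mm))
    return sorted(hits)
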