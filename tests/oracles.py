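"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately written in a different style from the
package implementation (set comprehensions, exact rational arithmetic,
memoized recursion) so agreement is meaningful.
"""

from fractions import Fraction
from functools import lru_cache
from math import comb

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rc(seq):
    return "".join(COMPLEMENT[c] for c in reversed(seq))


# ---------------------------------------------------------------- consensus

def recount_summary(rows, genes, mirna_id):
    """Brute-force per-miRNA tallies over raw rows.

    ``rows`` are tuples (mirna, gene, source, source_class, direction,
    confidence) with plain strings.
    """
    g = {x.upper() for x in genes}
    mine = [r for r in rows if r[0].lower() == mirna_id.lower() and r[1].upper() in g]
    validated = [r for r in mine if r[3] == "validated"]
    pos = sum(1 for r in validated if r[4] == "positive")
    neg = sum(1 for r in validated if r[4] == "negative")
    best = {}
    for r in mine:
        gene = r[1].upper()
        best[gene] = max(best.get(gene, 0.0), r[5])
    return {
        "n_sources": len({r[2] for r in mine}),
        "n_validated_genes": len({r[1].upper() for r in validated}),
        "n_predicted_genes": len({r[1].upper() for r in mine if r[3] == "predicted"}),
        "positive_evidence": pos,
        "negative_evidence": neg,
        "net_evidence": pos - neg,
        "integrated_score": sum(best.values()),
        "coverage": len({r[1].upper() for r in mine}),
    }


def brute_rank(rows, genes, min_coverage, top_k):
    """Independent filter + sort of recounted summaries; returns miRNA ids."""
    ids = []
    for r in rows:
        if r[0].lower() not in [i.lower() for i in ids]:
            ids.append(r[0])
    scored = []
    for m in ids:
        s = recount_summary(rows, genes, m)
        if s["coverage"] >= min_coverage:
            scored.append((m, s))
    scored.sort(
        key=lambda t: (
            -t[1]["n_validated_genes"],
            -t[1]["n_predicted_genes"],
            -t[1]["net_evidence"],
            -t[1]["integrated_score"],
            t[0].lower(),
        )
    )
    return [m for m, _ in scored[:top_k]]


# ------------------------------------------------------------------- duplex

def scan_seed_sites(mirna, utr):
    """Exhaustive per-offset scan of all four seed patterns.

    Tests each full pattern at every UTR offset by string equality, then
    keeps the most specific match per seed-core occurrence.  Returns
    (start, end, site_type) triples sorted by start.
    """
    pat = {
        "8mer": (rc(mirna[1:8]) + "A", 1),  # core begins 1 into the pattern
        "7mer-m8": (rc(mirna[1:8]), 1),
        "7mer-A1": (rc(mirna[1:7]) + "A", 0),
        "6mer": (rc(mirna[1:7]), 0),
    }
    order = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    by_core = {}
    for name in reversed(order):  # most specific written last wins
        p, core_off = pat[name]
        for i in range(len(utr) - len(p) + 1):
            if utr[i : i + len(p)] == p:
                by_core[i + core_off] = (i, i + len(p), name)
    return sorted(by_core.values())


def dp_align_score(mirna, window, match_wc=5.0, match_gu=1.0, mismatch=-3.0,
                   gap_open=-8.0, gap_extend=-2.0):
    """Affine-gap global alignment score by memoized recursion (score only)."""
    a = mirna[::-1]
    b = window
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "U"), ("U", "G")}

    def sc(x, y):
        return match_wc if (x, y) in wc else match_gu if (x, y) in gu else mismatch

    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def f(i, j, state):
        # best score aligning a[:i], b[:j] with the last column of kind
        # state: 0 pair, 1 gap consuming b, 2 gap consuming a
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        if state == 0:
            if i == 0 or j == 0:
                return NEG
            prev = max(f(i - 1, j - 1, s) for s in (0, 1, 2))
            return prev + sc(a[i - 1], b[j - 1])
        if state == 1:
            if j == 0:
                return NEG
            return max(
                f(i, j - 1, 0) + gap_open,
                f(i, j - 1, 1) + gap_extend,
                f(i, j - 1, 2) + gap_open,
            )
        if i == 0:
            return NEG
        return max(
            f(i - 1, j, 0) + gap_open,
            f(i - 1, j, 1) + gap_open,
            f(i - 1, j, 2) + gap_extend,
        )

    result = max(f(len(a), len(b), s) for s in (0, 1, 2))
    f.cache_clear()
    return result


# --------------------------------------------------------------- enrichment

def hypergeom_tail_exact(count, query_size, term_size, universe_size):
    """P[X >= count] via exact rational enumeration of the tail."""
    total = comb(universe_size, query_size)
    tail = sum(
        comb(term_size, k) * comb(universe_size - term_size, query_size - k)
        for k in range(count, min(term_size, query_size) + 1)
    )
    return float(Fraction(tail, total))


# --------------------------------------------------------------- statistics

def ks_stat_brute(values, mean, sd):
    """Sup-distance between the ECDF and a normal CDF, by direct scan."""
    from scipy.stats import norm

    xs = sorted(values)
    n = len(xs)
    d = 0.0
    for i, x in enumerate(xs):
        F = norm.cdf(x, mean, sd)
        d = max(d, abs((i + 1) / n - F), abs(i / n - F))
    return d
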