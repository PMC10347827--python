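"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — enumeration and direct definitions —
and shares no code path with the package internals it checks.
"""
from __future__ import annotations

import itertools
import math
from fractions import Fraction


# ---------------------------------------------------------------------------
# Variant-representation oracle
# ---------------------------------------------------------------------------

def apply_variant(context: str, pos: int, ref: str, alt: str,
                  context_start: int = 1) -> str:
    """Resulting sequence after applying a variant to the context."""
    lo = pos - context_start
    assert context[lo:lo + len(ref)] == ref
    return context[:lo] + alt + context[lo + len(ref):]


def minimal_representation(context: str, pos: int, ref: str, alt: str,
                           context_start: int = 1):
    """Enumerate every (pos, ref, alt) describing the same edit of the
    context and return the one with minimal allele length, leftmost position.
    """
    target = apply_variant(context, pos, ref, alt, context_start)
    candidates = []
    n = len(context)
    for p in range(n):
        for rlen in range(0, n - p + 1):
            r = context[p:p + rlen]
            # alt must reconstruct the target: target = context[:p] + a + context[p+rlen:]
            a_len = len(target) - (n - rlen)
            if a_len < 0:
                continue
            a = target[p:p + a_len]
            if context[:p] + a + context[p + rlen:] != target:
                continue
            if r == a or not r or not a:
                continue  # VCF-style: non-empty, differing alleles
            candidates.append((len(r) + len(a), p, r, a))
    assert candidates, "no VCF representation found"
    size = min(c[0] for c in candidates)
    best = min(c for c in candidates if c[0] == size)
    _, p, r, a = best
    return p + context_start, r, a


# ---------------------------------------------------------------------------
# Fisher oracles
# ---------------------------------------------------------------------------

def _table_prob(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact hypergeometric probability of a 2x2 table given its margins."""
    n = a + b + c + d
    return (Fraction(math.comb(a + b, a)) * math.comb(c + d, c)
            / math.comb(n, a + c))


def fisher_2x2_oracle(table, alternative: str = "two_sided") -> float:
    """Full-enumeration Fisher p-value for a 2x2 table."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    p_obs = _table_prob(a, b, c, d)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        y = c1 - x
        p = _table_prob(x, r1 - x, y, r2 - y)
        if alternative == "two_sided":
            if p <= p_obs:
                total += p
        elif alternative == "greater":
            if x >= a:
                total += p
        elif alternative == "less":
            if x <= a:
                total += p
    return float(min(total, Fraction(1)))


def exact_rxc_oracle(table) -> float:
    """Full-enumeration probability-mass p-value for an r x 2 table."""
    rows = [sum(r) for r in table]
    col0 = sum(r[0] for r in table)

    def log_table_prob(xs):
        lp = Fraction(1)
        # P(table) = prod_i C(rows_i, x_i) / C(total, col0)
        for row, x in zip(rows, xs):
            lp *= math.comb(row, x)
        return Fraction(lp, math.comb(sum(rows), col0))

    obs = log_table_prob([r[0] for r in table])
    total = Fraction(0)
    ranges = [range(0, r + 1) for r in rows[:-1]]
    for head in itertools.product(*ranges):
        last = col0 - sum(head)
        if not (0 <= last <= rows[-1]):
            continue
        p = log_table_prob(list(head) + [last])
        if p <= obs:
            total += p
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# Affected-individual oracle
# ---------------------------------------------------------------------------

def affected_oracle(genotypes, sex, gene_of, xlinked, variant_set):
    """O(samples x variants^2) scan for pathogenic genotypes.

    ``genotypes``: {(sample, key): allele tuple}; missing means reference.
    Returns a set of (sample, gene, mechanism) triples.
    """
    samples = {s for s, _ in genotypes}
    found = set()
    variants = [v for v in variant_set if v in gene_of]
    for s in samples:
        for v1 in variants:
            g1 = genotypes.get((s, v1))
            if g1 is None:
                continue
            gene = gene_of[v1]
            male_x = sex[s] == "male" and gene in xlinked
            if male_x and any(a == 1 for a in g1):
                found.add((s, gene, "hemi"))
            elif len(g1) == 2 and g1 == (1, 1):
                found.add((s, gene, "hom"))
            if len(g1) == 2 and sum(g1) == 1 and not male_x:
                for v2 in variants:
                    if v2 <= v1 or gene_of[v2] != gene:
                        continue
                    g2 = genotypes.get((s, v2))
                    if g2 is None or len(g2) != 2 or sum(g2) != 1:
                        continue
                    if g1[0] != g2[0]:
                        found.add((s, gene, "comphet"))
    return found
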