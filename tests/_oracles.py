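"""Independent brute-force oracles used by the tests.

Deliberately naive: all-pairs numpy broadcasts for interval operations,
base-by-base counting for coverage, exhaustive enumeration for window
scanning and for the exact rank-sum and Fisher tests.  Nothing here
shares code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _arrays(ivs):
    chroms = np.array([iv.chrom for iv in ivs])
    starts = np.array([iv.start for iv in ivs])
    ends = np.array([iv.end for iv in ivs])
    return chroms, starts, ends


def brute_intersect(a, b, min_overlap=1):
    """Set of (a.name, b.name) with >= min_overlap shared bases."""
    if not a or not b:
        return set()
    ca, sa, ea = _arrays(a)
    cb, sb, eb = _arrays(b)
    olap = np.minimum.outer(ea, eb) - np.maximum.outer(sa, sb)
    mask = (ca[:, None] == cb[None, :]) & (olap >= min_overlap)
    return {(a[i].name, b[j].name) for i, j in np.argwhere(mask)}


def brute_window(a, b, distance):
    """Set of (a.name, b.name, gap) with same-chromosome gap <= distance."""
    if not a or not b:
        return set()
    ca, sa, ea = _arrays(a)
    cb, sb, eb = _arrays(b)
    gap = np.maximum(0, np.maximum.outer(sa, sb) - np.minimum.outer(ea, eb))
    mask = (ca[:, None] == cb[None, :]) & (gap <= distance)
    return {(a[i].name, b[j].name, int(gap[i, j])) for i, j in np.argwhere(mask)}


def brute_coverage(a, b, genome_size=1_000_000):
    """Per-a fraction covered by the union of b, by marking single bases."""
    masks: dict[str, np.ndarray] = {}
    for iv in b:
        masks.setdefault(iv.chrom, np.zeros(genome_size, dtype=bool))[
            iv.start : iv.end
        ] = True
    out = []
    for iv in a:
        m = masks.get(iv.chrom)
        covered = int(m[iv.start : iv.end].sum()) if m is not None else 0
        out.append(covered / (iv.end - iv.start))
    return out


def brute_stratify(a, b, bounds):
    """{(a.name, b.name): (gap, smallest qualifying bound)}."""
    out = {}
    for an, bn, g in brute_window(a, b, bounds[-1]):
        out[(an, bn)] = (g, min(x for x in bounds if g <= x))
    return out


def brute_scan(seq, weights, k):
    """Exhaustive top-k windows: (offset, strand, score) triples.

    ``weights`` is an (L, 4) ACGT matrix.  Window score is the positional
    product; N masks a window entirely; per-offset score is the max of
    forward and reverse-complement; ties prefer + then smaller offset.
    """
    L = weights.shape[0]
    idx = {b: i for i, b in enumerate("ACGT")}

    def win_score(s):
        if "N" in s or "n" in s:
            return None
        p = 1.0
        for pos, base in enumerate(s.upper()):
            p *= weights[pos, idx[base]]
        return p

    rows = []
    for off in range(len(seq) - L + 1):
        w = seq[off : off + L]
        f = win_score(w)
        r = win_score(revcomp(w))
        if f is None:
            continue
        score, strand = (f, "+") if f >= r else (r, "-")
        rows.append((off, strand, score))
    rows.sort(key=lambda t: (-t[2], t[0], 0 if t[1] == "+" else 1))
    return rows[:k]


def enum_rank_sum_p(x, y, alternative="two-sided"):
    """Exact rank-sum p by enumerating every split of the pooled data."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def ustat(xs, ys):
        return float(
            (xs[:, None] > ys[None, :]).sum()
            + 0.5 * (xs[:, None] == ys[None, :]).sum()
        )

    us = []
    for sel in itertools.combinations(range(len(pooled)), n1):
        sel = list(sel)
        rest = np.delete(pooled, sel)
        us.append(ustat(pooled[sel], rest))
    us = np.array(us)
    u_obs = ustat(x, y)
    p_le = float(np.mean(us <= u_obs))
    p_ge = float(np.mean(us >= u_obs))
    if alternative == "two-sided":
        return min(1.0, 2 * min(p_le, p_ge))
    return p_ge if alternative == "greater" else p_le


def enum_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        b_, c_ = r1 - a_, c1 - a_
        d_ = r2 - c_
        if min(b_, c_, d_) < 0:
            return None
        return comb(r1, a_) * comb(r2, c_) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for a_ in range(0, min(r1, c1) + 1):
        p = prob(a_)
        if p is not None and p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def bh_adjust(p):
    """Step-up BH by the textbook formula."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
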