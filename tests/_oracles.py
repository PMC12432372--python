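"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (plain Python loops, exact rational
arithmetic) and shares no code with the package under test.
"""

from __future__ import annotations

import math
from fractions import Fraction


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeom(M=a+b+c+d, K=a+c, n=a+b), by exact summation."""
    M, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(M, n)
    total = Fraction(0)
    for x in range(a, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(M - K, n - x), denom)
    return float(total)


def hypergeom_pmf_table(M: int, K: int, n: int) -> list[Fraction]:
    """Exact pmf of Hypergeom(M, K, n) over a = max(0, K+n-M) .. min(K, n)."""
    denom = math.comb(M, n)
    lo, hi = max(0, K + n - M), min(K, n)
    return [
        Fraction(math.comb(K, x) * math.comb(M - K, n - x), denom) for x in range(lo, hi + 1)
    ]


def brute_force_kataegis(sample_rows, window_n=10, max_span_bp=10_000, threshold=1e-4):
    """Naive kataegis caller for one sample.

    ``sample_rows``: iterable of (chrom, pos).  Returns a list of event dicts
    {chrom, start, end, n_mutations, p}.  Mirrors the documented detection
    semantics — ADL pooled over chromosomes, strict below-ADL, background
    includes the window, transitive chains pooled with greedy prefix
    splitting — but is written independently with per-window loops and exact
    rational tail sums.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in sample_rows:
        by_chrom.setdefault(chrom, []).append(int(pos))
    for v in by_chrom.values():
        v.sort()

    all_dists = []
    for v in by_chrom.values():
        for i in range(1, len(v)):
            all_dists.append(v[i] - v[i - 1])
    if not all_dists:
        return []
    adl = (sum(all_dists) / len(all_dists)) / 10.0
    bg_below = sum(1 for x in all_dists if x < adl)
    bg_above = len(all_dists) - bg_below

    events = []
    for chrom in sorted(by_chrom):
        v = by_chrom[chrom]
        cands = []  # (first_idx, last_idx, p)
        for i in range(len(v) - window_n + 1):
            j = i + window_n - 1
            if v[j] - v[i] > max_span_bp:
                continue
            w_below = sum(1 for k in range(i, j) if v[k + 1] - v[k] < adl)
            w_above = (window_n - 1) - w_below
            p = hypergeom_upper_tail(w_below, w_above, bg_below, bg_above)
            if p < threshold:
                cands.append((i, j, p))
        # transitive overlap chains (windows share an index or a bp)
        chains = []
        for c in cands:
            if chains and (
                c[0] <= max(x[1] for x in chains[-1])
                or v[c[0]] <= max(v[x[1]] for x in chains[-1])
            ):
                chains[-1].append(c)
            else:
                chains.append([c])

        def pooled(first, last):
            w_below = sum(1 for k in range(first, last) if v[k + 1] - v[k] < adl)
            w_above = (last - first) - w_below
            return hypergeom_upper_tail(w_below, w_above, bg_below, bg_above)

        for chain in chains:
            i = 0
            while i < len(chain):
                j_pass = i
                first = chain[i][0]
                last = chain[i][1]
                best = (first, last, pooled(first, last))
                for j in range(i + 1, len(chain)):
                    f = min(chain[k][0] for k in range(i, j + 1))
                    l = max(chain[k][1] for k in range(i, j + 1))
                    p = pooled(f, l)
                    if p < threshold:
                        j_pass, best = j, (f, l, p)
                    else:
                        break
                events.append(
                    {
                        "chrom": chrom,
                        "start": v[best[0]],
                        "end": v[best[1]],
                        "n_mutations": best[1] - best[0] + 1,
                        "p": best[2],
                    }
                )
                i = j_pass + 1
    return events


def nnls_two_orthogonal(x, a, b):
    """Closed-form NNLS for two mutually orthogonal design columns.

    With a ⟂ b the least-squares problem separates; each coefficient is the
    clipped scalar projection max(0, <x, v> / <v, v>).
    """
    import numpy as np

    x, a, b = (np.asarray(v, dtype=float) for v in (x, a, b))
    assert abs(a @ b) < 1e-12
    return max(0.0, (x @ a) / (a @ a)), max(0.0, (x @ b) / (b @ b))
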