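"""Independent brute-force oracles used by the test suite.

Each oracle re-derives its quantity from first principles (enumeration,
naive recounting) without touching the implementation path it checks.
"""

import math
from math import comb


def literal_oracle(n: int, p: float) -> int | None:
    """Smallest m from which the binomial-vs-0.01·m/(n−m) inequality holds
    for every m' ≥ m, by direct evaluation (RHS = +inf at m = n)."""

    def holds(k):
        lhs = math.comb(n, k) * p**k * (1 - p) ** (n - k)
        rhs = math.inf if k == n else 0.01 * k / (n - k)
        return lhs < rhs

    for m in range(1, n + 1):
        if all(holds(k) for k in range(m, n + 1)):
            return m
    return None


def fisher_oracle(a: int, b: int, c: int, d: int, eps: float = 1e-12) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration
    (sum of all table probabilities not exceeding the observed one)."""
    r1, r2, n = a + b, c + d, a + c
    denom = comb(r1 + r2, n)
    pobs = comb(r1, a) * comb(r2, n - a) / denom
    total = 0.0
    for k in range(max(0, n - r2), min(r1, n) + 1):
        pk = comb(r1, k) * comb(r2, n - k) / denom
        if pk <= pobs * (1 + eps):
            total += pk
    return min(total, 1.0)


def brute_force_islands(seq: str) -> list[tuple[int, int]]:
    """Naive CpG-island scan: recount every 501-bp window from scratch,
    merge marked windows, then exhaustively enumerate the sub-intervals of
    each merged region and keep the longest qualifying one (leftmost tie)."""

    def stats(s, e):
        w = seq[s:e]
        L = e - s
        nc, ng = w.count("C"), w.count("G")
        ncpg = w.count("CG")  # CG cannot overlap itself
        gc = (nc + ng) / L
        oe = ncpg * L / (nc * ng) if nc and ng else 0.0
        return gc, oe, "N" in w

    def qualifies(s, e):
        gc, oe, has_n = stats(s, e)
        return not has_n and gc > 0.55 and oe >= 0.65

    marked = [s for s in range(len(seq) - 500) if qualifies(s, s + 501)]
    regions = []
    for s in marked:
        if regions and s <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], s + 501)
        else:
            regions.append([s, s + 501])
    out = []
    for lo, hi in regions:
        best = None
        for length in range(hi - lo, 500, -1):
            for a in range(lo, hi - length + 1):
                if qualifies(a, a + length):
                    best = (a, a + length)
                    break
            if best:
                break
        if best:
            out.append(best)
    return out


def brute_force_dmrs(positions, config) -> list[tuple[int, int]]:
    """Naive seed-extend-merge: enumerate every step-aligned window, merge
    qualifying runs, apply the final site/length thresholds, then merge
    overlapping spans."""
    pos = sorted(positions)
    if not pos:
        return []
    step, w = config.step_bp, config.window_bp
    starts = range(0, pos[-1] + w, step)
    ok = {s: sum(s <= p < s + w for p in pos) >= config.seed_min_sites for s in starts}
    runs = []
    for s in starts:
        if not ok[s]:
            continue
        if runs and ok.get(s - step) and runs[-1][1] == s - step + w:
            runs[-1][1] = s + w
        else:
            runs.append([s, s + w])
    kept = [
        (s, e)
        for s, e in runs
        if sum(s <= p < e for p in pos) >= config.final_min_sites
        and e - s >= config.min_length_bp
    ]
    merged = []
    for s, e in sorted(kept):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]
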