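"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately naive, loop-based implementation kept
separate from the library code paths it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Exact HWE by full enumeration
# ---------------------------------------------------------------------------

def hwe_enumeration(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE p-value by enumerating every het count."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n - na
    rare = min(na, nb)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        aa = (na - h) // 2
        bb = (nb - h) // 2
        probs[h] = (
            2**h
            * comb(n, aa)
            * comb(n - aa, h)
            / comb(2 * n, na)
        )
    total = sum(probs.values())
    obs = probs[n_ab] / total
    return min(1.0, sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# GRM / frequency / distance loops
# ---------------------------------------------------------------------------

def freq_loop(dosage: np.ndarray) -> np.ndarray:
    n, m = dosage.shape
    out = np.empty(m)
    for j in range(m):
        num = den = 0
        for i in range(n):
            if dosage[i, j] != MISSING:
                num += dosage[i, j]
                den += 2
        out[j] = num / den if den else np.nan
    return out


def grm_loop(dosage: np.ndarray, method: str) -> np.ndarray:
    """Naive GRM over polymorphic SNPs with mean imputation."""
    p = freq_loop(dosage)
    keep = [j for j in range(dosage.shape[1]) if 0 < p[j] < 1]
    n = dosage.shape[0]
    g = np.zeros((n, n))
    denom = 2 * sum(p[j] * (1 - p[j]) for j in keep)
    for i in range(n):
        for k in range(n):
            acc = 0.0
            for j in keep:
                xi = dosage[i, j] if dosage[i, j] != MISSING else 2 * p[j]
                xk = dosage[k, j] if dosage[k, j] != MISSING else 2 * p[j]
                zi, zk = xi - 2 * p[j], xk - 2 * p[j]
                if method == "vanraden":
                    acc += zi * zk
                else:
                    acc += zi * zk / (2 * p[j] * (1 - p[j]))
            g[i, k] = acc / denom if method == "vanraden" else acc / len(keep)
    return g


def ibs_loop(dosage: np.ndarray) -> np.ndarray:
    n, m = dosage.shape
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            num = cnt = 0
            for j in range(m):
                if dosage[i, j] != MISSING and dosage[k, j] != MISSING:
                    num += 2 - abs(int(dosage[i, j]) - int(dosage[k, j]))
                    cnt += 2
            d[i, k] = 1 - num / cnt
    return d


# ---------------------------------------------------------------------------
# ROH brute-force scanner
# ---------------------------------------------------------------------------

def roh_scan_loop(dos, pos, params) -> list[tuple[int, int]]:
    """Literal loop implementation of the window-based ROH criteria.

    Returns (start_bp, end_bp) tuples.
    """
    m = len(dos)
    w = min(params.window_snps, m)
    win_ok = []
    for s in range(m - w + 1):
        window = dos[s : s + w]
        het = sum(1 for x in window if x == 1)
        mis = sum(1 for x in window if x == MISSING)
        win_ok.append(het <= params.window_max_het and mis <= params.window_max_missing)

    in_run = []
    for j in range(m):
        hits = tot = 0
        for s in range(max(0, j - w + 1), min(j, m - w) + 1):
            tot += 1
            hits += win_ok[s]
        in_run.append(tot > 0 and hits / tot >= params.window_hit_threshold)

    # consecutive stretches split at big gaps
    stretches = []
    start = None
    for j in range(m + 1):
        gap_break = (
            start is not None
            and j < m
            and j > 0
            and (pos[j] - pos[j - 1]) > params.max_gap_kb * 1000
        )
        if start is not None and (j == m or not in_run[j] or gap_break):
            stretches.append((start, j - 1))
            start = None
        if j < m and in_run[j] and start is None:
            start = j

    out = []
    for a, b in stretches:
        while a <= b and not (dos[a] in (0, 2)):
            a += 1
        while b >= a and not (dos[b] in (0, 2)):
            b -= 1
        if a > b:
            continue
        n_snps = b - a + 1
        length = pos[b] - pos[a] + 1
        if n_snps < params.min_snps:
            continue
        if length < params.min_length_kb * 1000:
            continue
        if length / n_snps > params.max_kb_per_snp * 1000:
            continue
        out.append((int(pos[a]), int(pos[b])))
    return out


# ---------------------------------------------------------------------------
# Two-locus haplotype-frequency MLE by 1-D grid search
# ---------------------------------------------------------------------------

def ml_r2_grid(counts9: np.ndarray) -> float:
    """Brute-force ML r^2 from a 9-cell two-locus genotype count table.

    The haplotype-frequency MLE keeps the marginals at the observed allele
    frequencies, so the likelihood is maximized over the single free
    parameter p11 on its feasible interval (dense grid plus local refine).
    """
    g = np.asarray(counts9, dtype=float).reshape(3, 3)
    n = g.sum()
    tot = 2 * n
    pa = (2 * g[2].sum() + g[1].sum()) / tot
    pb = (2 * g[:, 2].sum() + g[:, 1].sum()) / tot
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)

    def loglik(p11):
        p10 = pa - p11
        p01 = pb - p11
        p00 = 1 - pa - pb + p11
        h = np.array([p00, p01, p10, p11])
        if (h < 0).any():
            return -np.inf
        # genotype cell probs from random union of gametes
        probs = np.zeros((3, 3))
        for i1 in range(4):
            for i2 in range(4):
                a = (i1 >> 1) + (i2 >> 1)
                b = (i1 & 1) + (i2 & 1)
                probs[a, b] += h[i1] * h[i2]
        with np.errstate(divide="ignore"):
            lp = np.where(g > 0, g * np.log(np.maximum(probs, 1e-300)), 0.0)
        return lp.sum()

    grid = np.linspace(lo, hi, 4001)
    best = grid[np.argmax([loglik(x) for x in grid])]
    span = (hi - lo) / 4000
    fine = np.linspace(max(lo, best - span), min(hi, best + span), 2001)
    p11 = fine[np.argmax([loglik(x) for x in fine])]
    return (p11 - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))


# ---------------------------------------------------------------------------
# Weir & Cockerham 1984, two populations, from genotype counts
# ---------------------------------------------------------------------------

def wc_theta_counts(counts1, counts2):
    """theta from (n_AA, n_Aa, n_aa) genotype counts of two populations."""
    def stats(c):
        n_aa, n_ab, n_bb = c
        n = n_aa + n_ab + n_bb
        p = (2 * n_aa + n_ab) / (2 * n)
        h = n_ab / n
        return n, p, h

    n1, p1, h1 = stats(counts1)
    n2, p2, h2 = stats(counts2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# Interval helpers
# ---------------------------------------------------------------------------

def grid_intersection(island_sets, positions):
    """Per-SNP-grid intersection oracle: SNP positions covered by at least
    one island in every set."""
    covered = np.ones(len(positions), dtype=bool)
    for islands in island_sets:
        hit = np.zeros(len(positions), dtype=bool)
        for a, b in islands:
            hit |= (positions >= a) & (positions <= b)
        covered &= hit
    return covered
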