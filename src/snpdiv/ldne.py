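"""Linkage disequilibrium (r^2), distance-binned LD decay, and LD-based Ne.

r^2 between two loci is the squared allele-frequency correlation
D^2 / (p_a (1-p_a) p_b (1-p_b)).  From unphased genotypes the haplotype
frequencies are estimated by expectation-maximization over the two-locus
genotype table (only the double-heterozygote cell is phase-ambiguous); a
``genotype_corr`` method (squared Pearson correlation of dosages) is
available for speed.

Effective population size t generations ago follows the Sved-type
relationship Ne(t) = (1 / (4 c_t)) (1 / E[r^2_adj | c_t] - alpha) with
c_t = 1/(2t) Morgans, evaluated from SNP pairs whose genetic map distance
(linear cM/Mb map) falls in [1/(2(t+0.5)), 1/(2(t-0.5))].  The default
adjustment subtracts the 1/n sampling term from r^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

_EM_TOL = 1e-10
_EM_MAX_ITER = 200


@dataclass
class LDDecayBin:
    distance_lo_kb: float
    distance_hi_kb: float
    mean_r2: float
    n_pairs: int


# ---------------------------------------------------------------------------
# Pairwise r^2
# ---------------------------------------------------------------------------

def r2_from_haplotype_freqs(p_a: float, p_b: float, p_ab: float) -> float:
    """r^2 from (phased) allele and haplotype frequencies."""
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise ValueError("monomorphic locus: r^2 undefined")
    return (p_ab - p_a * p_b) ** 2 / denom

def r2_pair(g1: np.ndarray, g2: np.ndarray, method: str = "em") -> float:
    """r^2 between two dosage vectors over jointly non-missing samples."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must cover the same samples")
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than two jointly non-missing samples")
    a, b = g1[ok].astype(float), g2[ok].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic locus in the joint sample: r^2 undefined")
    if method == "genotype_corr":
        return float(np.corrcoef(a, b)[0, 1] ** 2)
    if method != "em":
        raise ValueError(f"unknown r^2 method {method!r}")
    counts = np.zeros(9)
    np.add.at(counts, (a * 3 + b).astype(int), 1.0)
    r2 = _em_r2(counts[None, :])[0]
    if np.isnan(r2):  # EM failed to converge; fall back to genotype correlation
        warnings.warn("EM did not converge; falling back to genotype_corr")
        return float(np.corrcoef(a, b)[0, 1] ** 2)
    return float(r2)


def _em_r2(counts: np.ndarray) -> np.ndarray:
    """Vectorized EM r^2 for a (P, 9) array of two-locus genotype counts.

    Cell order is 3*gA + gB.  Returns NaN for monomorphic or non-converged
    pairs.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    # known haplotype contributions from the eight unambiguous cells
    g = counts.reshape(-1, 3, 3)
    k11 = np.zeros(len(g))
    k10 = np.zeros(len(g))
    k01 = np.zeros(len(g))
    k00 = np.zeros(len(g))
    for a in range(3):
        for b in range(3):
            c = g[:, a, b]
            if a == 1 and b == 1:
                continue  # ambiguous double het handled by EM
            # diplotype: alleles at A: a copies of '1'; at B: b copies
            h1a, h2a = (1, 1) if a == 2 else (1, 0) if a == 1 else (0, 0)
            h1b, h2b = (1, 1) if b == 2 else (1, 0) if b == 1 else (0, 0)
            # single-het cells: the het allele pairs with both homozygote
            # alleles; assign haplotypes (h1a,h1b) and (h2a,h2b) -- for
            # a==1 xor b==1 the pairing is phase-unambiguous
            for ha, hb in ((h1a, h1b), (h2a, h2b)):
                if ha and hb:
                    k11 += c
                elif ha:
                    k10 += c
                elif hb:
                    k01 += c
                else:
                    k00 += c
    dh = g[:, 1, 1]  # double hets contribute one coupling or one repulsion pair
    tot = 2.0 * n
    pa = (2 * g[:, 2, :].sum(axis=1) + g[:, 1, :].sum(axis=1)) / tot
    pb = (2 * g[:, :, 2].sum(axis=1) + g[:, :, 1].sum(axis=1)) / tot
    poly = (pa > 0) & (pa < 1) & (pb > 0) & (pb < 1)

    # EM on the coupling fraction of double hets
    p11 = np.where(poly, pa * pb, np.nan)
    p10 = np.where(poly, pa * (1 - pb), np.nan)
    p01 = np.where(poly, (1 - pa) * pb, np.nan)
    p00 = np.where(poly, (1 - pa) * (1 - pb), np.nan)
    converged = np.zeros(len(g), dtype=bool)
    for _ in range(_EM_MAX_ITER):
        with np.errstate(invalid="ignore", divide="ignore"):
            coup = p11 * p00
            rep = p10 * p01
            w = np.where(coup + rep > 0, coup / (coup + rep), 0.5)
        n11 = k11 + dh * w
        n00 = k00 + dh * w
        n10 = k10 + dh * (1 - w)
        n01 = k01 + dh * (1 - w)
        new11, new10, new01, new00 = n11 / tot, n10 / tot, n01 / tot, n00 / tot
        delta = np.abs(new11 - p11)
        p11, p10, p01, p00 = new11, new10, new01, new00
        converged |= delta < _EM_TOL
        if converged[poly].all():
            break
    with np.errstate(invalid="ignore", divide="ignore"):
        d = p11 - pa * pb
        r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    r2 = np.where(poly & converged, r2, np.nan)
    return r2


# ---------------------------------------------------------------------------
# Genome-wide pair machinery
# ---------------------------------------------------------------------------

def _intra_chromosome_pairs(gm: GenotypeMatrix, max_dist_bp: float):
    """Indices (i, j, dist_bp) of all intra-chromosome pairs within range."""
    ii, jj = [], []
    chroms = gm.chromosomes
    pos = gm.positions
    for chrom in gm.chromosome_labels():
        vidx = np.flatnonzero(chroms == chrom)
        cpos = pos[vidx]
        hi = np.searchsorted(cpos, cpos + max_dist_bp, side="right")
        for a in range(len(vidx)):
            b = np.arange(a + 1, hi[a])
            ii.append(np.full(b.size, vidx[a]))
            jj.append(vidx[b])
    if not ii:
        return (np.array([], dtype=int),) * 2 + (np.array([]),)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    return i, j, (pos[j] - pos[i]).astype(float)


def _pairwise_r2(gm: GenotypeMatrix, i: np.ndarray, j: np.ndarray, method: str,
                 chunk: int = 200_000) -> np.ndarray:
    """r^2 for many SNP pairs; NaN where undefined."""
    out = np.empty(i.size)
    d = gm.dosage
    for lo in range(0, i.size, chunk):
        sl = slice(lo, lo + chunk)
        g1 = d[:, i[sl]]
        g2 = d[:, j[sl]]
        ok = (g1 != MISSING) & (g2 != MISSING)
        if method == "em":
            code = np.where(ok, g1.astype(np.int64) * 3 + g2, 9)
            counts = np.stack([(code == c).sum(axis=0) for c in range(9)], axis=1)
            out[sl] = _em_r2(counts)
        elif method == "genotype_corr":
            out[sl] = _corr_r2(g1, g2, ok)
        else:
            raise ValueError(f"unknown r^2 method {method!r}")
    return out


def _corr_r2(g1, g2, ok):
    g1 = np.where(ok, g1, 0).astype(float)
    g2 = np.where(ok, g2, 0).astype(float)
    n = ok.sum(axis=0)
    s1, s2 = g1.sum(axis=0), g2.sum(axis=0)
    s11, s22 = (g1 * g1).sum(axis=0), (g2 * g2).sum(axis=0)
    s12 = (g1 * g2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s12 / n - s1 * s2 / n**2
        v1 = s11 / n - (s1 / n) ** 2
        v2 = s22 / n - (s2 / n) ** 2
        r2 = cov * cov / (v1 * v2)
    return np.where((n >= 2) & (v1 > 0) & (v2 > 0), r2, np.nan)


# ---------------------------------------------------------------------------
# LD decay and Ne
# ---------------------------------------------------------------------------

def ld_decay(
    gm: GenotypeMatrix,
    max_dist_kb: float = 2000.0,
    bin_kb: float = 100.0,
    method: str = "em",
) -> pd.DataFrame:
    """Mean r^2 in contiguous physical-distance bins (lower-inclusive)."""
    i, j, dist = _intra_chromosome_pairs(gm, max_dist_kb * 1000.0)
    edges = np.arange(0.0, max_dist_kb + bin_kb, bin_kb) * 1000.0
    if i.size == 0:
        warnings.warn("no SNP pairs within the distance range")
        return pd.DataFrame(
            columns=["distance_lo_kb", "distance_hi_kb", "mean_r2", "n_pairs"]
        )
    r2 = _pairwise_r2(gm, i, j, method)
    keep = np.isfinite(r2)
    which = np.digitize(dist[keep], edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append(
            {
                "distance_lo_kb": edges[b] / 1000.0,
                "distance_hi_kb": edges[b + 1] / 1000.0,
                "mean_r2": float(r2[keep][sel].mean()) if sel.any() else np.nan,
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def estimate_ne(
    gm: GenotypeMatrix,
    t_range=range(25, 101),
    alpha: float = 1.0,
    cm_per_mb: float = 1.0,
    sample_size_correction: str = "one_over_n",
    method: str = "em",
) -> pd.DataFrame:
    """Ne trajectory over past generations from binned LD.

    Each generation t maps to recombination rate c_t = 1/(2t) Morgans;
    pairs whose linear-map distance lies in [1/(2(t+0.5)), 1/(2(t-0.5))]
    contribute to that generation's mean adjusted r^2, and
    Ne(t) = (1/(4 c_t)) (1/mean(r^2_adj) - alpha).  Rows with no pairs or a
    non-positive estimate are flagged invalid rather than fabricated.
    """
    if sample_size_correction not in ("none", "one_over_n"):
        raise ValueError(f"unknown correction {sample_size_correction!r}")
    n = gm.n_samples
    if n < 10:
        warnings.warn(f"only {n} samples: LD-based Ne will be noisy")
    t_values = list(t_range)
    c_hi_max = 1.0 / (2.0 * (min(t_values) - 0.5))
    max_dist_bp = c_hi_max * 100.0 / cm_per_mb * 1e6
    i, j, dist = _intra_chromosome_pairs(gm, max_dist_bp)
    c = dist / 1e6 * cm_per_mb / 100.0  # Morgans under the linear map
    r2 = _pairwise_r2(gm, i, j, method) if i.size else np.array([])
    adj = r2 - (1.0 / n if sample_size_correction == "one_over_n" else 0.0)

    rows = []
    for t in t_values:
        c_t = 1.0 / (2.0 * t)
        lo, hi = 1.0 / (2.0 * (t + 0.5)), 1.0 / (2.0 * (t - 0.5))
        sel = (c >= lo) & (c <= hi) & np.isfinite(r2) if i.size else np.array([], bool)
        n_pairs = int(sel.sum())
        mean_adj = float(adj[sel].mean()) if n_pairs else np.nan
        ne = np.nan
        valid = False
        if n_pairs and mean_adj > 0:
            ne = (1.0 / (4.0 * c_t)) * (1.0 / mean_adj - alpha)
            valid = ne > 0
        rows.append(
            {
                "t": t,
                "c_t": c_t,
                "mean_r2_adj": mean_adj,
                "n_pairs": n_pairs,
                "ne": float(ne) if valid else np.nan,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)
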