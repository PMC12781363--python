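"""Weir-Cockerham F_ST: per-SNP variance components, sliding windows,
top-quantile outliers, and shared outlier regions.

Per SNP the two-population Weir & Cockerham (1984) components are

* ``a`` — among-population variance,
* ``b`` — among-individual-within-population variance,
* ``c`` — within-individual variance,

with theta = a / (a + b + c); negative theta is permitted.  Window values
use the ratio-of-sums ("weighted") form sum(a) / sum(a + b + c) over the
SNPs in each 100-kb window advanced in 10-kb steps, anchored at position 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix


def wc_fst_components(gm1: GenotypeMatrix, gm2: GenotypeMatrix):
    """Per-SNP W&C (a, b, c) arrays for two populations sharing a variant list.

    SNPs monomorphic across both populations (or untyped in either) get
    components (0, 0, 0) and are excluded from any ratio downstream.
    """
    if gm1.n_snps != gm2.n_snps:
        raise ValueError("populations must share the variant list")
    stats = []
    for gm in (gm1, gm2):
        called = gm.dosage != MISSING
        n_i = called.sum(axis=0).astype(float)  # individuals with calls
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(called, gm.dosage, 0).sum(axis=0) / (2.0 * n_i)
            h_i = ((gm.dosage == 1) & called).sum(axis=0) / n_i
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        cc = hbar / 2.0

    usable = (
        (n1 > 0)
        & (n2 > 0)
        & (nbar > 1)
        & np.isfinite(a) & np.isfinite(b) & np.isfinite(cc)
        & (pbar > 0)
        & (pbar < 1)
    )
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    cc = np.where(usable, cc, 0.0)
    return a, b, cc, usable


def wc_fst_snp(gm1: GenotypeMatrix, gm2: GenotypeMatrix) -> np.ndarray:
    """Per-SNP theta = a/(a+b+c); NaN where the locus is unusable."""
    a, b, c, usable = wc_fst_components(gm1, gm2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    return np.where(usable & ((a + b + c) != 0), theta, np.nan)


def windowed_fst(
    gm1: GenotypeMatrix,
    gm2: GenotypeMatrix,
    window_kb: float = 100.0,
    step_kb: float = 10.0,
) -> pd.DataFrame:
    """Sliding-window weighted F_ST; windows with zero usable SNPs omitted.

    Windows are anchored at positions 1, 1+step, ... per chromosome; a SNP
    belongs to every window whose closed interval contains its position.
    """
    a, b, c, usable = wc_fst_components(gm1, gm2)
    denom = a + b + c
    win = int(window_kb * 1000)
    step = int(step_kb * 1000)

    rows = []
    chroms = gm1.chromosomes
    pos = gm1.positions
    for chrom in gm1.chromosome_labels():
        vidx = np.flatnonzero((chroms == chrom) & usable)
        if vidx.size == 0:
            continue
        cpos = pos[vidx]
        ca = np.concatenate(([0.0], np.cumsum(a[vidx])))
        cd = np.concatenate(([0.0], np.cumsum(denom[vidx])))
        last_start = int(cpos.max())
        for start in range(1, last_start + 1, step):
            end = start + win - 1
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="right")
            if hi <= lo:
                continue
            den = cd[hi] - cd[lo]
            rows.append(
                {
                    "chromosome": chrom,
                    "start_bp": start,
                    "end_bp": end,
                    "n_snps": int(hi - lo),
                    "fst_weighted": (ca[hi] - ca[lo]) / den if den != 0 else np.nan,
                }
            )
    out = pd.DataFrame(
        rows, columns=["chromosome", "start_bp", "end_bp", "n_snps", "fst_weighted"]
    )
    out["is_outlier"] = False
    return out


def outlier_windows(windows: pd.DataFrame, top_fraction: float = 0.01) -> pd.DataFrame:
    """Flag the top ``top_fraction`` of windows genome-wide by weighted F_ST.

    The cutoff is the k-th largest value with k = ceil(top_fraction * N);
    ties at the cutoff are kept.
    """
    if len(windows) == 0:
        raise ValueError("no windows to rank")
    vals = windows["fst_weighted"].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    k = max(1, int(np.ceil(top_fraction * finite.sum())))
    cutoff = np.sort(vals[finite])[::-1][k - 1]
    out = windows.copy()
    out["is_outlier"] = finite & (vals >= cutoff)
    return out


def shared_outliers(scan1: pd.DataFrame, scan2: pd.DataFrame) -> pd.DataFrame:
    """Genomic intersection of the two scans' outlier windows, merged."""
    from .roh import _intersect, _merge

    def outlier_intervals(scan):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for _, row in scan[scan["is_outlier"]].iterrows():
            per_chrom.setdefault(str(row["chromosome"]), []).append(
                (int(row["start_bp"]), int(row["end_bp"]))
            )
        return {c: _merge(v) for c, v in per_chrom.items()}

    s1, s2 = outlier_intervals(scan1), outlier_intervals(scan2)
    rows = [
        {"chromosome": c, "start_bp": a, "end_bp": b}
        for c in sorted(set(s1) & set(s2))
        for a, b in _intersect(s1[c], s2[c])
    ]
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"])
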