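"""Diversity summaries, genomic relationship matrices, PCA, IBS distances.

Per-SNP quantities are computed over non-missing calls only; population
means are unweighted means over SNPs.  The genomic relationship matrix
(GRM) comes in two flavours:

* ``vanraden`` — G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z = dosage - 2p
  (its diagonal minus one is the F_GRM inbreeding estimator);
* ``variance_standardized`` — G = W W' / m with
  W_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)), the matrix used for PCA.

Missing dosages are mean-imputed to 2p before forming either matrix;
monomorphic SNPs are excluded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix


@dataclass
class RelationshipMatrix:
    sample_ids: np.ndarray
    values: np.ndarray
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")
        self.values = v


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per SNP; NaN where no non-missing calls."""
    called = gm.dosage != MISSING
    num = np.where(called, gm.dosage, 0).sum(axis=0, dtype=float)
    den = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return freq


def diversity_summary(gm: GenotypeMatrix, mode: str = "heterozygosity") -> dict:
    """Population diversity summary (mean MAF, Ho, He over SNPs).

    ``mode='homozygosity'`` reports the complements 1-Ho and 1-He instead,
    matching the alternative convention some summary tables use.
    """
    if mode not in ("heterozygosity", "homozygosity"):
        raise ValueError(f"unknown mode {mode!r}")
    if gm.n_snps == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    p = allele_frequencies(gm)
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, (gm.dosage == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    he = 2.0 * p * (1.0 - p)
    maf = np.minimum(p, 1.0 - p)
    if mode == "homozygosity":
        ho, he = 1.0 - ho, 1.0 - he
    pops = gm.samples["population"].unique()
    return {
        "population": pops[0] if len(pops) == 1 else "+".join(map(str, pops)),
        "n_samples": gm.n_samples,
        "n_snps": gm.n_snps,
        "mean_maf": float(np.nanmean(maf)),
        "mean_ho": float(np.nanmean(ho)),
        "mean_he": float(np.nanmean(he)),
        "mode": mode,
    }


def _standardized_dosage(gm: GenotypeMatrix):
    p = allele_frequencies(gm)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic/undefined SNPs from GRM"
        )
    if not poly.any():
        raise ValueError("no polymorphic SNPs usable for GRM")
    d = gm.dosage[:, poly].astype(float)
    p = p[poly]
    d[d == MISSING] = np.take(2 * p, np.nonzero(d == MISSING)[1])  # mean imputation
    z = d - 2 * p
    return z, p


def compute_grm(gm: GenotypeMatrix, method: str = "vanraden") -> RelationshipMatrix:
    z, p = _standardized_dosage(gm)
    if method == "vanraden":
        g = z @ z.T / (2.0 * np.sum(p * (1 - p)))
    elif method == "variance_standardized":
        w = z / np.sqrt(2 * p * (1 - p))
        g = w @ w.T / z.shape[1]
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    g = (g + g.T) / 2.0  # enforce exact symmetry against rounding
    return RelationshipMatrix(gm.sample_ids, g, method)


def pca(grm: RelationshipMatrix, k: int):
    """PCA of a (variance-standardized) GRM.

    Returns ``(coords, var_explained)``: an (n, k) coordinate array with
    components ordered by descending eigenvalue and the per-component
    fraction of the total positive-eigenvalue variance.  Sign convention:
    the largest-magnitude loading of each component is positive.
    """
    n = grm.values.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    eigval, eigvec = np.linalg.eigh(grm.values)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos_total = eigval[eigval > 0].sum()
    var_explained = np.maximum(eigval[:k], 0.0) / pos_total
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    for c in range(k):
        j = np.argmax(np.abs(coords[:, c]))
        if coords[j, c] < 0:
            coords[:, c] = -coords[:, c]
    return coords, var_explained


def ibs_distance(gm: GenotypeMatrix) -> np.ndarray:
    """1 - IBS genetic distance matrix over jointly non-missing SNPs."""
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    d = gm.dosage.astype(np.int16)
    called = gm.dosage != MISSING
    dist = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        m_pair = both.sum(axis=1)
        if (m_pair == 0).any():
            bad = np.nonzero(m_pair == 0)[0] + i + 1
            raise ValueError(
                f"sample pairs with zero jointly typed SNPs: {i} vs {bad.tolist()}"
            )
        diff = np.abs(d[i] - d[i + 1 :]) * both
        ibs = (2 * m_pair - diff.sum(axis=1)) / (2.0 * m_pair)
        dist[i, i + 1 :] = dist[i + 1 :, i] = 1.0 - ibs
    return dist


def diversity_table(gm: GenotypeMatrix, mode: str = "heterozygosity") -> pd.DataFrame:
    """Per-population diversity summary table (one row per population)."""
    rows = [
        diversity_summary(gm.subset_population(pop), mode)
        for pop in dict.fromkeys(gm.samples["population"])
    ]
    return pd.DataFrame(rows)
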