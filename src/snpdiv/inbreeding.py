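"""The ten genomic inbreeding coefficients and their correlations.

Per individual i with dosage x (copies of the counted allele) and
within-population counted-allele frequency p at each SNP:

* ``F_GRM``   = G_ii - 1 from the VanRaden genomic relationship matrix;
* ``F_HOM1``  = (E_het - O_het) / E_het, the heterozygosity-deficit form of
  the observed-vs-expected homozygosity estimator (ratio of sums, positive
  for inbred individuals, identical to PLINK --het's F);
* ``F_HOM2``  = mean over SNPs of 1 - x(2-x) / (2 p (1-p)) (mean of ratios);
* ``F_UNI``   = sum_j [x_j^2 - (1+2p_j) x_j + 2 p_j^2] / sum_j 2 p_j (1-p_j),
  the correlation-between-uniting-gametes estimator (ratio of sums);
* ``F_ROH``   = total ROH length / L_auto, where L_auto is the autosomal
  genome length spanned by the post-QC SNPs, plus the five length-class
  stratified variants (lt2, 2to4, 4to8, 8to16, gt16) which sum to F_ROH.

Sums run over each individual's non-missing SNPs; F_HOM2/F_UNI also exclude
SNPs monomorphic in the population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix
from .popgen import RelationshipMatrix, allele_frequencies, compute_grm
from .roh import LENGTH_CLASSES

METRICS = [
    "f_grm", "f_hom1", "f_hom2", "f_uni",
    "f_roh", "f_roh_lt2", "f_roh_2_4", "f_roh_4_8", "f_roh_8_16", "f_roh_gt16",
]
_CLASS_TO_COLUMN = {
    "lt2": "f_roh_lt2", "2to4": "f_roh_2_4", "4to8": "f_roh_4_8",
    "8to16": "f_roh_8_16", "gt16": "f_roh_gt16",
}


def f_grm(grm: RelationshipMatrix) -> np.ndarray:
    if grm.method != "vanraden":
        raise ValueError("F_GRM requires the vanraden relationship matrix")
    return np.diag(grm.values) - 1.0


def f_hom1(gm: GenotypeMatrix) -> np.ndarray:
    p = allele_frequencies(gm)
    called = gm.dosage != MISSING
    e_het_snp = 2.0 * p * (1.0 - p)
    e_het = np.where(called, e_het_snp, 0.0).sum(axis=1)
    o_het = ((gm.dosage == 1) & called).sum(axis=1)
    if np.any(e_het == 0):
        raise ValueError("individual with zero expected heterozygosity")
    return (e_het - o_het) / e_het


def _usable(gm: GenotypeMatrix):
    p = allele_frequencies(gm)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    called = (gm.dosage != MISSING) & poly
    if not called.any(axis=1).all():
        raise ValueError("individual with zero usable (polymorphic, called) SNPs")
    return p, called


def f_hom2(gm: GenotypeMatrix) -> np.ndarray:
    p, called = _usable(gm)
    x = gm.dosage.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = 1.0 - x * (2.0 - x) / (2.0 * p * (1.0 - p))
    per_snp = np.where(called, per_snp, 0.0)
    return per_snp.sum(axis=1) / called.sum(axis=1)


def f_uni(gm: GenotypeMatrix) -> np.ndarray:
    p, called = _usable(gm)
    x = gm.dosage.astype(float)
    num = np.where(called, x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p, 0.0).sum(axis=1)
    den = np.where(called, 2.0 * p * (1.0 - p), 0.0).sum(axis=1)
    return num / den


def f_roh(segments: pd.DataFrame, gm: GenotypeMatrix) -> pd.DataFrame:
    """Total and length-class-stratified F_ROH per sample.

    L_auto is the sum over chromosomes of (max SNP position - min SNP
    position + 1) on the post-QC map of ``gm``.
    """
    l_auto = 0
    for chrom in gm.chromosome_labels():
        cpos = gm.positions[gm.chromosomes == chrom]
        l_auto += int(cpos.max() - cpos.min() + 1)
    if l_auto == 0:
        raise ValueError("L_auto is zero")

    out = pd.DataFrame(
        0.0,
        index=gm.sample_ids,
        columns=["f_roh"] + [_CLASS_TO_COLUMN[c] for c in LENGTH_CLASSES],
    )
    if len(segments):
        for (sid, cls), lengths in segments.groupby(["sample_id", "length_class"])[
            "length_bp"
        ]:
            if sid in out.index:
                out.loc[sid, _CLASS_TO_COLUMN[cls]] = lengths.sum() / l_auto
        out["f_roh"] = out[[_CLASS_TO_COLUMN[c] for c in LENGTH_CLASSES]].sum(axis=1)
    out.index.name = "sample_id"
    return out.reset_index()


def inbreeding_records(gm: GenotypeMatrix, segments: pd.DataFrame) -> pd.DataFrame:
    """All ten coefficients per individual (tabular surface of the toolkit)."""
    grm = compute_grm(gm, method="vanraden")
    rec = f_roh(segments, gm)
    rec.insert(1, "f_grm", f_grm(grm))
    rec.insert(2, "f_hom1", f_hom1(gm))
    rec.insert(3, "f_hom2", f_hom2(gm))
    rec.insert(4, "f_uni", f_uni(gm))
    return rec[["sample_id"] + METRICS]


def correlation_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between all metric pairs.

    Zero-variance metrics yield NaN entries (flagged, not silently zero).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 samples for correlations")
    data = records[METRICS].astype(float)
    corr = data.corr(method="pearson")  # pandas leaves NaN for zero variance
    np.fill_diagonal(corr.values, 1.0)
    return corr
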