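"""Shared data model: the genotype matrix and its metadata tables.

A :class:`GenotypeMatrix` is the universal currency of the toolkit: a
``samples x snps`` dosage matrix counting copies of the *counted allele*
(``allele_a``) at each biallelic SNP, together with two metadata tables.

Conventions
-----------
* Dosage entries are ``{0, 1, 2}`` or :data:`MISSING` (``-1``).
* Physical coordinates are 1-based and intervals are closed; conversion to
  BED's 0-based half-open convention happens only at the I/O boundary.
* Chromosome labels are opaque strings.  What counts as an autosome is a
  configurable list (pig has 18 autosomes, the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

#: Default autosome labels (Sscrofa genome build: 18 autosomes).
PIG_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 19))

VARIANT_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "population", "group"]


class ValidationError(ValueError):
    """Raised when a genotype dataset violates a structural invariant."""


class EmptySelectionError(ValueError):
    """Raised when a subset operation selects zero samples or variants."""


def _as_variant_frame(variants: pd.DataFrame) -> pd.DataFrame:
    out = variants.copy().reset_index(drop=True)
    for col in VARIANT_COLUMNS:
        if col not in out.columns:
            raise ValidationError(f"variant table missing column {col!r}")
    out["chromosome"] = out["chromosome"].astype(str)
    out["position_bp"] = out["position_bp"].astype(np.int64)
    return out[VARIANT_COLUMNS]


def _as_sample_frame(samples: pd.DataFrame) -> pd.DataFrame:
    out = samples.copy().reset_index(drop=True)
    if "sample_id" not in out.columns:
        raise ValidationError("sample table missing column 'sample_id'")
    if "population" not in out.columns:
        out["population"] = "pop0"
    if "group" not in out.columns:
        out["group"] = None
    return out[SAMPLE_COLUMNS]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP genotypes for a cohort.

    Parameters
    ----------
    samples : pandas.DataFrame
        One row per individual; columns ``sample_id`` (unique),
        ``population``, ``group``.
    variants : pandas.DataFrame
        One row per SNP; columns ``snp_id``, ``chromosome``,
        ``position_bp`` (1-based), ``allele_a`` (counted), ``allele_b``.
        Within each chromosome rows must be sorted by strictly increasing
        position.
    dosage : numpy.ndarray
        ``(n_samples, n_snps)`` int8 array with entries in
        ``{0, 1, 2, MISSING}`` counting copies of ``allele_a``.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = _as_sample_frame(self.samples)
        self.variants = _as_variant_frame(self.variants)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValidationError(
                f"dosage has {n} rows but sample table has {len(self.samples)}"
            )
        if m != len(self.variants):
            raise ValidationError(
                f"dosage has {m} columns but variant table has {len(self.variants)}"
            )
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample IDs: {sorted(set(dups))}")
        legal = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not legal.all():
            bad = np.unique(self.dosage[~legal])
            raise ValidationError(f"illegal dosage values {bad.tolist()}")
        if (self.variants["position_bp"] < 0).any():
            raise ValidationError("position_bp must be >= 0 (0 marks unknown)")
        for chrom, sub in self.variants.groupby("chromosome", sort=False):
            # position 0 means "unknown" pre-QC and is exempt from ordering;
            # duplicates are tolerated pre-QC (rule 5 removes them), so the
            # requirement here is non-decreasing; strict uniqueness holds
            # after QC.
            pos = sub.loc[sub["position_bp"] >= 1, "position_bp"].to_numpy()
            if not (np.diff(pos) >= 0).all():
                raise ValidationError(
                    f"positions on chromosome {chrom} not sorted ascending"
                )

    # -- convenience accessors ---------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.variants["position_bp"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.variants["chromosome"].to_numpy()

    def chromosome_labels(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.variants["chromosome"]))

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    # -- subsetting ---------------------------------------------------------

    def subset(self, sample_filter=None, variant_filter=None) -> "GenotypeMatrix":
        """Return a consistent sub-matrix; order preserved, original untouched.

        ``sample_filter`` / ``variant_filter`` are predicates applied to each
        metadata row (a pandas Series), or ``None`` for identity.  Boolean /
        integer index arrays are also accepted.
        """
        sm = _resolve_index(self.samples, sample_filter)
        vm = _resolve_index(self.variants, variant_filter)
        if len(sm) == 0:
            raise EmptySelectionError("sample selection is empty")
        if len(vm) == 0:
            raise EmptySelectionError("variant selection is empty")
        return GenotypeMatrix(
            samples=self.samples.iloc[sm],
            variants=self.variants.iloc[vm],
            dosage=self.dosage[np.ix_(sm, vm)].copy(),
        )

    def subset_population(self, population: str) -> "GenotypeMatrix":
        return self.subset(sample_filter=lambda s: s["population"] == population)


def _resolve_index(table: pd.DataFrame, selector) -> np.ndarray:
    if selector is None:
        return np.arange(len(table))
    if callable(selector):
        keep = np.fromiter(
            (bool(selector(row)) for _, row in table.iterrows()),
            dtype=bool,
            count=len(table),
        )
        return np.flatnonzero(keep)
    arr = np.asarray(selector)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return arr.astype(np.intp)
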