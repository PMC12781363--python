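"""Six-rule SNP-array quality control and the exact Hardy-Weinberg test.

The removal rules, applied in order with call rates and allele frequencies
recomputed after each rule:

1. SNPs with call rate below ``snp_call_rate_min`` (default 0.95);
2. SNPs with MAF below ``maf_min`` (default 0.05; can be disabled — the ROH
   profile runs without a MAF filter);
3. SNPs, then individuals, with call rate below ``joint_call_rate_min``
   (default 0.90);
4. SNPs departing from Hardy-Weinberg equilibrium at ``p < hwe_p_min``
   (default 1e-6), by the plain (non-mid-p) exact test;
5. SNPs with unknown (position < 1) or duplicated positions — the first
   occurrence of a duplicated (chromosome, position) is kept;
6. SNPs on non-autosomal chromosomes.

Note rule 3's SNP pass is vacuous whenever ``joint_call_rate_min`` is below
``snp_call_rate_min`` (any SNP failing the looser threshold already failed
rule 1); it is kept for profiles that relax rule 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .datamodel import MISSING, PIG_AUTOSOMES, GenotypeMatrix


class DegenerateOutputError(ValueError):
    """All SNPs or all samples would be removed."""


@dataclass(frozen=True)
class QCProfile:
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.05
    joint_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    drop_unknown_or_duplicate_pos: bool = True
    autosomes_only: bool = True
    apply_maf_filter: bool = True
    autosomes: tuple[str, ...] = PIG_AUTOSOMES

    def __post_init__(self):
        for name in ("snp_call_rate_min", "maf_min", "joint_call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


#: Profile used for ROH analyses: identical but with no MAF filter.
def roh_profile(**kwargs) -> QCProfile:
    return replace(QCProfile(), apply_maf_filter=False, **kwargs)


@dataclass
class QCReport:
    input_snps: int = 0
    input_samples: int = 0
    output_snps: int = 0
    output_samples: int = 0
    snp_removals: dict = field(default_factory=dict)
    sample_removals: dict = field(default_factory=dict)
    rule_log: list = field(default_factory=list)

    def record(self, rule: str, n_snps: int = 0, n_samples: int = 0) -> None:
        self.snp_removals[rule] = self.snp_removals.get(rule, 0) + n_snps
        self.sample_removals[rule] = self.sample_removals.get(rule, 0) + n_samples
        self.rule_log.append((rule, n_snps, n_samples))

    def check_conservation(self) -> bool:
        snp_ok = self.input_snps - sum(self.snp_removals.values()) == self.output_snps
        smp_ok = (
            self.input_samples - sum(self.sample_removals.values())
            == self.output_samples
        )
        return snp_ok and smp_ok

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(r, s, i) for r, s, i in self.rule_log],
            columns=["rule", "snps_removed", "samples_removed"],
        )


# ---------------------------------------------------------------------------
# Exact HWE test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Sums, under the exact conditional distribution of the heterozygote count
    given the allele counts, the probabilities of all configurations no more
    probable than the observed one (same parity, same allele counts).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts zero")
    na = 2 * n_aa + n_ab  # copies of allele a
    nb = 2 * n - na
    rare = min(na, nb)
    if rare == 0:
        return 1.0  # monomorphic: single possible configuration

    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((na - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((nb - hets) / 2 + 1)
        - (gammaln(2 * n + 1) - gammaln(na + 1) - gammaln(nb + 1))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.nonzero(hets == n_ab)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------------

def _snp_call_rate(dosage: np.ndarray) -> np.ndarray:
    return (dosage != MISSING).mean(axis=0)


def _sample_call_rate(dosage: np.ndarray) -> np.ndarray:
    return (dosage != MISSING).mean(axis=1)


def _maf(dosage: np.ndarray) -> np.ndarray:
    called = dosage != MISSING
    counts = np.where(called, dosage, 0).sum(axis=0)
    denom = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
    return np.minimum(p, 1 - p)


def apply_qc(gm: GenotypeMatrix, profile: QCProfile | None = None):
    """Apply the six QC rules in order; returns (filtered matrix, report)."""
    profile = profile or QCProfile()
    report = QCReport(
        input_snps=gm.n_snps,
        input_samples=gm.n_samples,
    )

    keep_snps = np.arange(gm.n_snps)
    keep_samples = np.arange(gm.n_samples)

    def current():
        return gm.dosage[np.ix_(keep_samples, keep_snps)]

    def drop_snps(bad_local: np.ndarray, rule: str):
        nonlocal keep_snps
        n_bad = int(bad_local.sum())
        keep_snps = keep_snps[~bad_local]
        report.record(rule, n_snps=n_bad)
        if keep_snps.size == 0:
            raise DegenerateOutputError(f"rule {rule!r} removed every SNP")

    # rule 1: SNP call rate
    drop_snps(_snp_call_rate(current()) < profile.snp_call_rate_min, "snp_call_rate")

    # rule 2: MAF
    if profile.apply_maf_filter:
        drop_snps(_maf(current()) < profile.maf_min, "maf")
    else:
        report.record("maf", 0)

    # rule 3: joint call rate, SNPs first then individuals
    drop_snps(
        _snp_call_rate(current()) < profile.joint_call_rate_min, "joint_call_rate"
    )
    bad_samples = _sample_call_rate(current()) < profile.joint_call_rate_min
    n_bad = int(bad_samples.sum())
    keep_samples = keep_samples[~bad_samples]
    report.record("joint_call_rate", n_samples=n_bad)
    if keep_samples.size == 0:
        raise DegenerateOutputError("joint call-rate rule removed every sample")

    # rule 4: HWE exact test
    d = current()
    pvals = np.ones(d.shape[1])
    for j in range(d.shape[1]):
        col = d[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        pvals[j] = hwe_exact_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    drop_snps(pvals < profile.hwe_p_min, "hwe")

    # rule 5: unknown or duplicated positions (keep first occurrence)
    if profile.drop_unknown_or_duplicate_pos:
        vsub = gm.variants.iloc[keep_snps]
        unknown = (vsub["position_bp"] < 1).to_numpy()
        dup = vsub.duplicated(subset=["chromosome", "position_bp"]).to_numpy()
        drop_snps(unknown | dup, "position")
    else:
        report.record("position", 0)

    # rule 6: non-autosomal chromosomes
    if profile.autosomes_only:
        vsub = gm.variants.iloc[keep_snps]
        drop_snps(~vsub["chromosome"].isin(profile.autosomes).to_numpy(), "autosome")
    else:
        report.record("autosome", 0)

    out = gm.subset(sample_filter=keep_samples, variant_filter=keep_snps)
    report.output_snps = out.n_snps
    report.output_samples = out.n_samples
    assert report.check_conservation()
    return out, report
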