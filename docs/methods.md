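# Methods

This note documents the models, conventions and numerical choices behind
`snpdiv`, in the order data flows through the pipeline.

## Data model and coordinates

Genotypes are stored as a samples × SNPs dosage matrix counting copies of
the *counted allele* per SNP (`-1` = missing). All internal coordinates
are 1-based closed intervals; only the BED exporter converts to 0-based
half-open. Pre-QC data may contain position 0 ("unknown") and duplicated
positions — the QC position rule removes them, and strict per-chromosome
ordering and uniqueness hold afterwards. Chromosome labels are opaque
strings; autosome status comes from a configurable list (default "1".."18",
the pig autosomes), so other species remain usable.

The counted allele is ALT for VCF input and the minor-by-frequency allele
(lexicographic tie-break) for PED/MAP input. Every statistic in the
package is invariant to this choice except the sign of dosage itself,
which the round-trip tests harmonize explicitly. Monomorphic PED SNPs get
an unobserved placeholder counted allele (dosage 0, MAF 0), mirroring how
array tooling encodes a missing minor allele.

## Quality control

Six removal rules run in a fixed order, with call rates and allele
frequencies recomputed on the surviving data after each rule: (1) SNP call
rate < 0.95; (2) MAF < 0.05 (disabled in the `roh` profile, since ROH
analyses must keep low-MAF and monomorphic SNPs); (3) call rate < 0.90 for
SNPs, then individuals; (4) exact Hardy–Weinberg p < 1e-6; (5) unknown or
duplicated positions (first occurrence kept); (6) non-autosomal SNPs.
Rule 3's SNP pass is vacuous at the default thresholds (anything below
0.90 already failed rule 1); it is retained for profiles that relax
rule 1. MAF and HWE are computed within whatever dataset is passed in —
per population when the pipeline runs populations separately.

The HWE test is the plain (non-mid-p) two-sided exact conditional test:
given the allele counts, the probabilities of all heterozygote counts of
the correct parity are computed in log space (gammaln), and those no more
probable than the observed configuration are summed. A tolerance factor of
1+1e-12 guards the equality comparison against floating-point noise. The
test suite checks it against a full-enumeration oracle for all tables it
draws (totals up to ~200).

## Diversity, GRM, PCA, distances

Per-SNP Ho is the heterozygote fraction among non-missing calls, He is
2p(1−p), MAF is min(p, 1−p); population values are unweighted means over
SNPs. Because summary tables in the field are printed under both the
heterozygosity and the homozygosity convention, a `mode` switch reports
either Ho/He or their complements; the default is heterozygosity (the
He = 2pq convention).

Two GRMs are available: VanRaden (Z Z' / 2Σp_jq_j, used for F_GRM) and
variance-standardized (W W'/m with W = Z/sqrt(2pq), used for PCA). Missing
dosages are mean-imputed to 2p; monomorphic SNPs are excluded with a
warning. PCA is a symmetric eigendecomposition; components are ordered by
descending eigenvalue, variance fractions are eigenvalue shares of the
positive-eigenvalue total, and the sign convention makes each component's
largest-magnitude loading positive. The IBS distance between two samples
is 1 − (shared-allele score)/(2 × jointly typed SNPs) with per-SNP score
2 − |x_k − x_l|.

## Runs of homozygosity

Detection follows the PLINK sliding-window procedure with its published
defaults (window 50 SNPs, ≤1 het, ≤5 missing per window, per-SNP hit
threshold 0.05, min 15 SNPs, min 500 kb, max gap 500 kb, max 75 kb/SNP).
The hit threshold is PLINK 1.9's default since the source workflow never
states it. Consequences worth knowing:

* the hit-fraction rule leaves the outermost SNP of a clean run out (an
  edge SNP is covered by only ~2 qualifying windows, 0.04 < 0.05), so
  detected boundaries sit one SNP inside the true homozygous stretch;
* a run can only be detected where the map supports it: at least
  window-length SNPs and one SNP per 75 kb. On a 30k-SNP pig-scale map
  (~60 kb spacing) the shortest detectable tract is ≈3 Mb, far above the
  500-kb length floor;
* stretches are trimmed so both endpoints are homozygous non-missing
  SNPs, then filtered by SNP count, length and density; chromosomes
  shorter than the window are scanned with the largest feasible window.

Length classes are lower-inclusive: [0.5,2), [2,4), [4,8), [8,16),
[16,∞) Mb, with length = end − start + 1.

Per-SNP incidence is the fraction of individuals with ≥1 segment covering
the SNP. Islands use the dual threshold — incidence at or above the
population's 99th-percentile incidence (nearest-rank quantile, the
deterministic choice) *and* at least 0.35 — and candidates on a chromosome
separated by <100 kb merge into maximal intervals bounded by candidate
SNPs. Shared islands across a group are the genomic intersection of the
member populations' (merged) islands; intersection is the strictest of
the defensible readings and the documented default.

## Inbreeding coefficients

The heterozygosity-deficit estimator is implemented as
(E_het − O_het)/E_het (ratio of sums). The homozygosity wording of the
usual formula has the opposite sign; the heterozygosity form is the one
that is algebraically identical to PLINK `--het`'s
(O(hom) − E(hom))/(N − E(hom)) and that makes inbred individuals positive.
Aggregation conventions follow the tools the estimators come from: F_HOM1
and F_UNI are ratios of sums, F_HOM2 is a mean of per-SNP ratios — which
is why F_HOM1 and F_HOM2 are near-identical but not equal on real data.
F_HOM2 and F_UNI exclude SNPs monomorphic in the population; all
estimators use within-population frequencies and each individual's
non-missing SNPs. F_ROH divides summed segment length by L_auto, the sum
over chromosomes of (max SNP position − min SNP position + 1) on the
post-QC map, and decomposes exactly into the five length-class components.
Correlation matrices are Pearson; zero-variance metrics produce NaN
entries rather than a silent 0.

## LD and effective population size

r² between unphased SNPs uses maximum-likelihood haplotype frequencies
from an EM over the two-locus genotype table (the double heterozygote is
the only phase-ambiguous cell). The EM is vectorized across SNP pairs,
initialized at linkage equilibrium, and iterated to 1e-10 (cap 200
iterations); non-converged pairs fall back to the squared genotype
correlation with a warning. The EM fixed point is checked in the tests
against a brute-force likelihood grid search — note this is the MLE, not
the realized phased count, which it approaches only statistically.

LD decay bins all intra-chromosome pairs within 2,000 kb into contiguous
100-kb distance bins (lower-inclusive) and reports unweighted mean r².

Ne estimation inverts the Sved-type relationship
Ne(t) = (1/(4c_t)) (1/E[r²_adj|c_t] − α). Design choices, all
configurable: a linear 1 cM/Mb map (t ∈ [25,100] then corresponds to pair
distances of 0.5–2 Mb, matching the LD range analysed); t ↔ c via
t = 1/(2c); α = 1 (the classical no-mutation form); sampling correction
r²_adj = r² − 1/n (the estimator is named "adjusted" for a reason, and
without the correction small-n estimates collapse). Pairs are assigned to
generation t when their map distance lies in [1/(2(t+0.5)), 1/(2(t−0.5))].
Rows with no pairs, or a non-positive mean adjusted r² or Ne, are flagged
invalid rather than fabricated.

## F_ST scan

Per-SNP Weir–Cockerham (1984) two-population components a, b, c are
computed from per-population sample sizes, frequencies and heterozygote
fractions; θ = a/(a+b+c) may be negative and is not clamped; loci
monomorphic across both populations contribute (0,0,0) and are excluded
from ratios. Windows of 100 kb advance in 10-kb steps anchored at
position 1 per chromosome; a SNP belongs to every window containing it;
window values are the ratio of sums Σa/Σ(a+b+c); windows without usable
SNPs are omitted. Outliers are the top fraction (default 1%) genome-wide:
the cutoff is the k-th largest window value with k = ceil(f·N) and ties
at the cutoff are kept, so 100 distinct windows yield exactly one outlier
and a fully tied scan flags everything. Shared outlier regions between two
scans are the merged genomic intersection of their outlier windows.

## Synthetic data

The generator is a forward-in-time diploid Wright–Fisher model, not a
coalescent: forward simulation directly produces the recent-generation LD
regime the Ne estimator probes (t ≤ 100) and makes inbreeding and sweep
planting trivial.

* **Founders**: 2·Ne haplotypes; SNP positions uniform per chromosome
  (even allocation of the SNP budget across chromosomes); counted-allele
  frequencies uniform on [maf_min, 1−maf_min] (array-like spectrum,
  default floor 0.05); founder alleles drawn independently per SNP, i.e.
  linkage equilibrium at generation 0.
* **Reproduction**: each offspring draws two distinct parents uniformly
  (no selfing); each gamete recombines as a Poisson process on the linear
  genetic map (Haldane, no interference, default 1 cM/Mb); optional
  symmetric mutation (default 0).
* **Inbred lines**: each requested individual comes from an independent
  sub-line — two unrelated founders, g generations of full-sib mating,
  one final offspring — with pedigree-expected F from the full-sib
  recurrence F_t = (1 + 2F_{t−1} + F_{t−2})/4: 0.25, 0.375, 0.5, 0.594…
* **Planting**: `plant_autozygosity` copies haplotype 1 over haplotype 2
  inside an interval (tracked as a per-sample interval union so
  overlapping plants are not double-counted); `het_flanks` forces that
  many flanking SNPs heterozygous on each side, making the tract boundary
  *identifiable* — in an outbred flank, chance homozygosity otherwise
  extends the observable run beyond the planted interval, and because the
  detector tolerates one heterozygote per window, two forced
  heterozygotes per side are needed to hard-stop a run. `plant_sweep`
  copies one reference haplotype onto both chromosomes of a random
  carrier fraction inside a region, emulating an extended haplotype at
  high frequency. `diverge_populations` evolves two replicate populations
  independently from the same founders and records the drift expectation
  E[F_ST] ≈ 1 − (1 − 1/(2Ne))^t.

What the simulator does *not* emulate: realistic demography, mutation
spectra, array ascertainment beyond the MAF floor, genotyping error, or
selection beyond haplotype copying. Passing parameter-recovery tests
therefore shows the estimators are correctly implemented and calibrated
under their own model assumptions, not that they are robust to real-data
artefacts such as array batch effects or map errors.

## Validation experiment sizes

The validation suite uses problem sizes chosen to exercise each stage at
the scale the estimators are designed for while keeping the whole suite
quick to run: 200 random single-chromosome genomes (≤300 SNPs) for ROH
oracle equivalence; 50 planted tracts of ~72 SNPs on a 30k-SNP/18-
chromosome map (tracts are placed on spans whose local SNP density and
gaps satisfy the detector's own criteria — a tract the map cannot support
is undetectable by construction, see above); n=300, m=10,000 for HWE
calibration; 300 individuals × 20,000 SNPs for the inbreeding-gradient
correlation; ten replicates of an 18-chromosome, ~15k-SNP, Ne=100
constant-size population with a 120-generation burn-in (enough history to
equilibrate LD at the probed map distances of 0.5–2 Mb) for Ne recovery;
ten replicates of a 6-chromosome, 5,400-SNP divergence at Ne=100,
t=20 for F_ST calibration; and a 21k-SNP, 6-chromosome cohort with a 1-Mb
60%-carrier sweep for island recovery.

## Known limitations

* No haplotype phasing, imputation, liftover, or binary PLINK input.
* The shared-SNP panel for cross-population PCA is the intersection of
  SNPs typed in every population; multi-array strand harmonization is out
  of scope.
* LD-based Ne carries no confidence intervals; treat trajectories from
  <50 samples as qualitative.
* Plot rendering is out of scope; all results are tabular (TSV/BED/JSON).
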