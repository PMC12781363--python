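"""Forward-in-time synthetic genotype generator with recorded ground truth.

Every analysis stage of the toolkit can be exercised against data whose
generating parameters are known: a founder haplotype pool with an
array-like allele-frequency spectrum, discrete-generation Wright-Fisher
reproduction with Haldane crossovers on a linear genetic map, full-sib
inbred lines with pedigree-expected F, planted autozygous tracts, planted
haplotype sweeps, and population divergence.

All randomness flows through a single integer seed; the same seed gives
byte-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix


@dataclass(frozen=True)
class SimConfig:
    n_snps: int
    n_chromosomes: int = 18
    chrom_length_mb: float = 100.0
    founder_maf_min: float = 0.05
    ne: int = 100
    n_generations: int = 0
    cm_per_mb: float = 1.0
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        for name in ("n_chromosomes", "chrom_length_mb", "cm_per_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.founder_maf_min < 0.5:
            raise ValueError("founder_maf_min must be in (0, 0.5)")
        if self.ne < 2:
            raise ValueError("ne must be >= 2")

    @property
    def chrom_length_bp(self) -> int:
        return int(self.chrom_length_mb * 1e6)

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_length_mb * self.cm_per_mb / 100.0

    def snps_per_chromosome(self) -> list[int]:
        base, extra = divmod(self.n_snps, self.n_chromosomes)
        return [base + (1 if c < extra else 0) for c in range(self.n_chromosomes)]


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated dataset."""

    ne_history: list = field(default_factory=list)
    autozygosity_fraction: dict = field(default_factory=dict)
    planted_tracts: list = field(default_factory=list)  # (sample, chrom, start, end)
    sweep_regions: list = field(default_factory=list)   # (chrom, start, end, carrier_fraction)
    divergence_time_generations: int | None = None
    expected_fst: float | None = None
    pedigree_f: dict = field(default_factory=dict)


@dataclass
class FounderPool:
    cfg: SimConfig
    variants: pd.DataFrame
    haplotypes: list[np.ndarray]  # per chromosome: (2*ne, m_c) int8
    founder_freqs: np.ndarray


@dataclass
class SimulatedPopulation:
    """Haplotype-bearing population; the genotype matrix is derived from it."""

    cfg: SimConfig
    variants: pd.DataFrame
    haplotypes: list[np.ndarray]  # per chromosome: (2*n, m_c), row 2i/2i+1 = sample i
    sample_ids: list[str]
    population: str = "sim"

    @property
    def n_samples(self) -> int:
        return self.haplotypes[0].shape[0] // 2

    def to_genotype_matrix(self) -> GenotypeMatrix:
        dosage = np.concatenate(
            [h[0::2] + h[1::2] for h in self.haplotypes], axis=1
        ).astype(np.int8)
        samples = pd.DataFrame(
            {"sample_id": self.sample_ids, "population": self.population}
        )
        return GenotypeMatrix(samples, self.variants, dosage)

    def genome_length_bp(self) -> int:
        total = 0
        for chrom in dict.fromkeys(self.variants["chromosome"]):
            cpos = self.variants.loc[
                self.variants["chromosome"] == chrom, "position_bp"
            ]
            total += int(cpos.max() - cpos.min() + 1)
        return total


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def simulate_founders(cfg: SimConfig) -> FounderPool:
    """2*Ne founder haplotypes with a truncated-uniform frequency spectrum.

    SNP positions are uniform per chromosome (sorted, unique); founder
    counted-allele frequencies are uniform on [maf_min, 1 - maf_min];
    founder haplotypes draw alleles independently per SNP (linkage
    equilibrium in the founder generation).
    """
    rng = np.random.default_rng(cfg.seed)
    rows, haps, freqs = [], [], []
    for c, m_c in enumerate(cfg.snps_per_chromosome()):
        chrom = str(c + 1)
        pos = _unique_positions(rng, m_c, cfg.chrom_length_bp)
        p = rng.uniform(cfg.founder_maf_min, 1 - cfg.founder_maf_min, size=m_c)
        h = (rng.random((2 * cfg.ne, m_c)) < p).astype(np.int8)
        for k in range(m_c):
            rows.append(
                {
                    "snp_id": f"snp_{chrom}_{k}",
                    "chromosome": chrom,
                    "position_bp": int(pos[k]),
                    "allele_a": "A",
                    "allele_b": "G",
                }
            )
        haps.append(h)
        freqs.append(p)
    return FounderPool(cfg, pd.DataFrame(rows), haps, np.concatenate(freqs))


def _unique_positions(rng: np.random.Generator, m: int, length_bp: int) -> np.ndarray:
    """``m`` sorted unique uniform positions in [1, length_bp]."""
    if m > length_bp:
        raise ValueError("more SNPs than base pairs on a chromosome")
    uniq = np.unique(rng.integers(1, length_bp + 1, size=2 * m + 16))
    while uniq.size < m:
        more = rng.integers(1, length_bp + 1, size=2 * m)
        uniq = np.unique(np.concatenate([uniq, more]))
    if uniq.size > m:
        uniq = np.sort(rng.choice(uniq, size=m, replace=False))
    return uniq.astype(np.int64)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _make_gametes(
    haps: np.ndarray,
    pos: np.ndarray,
    morgans: float,
    parents: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parents`` (diploid parent indices).

    Crossovers follow a Poisson process on the genetic map (Haldane, no
    interference): k ~ Poisson(L Morgans), breakpoints uniform; the allele
    at each SNP comes from haplotype (start + crossovers-before) mod 2.
    """
    m = haps.shape[1]
    n_g = parents.size
    out = np.empty((n_g, m), dtype=np.int8)
    k = rng.poisson(morgans, size=n_g)
    start = rng.integers(0, 2, size=n_g)
    span = pos[-1] - pos[0] + 1

    plain = k == 0
    out[plain] = haps[2 * parents[plain] + start[plain]]
    for g in np.flatnonzero(~plain):
        bp = pos[0] + rng.random(k[g]) * span
        crossings = np.searchsorted(np.sort(bp), pos)
        which = (start[g] + crossings) % 2
        p2 = 2 * parents[g]
        out[g] = np.where(which == 0, haps[p2], haps[p2 + 1])
    return out


def _next_generation(
    haps_by_chrom: list[np.ndarray],
    positions: list[np.ndarray],
    cfg: SimConfig,
    n_offspring: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    n_parents = haps_by_chrom[0].shape[0] // 2
    dads = rng.integers(0, n_parents, size=n_offspring)
    mums = rng.integers(0, n_parents, size=n_offspring)
    clash = dads == mums  # selfing excluded
    while clash.any():
        mums[clash] = rng.integers(0, n_parents, size=int(clash.sum()))
        clash = dads == mums
    new = []
    for haps, pos in zip(haps_by_chrom, positions):
        child = np.empty((2 * n_offspring, haps.shape[1]), dtype=np.int8)
        child[0::2] = _make_gametes(haps, pos, cfg.morgans_per_chrom, dads, rng)
        child[1::2] = _make_gametes(haps, pos, cfg.morgans_per_chrom, mums, rng)
        if cfg.mutation_rate > 0:
            mu = cfg.mutation_rate * (pos[-1] - pos[0]) / haps.shape[1]
            flips = rng.random(child.shape) < mu
            child[flips] = 1 - child[flips]
        new.append(child)
    return new


def _positions_by_chrom(variants: pd.DataFrame) -> list[np.ndarray]:
    return [
        variants.loc[variants["chromosome"] == c, "position_bp"].to_numpy()
        for c in dict.fromkeys(variants["chromosome"])
    ]


# ---------------------------------------------------------------------------
# Wright-Fisher
# ---------------------------------------------------------------------------

def simulate_wright_fisher(
    pool: FounderPool,
    cfg: SimConfig | None = None,
    n_samples: int | None = None,
    seed: int | None = None,
) -> tuple[SimulatedPopulation, TruthRecord]:
    """Evolve the founder pool for ``cfg.n_generations`` at size ``cfg.ne``.

    Each offspring draws two distinct parents uniformly; the final
    generation is sampled down to ``n_samples`` individuals (all by
    default).
    """
    cfg = cfg or pool.cfg
    rng = np.random.default_rng(pool.cfg.seed + 1 if seed is None else seed)
    positions = _positions_by_chrom(pool.variants)
    haps = [h.copy() for h in pool.haplotypes]
    for _ in range(cfg.n_generations):
        haps = _next_generation(haps, positions, cfg, cfg.ne, rng)

    n_pop = haps[0].shape[0] // 2
    take = n_pop if n_samples is None else min(n_samples, n_pop)
    chosen = rng.choice(n_pop, size=take, replace=False)
    rows = np.empty(2 * take, dtype=np.intp)
    rows[0::2], rows[1::2] = 2 * chosen, 2 * chosen + 1
    haps = [h[rows] for h in haps]

    sp = SimulatedPopulation(
        cfg,
        pool.variants,
        haps,
        [f"wf_{i}" for i in range(take)],
    )
    truth = TruthRecord(ne_history=[(cfg.n_generations, cfg.ne)])
    return sp, truth


# ---------------------------------------------------------------------------
# Inbred lines
# ---------------------------------------------------------------------------

def pedigree_full_sib_f(g: int) -> float:
    """Expected inbreeding after g generations of full-sib mating."""
    f_prev2, f_prev = 0.0, 0.0
    for _ in range(g):
        f_prev2, f_prev = f_prev, 0.25 * (1.0 + 2.0 * f_prev + f_prev2)
    return f_prev


def simulate_inbred_lines(
    pool: FounderPool,
    line_generations,
    seed: int | None = None,
) -> tuple[SimulatedPopulation, TruthRecord]:
    """One individual per entry of ``line_generations``.

    Entry g produces an individual from an independent sub-line founded by
    two unrelated founder-pool individuals followed by g generations of
    full-sib mating (expected F: 0.25, 0.375, 0.5, 0.594... for g=1..4;
    g=0 is an outbred cross).
    """
    cfg = pool.cfg
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    positions = _positions_by_chrom(pool.variants)
    n_founders = pool.haplotypes[0].shape[0] // 2

    out_haps = [
        np.empty((2 * len(line_generations), h.shape[1]), dtype=np.int8)
        for h in pool.haplotypes
    ]
    pedigree_f: dict[str, float] = {}
    for idx, g in enumerate(line_generations):
        if g < 0:
            raise ValueError("generations of sib mating must be >= 0")
        a, b = rng.choice(n_founders, size=2, replace=False)
        pair = [
            np.stack([h[2 * a], h[2 * a + 1], h[2 * b], h[2 * b + 1]])
            for h in pool.haplotypes
        ]
        for _ in range(g):  # sib pair of the next generation
            new_pair = []
            for haps, pos in zip(pair, positions):
                child = np.empty((4, haps.shape[1]), dtype=np.int8)
                parents = np.array([0, 1, 0, 1])  # two sibs of parents 0 and 1
                gam = _make_gametes(haps, pos, cfg.morgans_per_chrom, parents, rng)
                child[0], child[1] = gam[0], gam[1]
                child[2], child[3] = gam[2], gam[3]
                new_pair.append(child)
            pair = new_pair
        sid = f"line{idx}_g{g}"
        for c, (haps, pos) in enumerate(zip(pair, positions)):
            gam = _make_gametes(
                haps, pos, cfg.morgans_per_chrom, np.array([0, 1]), rng
            )
            out_haps[c][2 * idx] = gam[0]
            out_haps[c][2 * idx + 1] = gam[1]
        pedigree_f[sid] = pedigree_full_sib_f(g)

    sp = SimulatedPopulation(
        cfg,
        pool.variants,
        out_haps,
        list(pedigree_f.keys()),
    )
    return sp, TruthRecord(pedigree_f=pedigree_f)


# ---------------------------------------------------------------------------
# Planting utilities
# ---------------------------------------------------------------------------

def plant_autozygosity(
    sp: SimulatedPopulation,
    truth: TruthRecord,
    sample_id: str,
    chrom: str,
    start_bp: int,
    end_bp: int,
    het_flanks: int = 0,
) -> tuple[SimulatedPopulation, TruthRecord]:
    """Overwrite the sample's second haplotype by its first in the interval.

    Every SNP inside becomes homozygous.  ``het_flanks`` forces that many
    SNPs immediately on each side of the tract heterozygous so that the
    tract boundary is identifiable: chance homozygosity in an outbred flank
    otherwise extends the observable run beyond the planted interval (a
    window-based detector tolerates one heterozygote per window, so two
    forced heterozygotes per side are needed to hard-stop a run).
    The union of planted tracts per sample is tracked so overlapping plants
    are not double-counted in the autozygosity fraction.
    """
    sp = copy.deepcopy(sp)
    truth = copy.deepcopy(truth)
    chrom_order = list(dict.fromkeys(sp.variants["chromosome"]))
    c = chrom_order.index(str(chrom))
    pos = sp.variants.loc[sp.variants["chromosome"] == str(chrom), "position_bp"].to_numpy()
    i = sp.sample_ids.index(sample_id)
    a = np.searchsorted(pos, start_bp, side="left")
    b = np.searchsorted(pos, end_bp, side="right")
    if b <= a:
        import warnings

        warnings.warn(f"planted interval {chrom}:{start_bp}-{end_bp} covers no SNPs")
    sp.haplotypes[c][2 * i + 1, a:b] = sp.haplotypes[c][2 * i, a:b]
    for k in range(int(het_flanks)):
        for j in (a - 1 - k, b + k):
            if 0 <= j < pos.size:
                sp.haplotypes[c][2 * i, j] = 0
                sp.haplotypes[c][2 * i + 1, j] = 1

    truth.planted_tracts.append((sample_id, str(chrom), int(start_bp), int(end_bp)))
    genome = sp.genome_length_bp()
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for sid, ch, s, e in truth.planted_tracts:
        if sid == sample_id:
            per_chrom.setdefault(ch, []).append((s, e))
    from .roh import _merge

    covered = sum(e - s + 1 for ch, iv in per_chrom.items() for s, e in _merge(iv))
    truth.autozygosity_fraction[sample_id] = covered / genome
    return sp, truth


def plant_sweep(
    sp: SimulatedPopulation,
    truth: TruthRecord,
    chrom: str,
    start_bp: int,
    end_bp: int,
    carrier_fraction: float,
    seed: int | None = None,
) -> tuple[SimulatedPopulation, TruthRecord]:
    """Copy one reference haplotype onto both haplotypes of a random
    ``carrier_fraction`` share of individuals inside the region, creating a
    high-incidence homozygous region (an ROH-island analogue of an extended
    haplotype segregating at high frequency)."""
    if not 0 < carrier_fraction <= 1:
        raise ValueError("carrier_fraction must be in (0, 1]")
    sp = copy.deepcopy(sp)
    truth = copy.deepcopy(truth)
    rng = np.random.default_rng(sp.cfg.seed + 3 if seed is None else seed)
    chrom_order = list(dict.fromkeys(sp.variants["chromosome"]))
    c = chrom_order.index(str(chrom))
    pos = sp.variants.loc[sp.variants["chromosome"] == str(chrom), "position_bp"].to_numpy()
    a = np.searchsorted(pos, start_bp, side="left")
    b = np.searchsorted(pos, end_bp, side="right")
    if b - a < 15:
        import warnings

        warnings.warn(
            f"sweep region {chrom}:{start_bp}-{end_bp} has {b - a} SNPs, "
            "below the ROH detector minimum of 15"
        )
    n = sp.n_samples
    n_carriers = int(round(carrier_fraction * n))
    carriers = rng.choice(n, size=n_carriers, replace=False)
    ref = sp.haplotypes[c][0, a:b].copy()
    for i in carriers:
        sp.haplotypes[c][2 * i, a:b] = ref
        sp.haplotypes[c][2 * i + 1, a:b] = ref
    truth.sweep_regions.append((str(chrom), int(start_bp), int(end_bp), carrier_fraction))
    return sp, truth


# ---------------------------------------------------------------------------
# Divergence
# ---------------------------------------------------------------------------

def diverge_populations(
    pool: FounderPool,
    t_div: int,
    n_samples: int | None = None,
    seed: int | None = None,
) -> tuple[SimulatedPopulation, SimulatedPopulation, TruthRecord]:
    """Two populations evolving independently from the same founders for
    ``t_div`` generations at size Ne each; expected per-SNP F_ST (relative
    to the founder generation) is recorded as 1 - (1 - 1/(2 Ne))^t."""
    if t_div < 0:
        raise ValueError("t_div must be >= 0")
    cfg = pool.cfg
    base_seed = cfg.seed + 10 if seed is None else seed
    pops = []
    for k in range(2):
        wf_cfg = SimConfig(
            n_snps=cfg.n_snps,
            n_chromosomes=cfg.n_chromosomes,
            chrom_length_mb=cfg.chrom_length_mb,
            founder_maf_min=cfg.founder_maf_min,
            ne=cfg.ne,
            n_generations=t_div,
            cm_per_mb=cfg.cm_per_mb,
            mutation_rate=cfg.mutation_rate,
            seed=cfg.seed,
        )
        sp, _ = simulate_wright_fisher(
            pool, wf_cfg, n_samples=n_samples, seed=base_seed + k
        )
        sp.population = f"pop{k + 1}"
        sp.sample_ids = [f"pop{k + 1}_{i}" for i in range(sp.n_samples)]
        pops.append(sp)
    truth = TruthRecord(
        ne_history=[(t_div, cfg.ne)],
        divergence_time_generations=t_div,
        expected_fst=1.0 - (1.0 - 1.0 / (2.0 * cfg.ne)) ** t_div,
    )
    return pops[0], pops[1], truth
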