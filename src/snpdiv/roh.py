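"""Runs of homozygosity: detection, length classes, incidence, islands.

The detector follows the PLINK-style sliding-window procedure: a window of
``window_snps`` SNPs slides one SNP at a time across each chromosome of each
individual; a window is called homozygous when it contains at most
``window_max_het`` heterozygous and ``window_max_missing`` missing calls; a
SNP is "in a run" when at least ``window_hit_threshold`` of the windows
covering it are homozygous.  Maximal stretches of in-run SNPs are split at
inter-SNP gaps above ``max_gap_kb``, trimmed so both endpoints are
homozygous non-missing SNPs, and emitted when they satisfy the minimum SNP
count, minimum length, and SNP-density criteria.

Coordinates are 1-based closed; ``length_bp = end_bp - start_bp + 1``.

Length classes (lower-inclusive, Mb): [0.5, 2), [2, 4), [4, 8), [8, 16),
[16, inf) — labelled lt2, 2to4, 4to8, 8to16, gt16.

ROH islands: SNPs whose population incidence (share of individuals whose
runs cover the SNP) reaches both the population's 99th-percentile incidence
(nearest-rank) and an absolute floor (default 35%) are island candidates;
candidates on a chromosome separated by less than ``merge_gap_kb`` are
merged into maximal intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

LENGTH_CLASSES = ("lt2", "2to4", "4to8", "8to16", "gt16")
_CLASS_EDGES_MB = (0.0, 2.0, 4.0, 8.0, 16.0, np.inf)


@dataclass(frozen=True)
class ROHParams:
    min_length_kb: float = 500.0
    min_snps: int = 15
    max_gap_kb: float = 500.0
    max_kb_per_snp: float = 75.0
    window_snps: int = 50
    window_max_missing: int = 5
    window_max_het: int = 1
    window_hit_threshold: float = 0.05

    def __post_init__(self):
        for name in ("min_length_kb", "min_snps", "max_gap_kb", "max_kb_per_snp",
                     "window_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if self.window_max_missing < 0 or self.window_max_het < 0:
            raise ValueError("window tolerances must be >= 0")


def length_class(length_bp: int) -> str:
    mb = length_bp / 1e6
    idx = np.searchsorted(_CLASS_EDGES_MB, mb, side="right") - 1
    return LENGTH_CLASSES[min(idx, len(LENGTH_CLASSES) - 1)]


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH segments for every individual.

    Returns a DataFrame with columns ``sample_id``, ``chromosome``,
    ``start_bp``, ``end_bp``, ``n_snps``, ``length_bp``, ``length_class``.
    """
    params = params or ROHParams()
    rows: list[dict] = []
    for chrom in gm.chromosome_labels():
        vmask = gm.chromosomes == chrom
        pos = gm.positions[vmask]
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"positions on chromosome {chrom} not strictly sorted")
        dosage = gm.dosage[:, vmask]
        for i, sid in enumerate(gm.sample_ids):
            for seg in _scan_individual(dosage[i], pos, params):
                rows.append({"sample_id": sid, "chromosome": chrom, **seg})
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps",
                 "length_bp", "length_class"],
    )


def _scan_individual(dos: np.ndarray, pos: np.ndarray, params: ROHParams) -> list[dict]:
    m = dos.size
    het = dos == 1
    mis = dos == MISSING
    hom = ~het & ~mis

    # chromosomes shorter than the window are scanned with the largest
    # feasible window
    w = min(params.window_snps, m)

    # per-window homozygosity call
    het_c = np.concatenate(([0], np.cumsum(het)))
    mis_c = np.concatenate(([0], np.cumsum(mis)))
    n_win = m - w + 1
    win_het = het_c[w:] - het_c[:-w]
    win_mis = mis_c[w:] - mis_c[:-w]
    win_ok = (win_het <= params.window_max_het) & (win_mis <= params.window_max_missing)

    # per-SNP hit fraction over covering windows
    ok_c = np.concatenate(([0], np.cumsum(win_ok)))
    j = np.arange(m)
    lo = np.maximum(j - w + 1, 0)
    hi = np.minimum(j, n_win - 1)
    covering = hi - lo + 1
    hits = ok_c[hi + 1] - ok_c[lo]
    in_run = hits / covering >= params.window_hit_threshold

    # maximal in-run stretches, split at large inter-SNP gaps
    gap_bp = params.max_gap_kb * 1000.0
    big_gap = np.concatenate(([False], np.diff(pos) > gap_bp))

    segments = []
    start = None
    for k in range(m + 1):
        inside = k < m and in_run[k]
        boundary = k == m or not inside or (start is not None and big_gap[k])
        if start is not None and boundary:
            segments.append((start, k - 1))
            start = None
        if k < m and inside and start is None:
            start = k

    out = []
    min_len = params.min_length_kb * 1000.0
    max_density = params.max_kb_per_snp * 1000.0
    for a, b in segments:
        # trim endpoints to homozygous non-missing SNPs
        while a <= b and not hom[a]:
            a += 1
        while b >= a and not hom[b]:
            b -= 1
        if a > b:
            continue
        n_snps = b - a + 1
        length = int(pos[b] - pos[a] + 1)
        if n_snps < params.min_snps or length < min_len:
            continue
        if length / n_snps > max_density:
            continue
        out.append(
            {
                "start_bp": int(pos[a]),
                "end_bp": int(pos[b]),
                "n_snps": int(n_snps),
                "length_bp": length,
                "length_class": length_class(length),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def classify_and_summarize(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-length-class count, mean (SD) and range of segment lengths (Mb)."""
    rows = []
    for cls in LENGTH_CLASSES:
        if len(segments):
            lens = segments.loc[segments["length_class"] == cls, "length_bp"] / 1e6
        else:
            lens = pd.Series(dtype=float)
        rows.append(
            {
                "length_class": cls,
                "count": int(len(lens)),
                "mean_mb": float(lens.mean()) if len(lens) else np.nan,
                "sd_mb": float(lens.std(ddof=0)) if len(lens) else np.nan,
                "min_mb": float(lens.min()) if len(lens) else np.nan,
                "max_mb": float(lens.max()) if len(lens) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def roh_incidence(segments: pd.DataFrame, gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP fraction of individuals with a run covering the SNP."""
    if gm.n_samples == 0:
        raise ValueError("population of size zero")
    sample_idx = {s: i for i, s in enumerate(gm.sample_ids)}
    covered = np.zeros((gm.n_samples, gm.n_snps), dtype=bool)
    chroms = gm.chromosomes
    pos = gm.positions
    for chrom in gm.chromosome_labels():
        vidx = np.flatnonzero(chroms == chrom)
        cpos = pos[vidx]
        if len(segments) == 0:
            continue
        segs = segments[segments["chromosome"].astype(str) == str(chrom)]
        for _, seg in segs.iterrows():
            i = sample_idx.get(seg["sample_id"])
            if i is None:
                continue
            a = np.searchsorted(cpos, seg["start_bp"], side="left")
            b = np.searchsorted(cpos, seg["end_bp"], side="right")
            covered[i, vidx[a:b]] = True
    return covered.mean(axis=0)


def detect_islands(
    incidence: np.ndarray,
    gm: GenotypeMatrix,
    quantile: float = 0.99,
    min_incidence: float = 0.35,
    merge_gap_kb: float = 100.0,
) -> pd.DataFrame:
    """Call ROH islands from per-SNP incidence with the dual-threshold rule."""
    incidence = np.asarray(incidence, dtype=float)
    if incidence.size == 0:
        raise ValueError("incidence defined on zero SNPs")
    cutoff = _nearest_rank_quantile(incidence, quantile)
    candidate = (incidence >= cutoff) & (incidence >= min_incidence)

    rows = []
    gap_bp = merge_gap_kb * 1000.0
    chroms = gm.chromosomes
    pos = gm.positions
    for chrom in gm.chromosome_labels():
        vidx = np.flatnonzero((chroms == chrom) & candidate)
        if vidx.size == 0:
            continue
        cpos = pos[vidx]
        breaks = np.flatnonzero(np.diff(cpos) >= gap_bp)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [vidx.size - 1]))
        for a, b in zip(starts, ends):
            inc = incidence[vidx[a : b + 1]]
            rows.append(
                {
                    "chromosome": chrom,
                    "start_bp": int(cpos[a]),
                    "end_bp": int(cpos[b]),
                    "n_snps": int(b - a + 1),
                    "peak_incidence": float(inc.max()),
                    "mean_incidence": float(inc.mean()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "n_snps",
                 "peak_incidence", "mean_incidence"],
    )


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile: x_(ceil(q*N)) of the sorted sample."""
    srt = np.sort(values)
    rank = max(1, int(np.ceil(q * srt.size)))
    return float(srt[rank - 1])


def shared_islands(islands_by_population: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genomic intersection of islands across every population of a group.

    Returns maximal intervals covered by at least one island in *every*
    member population.
    """
    if not islands_by_population:
        raise ValueError("empty group")
    interval_sets = []
    for islands in islands_by_population.values():
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for _, row in islands.iterrows():
            per_chrom.setdefault(str(row["chromosome"]), []).append(
                (int(row["start_bp"]), int(row["end_bp"]))
            )
        interval_sets.append({c: _merge(v) for c, v in per_chrom.items()})

    shared = interval_sets[0]
    for other in interval_sets[1:]:
        shared = {
            c: _intersect(shared[c], other[c])
            for c in set(shared) & set(other)
        }
    rows = [
        {"chromosome": c, "start_bp": a, "end_bp": b}
        for c in sorted(shared)
        for a, b in shared[c]
    ]
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"])


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def _intersect(xs: list[tuple[int, int]], ys: list[tuple[int, int]]):
    out = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if a <= b:
            out.append((a, b))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out
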