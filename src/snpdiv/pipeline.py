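"""Orchestrate the full per-population / per-group analysis from one config.

The configuration is a single declarative YAML file::

    input:
      vcf: cohort.vcf            # or: ped: x.ped / map: x.map
    sample_map: samples.tsv      # sample_id <tab> population <tab> group
    groups:
      duroc_eu_na: [Duroc1, Duroc2]
    qc: {}                       # QCProfile overrides
    roh: {}                      # ROHParams overrides
    islands: {quantile: 0.99, min_incidence: 0.35, merge_gap_kb: 100}
    ne: {t_min: 25, t_max: 100, alpha: 1.0, cm_per_mb: 1.0,
         correction: one_over_n, method: em}
    fst_pairs:
      - {name: d_vs_y, pool1: [Duroc1], pool2: [Yorkshire]}
    output_dir: results/
    seed: 1

Per-population analyses use the population-specific SNP sets that survive
QC; cross-population PCA and distances use the intersection of SNPs typed
in every population.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import MISSING, GenotypeMatrix
from .fst import outlier_windows, shared_outliers, windowed_fst
from .inbreeding import correlation_matrix, inbreeding_records
from .io import (
    apply_sample_map,
    intervals_to_bed,
    read_plink_text,
    read_sample_map,
    read_vcf,
    write_table,
)
from .ldne import estimate_ne, ld_decay
from .popgen import compute_grm, diversity_summary, ibs_distance, pca
from .qc import QCProfile, apply_qc, roh_profile
from .roh import ROHParams, classify_and_summarize, detect_islands, detect_roh, roh_incidence, shared_islands

log = logging.getLogger("snpdiv")


@dataclass
class AnalysisConfig:
    input: dict
    output_dir: str
    sample_map: str | None = None
    groups: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    islands: dict = field(default_factory=dict)
    ne: dict = field(default_factory=dict)
    fst_pairs: list = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def load_input(cfg: AnalysisConfig) -> GenotypeMatrix:
    inp = cfg.input
    if "vcf" in inp:
        gm = read_vcf(inp["vcf"])
    elif "ped" in inp and "map" in inp:
        gm = read_plink_text(inp["ped"], inp["map"])
    else:
        raise ValueError("input needs either 'vcf' or 'ped'+'map'")
    if cfg.sample_map:
        gm = apply_sample_map(gm, read_sample_map(cfg.sample_map))
    return gm


def validate_config(cfg: AnalysisConfig, gm: GenotypeMatrix) -> None:
    pops = set(gm.samples["population"])
    referenced = set()
    for members in cfg.groups.values():
        if not members:
            raise ValueError("empty group in config")
        referenced.update(members)
    for pair in cfg.fst_pairs:
        referenced.update(pair.get("pool1", []))
        referenced.update(pair.get("pool2", []))
    unknown = referenced - pops
    if unknown:
        raise ValueError(f"config references unknown populations: {sorted(unknown)}")


def shared_snp_mask(gm: GenotypeMatrix) -> np.ndarray:
    """SNPs typed (at least once) in every population — the shared panel."""
    mask = np.ones(gm.n_snps, dtype=bool)
    for pop in dict.fromkeys(gm.samples["population"]):
        rows = (gm.samples["population"] == pop).to_numpy()
        mask &= (gm.dosage[rows] != MISSING).any(axis=0)
    return mask


def run_full_analysis(cfg: AnalysisConfig) -> str:
    """Run every stage; returns the output directory.

    Per population: QC report, diversity summary, ROH segments and
    class summary, inbreeding records and means, LD decay, Ne trajectory,
    islands.  Per group: shared islands, inbreeding-metric correlations.
    Per configured pair: windowed F_ST with outliers; shared outlier
    regions between consecutive scans.
    """
    import os

    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    logging.basicConfig(
        filename=os.path.join(out, "run.log"), level=logging.INFO, force=True
    )
    gm = load_input(cfg)
    validate_config(cfg, gm)

    qc_profile = QCProfile(**cfg.qc)
    roh_qc = roh_profile(**cfg.qc)
    roh_params = ROHParams(**cfg.roh)
    island_kw = dict(cfg.islands)
    ne_kw = dict(cfg.ne)
    t_range = range(int(ne_kw.pop("t_min", 25)), int(ne_kw.pop("t_max", 100)) + 1)

    diversity_rows, islands_by_pop, records_by_pop = [], {}, {}
    populations = list(dict.fromkeys(gm.samples["population"]))
    for pop in populations:
        pdir = os.path.join(out, f"pop_{pop}")
        os.makedirs(pdir, exist_ok=True)
        sub = gm.subset_population(pop)

        clean, report = apply_qc(sub, qc_profile)
        write_table(report.to_frame(), os.path.join(pdir, "qc_report.tsv"))
        log.info("population %s: QC %s -> %s SNPs", pop, sub.n_snps, clean.n_snps)

        diversity_rows.append(diversity_summary(clean))
        write_table(pd.DataFrame([diversity_rows[-1]]), os.path.join(pdir, "diversity.tsv"))

        roh_gm, _ = apply_qc(sub, roh_qc)
        segments = detect_roh(roh_gm, roh_params)
        write_table(segments, os.path.join(pdir, "roh_segments.tsv"))
        if len(segments):
            intervals_to_bed(segments, os.path.join(pdir, "roh_segments.bed"),
                             extra_columns=("sample_id",))
        write_table(classify_and_summarize(segments),
                    os.path.join(pdir, "roh_summary.tsv"))

        incidence = roh_incidence(segments, roh_gm)
        islands = detect_islands(incidence, roh_gm, **island_kw)
        islands_by_pop[pop] = islands
        write_table(islands, os.path.join(pdir, "roh_islands.tsv"))

        records = inbreeding_records(clean, detect_roh(clean, roh_params))
        records_by_pop[pop] = records
        write_table(records, os.path.join(pdir, "inbreeding.tsv"))
        means = records.drop(columns="sample_id").mean().to_frame().T
        means.insert(0, "population", pop)
        write_table(means, os.path.join(pdir, "inbreeding_means.tsv"))

        write_table(ld_decay(clean, method=ne_kw.get("method", "em")),
                    os.path.join(pdir, "ld_decay.tsv"))
        write_table(estimate_ne(clean, t_range=t_range, **ne_kw),
                    os.path.join(pdir, "ne_trajectory.tsv"))

    write_table(pd.DataFrame(diversity_rows), os.path.join(out, "diversity.tsv"))

    # cross-population structure on the shared SNP panel
    if len(populations) > 1:
        shared = gm.subset(variant_filter=shared_snp_mask(gm))
        grm = compute_grm(shared, method="variance_standardized")
        k = min(10, shared.n_samples - 1)
        coords, varexp = pca(grm, k)
        pcs = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(k)])
        pcs.insert(0, "sample_id", shared.sample_ids)
        pcs["population"] = shared.samples["population"].to_numpy()
        write_table(pcs, os.path.join(out, "pca.tsv"))
        write_table(
            pd.DataFrame({"component": [f"PC{i+1}" for i in range(k)],
                          "variance_explained": varexp}),
            os.path.join(out, "pca_variance.tsv"),
        )
        dist = pd.DataFrame(ibs_distance(shared), index=shared.sample_ids,
                            columns=shared.sample_ids)
        dist.to_csv(os.path.join(out, "ibs_distance.tsv"), sep="\t")

    for group, members in cfg.groups.items():
        gdir = os.path.join(out, f"group_{group}")
        os.makedirs(gdir, exist_ok=True)
        write_table(
            shared_islands({m: islands_by_pop[m] for m in members}),
            os.path.join(gdir, "shared_islands.tsv"),
        )
        pooled = pd.concat([records_by_pop[m] for m in members], ignore_index=True)
        if len(pooled) >= 3:
            corr = correlation_matrix(pooled)
            corr.to_csv(os.path.join(gdir, "inbreeding_correlations.tsv"), sep="\t")

    scans = {}
    for pair in cfg.fst_pairs:
        name = pair.get("name") or f"{'_'.join(pair['pool1'])}_vs_{'_'.join(pair['pool2'])}"
        gm1 = gm.subset(sample_filter=gm.samples["population"].isin(pair["pool1"]).to_numpy())
        gm2 = gm.subset(sample_filter=gm.samples["population"].isin(pair["pool2"]).to_numpy())
        windows = outlier_windows(windowed_fst(gm1, gm2))
        scans[name] = windows
        write_table(windows, os.path.join(out, f"fst_{name}.tsv"))
        flagged = windows[windows["is_outlier"]]
        if len(flagged):
            intervals_to_bed(flagged, os.path.join(out, f"fst_{name}_outliers.bed"))
    names = list(scans)
    for s1, s2 in zip(names, names[1:]):
        write_table(
            shared_outliers(scans[s1], scans[s2]),
            os.path.join(out, f"fst_shared_{s1}__{s2}.tsv"),
        )

    manifest = {"config": asdict(cfg), "seed": cfg.seed, "version": __version__}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
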