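"""End-to-end orchestration: simulate/load -> QC -> scans -> windows ->
ROH -> AMOVA -> report, as one configured, seeded, logged run.

Analysis defaults are the protocol's printed values: call rate 0.95, MAF
0.05, sample missingness 0.10, LD pruning 50/5/0.60, 250-kb windows with
10-kb overlaps, significance threshold -log10(p) = 4 with >= 3 SNPs per
window, the seven ROH criteria, the 0.999 island quantile, and 1000 label
permutations for the AMOVA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __about__
from .amova import classical_mds, hamming_distance_matrix, permanova
from .genotype_io import (ConfigError, read_labels, read_ped_map, read_vcf,
                          split_by_group)
from .haplostats import ihs_scan, infer_ancestral, rsb_scan, xpehh_scan
from .qc import run_qc
from .report_annotate import genes_in_regions, load_annotation, write_report
from .roh import ROHParams, detect_roh, islands_to_frame, roh_islands
from .synthetic_data import CohortConfig, simulate_cohort, write_truth
from .window_scan import (classify_windows, intersect_regions, make_windows,
                          merge_to_regions, regions_to_frame)

logger = logging.getLogger("sweepscan")

PAPER_DEFAULTS = {
    "min_call_rate": 0.95, "min_maf": 0.05, "max_sample_missing": 0.10,
    "prune_window": 50, "prune_step": 5, "prune_r2": 0.60,
    "window_bp": 250_000, "overlap_bp": 10_000,
    "p_threshold": 4.0, "min_hits": 3,
    "roh_quantile": 0.999, "n_permutations": 1000,
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    # input: either simulate a cohort or load files
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    labels_file: str | None = None
    annotation: str | None = None
    annotation_format: str = "bed"
    # qc
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    max_sample_missing: float = 0.10
    ld_prune: bool = True
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.60
    # scans
    ehh_cutoff: float = 0.05
    scan_maf_min: float = 0.05
    ihs_bins: int = 20
    edge_rule: str = "discard"
    rsb_centering: str = "median"
    xpehh_centering: str = "mean"
    # windows
    window_bp: int = 250_000
    overlap_bp: int = 10_000
    p_threshold: float = 4.0
    min_hits: int = 3
    # roh
    roh: ROHParams = field(default_factory=ROHParams)
    roh_quantile: float = 0.999
    # amova
    amova_models: list = field(default_factory=lambda: [
        ["weight"], ["geography"], ["weight", "geography"]])
    n_permutations: int = 1000
    permute_unit: str = "population"
    # run
    out_dir: str = "sweepscan_out"
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 <= self.min_call_rate <= 1, "min_call_rate in [0,1]"),
            (0 <= self.min_maf <= 0.5, "min_maf in [0,0.5]"),
            (0 <= self.max_sample_missing <= 1,
             "max_sample_missing in [0,1]"),
            (self.prune_window > 0 and self.prune_step > 0,
             "pruning window/step positive"),
            (0 <= self.prune_r2 <= 1, "prune_r2 in [0,1]"),
            (0 < self.ehh_cutoff < 1, "ehh_cutoff in (0,1)"),
            (self.ihs_bins >= 1, "ihs_bins >= 1"),
            (self.edge_rule in ("discard", "truncate"), "edge_rule"),
            (self.window_bp > self.overlap_bp >= 0,
             "window_bp > overlap_bp >= 0"),
            (self.min_hits >= 1, "min_hits >= 1"),
            (0 < self.roh_quantile <= 1, "roh_quantile in (0,1]"),
            (self.n_permutations >= 1, "n_permutations >= 1"),
            (self.permute_unit in ("population", "sample"), "permute_unit"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(f"invalid configuration: {msg}")
        if not self.simulate and not (self.vcf or (self.ped and self.map)):
            raise ConfigError("need vcf or ped+map when not simulating")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "roh" in d and isinstance(d["roh"], dict):
            d["roh"] = ROHParams(**d["roh"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig, seed: int):
    if config.simulate:
        logger.info("stage simulate: seeded synthetic cohort (seed=%d)",
                    seed)
        return simulate_cohort(config.cohort, seed=seed)
    if config.vcf:
        g, panel = read_vcf(config.vcf, require_phased=True)
    else:
        g = read_ped_map(config.ped, config.map)
        panel = None
    if not config.labels_file:
        raise ConfigError("labels_file required for file input")
    labels = read_labels(config.labels_file)
    return g, panel, labels, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns a dict with the in-memory results (``scans``, ``regions``,
    ``islands``, ``amova``, ``qc_report``) and the written file paths
    (``files``).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    g, panel, labels, truth = _load_inputs(config, config.seed)
    if truth is not None:
        write_truth(truth, out_dir / "truth.bed", out_dir / "truth.json")

    logger.info("stage qc: %d samples x %d markers in", g.n_samples,
                g.n_markers)
    g_qc, qc_report = run_qc(
        g, config.min_call_rate, config.min_maf, config.max_sample_missing,
        prune=config.ld_prune, window_snps=config.prune_window,
        step_snps=config.prune_step, r2_max=config.prune_r2)
    logger.info("stage qc: %d samples x %d markers out", g_qc.n_samples,
                g_qc.n_markers)

    scans = []
    regions = []
    if panel is not None:
        kept = set(g_qc.map.snp_id)
        keep_idx = np.flatnonzero(
            np.array([s in kept for s in panel.map.snp_id]))
        panel_qc = panel.subset_markers(keep_idx) \
            .subset_samples(g_qc.samples)
        anc_panel, ambiguous = infer_ancestral(panel_qc)
        windows = make_windows(g_qc.map, config.window_bp,
                               config.overlap_bp)

        ihs_regions = {}
        for factor in ("weight", "geography", "local"):
            for name, sub in split_by_group(anc_panel, labels,
                                            factor).items():
                if sub.n_haplotypes < 4:
                    continue
                logger.info("stage scan: iHS group=%s (%d haplotypes)",
                            name, sub.n_haplotypes)
                tbl = ihs_scan(sub, config.ehh_cutoff, config.scan_maf_min,
                               config.ihs_bins, config.edge_rule,
                               group=name, ambiguous=ambiguous)
                scans.append(tbl)
                flagged = classify_windows(tbl, windows, config.p_threshold,
                                           config.min_hits)
                regs = merge_to_regions(flagged, tests=("ihs",), group=name)
                ihs_regions[name] = regs
                regions.extend(regs)

        raw_groups = split_by_group(panel_qc, labels, "weight") | \
            split_by_group(panel_qc, labels, "geography")
        for contrast, (g1, g2) in (("heavy_vs_light", ("heavy", "light")),
                                   ("north_vs_south", ("north", "south"))):
            p1, p2 = raw_groups[g1], raw_groups[g2]
            if p1.n_haplotypes < 4 or p2.n_haplotypes < 4:
                continue
            logger.info("stage scan: Rsb/XP-EHH %s", contrast)
            t_rsb = rsb_scan(p1, p2, config.ehh_cutoff,
                             config.rsb_centering, config.scan_maf_min,
                             config.edge_rule, group=contrast)
            t_xp = xpehh_scan(p1, p2, config.ehh_cutoff,
                              config.xpehh_centering, config.scan_maf_min,
                              config.edge_rule, group=contrast)
            scans += [t_rsb, t_xp]
            r_rsb = merge_to_regions(
                classify_windows(t_rsb, windows, config.p_threshold,
                                 config.min_hits),
                tests=("rsb",), group=contrast)
            r_xp = merge_to_regions(
                classify_windows(t_xp, windows, config.p_threshold,
                                 config.min_hits),
                tests=("xpehh",), group=contrast)
            regions.extend(r_rsb)
            regions.extend(r_xp)
            ihs_all = [r for regs in ihs_regions.values() for r in regs]
            regions.extend(intersect_regions(r_rsb, r_xp,
                                             annotate_with=ihs_all))

    logger.info("stage roh")
    segments = detect_roh(g_qc, config.roh)
    islands = []
    for factor in ("weight", "geography"):
        for name, sub in split_by_group(g_qc, labels, factor).items():
            if sub.n_samples == 0:
                continue
            islands += roh_islands(segments, g_qc.map, sub.samples,
                                   config.roh_quantile, group=name)

    logger.info("stage amova: %d permutations", config.n_permutations)
    D = hamming_distance_matrix(g_qc, normalize=True)
    amova_rows = []
    rng = np.random.default_rng(np.random.SeedSequence(
        (config.seed, 0xA110A)).generate_state(1)[0])
    for model in config.amova_models:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        table = permanova(D, labels, model, config.n_permutations,
                          config.permute_unit, seed=sub_seed)
        t = table.terms.copy()
        t.insert(0, "model", "+".join(model))
        amova_rows.append(t)
    amova_df = pd.concat(amova_rows, ignore_index=True) if amova_rows \
        else None

    # structure check: principal coordinates of the same distance matrix
    coords, _ = classical_mds(D, k=2)
    mds = pd.DataFrame({"sample": D.samples,
                        "population": [labels.population[s]
                                       for s in D.samples]})
    for k in range(coords.shape[1]):
        mds[f"dim{k + 1}"] = coords[:, k]
    mds.to_csv(out_dir / "mds_coordinates.tsv", sep="\t", index=False,
               float_format="%.6g")

    scan_df = pd.concat(scans, ignore_index=True) if scans else None
    region_df = regions_to_frame(regions) if regions else None
    island_df = islands_to_frame(islands) if islands else None

    gene_lists = None
    if config.annotation:
        genes = load_annotation(config.annotation,
                                config.annotation_format)
        keys, lists = [], []
        for r in regions:
            keys.append(f"{r.group}:{r.chrom}:{r.start_bp}-{r.end_bp}")
        lists = genes_in_regions(regions, genes)
        gene_lists = dict(zip(keys, lists))

    metadata = {
        "package": "sweepscan",
        "version": __about__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "qc": qc_report.to_dict(),
        "paper_defaults": PAPER_DEFAULTS,
    }
    files = write_report(out_dir, scan_df, region_df, island_df, amova_df,
                         gene_lists, metadata)
    return {"scans": scan_df, "regions": region_df, "islands": island_df,
            "amova": amova_df, "qc_report": qc_report,
            "segments": segments, "files": files,
            "genotypes": g_qc, "labels": labels, "truth": truth}
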