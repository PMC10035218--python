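"""Gene annotation of candidate regions and report-bundle output.

Annotations arrive as BED (0-based half-open, converted to the package's
1-based inclusive coordinates on load) or GFF3 restricted to ``gene``
features.  A gene belongs to a region when their intervals share at least
one bp.  ``write_report`` emits the run's tables: per-SNP Manhattan-ready
TSV, candidate-region and ROH-island TSVs (with BED exports), the AMOVA
table and a metadata JSON; output is a deterministic function of inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import ConfigError, FormatError

logger = __import__("logging").getLogger("sweepscan")


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start_bp: int   # 1-based inclusive
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise FormatError(
                f"gene {self.gene_id!r}: start must be < end")


def _gff3_attr(attrs: str, keys=("Name", "ID", "gene_id")) -> str | None:
    fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
    for k in keys:
        if k in fields:
            return fields[k]
    return None


def load_annotation(path, format: str = "bed") -> list:
    """Load gene records from BED or GFF3, sorted per chromosome.

    BED: ``chrom start end name [score [strand]]``; 0-based half-open,
    converted to 1-based inclusive.  GFF3: only ``gene``-type features are
    kept (others counted and logged); coordinates are already 1-based.
    Malformed lines raise with their line number.
    """
    if format not in ("bed", "gff3"):
        raise ConfigError(f"unknown annotation format {format!r}")
    genes = []
    n_skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if format == "bed":
                    if len(parts) < 4:
                        raise ValueError("need >= 4 BED columns")
                    chrom, start, end, name = parts[:4]
                    strand = parts[5] if len(parts) > 5 else "."
                    genes.append(GeneRecord(name, chrom,
                                            int(start) + 1, int(end),
                                            strand))
                else:
                    if len(parts) < 9:
                        raise ValueError("need 9 GFF3 columns")
                    if parts[2] != "gene":
                        n_skipped += 1
                        continue
                    name = _gff3_attr(parts[8]) or f"gene_line{ln}"
                    genes.append(GeneRecord(name, parts[0], int(parts[3]),
                                            int(parts[4]), parts[6]))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    if n_skipped:
        logger.info("load_annotation: skipped %d non-gene GFF3 features",
                    n_skipped)
    genes.sort(key=lambda g: (str(g.chrom), g.start_bp, g.end_bp))
    return genes


def genes_in_regions(regions: list, genes: list) -> list:
    """Per-region gene lists by >= 1 bp interval overlap (1-based inclusive
    coordinates on both sides).  Returns a list parallel to ``regions``."""
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for r in regions:
        hits = [g.gene_id for g in by_chrom.get(r.chrom, [])
                if max(g.start_bp, r.start_bp) <= min(g.end_bp, r.end_bp)]
        out.append(hits)
    return out


def export_annotation_bed(genes: list, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t"
                     f"{g.gene_id}\t0\t{g.strand}\n")


def regions_to_bed(regions: list, path) -> None:
    """Candidate regions / islands as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = getattr(r, "group", "") or "region"
            fh.write(f"{r.chrom}\t{r.start_bp - 1 if r.start_bp > 0 else 0}"
                     f"\t{r.end_bp}\t{name}\n")


def write_report(out_dir, scans: pd.DataFrame | None = None,
                 regions: pd.DataFrame | None = None,
                 islands: pd.DataFrame | None = None,
                 amova: pd.DataFrame | None = None,
                 gene_lists: dict | None = None,
                 metadata: dict | None = None) -> dict:
    """Write the report bundle; returns {name: path} of the files written.

    Every table is written even when empty (header-only TSV), so the bundle
    layout is stable across runs.
    """
    if all(x is None for x in (scans, regions, islands, amova)):
        raise ConfigError("write_report needs at least one input table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    def _tsv(name, df, columns):
        path = out / name
        (df if df is not None else pd.DataFrame(columns=columns)) \
            .to_csv(path, sep="\t", index=False, float_format="%.6g")
        written[name] = str(path)

    _tsv("scan_snps.tsv", scans,
         ["test", "group", "chrom", "pos_bp", "snp_id", "derived_freq",
          "raw", "z", "p_score", "status"])
    _tsv("candidate_regions.tsv", regions,
         ["group", "chrom", "start_bp", "end_bp", "length_kb", "tests",
          "n_hits"])
    _tsv("roh_islands.tsv", islands,
         ["group", "chrom", "start_bp", "end_bp", "length_kb", "n_snps",
          "peak_freq"])
    _tsv("amova.tsv", amova, ["term", "df", "SS", "R2", "F", "p_value"])

    if gene_lists:
        path = out / "region_genes.tsv"
        rows = []
        for region_key, names in gene_lists.items():
            rows.append({"region": region_key, "genes": ",".join(names)})
        pd.DataFrame(rows, columns=["region", "genes"]).to_csv(
            path, sep="\t", index=False)
        written["region_genes.tsv"] = str(path)

    meta_path = out / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(metadata or {}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["run_metadata.json"] = str(meta_path)
    return written
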