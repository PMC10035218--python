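"""Core data model and genotype/haplotype file IO.

The package works on three in-memory containers that every stage shares:

``MarkerMap``
    SNP-array style marker map: id, chromosome, physical position (1-based bp)
    and the two alleles of each biallelic marker.
``GenotypeMatrix``
    Diploid dosages in {0, 1, 2} (count of allele2/ALT copies) with ``-1``
    for missing, one row per sample.
``HaplotypePanel``
    Phased binary haplotypes (two rows per sample), either in "raw" coding
    (0 = allele1) or "ancestral" coding (0 = ancestral, 1 = derived) after
    explicit recoding.

Files are exchanged as classic PLINK PED/MAP text and VCF 4.2.  Positions are
1-based inclusive everywhere inside the package; BED exports convert to
0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("sweepscan")

MISSING = -1  # missing dosage sentinel

WEIGHT_LEVELS = ("heavy", "light", "none")
GEO_LEVELS = ("north", "south", "none")


class FormatError(ValueError):
    """Malformed or structurally inconsistent input file."""


class ConfigError(ValueError):
    """Invalid parameter or configuration value."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered biallelic marker map (positions 1-based, strictly increasing
    within each chromosome; marker ids unique)."""

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        n = len(self.snp_id)
        for name in ("chrom", "pos_bp", "allele1", "allele2"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"marker map field {name!r} length mismatch")
        if len(set(self.snp_id)) != n:
            raise FormatError("marker ids are not unique")
        for c in self.chromosomes():
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    def __len__(self) -> int:
        return len(self.snp_id)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(self.snp_id[idx], self.chrom[idx], self.pos_bp[idx],
                         self.allele1[idx], self.allele2[idx])


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix, samples x markers, values {0,1,2} or -1."""

    samples: list
    map: MarkerMap
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.map)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.map)} markers"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("dosage values outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.map)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.samples, self.map.subset(idx),
                              self.dosage[:, idx])

    def subset_samples(self, keep: Sequence) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            rows = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.samples)}
            rows = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix([self.samples[i] for i in rows], self.map,
                              self.dosage[rows])


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes; two consecutive rows (2i, 2i+1) per sample."""

    sample_ids: list
    map: MarkerMap
    alleles: np.ndarray
    coding: str = "raw"  # "raw": 0=allele1 | "ancestral": 0=ancestral

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.coding not in ("raw", "ancestral"):
            raise ConfigError(f"unknown haplotype coding {self.coding!r}")
        if self.alleles.ndim != 2 or self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise FormatError("haplotype count must be 2 x n_samples")
        if self.alleles.shape[1] != len(self.map):
            raise FormatError("haplotype marker count inconsistent with map")
        if self.alleles.size and self.alleles.max() > 1:
            raise FormatError("haplotype alleles must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def haplotype_ids(self) -> list:
        return [(s, p) for s in self.sample_ids for p in (0, 1)]

    def subset_markers(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(self.sample_ids, self.map.subset(idx),
                              self.alleles[:, idx], self.coding)

    def subset_samples(self, keep: Sequence) -> "HaplotypePanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in keep:
            i = pos[s]
            rows += [2 * i, 2 * i + 1]
        return HaplotypePanel(list(keep), self.map, self.alleles[rows],
                              self.coding)


@dataclass
class CohortLabels:
    """Sample -> population assignment plus population-level group factors."""

    population: dict          # sample -> population
    weight_class: dict        # population -> heavy|light|none
    geography: dict           # population -> north|south|none

    def __post_init__(self) -> None:
        pops = set(self.population.values())
        for p in pops:
            if p not in self.weight_class or p not in self.geography:
                raise FormatError(f"population {p!r} missing from group table")
        for p, v in self.weight_class.items():
            if v not in WEIGHT_LEVELS:
                raise FormatError(f"invalid weight class {v!r} for {p!r}")
        for p, v in self.geography.items():
            if v not in GEO_LEVELS:
                raise FormatError(f"invalid geography {v!r} for {p!r}")

    def populations(self) -> list:
        seen: dict = {}
        for p in self.population.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_of(self, population) -> list:
        return [s for s, p in self.population.items() if p == population]

    def factor_of_sample(self, sample, factor: str):
        pop = self.population[sample]
        if factor == "weight":
            return self.weight_class[pop]
        if factor == "geography":
            return self.geography[pop]
        if factor == "local":
            return "local"
        raise ConfigError(f"unknown factor {factor!r}")


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read classic PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    Alleles per marker are assigned alphabetically (allele1 < allele2) from
    the observed symbols; ``0`` or ``N`` codes a missing allele.  Dosage
    counts copies of allele2.
    """
    chroms, ids, poss = [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{ln}: MAP line has "
                                  f"{len(parts)} fields, expected >=4")
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(int(parts[3]))
    m = len(ids)

    samples: list = []
    raw_geno: list = []  # per sample: 2m allele symbols
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields for "
                    f"{m} markers, got {len(parts)}"
                )
            samples.append(parts[1])
            raw_geno.append(parts[6:])

    allele1 = np.empty(m, dtype=object)
    allele2 = np.empty(m, dtype=object)
    dosage = np.full((len(samples), m), MISSING, dtype=np.int8)
    geno = np.array(raw_geno, dtype=object).reshape(len(samples), m, 2) \
        if samples else np.empty((0, m, 2), dtype=object)
    for j in range(m):
        col = geno[:, j, :]
        obs = sorted({a for a in col.ravel() if a not in ("0", "N")})
        if len(obs) > 2:
            raise FormatError(f"marker {ids[j]!r} has >2 alleles: {obs}")
        a1 = obs[0] if obs else "0"
        a2 = obs[1] if len(obs) > 1 else "."
        allele1[j], allele2[j] = a1, a2
        miss = (col == "0") | (col == "N")
        ok = ~miss.any(axis=1)
        dosage[ok, j] = (col[ok] == a2).sum(axis=1)

    mmap = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.array(poss, dtype=np.int64), allele1, allele2)
    return GenotypeMatrix(samples, mmap, dosage)


def write_ped_map(g: GenotypeMatrix, ped_path, map_path,
                  labels: CohortLabels | None = None) -> None:
    """Write a GenotypeMatrix as PLINK text PED/MAP (space-delimited)."""
    mmap = g.map
    with open(map_path, "w") as fh:
        for j in range(len(mmap)):
            fh.write(f"{mmap.chrom[j]} {mmap.snp_id[j]} 0 {mmap.pos_bp[j]}\n")
    a1, a2 = mmap.allele1, mmap.allele2
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples):
            fid = labels.population[s] if labels is not None else s
            fields = [str(fid), str(s), "0", "0", "0", "-9"]
            row = g.dosage[i]
            for j in range(len(mmap)):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, require_phased: bool = False):
    """Read a biallelic-SNP VCF.

    Returns ``(GenotypeMatrix, HaplotypePanel or None)``; the panel is built
    only when ``require_phased`` is set, in which case any unphased or
    missing genotype is an error.  Non-biallelic records are skipped with a
    logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    chroms, ids, poss, a1s, a2s = [], [], [], [], []
    dosage_cols, hap_cols = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        chroms.append(v.CHROM)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        poss.append(v.POS)
        a1s.append(v.REF)
        a2s.append(v.ALT[0])
        col = np.full(len(samples), MISSING, dtype=np.int8)
        hap = np.zeros((len(samples), 2), dtype=np.uint8)
        for i, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                if require_phased:
                    raise FormatError(
                        f"missing genotype at {v.CHROM}:{v.POS} for sample "
                        f"{samples[i]} with require_phased"
                    )
                continue
            col[i] = a + b
            if require_phased:
                if not phased:
                    raise FormatError(
                        f"unphased genotype at {v.CHROM}:{v.POS} for sample "
                        f"{samples[i]} with require_phased"
                    )
                hap[i] = (a, b)
        dosage_cols.append(col)
        if require_phased:
            hap_cols.append(hap)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records",
                    n_skipped)
    mmap = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.array(poss, dtype=np.int64),
                     np.array(a1s, dtype=object), np.array(a2s, dtype=object))
    dosage = (np.stack(dosage_cols, axis=1) if dosage_cols
              else np.empty((len(samples), 0), dtype=np.int8))
    g = GenotypeMatrix(samples, mmap, dosage)
    panel = None
    if require_phased:
        alle = (np.stack(hap_cols, axis=1) if hap_cols
                else np.empty((len(samples), 0, 2), dtype=np.uint8))
        # (samples, markers, 2) -> (2*samples, markers) with rows 2i, 2i+1
        alle = alle.transpose(0, 2, 1).reshape(2 * len(samples), -1)
        panel = HaplotypePanel(samples, mmap, alle, coding="raw")
    return g, panel


def write_vcf(out_path, g: GenotypeMatrix | None = None,
              panel: HaplotypePanel | None = None) -> None:
    """Write VCF 4.2; phased GT (``0|1``) from a panel, else unphased from
    dosages.  Exactly one of ``g``/``panel`` drives the genotype columns."""
    if (g is None) == (panel is None):
        raise ConfigError("write_vcf needs exactly one of g or panel")
    src = g if g is not None else panel
    mmap = src.map
    samples = src.samples if g is not None else panel.sample_ids
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in mmap.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in samples) + "\n")
        for j in range(len(mmap)):
            ref = mmap.allele1[j] if mmap.allele1[j] != "." else "A"
            alt = mmap.allele2[j] if mmap.allele2[j] != "." else "T"
            cols = [str(mmap.chrom[j]), str(mmap.pos_bp[j]),
                    str(mmap.snp_id[j]), str(ref), str(alt), ".", "PASS",
                    ".", "GT"]
            if panel is not None:
                for i in range(len(samples)):
                    a, b = panel.alleles[2 * i, j], panel.alleles[2 * i + 1, j]
                    cols.append(f"{a}|{b}")
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                for i in range(len(samples)):
                    cols.append(code[int(g.dosage[i, j])])
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Labels TSV
# ---------------------------------------------------------------------------

def read_labels(path) -> CohortLabels:
    """Read the `sample population weight_class geography` TSV."""
    population, weight, geo = {}, {}, {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if ln == 1 and parts[0] == "sample":
                continue
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 tab-separated "
                                  f"fields, got {len(parts)}")
            s, p, w, ggeo = parts
            population[s] = p
            weight[p] = w
            geo[p] = ggeo
    return CohortLabels(population, weight, geo)


def write_labels(labels: CohortLabels, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tweight_class\tgeography\n")
        for s, p in labels.population.items():
            fh.write(f"{s}\t{p}\t{labels.weight_class[p]}\t"
                     f"{labels.geography[p]}\n")


# ---------------------------------------------------------------------------
# Conversions / grouping
# ---------------------------------------------------------------------------

def genotypes_from_haplotypes(panel: HaplotypePanel) -> GenotypeMatrix:
    """Collapse a complete phased panel into diploid dosages
    (sample i = haplotype rows 2i and 2i+1)."""
    if panel.n_haplotypes % 2:
        raise FormatError("odd haplotype count")
    dosage = (panel.alleles[0::2].astype(np.int8)
              + panel.alleles[1::2].astype(np.int8))
    return GenotypeMatrix(panel.sample_ids, panel.map, dosage)


def split_by_group(data, labels: CohortLabels, factor: str) -> dict:
    """Split a GenotypeMatrix or HaplotypePanel by a group factor.

    ``weight`` -> {'heavy','light'}; ``geography`` -> {'north','south'};
    ``local`` -> one subset with every sample.  Samples whose population has
    factor level 'none' are excluded from the two-level factors.
    """
    if factor == "local":
        level_names = ["local"]
    elif factor == "weight":
        level_names = ["heavy", "light"]
    elif factor == "geography":
        level_names = ["north", "south"]
    else:
        raise ConfigError(f"unknown factor {factor!r}")

    sample_list = data.samples if isinstance(data, GenotypeMatrix) \
        else data.sample_ids
    out = {}
    for level in level_names:
        keep = [s for s in sample_list
                if labels.factor_of_sample(s, factor) == level]
        out[level] = data.subset_samples(keep)
    return out
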