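"""Runs of homozygosity: per-individual segments and group-level islands.

Segment detection follows the PLINK sliding-window protocol with seven
criteria: (i) 50-SNP scanning windows; (ii) a SNP is "in ROH" when at least
5% of the windows covering it are homozygous-acceptable; (iii) >= 100 SNPs
per segment; (iv) >= 1 Mb span; (v) no gap between consecutive SNPs above
1000 kb; (vi) density of at most 100 kb per SNP (span / n_snps); (vii) at
most one heterozygous and two missing genotypes per window and per final
segment.  All seven are configurable.

Islands: per SNP the locus homozygosity is the fraction of a group's
animals whose ROH cover it; SNPs at or above the 0.999 empirical quantile
(inverse-CDF) of that distribution, taken genome-wide within the group, are
merged into islands when adjacent on the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, ConfigError, GenotypeMatrix, MarkerMap

logger = logging.getLogger("sweepscan")


@dataclass
class ROHParams:
    window_snps: int = 50
    min_window_frac: float = 0.05
    min_snps: int = 100
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    max_bp_per_snp: int = 100_000
    max_het: int = 1
    max_missing: int = 2


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class ROHIsland:
    group: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_freq: float

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def _in_roh_mask(het: np.ndarray, miss: np.ndarray,
                 params: ROHParams) -> np.ndarray:
    """Criteria (i)+(ii): SNP is in-ROH when the fraction of acceptable
    windows covering it reaches ``min_window_frac``.  The denominator is the
    number of windows that can cover the SNP given chromosome ends."""
    mc = len(het)
    w = params.window_snps
    if mc < w:
        return np.zeros(mc, dtype=bool)
    csum_h = np.concatenate([[0], np.cumsum(het)])
    csum_m = np.concatenate([[0], np.cumsum(miss)])
    n_win = mc - w + 1
    het_ct = csum_h[w:] - csum_h[:-w]
    mis_ct = csum_m[w:] - csum_m[:-w]
    acceptable = (het_ct <= params.max_het) & (mis_ct <= params.max_missing)
    csum_a = np.concatenate([[0], np.cumsum(acceptable)])
    s = np.arange(mc)
    lo = np.maximum(0, s - w + 1)
    hi = np.minimum(s, n_win - 1)
    covering = hi - lo + 1
    acc = csum_a[hi + 1] - csum_a[lo]
    return acc / covering >= params.min_window_frac


def _maximal_qualifying(run_idx: np.ndarray, pos: np.ndarray,
                        het: np.ndarray, miss: np.ndarray,
                        params: ROHParams) -> list:
    """Maximal sub-runs of one in-ROH run satisfying the final-segment
    criteria (run is already gap-split).  Returns (i, j) local index pairs."""
    L = len(run_idx)
    h = het[run_idx].astype(int)
    m = miss[run_idx].astype(int)
    ch = np.concatenate([[0], np.cumsum(h)])
    cm = np.concatenate([[0], np.cumsum(m)])
    p = pos[run_idx]

    def feasible(i, j):  # het/missing caps on [i, j]
        return (ch[j + 1] - ch[i] <= params.max_het
                and cm[j + 1] - cm[i] <= params.max_missing)

    def qualifies(i, j):
        n = j - i + 1
        span = p[j] - p[i]
        return (n >= params.min_snps and span >= params.min_length_bp
                and span / n <= params.max_bp_per_snp and feasible(i, j))

    # largest feasible end per start (two-pointer), then largest qualifying
    out = []
    best_j = -1
    jmax = 0
    for i in range(L):
        if jmax < i:
            jmax = i
        while jmax + 1 < L and feasible(i, jmax + 1):
            jmax += 1
        jq = None
        for j in range(jmax, i + params.min_snps - 2, -1):
            if qualifies(i, j):
                jq = j
                break
        if jq is not None and jq > best_j:
            out.append((i, jq))
            best_j = jq
    return out


def detect_roh_individual(g: GenotypeMatrix, sample,
                          params: ROHParams | None = None) -> list:
    """ROH segments for one sample under the seven criteria.

    Segment coordinates are the positions of the first and last member SNP.
    Maximal qualifying segments are reported; chromosomes shorter than one
    scanning window yield none.
    """
    params = params or ROHParams()
    row = g.samples.index(sample)
    segments = []
    for c in g.map.chromosomes():
        idx = g.map.chrom_indices(c)
        d = g.dosage[row, idx]
        pos = g.map.pos_bp[idx]
        het = d == 1
        miss = d == MISSING
        in_roh = _in_roh_mask(het, miss, params)
        if not in_roh.any():
            continue
        # maximal runs of in-ROH SNPs, split at over-long gaps
        boundaries = np.flatnonzero(np.diff(in_roh.astype(int)))
        starts = ([0] if in_roh[0] else []) + \
            [b + 1 for b in boundaries if in_roh[b + 1]]
        ends = [b for b in boundaries if in_roh[b]] + \
            ([len(in_roh) - 1] if in_roh[-1] else [])
        for s0, e0 in zip(starts, ends):
            run = np.arange(s0, e0 + 1)
            gaps = np.diff(pos[run])
            cuts = np.flatnonzero(gaps > params.max_gap_bp)
            pieces = np.split(run, cuts + 1)
            for piece in pieces:
                if len(piece) < params.min_snps:
                    continue
                for i, j in _maximal_qualifying(piece, pos, het, miss,
                                                params):
                    a, b = piece[i], piece[j]
                    segments.append(ROHSegment(
                        sample=sample, chrom=c,
                        start_bp=int(pos[a]), end_bp=int(pos[b]),
                        n_snps=int(b - a + 1),
                        n_het=int(het[a:b + 1].sum()),
                        n_missing=int(miss[a:b + 1].sum())))
    return segments


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> dict:
    """ROH segments for every sample: sample -> list of segments."""
    return {s: detect_roh_individual(g, s, params) for s in g.samples}


def locus_homozygosity(segments_by_sample: dict, mmap: MarkerMap,
                       group_samples: list) -> np.ndarray:
    """Per-SNP fraction of the group's animals whose ROH cover the SNP."""
    if len(group_samples) == 0:
        raise ConfigError("empty group")
    count = np.zeros(len(mmap), dtype=np.int64)
    for s in group_samples:
        covered = np.zeros(len(mmap), dtype=bool)  # animal counted once/SNP
        for seg in segments_by_sample.get(s, []):
            on_c = mmap.chrom_indices(seg.chrom)
            pos = mmap.pos_bp[on_c]
            lo = np.searchsorted(pos, seg.start_bp, side="left")
            hi = np.searchsorted(pos, seg.end_bp, side="right")
            covered[on_c[lo:hi]] = True
        count += covered
    return count / len(group_samples)


def roh_islands(segments_by_sample: dict, mmap: MarkerMap,
                group_samples: list, quantile: float = 0.999,
                group: str = "") -> list:
    """Group-level ROH islands by the locus-homozygosity percentile rule.

    The threshold is the genome-wide empirical ``quantile`` (inverse-CDF
    type) of the per-SNP locus homozygosity within the group; SNPs at or
    above it merge into islands when consecutive on the map.
    """
    freq = locus_homozygosity(segments_by_sample, mmap, group_samples)
    # empirical order-statistic threshold; "higher" keeps the selected set
    # at the upper (1 - quantile) tail even when n * quantile is integral
    thr = float(np.quantile(freq, quantile, method="higher"))
    qual = freq >= thr
    if qual.all():
        logger.info("roh_islands(%s): degenerate threshold %.4f selects "
                    "every SNP", group, thr)
    islands = []
    for c in mmap.chromosomes():
        idx = mmap.chrom_indices(c)
        q = qual[idx]
        if not q.any():
            continue
        boundaries = np.flatnonzero(np.diff(q.astype(int)))
        starts = ([0] if q[0] else []) + \
            [b + 1 for b in boundaries if q[b + 1]]
        ends = [b for b in boundaries if q[b]] + \
            ([len(q) - 1] if q[-1] else [])
        for s0, e0 in zip(starts, ends):
            sub = idx[s0:e0 + 1]
            islands.append(ROHIsland(
                group=group, chrom=c,
                start_bp=int(mmap.pos_bp[sub[0]]),
                end_bp=int(mmap.pos_bp[sub[-1]]),
                n_snps=len(sub),
                peak_freq=float(freq[sub].max())))
    return islands


def segments_to_frame(segments_by_sample: dict) -> pd.DataFrame:
    rows = [{"sample": seg.sample, "chrom": seg.chrom,
             "start_bp": seg.start_bp, "end_bp": seg.end_bp,
             "n_snps": seg.n_snps, "length_kb": seg.length_bp / 1000.0,
             "n_het": seg.n_het, "n_missing": seg.n_missing}
            for segs in segments_by_sample.values() for seg in segs]
    return pd.DataFrame(rows, columns=["sample", "chrom", "start_bp",
                                       "end_bp", "n_snps", "length_kb",
                                       "n_het", "n_missing"])


def islands_to_frame(islands: list) -> pd.DataFrame:
    rows = [{"group": isl.group, "chrom": isl.chrom,
             "start_bp": isl.start_bp, "end_bp": isl.end_bp,
             "length_kb": isl.length_kb, "n_snps": isl.n_snps,
             "peak_freq": isl.peak_freq} for isl in islands]
    return pd.DataFrame(rows, columns=["group", "chrom", "start_bp",
                                       "end_bp", "length_kb", "n_snps",
                                       "peak_freq"])
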