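"""Sliding-window candidate-region calling on per-SNP significance scores.

Per-SNP ``p_score`` values from a scan are aggregated into 250-kb sliding
windows that share 10 kb with their neighbour (step 240 kb); a window is
flagged as putatively under selection when it holds at least ``min_hits``
(default 3) SNPs at ``p_score >= p_threshold`` (default 4).  Overlapping or
book-ended flagged windows merge into candidate regions whose length is
reported in kb as ``(end - start) / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import ConfigError, MarkerMap
from .haplostats import STATUS_OK


@dataclass
class Window:
    chrom: str
    start_bp: int
    end_bp: int          # inclusive
    n_snps_total: int = 0
    n_snps_significant: int = 0
    flagged: bool = False


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    tests: list = field(default_factory=list)
    group: str = ""
    n_hits: int = 0

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def make_windows(mmap: MarkerMap, window_bp: int = 250_000,
                 overlap_bp: int = 10_000) -> list:
    """Tile each chromosome with sliding windows.

    Windows start at 0 and advance by ``window_bp - overlap_bp`` so that
    consecutive windows share ``overlap_bp``; the last window is truncated
    at the final marker position.  Boundaries are inclusive on both ends (a
    SNP exactly on a shared boundary counts in both windows).  Windows with
    no markers are retained with ``n_snps_total = 0``.
    """
    if not window_bp > overlap_bp >= 0:
        raise ConfigError("need window_bp > overlap_bp >= 0")
    step = window_bp - overlap_bp
    windows = []
    for c in mmap.chromosomes():
        pos = mmap.pos_bp[mmap.chrom_indices(c)]
        last = int(pos[-1])
        start = 0
        while start <= last:
            end = min(start + window_bp, last)
            n = int(np.count_nonzero((pos >= start) & (pos <= end)))
            windows.append(Window(c, start, end, n_snps_total=n))
            start += step
    return windows


def classify_windows(scan: pd.DataFrame, windows: list,
                     p_threshold: float = 4.0, min_hits: int = 3,
                     strict: bool = False) -> list:
    """Flag windows holding at least ``min_hits`` significant SNPs.

    A SNP is significant when its scan status is ``ok`` and its ``p_score``
    reaches ``p_threshold`` (``>=`` by default; ``strict`` uses ``>``).
    Returns new Window objects with hit counts and flags filled in.
    """
    usable = scan[(scan["status"] == STATUS_OK)
                  & np.isfinite(scan["p_score"])]
    sig = usable[usable["p_score"] > p_threshold] if strict else \
        usable[usable["p_score"] >= p_threshold]
    out = []
    for w in windows:
        on_c = sig[sig["chrom"] == w.chrom]
        hits = int(((on_c["pos_bp"] >= w.start_bp)
                    & (on_c["pos_bp"] <= w.end_bp)).sum())
        out.append(Window(w.chrom, w.start_bp, w.end_bp, w.n_snps_total,
                          hits, flagged=hits >= min_hits))
    return out


def merge_to_regions(windows: list, tests=("",), group: str = "") -> list:
    """Merge flagged windows into candidate regions.

    Overlapping or book-ended flagged windows on one chromosome become one
    region spanning min(start)..max(end); the region's hit count is the
    maximum over its member windows.
    """
    flagged = sorted((w for w in windows if w.flagged),
                     key=lambda w: (str(w.chrom), w.start_bp))
    regions: list = []
    for w in flagged:
        if regions and regions[-1].chrom == w.chrom \
                and w.start_bp <= regions[-1].end_bp + 1:
            regions[-1].end_bp = max(regions[-1].end_bp, w.end_bp)
            regions[-1].n_hits = max(regions[-1].n_hits,
                                     w.n_snps_significant)
        else:
            regions.append(CandidateRegion(w.chrom, w.start_bp, w.end_bp,
                                           list(tests), group,
                                           w.n_snps_significant))
    return regions


def intersect_regions(regions_a: list, regions_b: list,
                      annotate_with: list | None = None) -> list:
    """Positive-length pairwise intersections of two region sets.

    The result records the union of source tests; if ``annotate_with`` is
    given (e.g. within-group iHS regions), intersections overlapping any of
    those regions get ``"ihs_overlap"`` appended to their test list.
    """
    out = []
    for ra in regions_a:
        for rb in regions_b:
            if ra.chrom != rb.chrom:
                continue
            start = max(ra.start_bp, rb.start_bp)
            end = min(ra.end_bp, rb.end_bp)
            if start >= end:
                continue
            tests = list(dict.fromkeys(list(ra.tests) + list(rb.tests)))
            group = ra.group or rb.group
            reg = CandidateRegion(ra.chrom, start, end, tests, group,
                                  max(ra.n_hits, rb.n_hits))
            if annotate_with is not None:
                for rc in annotate_with:
                    if rc.chrom == reg.chrom \
                            and max(rc.start_bp, reg.start_bp) <= \
                            min(rc.end_bp, reg.end_bp):
                        reg.tests.append("ihs_overlap")
                        break
            out.append(reg)
    return out


def regions_to_frame(regions: list) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": r.group, "chrom": r.chrom, "start_bp": r.start_bp,
          "end_bp": r.end_bp, "length_kb": r.length_kb,
          "tests": "+".join(t for t in r.tests if t), "n_hits": r.n_hits}
         for r in regions],
        columns=["group", "chrom", "start_bp", "end_bp", "length_kb",
                 "tests", "n_hits"])
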