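"""Independent brute-force oracles used by the test suite.

Everything here recomputes a quantity from first principles (explicit pair
comparison, exhaustive enumeration, direct tallies) without touching the
package's optimized code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# --- EHH / EHHS by explicit pairwise comparison ---------------------------

def ehh_pairwise(alleles: np.ndarray, focal: int, core: int,
                 t: int) -> float:
    """EHH of ``core`` carriers at marker ``t``: fraction of carrier pairs
    identical over focal..t inclusive."""
    carriers = [h for h in range(alleles.shape[0])
                if alleles[h, focal] == core]
    lo, hi = min(focal, t), max(focal, t)
    pairs = list(combinations(carriers, 2))
    if not pairs:
        raise ValueError("fewer than 2 carriers")
    same = sum(1 for i, j in pairs
               if np.array_equal(alleles[i, lo:hi + 1],
                                 alleles[j, lo:hi + 1]))
    return same / len(pairs)


def ehhs_pairwise(alleles: np.ndarray, focal: int, t: int,
                  normalized: bool) -> float:
    """Pooled pair-identity fraction over focal..t, all haplotypes."""
    n = alleles.shape[0]
    lo, hi = min(focal, t), max(focal, t)
    pairs = list(combinations(range(n), 2))
    same = sum(1 for i, j in pairs
               if np.array_equal(alleles[i, lo:hi + 1],
                                 alleles[j, lo:hi + 1]))
    hh = same / len(pairs)
    if not normalized:
        return hh
    same0 = sum(1 for i, j in pairs if alleles[i, focal] == alleles[j, focal])
    return hh / (same0 / len(pairs))


# --- LD pruning -----------------------------------------------------------

def r2_complete(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok].astype(float), y[ok].astype(float)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_prune_oracle(dosage: np.ndarray, window: int, step: int,
                    r2max: float) -> np.ndarray:
    """Window/step pruning (remove the later marker of an offending pair),
    repeated over all window placements until globally stable."""
    m = dosage.shape[1]
    keep = np.ones(m, dtype=bool)
    stable = False
    while not stable:
        stable = True
        start = 0
        while True:
            idx = [j for j in range(start, min(start + window, m))
                   if keep[j]]
            for a, b in combinations(idx, 2):
                if keep[a] and keep[b] and \
                        r2_complete(dosage[:, a], dosage[:, b]) > r2max:
                    keep[b] = False
                    stable = False
            if start + window >= m:
                break
            start += step
    return keep


# --- window classification ------------------------------------------------

def classify_oracle(chroms, positions, p_scores, statuses, windows,
                    p_threshold, min_hits):
    """Per-window recount of significant SNPs by direct looping."""
    flags = []
    for w in windows:
        hits = 0
        for c, pos, p, st in zip(chroms, positions, p_scores, statuses):
            if c == w.chrom and st == "ok" and np.isfinite(p) \
                    and p >= p_threshold \
                    and w.start_bp <= pos <= w.end_bp:
                hits += 1
        flags.append(hits >= min_hits)
    return flags


# --- ROH ------------------------------------------------------------------

def roh_oracle_one_chrom(dosage_row: np.ndarray, pos: np.ndarray,
                         params) -> list:
    """Exhaustive ROH enumeration for one sample on one chromosome.

    Recomputes in-ROH status by direct window loops, then enumerates every
    (i, j) sub-run against all seven criteria and keeps the maximal ones.
    Returns (start_index, end_index) pairs.
    """
    mc = len(pos)
    het = dosage_row == 1
    miss = dosage_row < 0
    w = params.window_snps
    n_win = mc - w + 1
    if n_win < 1:
        return []
    acceptable = []
    for s in range(n_win):
        acceptable.append(het[s:s + w].sum() <= params.max_het
                          and miss[s:s + w].sum() <= params.max_missing)
    in_roh = []
    for j in range(mc):
        covering = [s for s in range(n_win) if s <= j <= s + w - 1]
        acc = sum(1 for s in covering if acceptable[s])
        in_roh.append(acc / len(covering) >= params.min_window_frac)

    qualifying = []
    for i in range(mc):
        for j in range(i + params.min_snps - 1, mc):
            if not all(in_roh[i:j + 1]):
                continue
            if any(pos[k + 1] - pos[k] > params.max_gap_bp
                   for k in range(i, j)):
                continue
            n = j - i + 1
            span = pos[j] - pos[i]
            if span < params.min_length_bp:
                continue
            if span / n > params.max_bp_per_snp:
                continue
            if het[i:j + 1].sum() > params.max_het:
                continue
            if miss[i:j + 1].sum() > params.max_missing:
                continue
            qualifying.append((i, j))
    maximal = [seg for seg in qualifying
               if not any(o != seg and o[0] <= seg[0] and o[1] >= seg[1]
                          for o in qualifying)]
    return sorted(set(maximal))


# --- intervals ------------------------------------------------------------

def intersect_oracle(set_a, set_b):
    """All-pairs positive-length interval intersections
    ((chrom, start, end) triples)."""
    out = []
    for ca, sa, ea in set_a:
        for cb, sb, eb in set_b:
            if ca == cb and max(sa, sb) < min(ea, eb):
                out.append((ca, max(sa, sb), min(ea, eb)))
    return sorted(out)


def overlap_oracle(regions, genes):
    """gene-in-region assignment by direct all-pairs overlap check
    (1-based inclusive)."""
    out = []
    for rc, rs, re_ in regions:
        hits = [name for name, gc, gs, ge in genes
                if gc == rc and max(gs, rs) <= min(ge, re_)]
        out.append(hits)
    return out


# --- AMOVA ----------------------------------------------------------------

def single_factor_r2_oracle(D: np.ndarray, groups: np.ndarray) -> float:
    """Classic between-group fraction from within/between pair sums:
    R2 = 1 - SS_W / SS_T with SS_T = sum_{i<j} d^2 / n and
    SS_W = sum_g sum_{i<j in g} d^2 / n_g."""
    n = len(groups)
    ss_t = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in set(groups):
        members = [i for i in range(n) if groups[i] == g]
        ss_w += sum(D[i, j] ** 2 for i in members for j in members
                    if i < j) / len(members)
    return (ss_t - ss_w) / ss_t


def hamming_oracle(a: np.ndarray, b: np.ndarray) -> tuple:
    """(raw allele-count distance, comparable count) by direct looping."""
    raw, comp = 0, 0
    for x, y in zip(a, b):
        if x >= 0 and y >= 0:
            raw += abs(int(x) - int(y))
            comp += 1
    return raw, comp
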