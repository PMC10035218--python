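"""Extended haplotype homozygosity statistics: EHH/EHHS, iHS, Rsb, XP-EHH.

Definitions (all on phased binary haplotypes with a physical map):

EHH(core allele a at focal s, marker t)
    Probability that two random haplotypes carrying ``a`` at ``s`` are
    identical over every marker from ``s`` to ``t`` inclusive:
    ``sum_k C(n_k,2) / C(n_a,2)`` over identity classes of the carriers.
EHHS(s, t)
    Same pooled over *all* haplotypes regardless of core allele;
    "normalized" divides by the focal-site homozygosity so EHHS(s,s) = 1,
    "unnormalized" keeps the raw pair fraction.
iHH / iES
    Trapezoidal integral of the EHH / EHHS curve over physical distance,
    each side truncated at the first marker whose value falls below a decay
    cutoff (default 0.05).  A side whose curve never decays before the
    chromosome end is an edge case: by default the site's statistic is
    suppressed ("discard"), optionally integrated to the last marker
    ("truncate").
iHS
    ``ln(iHH_ancestral / iHH_derived)`` standardized to zero mean / unit sd
    within equal-width derived-allele-frequency bins.
Rsb / XP-EHH
    ``ln(iES_group1 / iES_group2)`` per site, standardized genome-wide
    (Rsb: median-centered on normalized iES; XP-EHH: mean-centered on
    unnormalized iES).

Every standardized score z is mapped to a two-sided significance scale
``p_score = -log10(1 - 2|Phi(z) - 0.5|)`` where Phi is the standard normal
CDF, i.e. ``-log10`` of the two-sided Gaussian p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotype_io import ConfigError, HaplotypePanel

STATUS_OK = "ok"
STATUS_UNDEFINED = "undefined"
STATUS_EDGE = "edge_truncated"
STATUS_UNSTD = "unstandardizable"

SCAN_COLUMNS = ["test", "group", "chrom", "pos_bp", "snp_id", "derived_freq",
                "raw", "z", "p_score", "status"]


# ---------------------------------------------------------------------------
# Ancestral-allele inference
# ---------------------------------------------------------------------------

def infer_ancestral(panel: HaplotypePanel):
    """Polarize a raw-coded panel using the majority allele as ancestral.

    The ancestral state of each marker is the more common allele over all
    haplotypes of the full cohort; haplotypes are recoded so 0 = ancestral,
    1 = derived.  Returns ``(recoded_panel, ambiguous)`` where ``ambiguous``
    flags exact 50:50 ties — those markers keep their raw coding and must be
    excluded from iHS (they remain usable for EHHS-based tests).
    """
    if panel.coding != "raw":
        raise ConfigError("infer_ancestral expects a raw-coded panel")
    ones = panel.alleles.sum(axis=0)
    n = panel.n_haplotypes
    flip = ones * 2 > n          # allele 1 is the majority -> it is ancestral
    ambiguous = ones * 2 == n
    alleles = panel.alleles.copy()
    alleles[:, flip] ^= 1
    return (HaplotypePanel(panel.sample_ids, panel.map, alleles,
                           coding="ancestral"), ambiguous)


# ---------------------------------------------------------------------------
# EHH / EHHS curves
# ---------------------------------------------------------------------------

@dataclass
class SiteCurve:
    """Homozygosity decay curve around one focal marker.

    ``positions_left``/``values_left`` run from the focal marker outward to
    lower positions (focal first); the right side likewise to higher
    positions.  ``*_complete`` records whether the walk ended because the
    curve dropped below its stop value (True) or because it hit the
    chromosome end first (False)."""

    focal_pos: int
    positions_left: np.ndarray
    values_left: np.ndarray
    positions_right: np.ndarray
    values_right: np.ndarray
    left_complete: bool
    right_complete: bool


def _pair_fraction_walk(A: np.ndarray, cols, stop: float):
    """Pooled pair-identity fraction along ``cols`` (focal first).

    At each marker t the haplotypes are partitioned into identity classes of
    the sub-haplotypes spanning focal..t; the value is
    ``sum_k n_k (n_k - 1) / (n (n - 1))``.  The walk stops after the first
    value below ``stop`` (that value is kept) or at zero, and reports
    whether it completed before running out of markers.
    """
    n = A.shape[0]
    denom = n * (n - 1)
    labels = np.zeros(n, dtype=np.int64)
    vals = []
    complete = len(cols) == 1  # bare focal side: nothing to decay through
    for t in cols:
        key = labels * 2 + A[:, t]
        _, labels, counts = np.unique(key, return_inverse=True,
                                      return_counts=True)
        hh = float((counts * (counts - 1)).sum()) / denom
        vals.append(hh)
        if hh < stop or hh == 0.0:
            complete = True
            break
    return np.array(vals), complete


def _site_curve(A: np.ndarray, pos: np.ndarray, focal_local: int,
                stop: float, scale: float = 1.0) -> SiteCurve:
    """Walk both directions from ``focal_local`` within one chromosome block;
    values are divided by ``scale`` (for the normalized EHHS estimator)."""
    mc = A.shape[1]
    right_cols = range(focal_local, mc)
    left_cols = range(focal_local, -1, -1)
    vr, cr = _pair_fraction_walk(A, right_cols, stop * scale)
    vl, cl = _pair_fraction_walk(A, left_cols, stop * scale)
    pr = pos[focal_local:focal_local + len(vr)]
    pl = pos[focal_local - len(vl) + 1:focal_local + 1][::-1]
    return SiteCurve(int(pos[focal_local]), pl, vl / scale, pr, vr / scale,
                     cl, cr)


def ehh_at_site(panel: HaplotypePanel, focal_index: int, core_allele: int,
                stop_value: float = 0.0) -> SiteCurve:
    """EHH curve for the carriers of ``core_allele`` at marker
    ``focal_index``, both directions within the focal chromosome.

    Raises if fewer than two haplotypes carry the core allele.  With the
    default ``stop_value`` the walk continues until the curve reaches zero
    or the chromosome end; scans pass their decay cutoff instead.
    """
    mmap = panel.map
    chrom = mmap.chrom[focal_index]
    cols = mmap.chrom_indices(chrom)
    local = int(np.searchsorted(cols, focal_index))
    carriers = panel.alleles[:, focal_index] == core_allele
    if carriers.sum() < 2:
        raise ValueError(
            f"EHH undefined: {int(carriers.sum())} carriers of allele "
            f"{core_allele} at marker {mmap.snp_id[focal_index]!r}")
    A = panel.alleles[np.ix_(carriers, cols)]
    return _site_curve(A, mmap.pos_bp[cols], local, stop_value)


def ehhs_at_site(panel: HaplotypePanel, focal_index: int,
                 estimator: str = "normalized",
                 stop_value: float = 0.0) -> SiteCurve:
    """Site-specific EHH over all haplotypes.

    ``normalized`` divides the pooled pair fraction by the focal-site
    homozygosity (curve starts at 1); ``unnormalized`` keeps the raw pair
    fraction (curve starts at the site homozygosity).  Raises if the panel
    has fewer than two haplotypes or, for the normalized estimator, if the
    focal-site homozygosity is zero.
    """
    if estimator not in ("normalized", "unnormalized"):
        raise ConfigError(f"unknown EHHS estimator {estimator!r}")
    if panel.n_haplotypes < 2:
        raise ValueError("EHHS needs at least 2 haplotypes")
    mmap = panel.map
    chrom = mmap.chrom[focal_index]
    cols = mmap.chrom_indices(chrom)
    local = int(np.searchsorted(cols, focal_index))
    A = panel.alleles[:, cols]
    scale = 1.0
    if estimator == "normalized":
        n = panel.n_haplotypes
        ones = int(A[:, local].sum())
        hh0 = (ones * (ones - 1) + (n - ones) * (n - ones - 1)) / (n * (n - 1))
        if hh0 == 0.0:
            raise ValueError("normalized EHHS undefined: focal-site "
                             "homozygosity is zero")
        scale = hh0
    return _site_curve(A, mmap.pos_bp[cols], local, stop_value, scale)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _integrate_side(pos: np.ndarray, vals: np.ndarray, complete: bool,
                    cutoff: float, edge_rule: str):
    if len(pos) > 1:
        d = np.diff(pos.astype(float))
        if np.any(d == 0) or not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("curve positions are not sorted")
    if len(pos) <= 1:
        return 0.0, STATUS_OK
    below = np.flatnonzero(vals < cutoff)
    if len(below):
        k = below[0]
    elif complete and vals[-1] == 0.0:
        k = len(vals) - 1
    else:
        if edge_rule == "discard":
            return np.nan, STATUS_EDGE
        k = len(vals) - 1
        area = float(np.trapezoid(vals[:k + 1],
                                  np.abs(pos[:k + 1] - pos[0]).astype(float)))
        return area, STATUS_EDGE
    area = float(np.trapezoid(vals[:k + 1],
                              np.abs(pos[:k + 1] - pos[0]).astype(float)))
    return area, STATUS_OK


def integrate_curve(curve: SiteCurve, cutoff: float = 0.05,
                    edge_rule: str = "discard"):
    """Integrate a decay curve over physical distance (bp).

    Each side is integrated by the trapezoid rule from the focal marker up
    to and including the first marker whose value falls below ``cutoff``.
    If a side never decays before the chromosome end, ``edge_rule`` decides:
    ``discard`` suppresses the statistic (NaN, status ``edge_truncated``);
    ``truncate`` integrates to the last marker and notes the status.
    Returns ``(integral_bp, status)``.
    """
    if edge_rule not in ("discard", "truncate"):
        raise ConfigError(f"unknown edge_rule {edge_rule!r}")
    left, st_l = _integrate_side(curve.positions_left, curve.values_left,
                                 curve.left_complete, cutoff, edge_rule)
    right, st_r = _integrate_side(curve.positions_right, curve.values_right,
                                  curve.right_complete, cutoff, edge_rule)
    status = STATUS_OK if (st_l == STATUS_OK and st_r == STATUS_OK) \
        else STATUS_EDGE
    if edge_rule == "discard" and status == STATUS_EDGE:
        return np.nan, status
    return left + right, status


# ---------------------------------------------------------------------------
# p-value transform and standardization
# ---------------------------------------------------------------------------

def p_score_from_z(z) -> np.ndarray:
    """Two-sided Gaussian significance scale
    ``-log10(1 - 2|Phi(z) - 0.5|) = -log10(2 (1 - Phi(|z|)))``."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = -np.log10(2.0 * norm.sf(np.abs(z)))
    return np.where(np.isfinite(z), p, np.nan)


def _standardize_bins(raw: np.ndarray, bin_idx: np.ndarray, n_bins: int):
    """Zero-mean / unit-sd (population convention) within bins.

    Returns ``(z, unstandardizable_mask)``; members of bins with fewer than
    two finite values, or zero spread, cannot be standardized.
    """
    z = np.full(len(raw), np.nan)
    unstd = np.zeros(len(raw), dtype=bool)
    finite = np.isfinite(raw)
    for b in range(n_bins):
        members = finite & (bin_idx == b)
        k = int(members.sum())
        if k == 0:
            continue
        if k < 2:
            unstd[members] = True
            continue
        mu = raw[members].mean()
        sd = raw[members].std()  # ddof=0
        if sd == 0:
            unstd[members] = True
            continue
        z[members] = (raw[members] - mu) / sd
    return z, unstd


def _finalize_table(test, group, mmap, keep_idx, derived_freq, raw, z,
                    status) -> pd.DataFrame:
    df = pd.DataFrame({
        "test": test,
        "group": group,
        "chrom": mmap.chrom[keep_idx],
        "pos_bp": mmap.pos_bp[keep_idx],
        "snp_id": mmap.snp_id[keep_idx],
        "derived_freq": derived_freq,
        "raw": raw,
        "z": z,
        "p_score": p_score_from_z(z),
        "status": status,
    })
    # edge_truncated keeps its (noted) statistic under edge_rule="truncate";
    # undefined/unstandardizable sites carry no numbers
    dead = df["status"].isin([STATUS_UNDEFINED, STATUS_UNSTD])
    df.loc[dead, ["z", "p_score"]] = np.nan
    return df


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def ihs_scan(panel: HaplotypePanel, cutoff: float = 0.05,
             maf_min: float = 0.05, n_bins: int = 20,
             edge_rule: str = "discard", group: str = "",
             ambiguous: np.ndarray | None = None) -> pd.DataFrame:
    """Within-group iHS scan on an ancestral-coded panel.

    Per marker: integrate the EHH curves of the ancestral and derived
    alleles, take ``raw = ln(iHH_A / iHH_D)``, then standardize within
    ``n_bins`` equal-width derived-allele-frequency bins over (0, 1).
    Markers flagged ``ambiguous`` (ancestral tie) and markers below
    ``maf_min`` in this panel are reported with status ``undefined``.
    """
    if panel.coding != "ancestral":
        raise ConfigError("ihs_scan needs an ancestral-coded panel "
                          "(run infer_ancestral first)")
    m = len(panel.map)
    p_der = panel.alleles.mean(axis=0)
    raw = np.full(m, np.nan)
    status = np.array([STATUS_OK] * m, dtype=object)
    for j in range(m):
        if ambiguous is not None and ambiguous[j]:
            status[j] = STATUS_UNDEFINED
            continue
        if min(p_der[j], 1 - p_der[j]) < maf_min:
            status[j] = STATUS_UNDEFINED
            continue
        try:
            c_anc = ehh_at_site(panel, j, 0, stop_value=cutoff)
            c_der = ehh_at_site(panel, j, 1, stop_value=cutoff)
        except ValueError:
            status[j] = STATUS_UNDEFINED
            continue
        ihh_a, st_a = integrate_curve(c_anc, cutoff, edge_rule)
        ihh_d, st_d = integrate_curve(c_der, cutoff, edge_rule)
        if st_a == STATUS_EDGE or st_d == STATUS_EDGE:
            status[j] = STATUS_EDGE
            if edge_rule == "discard":
                continue
        if not np.isfinite(ihh_a) or not np.isfinite(ihh_d) \
                or ihh_a <= 0 or ihh_d <= 0:
            status[j] = STATUS_UNDEFINED
            continue
        raw[j] = np.log(ihh_a / ihh_d)

    bin_idx = np.minimum((p_der * n_bins).astype(int), n_bins - 1)
    z, unstd = _standardize_bins(raw, bin_idx, n_bins)
    status[unstd & (status == STATUS_OK)] = STATUS_UNSTD
    return _finalize_table("ihs", group, panel.map, np.arange(m), p_der,
                           raw, z, status)


def _ies_scan(panel: HaplotypePanel, estimator: str, cutoff: float,
              edge_rule: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker integrated EHHS (iES) and per-marker status."""
    m = len(panel.map)
    ies = np.full(m, np.nan)
    status = np.array([STATUS_OK] * m, dtype=object)
    for j in range(m):
        try:
            curve = ehhs_at_site(panel, j, estimator, stop_value=cutoff)
        except ValueError:
            status[j] = STATUS_UNDEFINED
            continue
        val, st = integrate_curve(curve, cutoff, edge_rule)
        if st == STATUS_EDGE:
            status[j] = STATUS_EDGE
            if edge_rule == "discard":
                continue
        if not np.isfinite(val) or val <= 0:
            status[j] = STATUS_UNDEFINED
            continue
        ies[j] = val
    return ies, status


def _between_group_scan(test: str, estimator: str, centering: str,
                        panel1: HaplotypePanel, panel2: HaplotypePanel,
                        cutoff: float, maf_min: float, edge_rule: str,
                        group: str) -> pd.DataFrame:
    if len(panel1.map) != len(panel2.map) or \
            np.any(panel1.map.pos_bp != panel2.map.pos_bp) or \
            np.any(panel1.map.chrom != panel2.map.chrom):
        raise ConfigError(f"{test}: the two panels must share a marker map")
    m = len(panel1.map)
    n1, n2 = panel1.n_haplotypes, panel2.n_haplotypes
    pooled = (panel1.alleles.sum(axis=0) + panel2.alleles.sum(axis=0)) \
        / (n1 + n2)
    maf = np.minimum(pooled, 1 - pooled)

    ies1, st1 = _ies_scan(panel1, estimator, cutoff, edge_rule)
    ies2, st2 = _ies_scan(panel2, estimator, cutoff, edge_rule)

    raw = np.full(m, np.nan)
    status = np.array([STATUS_OK] * m, dtype=object)
    for j in range(m):
        if maf[j] < maf_min:
            status[j] = STATUS_UNDEFINED
            continue
        if st1[j] == STATUS_EDGE or st2[j] == STATUS_EDGE:
            status[j] = STATUS_EDGE
            if edge_rule == "discard":
                continue
        elif STATUS_UNDEFINED in (st1[j], st2[j]):
            status[j] = STATUS_UNDEFINED
            continue
        if not np.isfinite(ies1[j]) or not np.isfinite(ies2[j]):
            status[j] = STATUS_UNDEFINED
            continue
        raw[j] = np.log(ies1[j] / ies2[j])

    finite = np.isfinite(raw)
    z = np.full(m, np.nan)
    if finite.sum() >= 2:
        center = np.median(raw[finite]) if centering == "median" \
            else raw[finite].mean()
        sd = raw[finite].std()  # ddof=0
        if sd > 0:
            z[finite] = (raw[finite] - center) / sd
        else:
            status[finite] = STATUS_UNSTD
    else:
        status[finite] = STATUS_UNSTD
    return _finalize_table(test, group, panel1.map, np.arange(m), pooled,
                           raw, z, status)


def rsb_scan(panel_group1: HaplotypePanel, panel_group2: HaplotypePanel,
             cutoff: float = 0.05, centering: str = "median",
             maf_min: float = 0.05, edge_rule: str = "discard",
             group: str = "") -> pd.DataFrame:
    """Rsb scan: ``ln(iES_1 / iES_2)`` with the normalized EHHS estimator,
    standardized genome-wide (median-centered by default).  Sites below
    ``maf_min`` in the pooled two-group sample are reported undefined."""
    if centering not in ("median", "mean"):
        raise ConfigError(f"unknown centering {centering!r}")
    return _between_group_scan("rsb", "normalized", centering, panel_group1,
                               panel_group2, cutoff, maf_min, edge_rule,
                               group)


def xpehh_scan(panel_group1: HaplotypePanel, panel_group2: HaplotypePanel,
               cutoff: float = 0.05, centering: str = "mean",
               maf_min: float = 0.05, edge_rule: str = "discard",
               group: str = "") -> pd.DataFrame:
    """XP-EHH scan: as Rsb but with unnormalized EHHS integrals and
    mean-centering; sensitive to sweeps at or near fixation in one group."""
    if centering not in ("median", "mean"):
        raise ConfigError(f"unknown centering {centering!r}")
    return _between_group_scan("xpehh", "unnormalized", centering,
                               panel_group1, panel_group2, cutoff, maf_min,
                               edge_rule, group)
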