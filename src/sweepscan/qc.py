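"""Marker and sample quality control plus LD pruning.

The default filter chain mirrors the standard SNP-array editing protocol for
this kind of cohort: drop markers with call rate < 95%, markers with minor
allele frequency < 5%, samples with more than 10% missing genotypes, then LD
pruning with PLINK ``--indep-pairwise 50 5 0.60`` semantics.  The chain is
applied in exactly that order and each step is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, ConfigError, GenotypeMatrix


@dataclass
class QCReport:
    """Per-filter removal counts, in application order."""

    steps: list = field(default_factory=list)  # (name, axis, n_removed)
    input_shape: tuple | None = None
    output_shape: tuple | None = None

    def record(self, name: str, axis: str, n_removed: int) -> None:
        self.steps.append({"filter": name, "axis": axis,
                           "removed": int(n_removed)})

    def to_dict(self) -> dict:
        return {"input_shape": self.input_shape,
                "output_shape": self.output_shape, "steps": self.steps}

    def check_balance(self) -> bool:
        """Removal counts must reconcile input and output dimensions."""
        ns, nm = self.input_shape
        for st in self.steps:
            if st["axis"] == "markers":
                nm -= st["removed"]
            else:
                ns -= st["removed"]
        return (ns, nm) == tuple(self.output_shape)


def snp_call_rate_filter(g: GenotypeMatrix, min_rate: float = 0.95,
                         report: QCReport | None = None) -> GenotypeMatrix:
    """Remove markers whose non-missing fraction is below ``min_rate``."""
    if not 0 <= min_rate <= 1:
        raise ConfigError("min_rate must be in [0,1]")
    called = (g.dosage != MISSING).mean(axis=0) if g.n_samples else \
        np.ones(g.n_markers)
    keep = np.flatnonzero(called >= min_rate)
    if report is not None:
        report.record("snp_call_rate", "markers", g.n_markers - len(keep))
    return g.subset_markers(keep)


def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF from non-missing dosages; NaN where all are missing."""
    called = g.dosage != MISSING
    n_called = called.sum(axis=0)
    totals = np.where(called, g.dosage, 0).sum(axis=0).astype(float)
    p = np.divide(totals, 2.0 * n_called,
                  out=np.full(g.n_markers, np.nan), where=n_called > 0)
    return np.minimum(p, 1.0 - p)


def maf_filter(g: GenotypeMatrix, min_maf: float = 0.05,
               report: QCReport | None = None) -> GenotypeMatrix:
    """Remove markers with MAF < ``min_maf`` (all-missing markers removed)."""
    if not 0 <= min_maf <= 0.5:
        raise ConfigError("min_maf must be in [0, 0.5]")
    maf = minor_allele_frequencies(g)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= min_maf))
    if report is not None:
        report.record("maf", "markers", g.n_markers - len(keep))
    return g.subset_markers(keep)


def sample_missingness_filter(g: GenotypeMatrix, max_missing: float = 0.10,
                              report: QCReport | None = None
                              ) -> GenotypeMatrix:
    """Remove samples with strictly more than ``max_missing`` missing calls."""
    if not 0 <= max_missing <= 1:
        raise ConfigError("max_missing must be in [0,1]")
    miss = (g.dosage == MISSING).mean(axis=1) if g.n_markers else \
        np.zeros(g.n_samples)
    keep = miss <= max_missing
    if report is not None:
        report.record("sample_missingness", "samples", int((~keep).sum()))
    return g.subset_samples(keep)


def pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples (composite LD).  Zero variance -> 0.0."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    ok = (d1 != MISSING) & (d2 != MISSING)
    x, y = d1[ok], d2[ok]
    if len(x) < 2:
        return 0.0
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _window_r2_prune(dosage: np.ndarray, window: int, step: int,
                     r2_max: float, victim: str) -> np.ndarray:
    """Kept-marker boolean mask for one chromosome's dosage block."""
    m = dosage.shape[1]
    keep = np.ones(m, dtype=bool)
    mafs = None
    if victim == "lower_maf":
        d = dosage.astype(float)
        d[dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        mafs = np.minimum(p, 1.0 - p)
    start = 0
    while True:
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        changed = True
        while changed:
            changed = False
            for ai in range(len(idx)):
                a = idx[ai]
                if not keep[a]:
                    continue
                for bi in range(ai + 1, len(idx)):
                    b = idx[bi]
                    if not keep[b]:
                        continue
                    if pairwise_r2(dosage[:, a], dosage[:, b]) > r2_max:
                        if victim == "lower_maf" and mafs[a] < mafs[b]:
                            keep[a] = False
                        else:
                            keep[b] = False
                        changed = True
            idx = [j for j in idx if keep[j]]
        if start + window >= m:
            break
        start += step
    return keep


def ld_prune(g: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.60, victim: str = "later",
             report: QCReport | None = None) -> GenotypeMatrix:
    """LD pruning with indep-pairwise semantics, per chromosome.

    Within each ``window_snps`` window, repeatedly remove one marker of every
    pair with r^2 > ``r2_max`` until stable, then slide by ``step_snps``.
    ``victim`` picks which marker of an offending pair goes: ``later`` (the
    one further along the map; deterministic default) or ``lower_maf``.
    """
    if window_snps <= 0 or step_snps <= 0:
        raise ConfigError("window and step must be positive")
    if victim not in ("later", "lower_maf"):
        raise ConfigError(f"unknown victim rule {victim!r}")
    keep_all = np.ones(g.n_markers, dtype=bool)
    for c in g.map.chromosomes():
        idx = g.map.chrom_indices(c)
        keep_all[idx] = _window_r2_prune(g.dosage[:, idx], window_snps,
                                         step_snps, r2_max, victim)
    kept = np.flatnonzero(keep_all)
    if report is not None:
        report.record("ld_prune", "markers", g.n_markers - len(kept))
    return g.subset_markers(kept)


def run_qc(g: GenotypeMatrix, min_call_rate: float = 0.95,
           min_maf: float = 0.05, max_sample_missing: float = 0.10,
           prune: bool = True, window_snps: int = 50, step_snps: int = 5,
           r2_max: float = 0.60) -> tuple[GenotypeMatrix, QCReport]:
    """Full filter chain: call rate -> MAF -> sample missingness -> pruning."""
    report = QCReport()
    report.input_shape = (g.n_samples, g.n_markers)
    g = snp_call_rate_filter(g, min_call_rate, report)
    g = maf_filter(g, min_maf, report)
    g = sample_missingness_filter(g, max_sample_missing, report)
    if prune:
        g = ld_prune(g, window_snps, step_snps, r2_max, report=report)
    report.output_shape = (g.n_samples, g.n_markers)
    return g, report
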