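"""Distance-based AMOVA (PERMANOVA) on genotype Hamming distances, plus
classical MDS for structure checks.

The between-sample distance is the allele-count Hamming distance
``d_ij = sum_m |g_im - g_jm|`` over pairwise non-missing markers (optionally
normalized by ``2 x`` the comparable-marker count, or computed as plain
genotype mismatch).  The matrix is partitioned by group factors with the
standard pseudo-F machinery: Gower-center ``-1/2 D^2``, take sequential
(order-of-entry) sums of squares by projecting on the factor design spaces,
and assess each term by permuting group labels — by default whole
populations exchange labels, matching a design where the factor is a
population-level attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, CohortLabels, ConfigError, GenotypeMatrix)


@dataclass
class DistanceMatrix:
    samples: list
    values: np.ndarray              # symmetric, zero diagonal
    comparable: np.ndarray | None = None  # per-pair comparable-marker counts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ConfigError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ConfigError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ConfigError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("distance matrix has non-finite entries")


@dataclass
class AmovaTable:
    terms: pd.DataFrame      # term, df, SS, R2, F, p_value
    n_permutations: int
    permute_unit: str

    def r2(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        return float(row["R2"].iloc[0])

    def p_value(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        return float(row["p_value"].iloc[0])


def hamming_distance_matrix(g: GenotypeMatrix,
                            normalize: bool = False,
                            mode: str = "allele") -> DistanceMatrix:
    """Pairwise Hamming distances between samples.

    ``mode="allele"`` counts allele differences ``|g_i - g_j|`` per marker
    (0/2 differ by 2); ``mode="genotype"`` counts mismatching genotypes.
    Missing markers are excluded pairwise; a pair with no comparable marker
    is an error.  ``normalize`` divides by ``2 x`` comparable markers
    (allele mode) or by comparable markers (genotype mode).
    """
    if g.n_samples < 2:
        raise ConfigError("need at least 2 samples")
    if mode not in ("allele", "genotype"):
        raise ConfigError(f"unknown Hamming mode {mode!r}")
    d = g.dosage.astype(np.float64)
    mask = (g.dosage != MISSING).astype(np.float64)
    d = d * mask
    comparable = mask @ mask.T
    if np.any(comparable[~np.eye(g.n_samples, dtype=bool)] == 0):
        raise ConfigError("sample pair with zero comparable markers")
    if mode == "allele":
        # sum |a-b| = sum (a-b)^2 - 2 * #{(0,2) pairs}, all via matmuls
        sq = (d * d) @ mask.T + mask @ (d * d).T - 2.0 * (d @ d.T)
        is0 = ((g.dosage == 0) & (mask > 0)).astype(np.float64)
        is2 = (g.dosage == 2).astype(np.float64)
        n02 = is0 @ is2.T + is2 @ is0.T
        dist = sq - 2.0 * n02
        denom = 2.0 * comparable
    else:
        eq = np.zeros((g.n_samples, g.n_samples))
        for v in (0, 1, 2):
            iv = (g.dosage == v).astype(np.float64)
            eq += iv @ iv.T
        dist = comparable - eq
        denom = comparable
    if normalize:
        dist = dist / denom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(list(g.samples), dist, comparable)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D * D
    n = A.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def _design(levels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    uniq = sorted(set(levels))
    return np.column_stack([(levels == u).astype(float)
                            for u in uniq[1:]]) if len(uniq) > 1 else \
        np.empty((len(levels), 0))


def _projection_trace(X: np.ndarray, G: np.ndarray) -> float:
    """tr(H G) for H = X (X'X)^- X'."""
    XtX = X.T @ X
    XtGX = X.T @ G @ X
    return float(np.trace(np.linalg.pinv(XtX) @ XtGX))


def permanova(D: DistanceMatrix, labels: CohortLabels, model: list,
              n_perm: int = 1000, permute_unit: str = "population",
              seed: int = 0) -> AmovaTable:
    """Sequential (Type I) PERMANOVA of a distance matrix.

    ``model`` is an ordered list of factor names (``weight``,
    ``geography``).  Samples whose level is ``none`` for any model factor
    are excluded.  Each term's SS is the increment in tr(H G) as its dummy
    columns join the design; pseudo-F tests each term against the residual.
    Significance comes from ``n_perm`` random permutations of the factor
    levels at ``permute_unit`` ("population": whole populations swap label
    rows; "sample": labels shuffle freely), with the add-one correction
    ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if permute_unit not in ("population", "sample"):
        raise ConfigError(f"unknown permute_unit {permute_unit!r}")
    for f in model:
        if f not in ("weight", "geography"):
            raise ConfigError(f"unknown model factor {f!r}")

    keep = [i for i, s in enumerate(D.samples)
            if all(labels.factor_of_sample(s, f) != "none" for f in model)]
    samples = [D.samples[i] for i in keep]
    Dm = D.values[np.ix_(keep, keep)]
    n = len(samples)
    if n < 3:
        raise ConfigError("too few labelled samples for PERMANOVA")
    pops = np.array([labels.population[s] for s in samples], dtype=object)
    pop_names = sorted(set(pops))

    # factor levels per population (constant within population by design)
    def pop_levels(factor):
        table = {labels.population[s]: labels.factor_of_sample(s, factor)
                 for s in samples}
        return np.array([table[p] for p in pop_names], dtype=object)

    factor_pop = {f: pop_levels(f) for f in model}
    for f in model:
        if len(set(factor_pop[f])) < 2:
            raise ConfigError(f"factor {f!r} has a single level")

    G = _gower_center(Dm)
    ss_total = float(np.trace(G))
    # population indicator for aggregation: all per-permutation designs are
    # constant within populations, so X' G X reduces to population blocks
    P = np.column_stack([(pops == p).astype(float) for p in pop_names])
    Gp = P.T @ G @ P              # (n_pop, n_pop)
    pop_sizes = P.sum(axis=0)

    def term_stats(level_arrays):
        """Sequential SS / df / F from population-level factor levels."""
        Xs = [_design(lv) for lv in level_arrays]
        cum_tr = []
        cols = [np.ones((len(pop_names), 1))]
        for X in Xs:
            cols.append(X)
            Xc = np.hstack(cols)
            # sample-level X = P @ Xc; X'X and X'GX via population blocks
            XtX = Xc.T @ (Xc * pop_sizes[:, None])
            XtGX = Xc.T @ Gp @ Xc
            cum_tr.append(float(np.trace(np.linalg.pinv(XtX) @ XtGX)))
        # intercept contributes 0 after Gower centering
        ss = []
        prev = 0.0
        for t in cum_tr:
            ss.append(t - prev)
            prev = t
        df = [X.shape[1] for X in Xs]
        ss_res = ss_total - sum(ss)
        df_res = n - 1 - sum(df)
        Fs = []
        for s_k, d_k in zip(ss, df):
            if ss_res <= 1e-12 or df_res <= 0:
                Fs.append(np.inf if s_k > 0 else np.nan)
            else:
                Fs.append((s_k / d_k) / (ss_res / df_res))
        return ss, df, Fs, ss_res, df_res

    obs_levels = [factor_pop[f] for f in model]
    ss, df, F_obs, ss_res, df_res = term_stats(obs_levels)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(model), dtype=np.int64)
    for _ in range(n_perm):
        if permute_unit == "population":
            perm = rng.permutation(len(pop_names))
            lv = [factor_pop[f][perm] for f in model]
            _, _, F_p, _, _ = term_stats(lv)
        else:
            perm = rng.permutation(n)
            pops_p = pops[perm]
            # rebuild population-level structure for permuted sample labels
            sample_lv = [np.array([labels.factor_of_sample(s, f)
                                   for s in samples], dtype=object)[perm]
                         for f in model]
            Xs = [_design(lv) for lv in sample_lv]
            cum_tr = []
            cols = [np.ones((n, 1))]
            for X in Xs:
                cols.append(X)
                Xc = np.hstack(cols)
                cum_tr.append(_projection_trace(Xc, G))
            ss_p, prev = [], 0.0
            for t in cum_tr:
                ss_p.append(t - prev)
                prev = t
            ss_res_p = ss_total - sum(ss_p)
            F_p = []
            for s_k, d_k in zip(ss_p, df):
                if ss_res_p <= 1e-12 or df_res <= 0:
                    F_p.append(np.inf if s_k > 0 else np.nan)
                else:
                    F_p.append((s_k / d_k) / (ss_res_p / df_res))
        for k in range(len(model)):
            if not np.isnan(F_obs[k]):
                # tolerance keeps tied F statistics counted as ties even
                # when row order perturbs the last floating-point bits
                tol = 1e-8 * max(1.0, abs(F_obs[k])) \
                    if np.isfinite(F_obs[k]) else 0.0
                if F_p[k] >= F_obs[k] - tol:
                    exceed[k] += 1

    rows = []
    for k, f in enumerate(model):
        rows.append({"term": f, "df": df[k], "SS": ss[k],
                     "R2": ss[k] / ss_total, "F": F_obs[k],
                     "p_value": (1 + exceed[k]) / (1 + n_perm)})
    rows.append({"term": "residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p_value": np.nan})
    rows.append({"term": "total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p_value": np.nan})
    return AmovaTable(pd.DataFrame(rows), n_perm, permute_unit)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def classical_mds(D: DistanceMatrix, k: int = 2):
    """Principal-coordinates analysis of a distance matrix.

    Eigendecomposition of the Gower-centered matrix; coordinates are
    ordered by decreasing eigenvalue and negative eigenvalues are dropped
    (their mass fraction is logged).  Returns ``(coords, eigenvalues)``
    with ``coords`` of shape (n, k'), k' = min(k, positive eigenvalues).
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    G = _gower_center(D.values)
    w, v = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(1e-12, 1e-10 * abs(w[0])) if len(w) else w > 0
    n_pos = int(pos.sum())
    neg_mass = float(np.abs(w[w < 0]).sum())
    tot_mass = float(np.abs(w).sum())
    if neg_mass > 0 and tot_mass > 0:
        import logging
        logging.getLogger("sweepscan").info(
            "classical_mds: dropping negative eigenvalue mass %.3g",
            neg_mass / tot_mass)
    kk = min(k, n_pos)
    coords = v[:, :kk] * np.sqrt(w[:kk])[None, :] if kk else \
        np.zeros((len(D.samples), 0))
    if kk < k and n_pos < len(w):
        pass  # truncation logged above via negative mass
    return coords, w
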