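"""Synthetic structured cohorts with array-like LD and implanted sweeps.

The real study cohort (23 local chicken populations, 541 birds, 600K-array
genotypes) is not publicly deposited, so every downstream stage is exercised
on simulated data built to resemble it: ~20-24 diploids per population,
~1 SNP per 3 kb with MAF >= 0.05, linkage disequilibrium decaying over
tens to hundreds of kb, hierarchical group structure (weight class and
geography), and optional hard sweeps private to one group.

The model is a founder-mosaic copying process rather than a coalescent:

1. ``simulate_founder_pool`` draws K founder haplotypes at M biallelic sites.
2. ``mosaic_haplotypes`` copies founders segment-wise; the copying process
   switches founder between adjacent sites with probability
   ``1 - exp(-switch_rate * gap_bp)``, so LD decays with physical distance
   on the scale of ``1/switch_rate`` bp.
3. ``assemble_cohort`` assigns haplotypes to populations by weighted
   sampling without replacement.  The weights perturb founder-copy
   probabilities: every group level and every population draws a gamma
   multiplier per founder (variance proportional to ``drift_parameter``),
   and a haplotype's sampling weight is its founder-ancestry fractions
   dotted with the population's multipliers.  Because populations in the
   same group share the group multiplier, allele-frequency divergence is
   correlated within groups — the hierarchical structure the AMOVA stage
   measures — and a single scalar tunes its strength.
4. ``implant_sweep`` forces a chosen fraction of one group's haplotypes to
   be copies of a single template over a window — an exact, fully known
   "hard sweep" for power tests.  Optional segmental autozygosity
   (``ibd_rate``) copies one of an individual's haplotypes onto the other
   over a multi-Mb stretch, creating genuine runs of homozygosity.

Everything is driven by explicit integer seeds and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genotype_io import (MISSING, CohortLabels, ConfigError, GenotypeMatrix,
                          HaplotypePanel, MarkerMap, genotypes_from_haplotypes)

# Study design: 23 local Italian chicken populations with their sample sizes
# and contrast-group memberships (weight class: mean live weight >3.5 kg =
# heavy, <1.5 kg = light; geography: reared above the 45th parallel = north,
# below the 40th = south).  Totals: 541 birds; heavy 141, light 192,
# north 307, south 66.
STUDY_POPULATIONS = [
    #  code    N   weight    geography
    ("ANC", 24, "none", "none"),
    ("BSA", 24, "none", "north"),
    ("BPT", 22, "none", "north"),
    ("COR", 22, "none", "south"),
    ("PER", 23, "heavy", "north"),
    ("PLB", 24, "none", "none"),
    ("PLN", 24, "none", "none"),
    ("MER", 24, "light", "north"),
    ("PML", 23, "heavy", "north"),
    ("MOD", 24, "heavy", "none"),
    ("MUG", 24, "light", "none"),
    ("PPA", 24, "light", "north"),
    ("PPC", 24, "light", "north"),
    ("PPD", 24, "light", "north"),
    ("PPP", 24, "light", "north"),
    ("PPB", 24, "none", "north"),
    ("PPN", 24, "none", "north"),
    ("PRL", 23, "heavy", "north"),
    ("PRM", 24, "heavy", "north"),
    ("ROM", 24, "light", "none"),
    ("SIC", 24, "light", "south"),
    ("VLD", 24, "heavy", "none"),
    ("VLP", 20, "none", "south"),
]


def study_population_sizes() -> dict:
    return {code: n for code, n, _, _ in STUDY_POPULATIONS}


def study_group_table() -> dict:
    return {code: (w, g) for code, _, w, g in STUDY_POPULATIONS}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class FounderPool:
    """K founder haplotypes x M biallelic sites with a physical map."""

    founders: np.ndarray   # (K, M) in {0,1}
    positions: np.ndarray  # bp, 1-based, strictly increasing per chromosome
    chrom_ids: np.ndarray  # chromosome label per site

    def __post_init__(self) -> None:
        self.founders = np.asarray(self.founders, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chrom_ids = np.asarray(self.chrom_ids, dtype=object)
        if self.founders.shape[0] < 2:
            raise ConfigError("need at least 2 founders")
        if self.founders.size and self.founders.max() > 1:
            raise ConfigError("founder alleles must be binary")

    @property
    def n_founders(self) -> int:
        return self.founders.shape[0]

    @property
    def n_sites(self) -> int:
        return self.founders.shape[1]

    def marker_map(self) -> MarkerMap:
        # nucleotide allele symbols so VCF export stays spec-valid
        m = self.n_sites
        ids = np.array([f"snp{j}" for j in range(m)], dtype=object)
        return MarkerMap(ids, self.chrom_ids, self.positions,
                         np.full(m, "A", dtype=object),
                         np.full(m, "G", dtype=object))


@dataclass
class SweepSpec:
    """One implanted hard sweep: carriers are forced identical to a template
    over ``focal_bp +/- span_bp`` on ``chrom`` in ``target_populations``."""

    chrom: str
    focal_bp: int
    carrier_fraction: float
    span_bp: int
    target_populations: list = field(default_factory=list)
    name: str = "sweep"

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction <= 1:
            raise ConfigError("carrier_fraction must be in (0, 1]")
        if self.span_bp <= 0:
            raise ConfigError("span_bp must be positive")


@dataclass
class TruthSet:
    """Machine-readable ground truth for one simulated cohort."""

    sweeps: list
    drift_parameter: dict
    seed: int
    group_table: dict
    ibd_segments: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "drift_parameter": {k: float(v)
                                for k, v in self.drift_parameter.items()},
            "group_table": {k: list(v) for k, v in self.group_table.items()},
            "sweeps": [asdict(s) for s in self.sweeps],
            "ibd_segments": self.ibd_segments,
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_founder_pool(n_founders: int, n_sites: int,
                          chrom_lengths, maf_floor: float = 0.05,
                          seed: int = 0) -> FounderPool:
    """Draw founder haplotypes with per-site frequencies >= ``maf_floor``.

    ``chrom_lengths`` maps chromosome label -> length in bp (or is a list of
    lengths, labelled "1", "2", ...).  Sites are allocated to chromosomes
    proportionally to length, positions drawn uniformly without replacement.
    The per-site derived count among founders is drawn so that the founder
    allele frequency is always within ``[maf_floor, 1 - maf_floor]``.
    """
    if n_founders < 2:
        raise ConfigError("n_founders must be >= 2")
    if n_sites < 1:
        raise ConfigError("n_sites must be >= 1")
    if not 0 <= maf_floor <= 0.5:
        raise ConfigError("maf_floor must be in [0, 0.5]")
    if not isinstance(chrom_lengths, dict):
        chrom_lengths = {str(i + 1): int(L)
                         for i, L in enumerate(chrom_lengths)}
    for c, L in chrom_lengths.items():
        if L <= 0:
            raise ConfigError(f"non-positive length for chromosome {c}")

    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    names = list(chrom_lengths)
    counts = {c: int(round(n_sites * chrom_lengths[c] / total))
              for c in names}
    # fix rounding so counts sum to n_sites, keeping each chromosome >= 1
    diff = n_sites - sum(counts.values())
    counts[names[0]] += diff
    for c in names:
        counts[c] = max(1, min(counts[c], chrom_lengths[c]))

    positions, chrom_ids = [], []
    for c in names:
        k = counts[c]
        pos = np.sort(rng.choice(chrom_lengths[c], size=k, replace=False)) + 1
        positions.append(pos)
        chrom_ids.append(np.full(k, c, dtype=object))
    positions = np.concatenate(positions)
    chrom_ids = np.concatenate(chrom_ids)
    m = len(positions)

    lo = int(np.ceil(maf_floor * n_founders - 1e-9))
    hi = n_founders - lo
    if lo > hi:
        raise ConfigError(
            f"maf_floor {maf_floor} unreachable with {n_founders} founders")
    freq = rng.uniform(maf_floor, 1 - maf_floor, size=m)
    count = np.clip(np.rint(freq * n_founders).astype(int), lo, hi)
    founders = np.zeros((n_founders, m), dtype=np.uint8)
    for j in range(m):
        carriers = rng.choice(n_founders, size=count[j], replace=False)
        founders[carriers, j] = 1
    return FounderPool(founders, positions, chrom_ids)


def mosaic_haplotypes(pool: FounderPool, n_haplotypes: int,
                      switch_rate: float = 1e-5,
                      mutation_rate: float = 1e-3,
                      seed: int = 0,
                      founder_weights: np.ndarray | None = None,
                      return_ancestry: bool = False):
    """Generate haplotypes as segment-wise founder copies.

    Between adjacent sites separated by ``gap`` bp the copied founder is
    re-drawn with probability ``1 - exp(-switch_rate * gap)``; each allele is
    then flipped independently with ``mutation_rate``.  LD between sites
    therefore decays with physical distance on the ``1/switch_rate`` scale.

    With ``return_ancestry`` the per-haplotype founder composition (fraction
    of sites copied from each founder, a ``(n_haplotypes, K)`` matrix) is
    returned alongside the panel; ``assemble_cohort`` uses it to express
    population drift as founder-copy preference.
    """
    if pool.n_sites == 0:
        raise ConfigError("empty founder pool")
    if switch_rate < 0:
        raise ConfigError("switch_rate must be >= 0")
    if not 0 <= mutation_rate <= 1:
        raise ConfigError("mutation_rate must be in [0, 1]")
    if n_haplotypes % 2:
        raise ConfigError("n_haplotypes must be even (panel holds diploids)")
    rng = np.random.default_rng(seed)
    K = pool.n_founders
    if founder_weights is None:
        founder_weights = np.full(K, 1.0 / K)
    founder_weights = np.asarray(founder_weights, dtype=float)
    founder_weights = founder_weights / founder_weights.sum()

    out = np.empty((n_haplotypes, pool.n_sites), dtype=np.uint8)
    ancestry = np.zeros((n_haplotypes, K), dtype=np.float64)
    mmap_chroms = pool.chrom_ids
    for c in dict.fromkeys(mmap_chroms):
        cols = np.flatnonzero(mmap_chroms == c)
        mc = len(cols)
        gaps = np.diff(pool.positions[cols]).astype(float)
        p_switch = 1.0 - np.exp(-switch_rate * gaps)
        # segment index per site per haplotype
        switches = rng.random((n_haplotypes, mc - 1)) < p_switch[None, :] \
            if mc > 1 else np.zeros((n_haplotypes, 0), dtype=bool)
        seg = np.zeros((n_haplotypes, mc), dtype=np.int64)
        if mc > 1:
            seg[:, 1:] = np.cumsum(switches, axis=1)
        n_seg = int(seg[:, -1].max()) + 1 if mc else 1
        founder_of_seg = rng.choice(K, size=(n_haplotypes, n_seg),
                                    p=founder_weights)
        hap_founder = np.take_along_axis(founder_of_seg, seg, axis=1)
        block = pool.founders[:, cols]
        out[:, cols] = block[hap_founder, np.arange(mc)[None, :]]
        for i in range(n_haplotypes):
            ancestry[i] += np.bincount(hap_founder[i], minlength=K)
    if mutation_rate > 0:
        flips = rng.random(out.shape) < mutation_rate
        out ^= flips.astype(np.uint8)
    ancestry /= pool.n_sites

    sample_ids = [f"H{i}" for i in range(n_haplotypes // 2)]
    panel = HaplotypePanel(sample_ids, pool.marker_map(), out, coding="raw")
    return (panel, ancestry) if return_ancestry else panel


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def implant_sweep(panel: HaplotypePanel, spec: SweepSpec, seed: int = 0,
                  labels: CohortLabels | None = None) -> HaplotypePanel:
    """Return a copy of ``panel`` with a hard sweep implanted.

    A random ``carrier_fraction`` of the target haplotypes (round half up)
    have every site within ``focal_bp +/- span_bp`` replaced by one template
    haplotype that carries allele 1 at the focal site.  With ``labels``
    given, targets are the haplotypes of samples in
    ``spec.target_populations``; otherwise all haplotypes are targets.
    """
    mmap = panel.map
    on_chrom = np.flatnonzero(mmap.chrom == spec.chrom)
    if len(on_chrom) == 0:
        raise ConfigError(f"no sites on chromosome {spec.chrom!r}")
    pos = mmap.pos_bp[on_chrom]
    if not pos[0] <= spec.focal_bp <= pos[-1]:
        raise ConfigError("focal_bp outside chromosome marker extent")
    in_span = on_chrom[(pos >= spec.focal_bp - spec.span_bp)
                       & (pos <= spec.focal_bp + spec.span_bp)]
    if len(in_span) < 2:
        raise ConfigError("degenerate sweep: fewer than 2 sites in span")
    focal_idx = on_chrom[np.argmin(np.abs(pos - spec.focal_bp))]

    if labels is not None and spec.target_populations:
        targets = []
        for i, s in enumerate(panel.sample_ids):
            if labels.population[s] in spec.target_populations:
                targets += [2 * i, 2 * i + 1]
        targets = np.array(targets, dtype=int)
    else:
        targets = np.arange(panel.n_haplotypes)
    if len(targets) == 0:
        raise ConfigError("no haplotypes in target populations")

    rng = np.random.default_rng(seed)
    n_carriers = _round_half_up(spec.carrier_fraction * len(targets))
    n_carriers = max(1, min(n_carriers, len(targets)))
    carriers = rng.choice(targets, size=n_carriers, replace=False)

    alleles = panel.alleles.copy()
    template = alleles[carriers[0], in_span].copy()
    template[np.searchsorted(in_span, focal_idx)] = 1
    alleles[np.ix_(carriers, in_span)] = template[None, :]
    return HaplotypePanel(panel.sample_ids, mmap, alleles, panel.coding)


# How much of the founder-preference variance sits at the group level
# versus the individual population: group multipliers get variance
# drift * share, population multipliers drift / share.  With share > 1 the
# shared (group) component dominates, so group contrasts are both sizeable
# and clearly significant under population-label permutation, as in highly
# structured livestock cohorts.
GROUP_DRIFT_SHARE = 2.0


def _gamma_multiplier(rng, drift: float, k: int) -> np.ndarray:
    """Mean-1 per-founder multiplier with variance ``drift`` (1.0 if 0)."""
    if drift <= 0:
        return np.ones(k)
    shape = 1.0 / drift
    return rng.gamma(shape, 1.0 / shape, size=k)


def assemble_cohort(panel: HaplotypePanel, populations: dict,
                    group_table: dict, drift_parameter=0.0,
                    missing_rate: float = 0.0, seed: int = 0,
                    sweeps: list | None = None,
                    founder_ancestry: np.ndarray | None = None,
                    ibd_rate: float = 0.0,
                    ibd_span_bp: tuple = (1_500_000, 4_000_000),
                    assignment: str = "resample"):
    """Assign panel haplotypes to populations and emit the cohort.

    ``populations`` maps population -> number of diploids; ``group_table``
    maps population -> (weight_class, geography).  Each population draws
    its 2N haplotypes without replacement with perturbed weights controlled
    by ``drift_parameter`` (0 = uniform, no divergence beyond sampling
    noise):

    * with ``founder_ancestry`` (from ``mosaic_haplotypes``), the weights
      act on founder-copy probabilities — every group level and every
      population draws a mean-1 gamma multiplier per founder with variance
      ``drift``, and a haplotype's weight is its ancestry fractions dotted
      with the product of its population's group and own multipliers.
      Populations sharing a group level share that level's multiplier, so
      divergence is hierarchically structured;
    * without ancestry, weights are a symmetric Dirichlet (concentration
      ``1/drift``) directly over panel haplotypes.

    Diploids pair consecutive draws.  ``ibd_rate`` is the per-individual
    probability of one autozygous stretch (second haplotype overwritten by
    the first over a uniform ``ibd_span_bp`` span) — the source of runs of
    homozygosity.  Sweeps (if any) are implanted after assignment, then
    genotypes are derived and missingness injected (the returned haplotype
    panel stays complete).

    With ``assignment="sequential"`` the panel is taken as already ordered
    by population (first 2N_1 haplotypes to the first population, and so
    on) and no resampling occurs — the path used by ``simulate_cohort``,
    which generates each population's mosaics with its own founder-copy
    weights.

    Returns ``(GenotypeMatrix, HaplotypePanel, CohortLabels, TruthSet)``.
    """
    if assignment not in ("resample", "sequential"):
        raise ConfigError(f"unknown assignment mode {assignment!r}")
    if not 0 <= missing_rate < 1:
        raise ConfigError("missing_rate must be in [0, 1)")
    if not 0 <= ibd_rate <= 1:
        raise ConfigError("ibd_rate must be in [0, 1]")
    for p in populations:
        if p not in group_table:
            raise ConfigError(f"population {p!r} absent from group_table")
    if not isinstance(drift_parameter, dict):
        drift_parameter = {p: float(drift_parameter) for p in populations}
    for p, d in drift_parameter.items():
        if d < 0:
            raise ConfigError("drift_parameter must be >= 0")

    needed = 2 * sum(populations.values())
    if needed > panel.n_haplotypes:
        raise ConfigError(
            f"cohort needs {needed} haplotypes, panel has "
            f"{panel.n_haplotypes}")

    rng = np.random.default_rng(seed)
    mean_drift = float(np.mean(list(drift_parameter.values()))) \
        if drift_parameter else 0.0
    level_mult = {}
    if founder_ancestry is not None:
        K = founder_ancestry.shape[1]
        for level in ("heavy", "light", "north", "south"):
            level_mult[level] = _gamma_multiplier(rng, mean_drift, K)

    available = np.arange(panel.n_haplotypes)
    rows, sample_ids, sample_pop = [], [], {}
    offset = 0
    for p, n_dip in populations.items():
        if assignment == "sequential":
            rows.append(np.arange(offset, offset + 2 * n_dip))
            offset += 2 * n_dip
            for k in range(n_dip):
                sid = f"{p}_{k}"
                sample_ids.append(sid)
                sample_pop[sid] = p
            continue
        drift = drift_parameter.get(p, 0.0)
        if drift == 0:
            w = np.full(len(available), 1.0 / len(available))
        elif founder_ancestry is not None:
            K = founder_ancestry.shape[1]
            mult = _gamma_multiplier(rng, drift, K)
            wl, geo = group_table[p]
            for level in (wl, geo):
                if level in level_mult:
                    mult = mult * level_mult[level]
            w = founder_ancestry[available] @ mult
            w = w / w.sum()
        else:
            w = rng.dirichlet(np.full(len(available), 1.0 / drift))
        take = rng.choice(available, size=2 * n_dip, replace=False, p=w)
        rows.append(take)
        mask = ~np.isin(available, take)
        available = available[mask]
        for k in range(n_dip):
            sid = f"{p}_{k}"
            sample_ids.append(sid)
            sample_pop[sid] = p

    rows = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    labels = CohortLabels(sample_pop,
                          {p: group_table[p][0] for p in populations},
                          {p: group_table[p][1] for p in populations})
    cohort_panel = HaplotypePanel(sample_ids, panel.map,
                                  panel.alleles[rows].copy(), panel.coding)

    ibd_segments = []
    if ibd_rate > 0:
        mmap = panel.map
        chroms = mmap.chromosomes()
        extents = {c: (int(mmap.pos_bp[mmap.chrom_indices(c)][0]),
                       int(mmap.pos_bp[mmap.chrom_indices(c)][-1]))
                   for c in chroms}
        weights = np.array([extents[c][1] - extents[c][0] for c in chroms],
                           dtype=float)
        weights /= weights.sum()
        for i, sid in enumerate(sample_ids):
            if rng.random() >= ibd_rate:
                continue
            c = chroms[rng.choice(len(chroms), p=weights)]
            lo, hi = extents[c]
            span = int(rng.uniform(*ibd_span_bp))
            start = int(rng.uniform(lo, max(lo + 1, hi - span)))
            end = start + span
            idx = mmap.chrom_indices(c)
            sel = idx[(mmap.pos_bp[idx] >= start)
                      & (mmap.pos_bp[idx] <= end)]
            if len(sel) < 2:
                continue
            cohort_panel.alleles[2 * i + 1, sel] = \
                cohort_panel.alleles[2 * i, sel]
            ibd_segments.append({"sample": sid, "chrom": c,
                                 "start_bp": start, "end_bp": end})

    sweeps = list(sweeps or [])
    for i, spec in enumerate(sweeps):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cohort_panel = implant_sweep(cohort_panel, spec, seed=sub_seed,
                                     labels=labels)

    g = genotypes_from_haplotypes(cohort_panel)
    if missing_rate > 0:
        miss = rng.random(g.dosage.shape) < missing_rate
        dosage = g.dosage.copy()
        dosage[miss] = MISSING
        g = GenotypeMatrix(g.samples, g.map, dosage)

    truth = TruthSet(sweeps=sweeps, drift_parameter=drift_parameter,
                     seed=int(seed), group_table=dict(group_table),
                     ibd_segments=ibd_segments)
    return g, cohort_panel, labels, truth


# ---------------------------------------------------------------------------
# High-level cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Simulation recipe.  Defaults are the study-like conditions at desk
    scale: the 23-population / 541-bird design, ~1 SNP per 3 kb, MAF >= 0.05,
    LD over ~100 kb and a drift level giving group-structure variance in the
    ~15% range."""

    chrom_lengths: dict = field(
        default_factory=lambda: {"1": 9_000_000, "2": 9_000_000})
    snp_spacing_bp: int = 3_000
    n_founders: int = 40
    maf_floor: float = 0.05
    switch_rate: float = 1e-5
    mutation_rate: float = 1e-3
    populations: dict = field(default_factory=study_population_sizes)
    group_table: dict = field(default_factory=study_group_table)
    drift_parameter: float = 2.0
    missing_rate: float = 0.002
    ibd_rate: float = 0.25
    ibd_span_bp: tuple = (1_500_000, 4_000_000)
    sweeps: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return int(sum(self.chrom_lengths.values()) // self.snp_spacing_bp)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Run the whole generator: founders -> per-population mosaics -> cohort.

    Population drift acts on founder-copy probabilities: every group level
    (heavy/light/north/south) and every population draws an independent
    mean-1 gamma multiplier per founder with variance ``drift_parameter``;
    a population's mosaic haplotypes copy founders with probability
    proportional to the product of its own and its group levels'
    multipliers.  Populations sharing a group therefore drift in a shared
    direction — the hierarchical structure the AMOVA stage measures —
    while ``drift_parameter = 0`` gives one exchangeable pool.

    Returns ``(GenotypeMatrix, HaplotypePanel, CohortLabels, TruthSet)``.
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 + len(config.populations))

    def _seed_of(child):
        return int(child.generate_state(1)[0] % (2**31 - 1))

    s_pool, s_levels, s_asm = (_seed_of(c) for c in children[:3])
    pool = simulate_founder_pool(config.n_founders, config.n_sites,
                                 config.chrom_lengths, config.maf_floor,
                                 seed=s_pool)
    drift = config.drift_parameter
    rng_lv = np.random.default_rng(s_levels)
    level_mult = {lv: _gamma_multiplier(rng_lv, drift * GROUP_DRIFT_SHARE,
                                        config.n_founders)
                  for lv in ("heavy", "light", "north", "south")}

    blocks = []
    for child, (p, n_dip) in zip(children[3:], config.populations.items()):
        mult = _gamma_multiplier(rng_lv, drift / GROUP_DRIFT_SHARE,
                                 config.n_founders)
        wl, geo = config.group_table[p]
        for level in (wl, geo):
            if level in level_mult:
                mult = mult * level_mult[level]
        w = mult / mult.sum()
        blocks.append(mosaic_haplotypes(pool, 2 * n_dip,
                                        config.switch_rate,
                                        config.mutation_rate,
                                        seed=_seed_of(child),
                                        founder_weights=w))
    alleles = np.vstack([b.alleles for b in blocks])
    n_total = alleles.shape[0]
    panel = HaplotypePanel([f"H{i}" for i in range(n_total // 2)],
                           pool.marker_map(), alleles, coding="raw")
    return assemble_cohort(panel, config.populations, config.group_table,
                           config.drift_parameter, config.missing_rate,
                           seed=s_asm, sweeps=config.sweeps,
                           ibd_rate=config.ibd_rate,
                           ibd_span_bp=config.ibd_span_bp,
                           assignment="sequential")


def write_truth(truth: TruthSet, bed_path, json_path) -> None:
    """Write sweep intervals as BED (0-based half-open) plus a JSON sidecar."""
    with open(bed_path, "w") as fh:
        for i, s in enumerate(truth.sweeps):
            start1 = max(1, s.focal_bp - s.span_bp)
            end1 = s.focal_bp + s.span_bp
            name = s.name if s.name != "sweep" else f"sweep{i}"
            fh.write(f"{s.chrom}\t{start1 - 1}\t{end1}\t{name}\t"
                     f"{s.carrier_fraction}\n")
    with open(json_path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
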