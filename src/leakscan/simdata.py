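"""Synthetic pedigreed populations with LD-structured genotypes and QTL.

This module is the stand-in for a real breeding-line dataset: it produces a
multi-generation litter-structured pedigree (see :mod:`leakscan.pedigree`),
founder haplotypes with distance-decaying linkage disequilibrium, genotypes
gene-dropped through the pedigree with recombination, an additive QTL
architecture (with a designated large-effect QTL and a designated QTL that
the medium-density panel cannot tag), and phenotypes with contemporary-group
fixed effects, common-litter random effects, a pedigree polygenic term and
an optional linear covariate.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pedigree import ConfigError, Pedigree, PedigreeError

MISSING = -1  # sentinel for a missing dosage in the int8 matrix


class DataError(ValueError):
    """Data does not support the requested operation."""


# ---------------------------------------------------------------------------
# marker map and genotype containers


@dataclass
class MarkerMap:
    """Per-SNP map: id, chromosome, 1-based bp position, MD-panel membership.

    Positions are strictly increasing within a chromosome and every
    medium-density (MD) SNP is by construction also an ultra-high-density
    (UHD) SNP: the MD panel is a flagged subset of the UHD map.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    is_md: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.is_md = np.asarray(self.is_md, dtype=bool)
        for c in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise DataError(f"positions not strictly increasing on chromosome {c}")
        if np.any(self.position_bp < 1) or np.any(self.chromosome < 1):
            raise DataError("chromosomes and positions must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_index(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.chromosome == c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chromosome": self.chromosome, "snp_id": self.snp_id,
             "position_bp": self.position_bp, "is_md": self.is_md.astype(int)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(df["snp_id"].to_numpy(), df["chromosome"].to_numpy(),
                   df["position_bp"].to_numpy(), df["is_md"].to_numpy().astype(bool))


def random_marker_map(
    n_chromosomes: int,
    snps_per_chromosome: int,
    chromosome_length_bp: int = 50_000_000,
    seed: int = 0,
) -> MarkerMap:
    """Draw a UHD map with per-chromosome positions uniform on [1, length]."""
    rng = np.random.default_rng(seed)
    chrom, pos, sid = [], [], []
    for c in range(1, n_chromosomes + 1):
        p = np.sort(rng.choice(np.arange(1, chromosome_length_bp + 1),
                               size=snps_per_chromosome, replace=False))
        chrom.append(np.full(snps_per_chromosome, c))
        pos.append(p)
        sid.extend(f"snp{c}_{i}" for i in range(snps_per_chromosome))
    return MarkerMap(np.array(sid, dtype=object), np.concatenate(chrom),
                     np.concatenate(pos), np.zeros(n_chromosomes * snps_per_chromosome, bool))


@dataclass
class GenotypeMatrix:
    """Animals × SNPs dosage matrix, entries in {0, 1, 2} or MISSING (-1)."""

    dosage: np.ndarray
    animal_ids: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        n, m = self.dosage.shape
        if n != len(self.animal_ids):
            raise DataError("row count does not match animal_ids")
        if m != self.map.n_snps:
            raise DataError("column count does not match marker map")
        bad = (self.dosage > 2) | ((self.dosage < 0) & (self.dosage != MISSING))
        if bad.any():
            raise DataError("dosages must be 0/1/2 or missing")

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Allele frequency of the '1' allele per SNP from non-missing dosages."""
        d = self.dosage.astype(np.float64)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        m = MarkerMap(self.map.snp_id[index], self.map.chromosome[index],
                      self.map.position_bp[index], self.map.is_md[index])
        return GenotypeMatrix(self.dosage[:, index], self.animal_ids, m)

    def subset_animals(self, ids) -> "GenotypeMatrix":
        ids = np.asarray(ids, dtype=np.int64)
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            rows = np.array([lookup[a] for a in ids])
        except KeyError as exc:
            raise DataError(f"animal {exc.args[0]} not genotyped") from None
        return GenotypeMatrix(self.dosage[rows], ids, self.map)

    def md_panel(self) -> "GenotypeMatrix":
        return self.subset_snps(np.flatnonzero(self.map.is_md))

    def dosages_float(self, impute_mean: bool = False) -> np.ndarray:
        x = self.dosage.astype(np.float64)
        miss = self.dosage == MISSING
        if miss.any():
            x[miss] = np.nan
            if impute_mean:
                col = np.nanmean(x, axis=0)
                idx = np.where(miss)
                x[idx] = col[idx[1]]
        return x


# ---------------------------------------------------------------------------
# founder haplotypes


def simulate_founder_haplotypes(
    mmap: MarkerMap,
    n_founders: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    ld_decay: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """Founder haplotype pool with distance-decaying LD.

    Haplotypes follow a first-order Markov chain along each chromosome: the
    allele at SNP *j* copies the allele at SNP *j−1* with probability
    ``exp(-ld_decay * distance_bp)`` and is otherwise drawn fresh at that
    SNP's target frequency (drawn uniformly from ``maf_range``). Squared
    correlation between SNPs therefore decays roughly as
    ``exp(-2 * ld_decay * distance)``. Chromosomes are independent.

    Returns a ``(2 * n_founders, n_snps)`` 0/1 array (two haplotypes per
    founder, rows 2k and 2k+1 belong to founder k).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
    if ld_decay < 0:
        raise ConfigError("ld_decay must be non-negative")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_founders
    m = mmap.n_snps
    freqs = rng.uniform(lo, hi, size=m)
    copy_u = rng.random((n_hap, m))
    fresh = rng.random((n_hap, m)) < freqs
    H = np.empty((n_hap, m), dtype=np.uint8)
    for c in mmap.chromosomes:
        idx = mmap.chrom_index(c)
        pos = mmap.position_bp[idx]
        j0 = idx[0]
        H[:, j0] = fresh[:, j0]
        copy_p = np.exp(-ld_decay * np.diff(pos).astype(np.float64))
        for k in range(1, len(idx)):
            j = idx[k]
            copy = copy_u[:, j] < copy_p[k - 1]
            H[:, j] = np.where(copy, H[:, j - 1], fresh[:, j])
    return H


# ---------------------------------------------------------------------------
# gene dropping


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: np.ndarray,
    mmap: MarkerMap,
    recomb_rate_per_bp: float = 1e-8,
    seed: int = 0,
) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree with recombination.

    Each non-founder inherits one recombinant gamete from each parent: the
    number of crossovers per chromosome is Poisson with mean
    ``recomb_rate_per_bp × chromosome length`` (length = last SNP position),
    crossover positions are uniform, and the starting parental haplotype is
    random. No mutation. Returns the UHD dosage matrix (no missing values).
    """
    if recomb_rate_per_bp < 0:
        raise ConfigError("recomb_rate_per_bp must be non-negative")
    n = pedigree.n
    m = mmap.n_snps
    founders = np.flatnonzero(pedigree.is_founder)
    if founder_haplotypes.shape != (2 * len(founders), m):
        raise PedigreeError("founder haplotype pool must have 2 haplotypes per founder")
    rng = np.random.default_rng(seed)
    sire_row, dam_row = pedigree.parent_rows()
    if np.any((sire_row == -1) != (dam_row == -1)):
        raise PedigreeError("animals must have both parents known or both unknown")

    chrom_idx = [mmap.chrom_index(c) for c in mmap.chromosomes]
    chrom_pos = [mmap.position_bp[ix] for ix in chrom_idx]
    chrom_len = [int(p[-1]) for p in chrom_pos]

    haps = np.empty((n, 2, m), dtype=np.uint8)
    for k, f in enumerate(founders):
        haps[f, 0] = founder_haplotypes[2 * k]
        haps[f, 1] = founder_haplotypes[2 * k + 1]

    def gamete(parent_row: int) -> np.ndarray:
        out = np.empty(m, dtype=np.uint8)
        for ix, pos, L in zip(chrom_idx, chrom_pos, chrom_len):
            k = rng.poisson(recomb_rate_per_bp * L)
            start = rng.integers(2)
            if k == 0:
                out[ix] = haps[parent_row, start, ix]
                continue
            xo = np.sort(rng.integers(1, L + 1, size=k))
            # parity of crossovers left of each SNP selects the haplotype
            which = (start + np.searchsorted(xo, pos, side="left")) % 2
            seg = haps[parent_row, :, ix[0] : ix[-1] + 1]
            out[ix] = seg[which, np.arange(len(ix))]
        return out

    for row in range(n):
        if sire_row[row] == -1:
            continue
        haps[row, 0] = gamete(sire_row[row])
        haps[row, 1] = gamete(dam_row[row])

    dosage = haps.sum(axis=1, dtype=np.int8)
    return GenotypeMatrix(dosage, pedigree.animal_id, mmap)


# ---------------------------------------------------------------------------
# QTL architecture and MD panel


@dataclass
class QtlArchitecture:
    """Additive causal loci on the UHD map.

    ``effects`` are allele-substitution effects on the scale of the raw
    draws; they are rescaled at phenotype construction so that the QTL score
    explains the configured fraction of phenotypic variance. One QTL is the
    designated large-effect locus and one other the designated locus whose
    neighbourhood is excluded from the MD panel ("untagged").
    """

    qtl_indices: np.ndarray
    effects: np.ndarray
    large_effect_index: int
    untagged_index: int

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise DataError("qtl_indices must be distinct")
        if not np.all(np.isfinite(self.effects)):
            raise DataError("effects must be finite")
        for tag in (self.large_effect_index, self.untagged_index):
            if tag not in self.qtl_indices:
                raise DataError("designated QTL must be among qtl_indices")


def assign_qtl(
    genotypes: GenotypeMatrix,
    n_qtl: int = 30,
    large_effect_multiplier: float = 7.0,
    seed: int = 0,
    untagged_multiplier: float = 1.0,
    tag_neighbor_max_bp: int | None = None,
    tag_neighbor_min_bp: int = 0,
    min_designated_maf: float = 0.2,
) -> QtlArchitecture:
    """Sample an additive QTL architecture from the polymorphic UHD SNPs.

    Baseline effects are i.i.d. standard normal. A multiplier above 1 marks
    a *designed* locus: its effect is set to ``±multiplier`` (random sign)
    rather than ``multiplier × draw``, so the designated large-effect and
    untagged QTL carry a guaranteed, reproducible share of the QTL variance
    instead of one that fluctuates with a single Gaussian draw. Designed
    loci are placed at common variants (MAF ≥ ``min_designated_maf``), where
    array-detectable large QTL segregate. With a multiplier of 1 the
    baseline draw is kept, so all effects stay i.i.d. normal. If
    ``tag_neighbor_max_bp`` is given, the large-effect QTL is drawn from
    SNPs whose nearest UHD neighbour lies within
    [``tag_neighbor_min_bp``, ``tag_neighbor_max_bp``], so the
    medium-density panel can include a strong — but not perfect — proxy.
    """
    if n_qtl < 2:
        raise ConfigError("need at least 2 QTL (large-effect and untagged)")
    if large_effect_multiplier < 1 or untagged_multiplier < 1:
        raise ConfigError("effect multipliers must be >= 1")
    rng = np.random.default_rng(seed)
    freq = genotypes.allele_frequencies()
    poly = np.flatnonzero((freq > 0) & (freq < 1))
    maf = np.minimum(freq, 1 - freq)
    common = np.flatnonzero(maf >= min_designated_maf)
    if len(poly) < n_qtl:
        raise DataError("fewer polymorphic SNPs than requested QTL")

    mmap = genotypes.map
    designed_pool = common if (large_effect_multiplier > 1 and len(common) >= n_qtl) else poly
    if tag_neighbor_max_bp is None:
        large_pool = designed_pool
    else:
        gaps = np.full(mmap.n_snps, np.iinfo(np.int64).max)
        for c in mmap.chromosomes:
            ix = mmap.chrom_index(c)
            d = np.diff(mmap.position_bp[ix])
            g = np.full(len(ix), np.iinfo(np.int64).max)
            g[:-1] = np.minimum(g[:-1], d)
            g[1:] = np.minimum(g[1:], d)
            gaps[ix] = g
        close = np.flatnonzero((gaps <= tag_neighbor_max_bp)
                               & (gaps >= tag_neighbor_min_bp))
        large_pool = np.intersect1d(designed_pool, close)
        if len(large_pool) == 0:
            large_pool = np.intersect1d(poly, close)
        if len(large_pool) == 0:
            raise DataError("no polymorphic SNP has a neighbour within tag_neighbor_max_bp")
    large = int(rng.choice(large_pool))
    untag_pool = designed_pool if untagged_multiplier > 1 else poly
    untag_pool = untag_pool[untag_pool != large]
    untagged = int(rng.choice(untag_pool))
    rest_pool = poly[(poly != large) & (poly != untagged)]
    rest = rng.choice(rest_pool, size=n_qtl - 2, replace=False)
    qtl = np.concatenate([[large, untagged], rest])
    effects = rng.normal(size=len(qtl))
    if large_effect_multiplier > 1:
        effects[0] = np.sign(effects[0]) * large_effect_multiplier
    else:
        effects[0] *= large_effect_multiplier
    if untagged_multiplier > 1:
        effects[1] = np.sign(effects[1]) * untagged_multiplier
    else:
        effects[1] *= untagged_multiplier
    return QtlArchitecture(qtl, effects, int(large), int(untagged))


def make_md_panel(
    uhd: GenotypeMatrix,
    n_md: int,
    qtl: QtlArchitecture,
    untag_window_bp: int = 2_000_000,
    seed: int = 0,
    tag_large_qtl: bool = True,
) -> GenotypeMatrix:
    """Flag an approximately evenly spaced medium-density subset of the UHD map.

    Excluded from the MD panel are all QTL SNPs themselves and every SNP
    within ``untag_window_bp`` of the designated untagged QTL, so that locus
    has no close MD proxy. If ``tag_large_qtl`` the nearest eligible SNP to
    the large-effect QTL is forced into the panel (the mechanism the panel
    is meant to model: commercial arrays tag known large QTL well).

    Returns the same matrix with ``is_md`` updated on its map.
    """
    mmap = uhd.map
    if n_md >= mmap.n_snps:
        raise ConfigError("n_md must be smaller than the UHD SNP count")
    eligible = np.ones(mmap.n_snps, dtype=bool)
    eligible[qtl.qtl_indices] = False
    uc = mmap.chromosome[qtl.untagged_index]
    upos = mmap.position_bp[qtl.untagged_index]
    eligible &= ~((mmap.chromosome == uc)
                  & (np.abs(mmap.position_bp - upos) <= untag_window_bp))
    n_eligible = int(eligible.sum())
    if n_md > n_eligible:
        raise ConfigError(f"only {n_eligible} SNPs eligible for an MD panel of {n_md}")

    chroms = mmap.chromosomes
    counts = np.array([int(eligible[mmap.chrom_index(c)].sum()) for c in chroms])
    # largest-remainder apportionment of n_md across chromosomes
    quota = n_md * counts / counts.sum()
    alloc = np.floor(quota).astype(int)
    order = np.argsort(-(quota - alloc))
    for i in order[: n_md - alloc.sum()]:
        alloc[i] += 1
    alloc = np.minimum(alloc, counts)
    short = n_md - alloc.sum()
    while short > 0:  # spill over if a chromosome saturated
        for i in np.argsort(alloc - counts):
            if alloc[i] < counts[i]:
                alloc[i] += 1
                short -= 1
                if short == 0:
                    break

    is_md = np.zeros(mmap.n_snps, dtype=bool)
    for c, k in zip(chroms, alloc):
        ix = mmap.chrom_index(c)
        el = ix[eligible[ix]]
        if k == 0 or len(el) == 0:
            continue
        pick = el[np.unique(np.round(np.linspace(0, len(el) - 1, k)).astype(int))]
        is_md[pick] = True

    if tag_large_qtl:
        lc = mmap.chromosome[qtl.large_effect_index]
        lpos = mmap.position_bp[qtl.large_effect_index]
        cand = np.flatnonzero(eligible & (mmap.chromosome == lc))
        if len(cand):
            tag = cand[np.argmin(np.abs(mmap.position_bp[cand] - lpos))]
            if not is_md[tag]:
                # swap out the currently selected SNP nearest to the tag
                sel = np.flatnonzero(is_md & (mmap.chromosome == lc))
                if len(sel) and is_md.sum() >= n_md:
                    drop = sel[np.argmin(np.abs(mmap.position_bp[sel] - lpos))]
                    is_md[drop] = False
                is_md[tag] = True

    new_map = MarkerMap(mmap.snp_id, mmap.chromosome, mmap.position_bp, is_md)
    return GenotypeMatrix(uhd.dosage, uhd.animal_ids, new_map)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class TraitSimConfig:
    """Variance partition and fixed-effect structure of the simulated trait.

    Fractions are of the phenotypic variance of the random part (QTL +
    polygenic + litter + noise), which is scaled to 1. Contemporary-group
    effects and the covariate are fixed effects added on top (they are what
    pre-correction removes).
    """

    h2_qtl: float = 0.40
    h2_polygenic: float = 0.15
    litter_var_frac: float = 0.10
    n_contemporary_groups: int = 20
    cg_effect_sd: float = 0.5
    covariate_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.h2_qtl, self.h2_polygenic, self.litter_var_frac)
        if any(f < 0 for f in fracs) or sum(fracs) >= 1:
            raise ConfigError("variance fractions must be non-negative and sum to < 1")
        if self.n_contemporary_groups < 1:
            raise ConfigError("need at least one contemporary group")


@dataclass
class SimulatedTrait:
    """Phenotype table plus the simulation truth needed for evaluation."""

    phenotypes: pd.DataFrame  # animal_id, raw_y, cg, litter, covariate
    true_genetic: pd.Series  # QTL score + polygenic value, indexed by animal_id
    qtl_score: pd.Series
    scaled_effects: np.ndarray  # allele-substitution effects on the trait scale
    config: TraitSimConfig


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    qtl: QtlArchitecture,
    config: TraitSimConfig,
    phenotype_founders: bool = False,
) -> SimulatedTrait:
    """Simulate phenotypes: CG + covariate + QTL + polygenic + litter + noise.

    The polygenic term follows the pedigree covariance: founders are
    N(0, σ²_pg) and offspring are the parental mean plus a Mendelian-sampling
    deviation with variance σ²_pg·(½ − ¼(F_sire + F_dam)). QTL effects are
    rescaled so the realized QTL-score variance among phenotyped animals
    equals ``h2_qtl``. Deterministic given ``config.seed``.
    """
    from .kinship import inbreeding_coefficients  # local import avoids cycle at import time

    rng = np.random.default_rng(config.seed)
    rows = pedigree.rows(genotypes.animal_ids)
    if not np.array_equal(rows, np.arange(pedigree.n)) and len(genotypes.animal_ids) < pedigree.n:
        raise DataError("all pedigree animals must be genotyped in the UHD matrix")

    pheno_mask = np.ones(pedigree.n, bool) if phenotype_founders else ~pedigree.is_founder
    if not pheno_mask.any():
        raise ConfigError("no phenotyped animals (pedigree has no offspring)")

    # QTL score, rescaled to hit the configured variance among phenotyped animals
    X = genotypes.dosage[:, qtl.qtl_indices].astype(np.float64)
    score = X @ qtl.effects
    sd = score[pheno_mask].std()
    if config.h2_qtl > 0:
        if sd == 0:
            raise DataError("QTL score is constant; cannot scale to target variance")
        scale = np.sqrt(config.h2_qtl) / sd
    else:
        scale = 0.0
    eff = qtl.effects * scale
    score = score * scale

    # polygenic term by mean-parental recursion with Mendelian sampling
    s2_pg = config.h2_polygenic
    u = np.zeros(pedigree.n)
    if s2_pg > 0:
        F = inbreeding_coefficients(pedigree)
        sire_row, dam_row = pedigree.parent_rows()
        z = rng.normal(size=pedigree.n)
        for i in range(pedigree.n):
            s, d = sire_row[i], dam_row[i]
            if s == -1:
                u[i] = z[i] * np.sqrt(s2_pg)
            else:
                msv = s2_pg * (0.5 - 0.25 * (F[s] + F[d]))
                u[i] = 0.5 * (u[s] + u[d]) + z[i] * np.sqrt(max(msv, 0.0))

    # common litter
    litters = pedigree.litter_id
    uniq_l = np.unique(litters[pheno_mask])
    l_eff = dict(zip(uniq_l, rng.normal(0.0, np.sqrt(config.litter_var_frac), len(uniq_l))))
    litter_term = np.array([l_eff.get(l, 0.0) for l in litters])

    # contemporary groups: allocated within generation (CG never spans generations)
    gens = np.unique(pedigree.generation[pheno_mask])
    n_per_gen = np.array([np.sum(pedigree.generation[pheno_mask] == g) for g in gens])
    quota = config.n_contemporary_groups * n_per_gen / n_per_gen.sum()
    g_alloc = np.maximum(1, np.round(quota).astype(int))
    cg = np.zeros(pedigree.n, dtype=np.int64)
    next_cg = 1
    for g, k in zip(gens, g_alloc):
        sel = np.flatnonzero(pheno_mask & (pedigree.generation == g))
        cg[sel] = next_cg + rng.integers(0, k, size=len(sel))
        next_cg += k
    n_cg_total = next_cg - 1
    cg_effects = rng.normal(0.0, config.cg_effect_sd, n_cg_total + 1)
    cg_term = np.where(cg > 0, cg_effects[cg], 0.0)

    covariate = rng.normal(size=pedigree.n)
    noise_sd = np.sqrt(1.0 - config.h2_qtl - config.h2_polygenic - config.litter_var_frac)
    e = rng.normal(0.0, noise_sd, pedigree.n)

    raw_y = cg_term + config.covariate_slope * covariate + score + u + litter_term + e

    sel = np.flatnonzero(pheno_mask)
    ids = pedigree.animal_id[sel]
    table = pd.DataFrame(
        {
            "animal_id": ids,
            "raw_y": raw_y[sel],
            "cg": cg[sel],
            "litter": litters[sel],
            "covariate": covariate[sel],
        }
    )
    return SimulatedTrait(
        phenotypes=table,
        true_genetic=pd.Series((score + u)[sel], index=ids),
        qtl_score=pd.Series(score[sel], index=ids),
        scaled_effects=eff,
        config=config,
    )


# ---------------------------------------------------------------------------
# genotyping masks


def mask_genotyped(animal_ids, pct: int, seed: int = 0) -> set:
    """Random subset of ``⌊pct·n/100⌋`` animal ids, nested across pct.

    The same seed yields nested subsets: the 20% set is contained in the 50%
    set, etc., so genotyping scenarios differ only by added genotypes.
    """
    if not 0 <= pct <= 100:
        raise ConfigError("pct must be in [0, 100]")
    ids = np.asarray(animal_ids)
    perm = np.random.default_rng(seed).permutation(ids)
    k = int(np.floor(pct * len(ids) / 100))
    return set(int(a) for a in perm[:k])


def add_missingness(genotypes: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set a random fraction of dosages to missing (to exercise QC filters)."""
    if not 0 <= rate < 1:
        raise ConfigError("missingness rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    d = genotypes.dosage.copy()
    d[rng.random(d.shape) < rate] = MISSING
    return GenotypeMatrix(d, genotypes.animal_ids, genotypes.map)
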