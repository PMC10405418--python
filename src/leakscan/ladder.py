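"""Orchestrate the full ladder experiment from a single config.

simulate → pre-correct → fit the model ladder (PBLUP, ssGBLUP at graded
genotyping percentages, BRR, BayesC, BayesB) → residual-GWAS scans per
model × panel × set → cross-scenario summary. Everything is reproducible
from the config plus a single master seed; per-stage seeds are derived
deterministically from it.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinship import a_inverse, a_matrix
from .mme import VarianceComponents, precorrect_phenotypes
from .pedigree import ConfigError, Pedigree, simulate_pedigree
from .predictors import BayesianWGR, GibbsConfig, PedigreeBLUP, SingleStepGBLUP
from .scan import ResidualGWAS, ScanResults, qc_filter
from .simdata import (GenotypeMatrix, QtlArchitecture, SimulatedTrait,
                      TraitSimConfig, add_missingness, assign_qtl, gene_drop,
                      make_md_panel, mask_genotyped, random_marker_map,
                      simulate_founder_haplotypes, simulate_phenotypes)

ALL_MODELS = ("PBLUP", "ssGBLUP_20", "ssGBLUP_50", "ssGBLUP_80", "ssGBLUP_100",
              "BRR", "BayesC", "BayesB")


@dataclass
class SimulationConfig:
    """Population, genome, QTL and trait settings for one simulated study.

    Defaults define a constant-size five-generation breeding population of
    2,500 phenotyped animals (500 founders, single-pair matings, two
    offspring per litter; the last generation is the 500-animal testing
    set, so training has 2,000 animals), a 5 × 50 Mb genome with 10,000 UHD
    SNPs of which 1,000 form the MD panel, and 30 additive QTL including a
    large-effect QTL with a strong-but-imperfect MD tag (nearest UHD
    neighbour 10-20 kb away, r² ≈ 0.96-0.98 at the default LD decay) and an
    untagged QTL whose 2 Mb neighbourhood is excluded from the MD panel.
    """

    n_founders: int = 500
    n_generations: int = 5
    n_dams_per_sire: int = 1
    litter_size: int = 2
    n_chromosomes: int = 5
    snps_per_chromosome: int = 2000
    chromosome_length_bp: int = 50_000_000
    maf_range: list = field(default_factory=lambda: [0.1, 0.5])
    ld_decay: float = 1e-6
    recomb_rate_per_bp: float = 1e-8
    n_qtl: int = 30
    large_effect_multiplier: float = 4.0
    untagged_multiplier: float = 2.5
    tag_neighbor_min_bp: int = 10_000
    tag_neighbor_max_bp: int = 20_000
    n_md: int = 1000
    untag_window_bp: int = 2_000_000
    h2_qtl: float = 0.45
    h2_polygenic: float = 0.05
    litter_var_frac: float = 0.10
    n_contemporary_groups: int = 20
    cg_effect_sd: float = 0.5
    covariate_slope: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.maf_range = list(self.maf_range)


@dataclass
class LadderConfig:
    """Scenario grid plus analysis settings for one ladder run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    models: list = field(default_factory=lambda: list(ALL_MODELS))
    panels: list = field(default_factory=lambda: ["MD", "UHD"])
    sets: list = field(default_factory=lambda: ["training", "testing"])
    fdr_target: float = 0.01
    n_testing_generations: int = 1
    blend_weight: float = 0.95
    tune_g: bool = True
    gibbs_n_iter: int = 2500
    gibbs_burn_in: int = 800
    gibbs_thin: int = 2
    md_maf_min: float = 0.01
    md_call_rate_min: float = 0.8
    uhd_maf_min: float = 0.001
    uhd_call_rate_min: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.models = list(self.models)
        self.panels = list(self.panels)
        self.sets = list(self.sets)
        if not self.models:
            raise ConfigError("model list must be non-empty")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ConfigError(f"unknown models: {sorted(unknown)}")
        if not 0 < self.fdr_target < 1:
            raise ConfigError("fdr_target must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LadderConfig":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "LadderConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def stage_seeds(self) -> dict:
        names = ["pedigree", "haplotypes", "gene_drop", "qtl", "md_panel",
                 "phenotypes", "masks", "gibbs", "missing"]
        state = np.random.SeedSequence(self.master_seed).generate_state(len(names))
        return {k: int(s % (2**31)) for k, s in zip(names, state)}


@dataclass
class SimulatedPopulation:
    """One simulated study: pedigree, genotypes (MD flagged), QTL, trait."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    qtl: QtlArchitecture
    trait: SimulatedTrait

    @property
    def large_qtl_locus(self) -> tuple[int, int]:
        m = self.genotypes.map
        i = self.qtl.large_effect_index
        return int(m.chromosome[i]), int(m.position_bp[i])

    @property
    def untagged_qtl_locus(self) -> tuple[int, int]:
        m = self.genotypes.map
        i = self.qtl.untagged_index
        return int(m.chromosome[i]), int(m.position_bp[i])


def simulate_population(config: LadderConfig) -> SimulatedPopulation:
    """Run the full synthetic-data pipeline for one master seed."""
    sim = config.simulation
    seeds = config.stage_seeds()
    ped = simulate_pedigree(sim.n_founders, sim.n_generations, sim.n_dams_per_sire,
                            sim.litter_size, seed=seeds["pedigree"])
    mmap = random_marker_map(sim.n_chromosomes, sim.snps_per_chromosome,
                             sim.chromosome_length_bp, seed=seeds["haplotypes"])
    founders = simulate_founder_haplotypes(mmap, int(ped.is_founder.sum()),
                                           tuple(sim.maf_range), sim.ld_decay,
                                           seed=seeds["haplotypes"])
    uhd = gene_drop(ped, founders, mmap, sim.recomb_rate_per_bp, seed=seeds["gene_drop"])
    qtl = assign_qtl(uhd, sim.n_qtl, sim.large_effect_multiplier, seed=seeds["qtl"],
                     untagged_multiplier=sim.untagged_multiplier,
                     tag_neighbor_max_bp=sim.tag_neighbor_max_bp,
                     tag_neighbor_min_bp=sim.tag_neighbor_min_bp)
    uhd = make_md_panel(uhd, sim.n_md, qtl, sim.untag_window_bp, seed=seeds["md_panel"])
    trait_cfg = TraitSimConfig(
        h2_qtl=sim.h2_qtl, h2_polygenic=sim.h2_polygenic,
        litter_var_frac=sim.litter_var_frac,
        n_contemporary_groups=sim.n_contemporary_groups,
        cg_effect_sd=sim.cg_effect_sd, covariate_slope=sim.covariate_slope,
        seed=seeds["phenotypes"])
    trait = simulate_phenotypes(uhd, ped, qtl, trait_cfg)
    if sim.missing_rate > 0:
        uhd = add_missingness(uhd, sim.missing_rate, seed=seeds["missing"])
    return SimulatedPopulation(ped, uhd, qtl, trait)


@dataclass
class RunManifest:
    """Provenance record of one ladder run."""

    config: dict
    stage_seeds: dict
    version: str
    scan_files: dict
    qc_counts: dict
    runtimes: dict
    failures: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


class LadderResult:
    """All scans and fits of one ladder run, with a cross-scenario summary."""

    def __init__(self, config: LadderConfig, population: SimulatedPopulation,
                 scans: dict, fits: dict, manifest: RunManifest,
                 train_ids: np.ndarray, test_ids: np.ndarray):
        self.config = config
        self.population = population
        self.scans = scans  # (model, panel, set) -> ScanResults
        self.fits = fits  # model -> results object
        self.manifest = manifest
        self.train_ids = train_ids
        self.test_ids = test_ids

    def scan(self, model: str, panel: str, which_set: str = "training") -> ScanResults:
        return self.scans[(model, panel, which_set)]

    def summary(self, peak_window_bp: int = 1_000_000) -> pd.DataFrame:
        rows = []
        for (model, panel, which_set), scan in self.scans.items():
            t = scan.tested
            lam = scan.qq_data().inflation_factor if len(t) >= 10 else np.nan
            rows.append(
                {
                    "model": model,
                    "pct": _model_pct(model),
                    "panel": panel,
                    "set": which_set,
                    "n_tested": len(t),
                    "n_significant": scan.n_significant,
                    "max_neglog10_p": float(-np.log10(t["p_value"].min())) if len(t) else np.nan,
                    "inflation_factor": lam,
                    "n_peaks": len(scan.peaks(peak_window_bp)),
                }
            )
        return pd.DataFrame(rows)

    # ----- leakage diagnostics used by the acceptance properties -----

    def chromosomes_with_leakage(self, model: str, panel: str = "UHD",
                                 which_set: str = "training") -> int:
        t = self.scan(model, panel, which_set).tested
        return int(t.loc[t["significant"], "chromosome"].nunique())

    def significant_near(self, model: str, locus: tuple[int, int], panel: str = "UHD",
                         which_set: str = "training", window_bp: int = 1_000_000) -> bool:
        t = self.scan(model, panel, which_set).tested
        chrom, pos = locus
        sel = (t["significant"] & (t["chromosome"] == chrom)
               & (np.abs(t["position_bp"] - pos) <= window_bp))
        return bool(sel.any())

    def ssgblup_significance_counts(self, panel: str = "UHD",
                                    which_set: str = "training") -> list:
        counts = []
        for m in self.config.models:
            if m.startswith("ssGBLUP_"):
                counts.append(self.scan(m, panel, which_set).n_significant)
        return counts


def _model_pct(model: str):
    return int(model.split("_")[1]) if model.startswith("ssGBLUP_") else "n/a"


def run_ladder(config: LadderConfig, out_dir=None,
               population: SimulatedPopulation | None = None) -> LadderResult:
    """Execute the full experiment defined by ``config``.

    The training set is every phenotyped generation except the last
    ``n_testing_generations`` (forward prediction, like a birth-date split);
    models are fitted to training data only and testing residuals use
    training-fitted parameters. Scenario failures are collected in the
    manifest rather than aborting the remaining grid.
    """
    t_all = time.time()
    seeds = config.stage_seeds()
    runtimes, failures, qc_counts, scan_files = {}, {}, {}, {}

    t0 = time.time()
    pop = population if population is not None else simulate_population(config)
    runtimes["simulate"] = time.time() - t0
    ped, uhd, trait = pop.pedigree, pop.genotypes, pop.trait
    sim = config.simulation

    vc = VarianceComponents(
        sigma2_g=sim.h2_qtl + sim.h2_polygenic,
        sigma2_e=1.0 - sim.h2_qtl - sim.h2_polygenic - sim.litter_var_frac,
        sigma2_litter=sim.litter_var_frac)

    t0 = time.time()
    pheno = precorrect_phenotypes(trait.phenotypes, ped, vc,
                                  covariate_flag=sim.covariate_slope != 0)
    runtimes["precorrect"] = time.time() - t0

    gens = pheno["animal_id"].map(
        dict(zip(ped.animal_id, ped.generation))).to_numpy()
    test_gens = np.sort(np.unique(gens))[-config.n_testing_generations:]
    is_test = np.isin(gens, test_gens)
    y = pd.Series(pheno["precorrected_y"].to_numpy(), index=pheno["animal_id"].to_numpy())
    y_train, y_test = y[~is_test], y[is_test]
    train_ids, test_ids = y_train.index.to_numpy(), y_test.index.to_numpy()

    # QC'd scan panels over the phenotyped animals
    pheno_gm = uhd.subset_animals(pheno["animal_id"].to_numpy())
    panels = {}
    if "UHD" in config.panels:
        panels["UHD"] = qc_filter(pheno_gm, config.uhd_maf_min, config.uhd_call_rate_min)
        qc_counts["UHD"] = panels["UHD"].qc_log
    md_all = qc_filter(pheno_gm.md_panel(), config.md_maf_min, config.md_call_rate_min)
    qc_counts["MD"] = md_all.qc_log
    if "MD" in config.panels:
        panels["MD"] = md_all

    a_inv = a_matrix_cache = None
    needs_pedigree = any(m == "PBLUP" or m.startswith("ssGBLUP") for m in config.models)
    if needs_pedigree:
        t0 = time.time()
        a_inv = a_inverse(ped)
        a_matrix_cache = a_matrix(ped)
        runtimes["kinship"] = time.time() - t0

    vc_stage = VarianceComponents(sigma2_g=vc.sigma2_g, sigma2_e=vc.sigma2_e)
    gibbs_seed = seeds["gibbs"]
    fits = {}
    for model in config.models:
        t0 = time.time()
        try:
            if model == "PBLUP":
                fits[model] = PedigreeBLUP(y_train, ped, vc_stage, a_inv=a_inv).fit()
            elif model.startswith("ssGBLUP_"):
                pct = _model_pct(model)
                genotyped = mask_genotyped(train_ids, pct, seed=seeds["masks"])
                genotyped |= set(int(a) for a in test_ids)
                fits[model] = SingleStepGBLUP(
                    y_train, ped, md_all, genotyped, vc_stage,
                    blend_weight=config.blend_weight, tune=config.tune_g,
                    pct_genotyped=pct, a_inv=a_inv, a_full=a_matrix_cache).fit()
            else:  # BRR / BayesC / BayesB
                gcfg = GibbsConfig(n_iter=config.gibbs_n_iter,
                                   burn_in=config.gibbs_burn_in,
                                   thin=config.gibbs_thin,
                                   seed=gibbs_seed + {"BRR": 1, "BayesC": 2,
                                                      "BayesB": 3}[model])
                fits[model] = BayesianWGR(y_train, md_all, model, gcfg).fit()
        except Exception as exc:  # noqa: BLE001 - report per scenario
            failures[model] = repr(exc)
        runtimes[f"fit:{model}"] = time.time() - t0

    scans = {}
    t0 = time.time()
    for model, res in fits.items():
        for which_set, y_set in (("training", y_train), ("testing", y_test)):
            if which_set not in config.sets or len(y_set) == 0:
                continue
            resid = res.residuals(y_set)
            for panel_name, panel_gm in panels.items():
                gm_set = panel_gm.subset_animals(y_set.index.to_numpy())
                meta = {"model": model, "panel": panel_name, "set": which_set}
                scans[(model, panel_name, which_set)] = ResidualGWAS(
                    resid, gm_set, meta=meta).fit(config.fdr_target)
    runtimes["scan"] = time.time() - t0
    runtimes["total"] = time.time() - t_all

    manifest = RunManifest(config.to_dict(), seeds, __version__, scan_files,
                           qc_counts, runtimes, failures)
    result = LadderResult(config, pop, scans, fits, manifest, train_ids, test_ids)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (model, panel, which_set), scan in scans.items():
            f = out / f"scan_{model}_{panel}_{which_set}.tsv"
            scan.to_tsv(f)
            scan_files[f"{model}|{panel}|{which_set}"] = str(f)
        result.summary().to_csv(out / "summary.tsv", sep="\t", index=False,
                                float_format="%.6g")
        config.to_yaml(out / "config.yaml")
        manifest.to_json(out / "manifest.json")
    return result


def summarize_run(source) -> pd.DataFrame:
    """Cross-scenario summary table from a LadderResult or an output directory.

    For a directory, rows are re-derived from the scan TSV files listed in
    the manifest; missing files are reported and skipped.
    """
    if isinstance(source, LadderResult):
        return source.summary()
    out = Path(source)
    manifest = json.loads((out / "manifest.json").read_text())
    rows = []
    for key, f in manifest["scan_files"].items():
        model, panel, which_set = key.split("|")
        path = Path(f)
        if not path.exists():
            rows.append({"model": model, "panel": panel, "set": which_set,
                         "error": "missing scan file"})
            continue
        t = pd.read_csv(path, sep="\t")
        tested = t[np.isfinite(t["P"])]
        from scipy import stats as _st

        lam = float(np.median(_st.chi2.isf(tested["P"], df=1))
                    / _st.chi2.ppf(0.5, df=1)) if len(tested) >= 10 else np.nan
        rows.append(
            {
                "model": model,
                "pct": _model_pct(model),
                "panel": panel,
                "set": which_set,
                "n_tested": len(tested),
                "n_significant": int(tested["SIG"].sum()),
                "max_neglog10_p": float(-np.log10(tested["P"].min())) if len(tested) else np.nan,
                "inflation_factor": lam,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# replicated-experiment diagnostics


@dataclass
class ReplicateProperties:
    """Qualitative leakage properties measured over replicate ladder runs."""

    pblup_chroms_with_leakage: list
    ssgblup_counts: list  # one row of counts (20, 50, 80, 100) per replicate
    page_trend_p: float
    gaussian_retains_large_qtl: list  # per replicate: ssGBLUP_100 and BRR both flag it
    selection_clears_large_qtl: list  # per replicate: BayesC and BayesB both clear
    untagged_uhd_only: list  # per replicate: UHD-sig & MD-clean at the untagged QTL

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def page_trend_test(counts: np.ndarray) -> float:
    """Page's L test p-value for a decreasing trend across ordered scenarios."""
    from scipy.stats import page_trend_test as _page

    data = np.asarray(counts, dtype=float)
    # predicted ranks: later scenarios smaller -> reverse columns for scipy's
    # increasing-trend convention
    res = _page(data[:, ::-1], method="exact" if data.shape[0] <= 8 else "asymptotic")
    return float(res.pvalue)


def run_replicates(base_config: LadderConfig, seeds, window_bp: int = 1_000_000,
                   md_clear_window_bp: int | None = None) -> ReplicateProperties:
    """Run the ladder at several master seeds and measure the leakage properties.

    Per replicate: the number of chromosomes with significant PBLUP leakage,
    the ssGBLUP significance counts across genotyping percentages, whether
    the Gaussian genomic models (ssGBLUP_100, BRR) retain a significant peak
    near the large-effect QTL while the variable-selection models (BayesC,
    BayesB) do not, and whether the untagged QTL is flagged in UHD scans but
    clean in MD scans for the fully genotyped genomic models.
    """
    if md_clear_window_bp is None:
        md_clear_window_bp = base_config.simulation.untag_window_bp
    props = ReplicateProperties([], [], np.nan, [], [], [])
    for s in seeds:
        cfg = dataclasses.replace(base_config, master_seed=int(s))
        res = run_ladder(cfg)
        large = res.population.large_qtl_locus
        untag = res.population.untagged_qtl_locus
        props.pblup_chroms_with_leakage.append(
            res.chromosomes_with_leakage("PBLUP", "UHD"))
        props.ssgblup_counts.append(res.ssgblup_significance_counts("UHD"))
        gauss = all(res.significant_near(m, large, "UHD", window_bp=window_bp)
                    for m in ("ssGBLUP_100", "BRR"))
        clear = all(not res.significant_near(m, large, "UHD", window_bp=window_bp)
                    for m in ("BayesC", "BayesB"))
        props.gaussian_retains_large_qtl.append(bool(gauss))
        props.selection_clears_large_qtl.append(bool(clear))
        full_models = ("ssGBLUP_100", "BRR", "BayesC", "BayesB")
        uhd_hit = all(res.significant_near(m, untag, "UHD", window_bp=window_bp)
                      for m in full_models)
        md_clean = all(not res.significant_near(m, untag, "MD",
                                                window_bp=md_clear_window_bp)
                       for m in full_models)
        props.untagged_uhd_only.append(bool(uhd_hit and md_clean))
    counts = np.asarray(props.ssgblup_counts, dtype=float)
    if counts.shape[0] >= 2 and counts.shape[1] >= 3:
        props.page_trend_p = page_trend_test(counts)
    return props
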