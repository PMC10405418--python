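"""Genetic-evaluation model ladder: PBLUP, single-step GBLUP, Bayesian WGR.

Each model class is constructed from data and configuration; ``fit()``
returns a results object carrying per-animal genetic predictions, and the
results object computes residuals (pre-corrected phenotype minus prediction)
for training or testing animals. The ladder progresses from pedigree-only
information to genomic models with increasing prior density on large
effects:

* :class:`PedigreeBLUP` — additive values from the pedigree A matrix only.
* :class:`SingleStepGBLUP` — joint pedigree+genomic evaluation through H⁻¹,
  at any percentage of genotyped animals.
* :class:`BayesianWGR` — whole-genome regression on marker dosages with a
  Gaussian prior (BRR), a point mass + Gaussian slab (BayesC) or a point
  mass + scaled-t slab (BayesB), fitted by single-site Gibbs sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gibbs import MODEL_CODES, gibbs_kernel
from .kinship import (RelationshipMatrix, SparsePrecision, a_inverse, a_matrix,
                      blend_tune_g, g_matrix, h_inverse)
from .mme import VarianceComponents, precorrect_phenotypes, solve_animal_mme
from .pedigree import ConfigError, Pedigree
from .simdata import DataError, GenotypeMatrix

__all__ = [
    "VarianceComponents", "precorrect_phenotypes", "GibbsConfig",
    "PosteriorSummary", "PedigreeBLUP", "SingleStepGBLUP", "BayesianWGR",
    "BLUPResults", "WGRResults", "solve_pblup", "solve_ssgblup", "gibbs_wgr",
    "predict_out_of_sample", "model_fit_frame", "effective_sample_size",
]


# ---------------------------------------------------------------------------
# results containers


class _ResultsBase:
    """Common residual/summary logic: prediction includes the intercept."""

    scenario: dict

    def predict(self, animal_ids) -> pd.Series:
        raise NotImplementedError

    def residuals(self, y: pd.Series) -> pd.Series:
        """Residuals e = y − prediction for the animals indexing ``y``."""
        pred = self.predict(y.index.to_numpy())
        return y - pred

    def fit_frame(self, y: pd.Series, which_set: str = "training") -> pd.DataFrame:
        pred = self.predict(y.index.to_numpy())
        return pd.DataFrame(
            {
                "animal_id": y.index.to_numpy(),
                "set": which_set,
                "model": self.scenario.get("model", ""),
                "pct": self.scenario.get("pct_genotyped", ""),
                "panel": self.scenario.get("panel", ""),
                "prediction": pred.to_numpy(),
                "residual": (y - pred).to_numpy(),
            }
        )


@dataclass
class BLUPResults(_ResultsBase):
    """Solution of an animal-model MME (PBLUP or ssGBLUP)."""

    intercept: float
    u: pd.Series  # additive values for every pedigree animal
    vc: VarianceComponents
    scenario: dict = field(default_factory=dict)

    def predict(self, animal_ids) -> pd.Series:
        return self.intercept + self.u.reindex(np.asarray(animal_ids))

    def summary(self) -> str:
        s = self.scenario
        lines = [
            f"{s.get('model', 'BLUP')} animal model "
            f"(pct genotyped: {s.get('pct_genotyped', 'n/a')})",
            f"  animals in pedigree : {len(self.u)}",
            f"  intercept           : {self.intercept:.6g}",
            f"  lambda (sigma_e^2/sigma_g^2): {self.vc.lambda_g:.4g}",
            f"  sd of additive values: {self.u.std():.6g}",
        ]
        return "\n".join(lines)


@dataclass
class PosteriorSummary:
    """Posterior means from a Gibbs run, per SNP and for the variances."""

    snp_ids: np.ndarray
    effect_mean: np.ndarray
    inclusion_prob: np.ndarray
    sigma2_e: float
    sigma2_b: float
    pi: float
    ess_sigma2_e: float
    sigma2_e_chain: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "post_mean_effect": self.effect_mean,
             "inclusion_prob": self.inclusion_prob}
        )


@dataclass
class WGRResults(_ResultsBase):
    """Posterior-mean predictor from a Bayesian whole-genome regression."""

    posterior: PosteriorSummary
    intercept: float
    col_means: np.ndarray
    model: object  # the parent BayesianWGR
    scenario: dict = field(default_factory=dict)

    def predict_dosages(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + (X - self.col_means) @ self.posterior.effect_mean

    def predict(self, animal_ids) -> pd.Series:
        gm: GenotypeMatrix = self.model.genotypes
        sub = gm.subset_animals(np.asarray(animal_ids))
        X = sub.dosages_float(impute_mean=True)
        X = np.where(np.isnan(X), self.col_means, X)
        return pd.Series(self.predict_dosages(X), index=np.asarray(animal_ids))

    def summary(self) -> str:
        po = self.posterior
        lines = [
            f"{self.scenario.get('model', 'WGR')} whole-genome regression",
            f"  markers             : {len(po.effect_mean)}",
            f"  intercept           : {self.intercept:.6g}",
            f"  post. mean sigma2_e : {po.sigma2_e:.6g} (ESS {po.ess_sigma2_e:.0f})",
            f"  post. mean sigma2_b : {po.sigma2_b:.6g}",
            f"  post. mean pi       : {po.pi:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# PBLUP


class PedigreeBLUP:
    """Pedigree BLUP: y = 1·mu + u + e with u ~ N(0, A·sigma2_g).

    ``y`` is a Series of pre-corrected phenotypes indexed by animal id
    (training animals); predictions are produced for every pedigree animal
    through the joint MME, so testing animals are predicted by relationship.
    """

    def __init__(self, y: pd.Series, pedigree: Pedigree, vc: VarianceComponents,
                 a_inv: SparsePrecision | None = None):
        self.y = y
        self.pedigree = pedigree
        self.vc = vc
        self.a_inv = a_inv if a_inv is not None else a_inverse(pedigree)

    def fit(self, method: str = "auto") -> BLUPResults:
        mu, u = solve_animal_mme(self.y, self.a_inv, self.vc.lambda_g, method=method)
        return BLUPResults(mu, u, self.vc,
                           scenario={"model": "PBLUP", "pct_genotyped": "n/a"})


# ---------------------------------------------------------------------------
# ssGBLUP


class SingleStepGBLUP:
    """Single-step GBLUP: PBLUP's MME with A⁻¹ replaced by H⁻¹.

    ``genotypes`` is the marker panel used to build G (typically the
    medium-density panel); ``genotyped_ids`` the animals whose genotypes
    enter H for this scenario. G is VanRaden method 1, tuned to A22 and
    blended as G* = w·G + (1−w)·A22 before inversion.
    """

    def __init__(self, y: pd.Series, pedigree: Pedigree, genotypes: GenotypeMatrix,
                 genotyped_ids, vc: VarianceComponents, blend_weight: float = 0.95,
                 tune: bool = True, pct_genotyped=None,
                 a_inv: SparsePrecision | None = None,
                 a_full: RelationshipMatrix | None = None):
        self.y = y
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.genotyped_ids = np.asarray(sorted(genotyped_ids), dtype=np.int64)
        self.vc = vc
        self.blend_weight = blend_weight
        self.tune = tune
        self.pct_genotyped = pct_genotyped
        self.a_inv = a_inv if a_inv is not None else a_inverse(pedigree)
        self.a_full = a_full

    def fit(self, method: str = "auto") -> BLUPResults:
        label = (f"ssGBLUP_{self.pct_genotyped}" if self.pct_genotyped is not None
                 else "ssGBLUP")
        if len(self.genotyped_ids) == 0:
            mu, u = solve_animal_mme(self.y, self.a_inv, self.vc.lambda_g, method=method)
            return BLUPResults(mu, u, self.vc,
                               scenario={"model": label, "pct_genotyped": self.pct_genotyped})
        a_full = self.a_full if self.a_full is not None else a_matrix(self.pedigree)
        A22 = a_full.subset(self.genotyped_ids, kind="A22")
        G = g_matrix(self.genotypes.subset_animals(self.genotyped_ids))
        G_star = blend_tune_g(G, A22, self.blend_weight, self.tune)
        h_inv = h_inverse(self.a_inv, A22, G_star, self.genotyped_ids)
        mu, u = solve_animal_mme(self.y, h_inv, self.vc.lambda_g, method=method)
        return BLUPResults(mu, u, self.vc,
                           scenario={"model": label, "pct_genotyped": self.pct_genotyped})


# ---------------------------------------------------------------------------
# Bayesian whole-genome regression


@dataclass
class GibbsConfig:
    """Chain and prior settings for the whole-genome regression samplers.

    Priors follow common whole-genome-regression defaults: scaled inverse
    chi-square priors with 5 degrees of freedom for the variances, scales set
    so the prior *expected* variances correspond to the model explaining
    ``prior_R2`` of the phenotypic variance, and a Beta(5, 5) prior on the
    proportion of non-zero effects (prior mean 0.5).
    """

    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 5
    prior_df: float = 5.0
    prior_R2: float = 0.5
    pi_shape1: float = 5.0
    pi_shape2: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if not 0 < self.prior_R2 < 1:
            raise ConfigError("prior_R2 must be in (0, 1)")
        if self.thin < 1 or self.prior_df <= 2:
            raise ConfigError("thin must be >= 1 and prior_df > 2")


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS from the initial positive sequence of autocorrelations."""
    x = np.asarray(chain, dtype=np.float64)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 2, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


class BayesianWGR:
    """Bayesian whole-genome regression fitted by single-site Gibbs sampling.

    Parameters
    ----------
    y : pd.Series
        Pre-corrected phenotypes indexed by animal id; every animal must be
        genotyped (the Bayesian rungs of the ladder are fitted with all
        animals genotyped).
    genotypes : GenotypeMatrix
        Marker panel; columns are centered internally.
    prior : {"BRR", "BayesC", "BayesB"}
    config : GibbsConfig
    pi_fixed : float, optional
        Hold the inclusion proportion fixed (e.g. 1.0 turns BayesC into BRR).
    """

    def __init__(self, y: pd.Series, genotypes: GenotypeMatrix, prior: str = "BRR",
                 config: GibbsConfig | None = None, pi_fixed: float | None = None):
        if prior not in MODEL_CODES:
            raise ConfigError(f"unknown prior {prior!r}")
        if not np.all(np.isfinite(y.to_numpy(dtype=np.float64))):
            raise DataError("phenotypes contain non-finite values")
        self.y = y
        self.genotypes = genotypes
        self.prior = prior
        self.config = config if config is not None else GibbsConfig()
        self.pi_fixed = -1.0 if pi_fixed is None else float(pi_fixed)

    def fit(self) -> WGRResults:
        cfg = self.config
        gm = self.genotypes.subset_animals(self.y.index.to_numpy())
        X = gm.dosages_float(impute_mean=True)
        col_means = X.mean(axis=0)
        Xc = np.asfortranarray(X - col_means)
        yv = self.y.to_numpy(dtype=np.float64)
        n, p = Xc.shape

        vy = float(np.var(yv))
        if vy == 0:
            vy = 1.0
        df = cfg.prior_df
        # scales chosen so the prior EXPECTED variances split var(y) as
        # prior_R2 (markers) vs 1 - prior_R2 (residual)
        S_e = vy * (1.0 - cfg.prior_R2) * (df - 2.0) / df
        msx = float(np.sum(Xc * Xc) / n)
        if msx == 0:
            msx = 1.0
        pi0 = (cfg.pi_shape1 / (cfg.pi_shape1 + cfg.pi_shape2)
               if self.pi_fixed < 0 else max(self.pi_fixed, 1e-8))
        frac_in = 1.0 if self.prior == "BRR" else pi0
        S_b = vy * cfg.prior_R2 / (msx * frac_in) * (df - 2.0) / df

        (beta, incl, mu, s2e, s2b, pi, se_chain) = gibbs_kernel(
            yv, Xc, MODEL_CODES[self.prior], cfg.n_iter, cfg.burn_in, cfg.thin,
            df, S_e, df, S_b, cfg.pi_shape1, cfg.pi_shape2, self.pi_fixed,
            cfg.seed % (2**31),
        )
        posterior = PosteriorSummary(
            snp_ids=gm.map.snp_id, effect_mean=beta, inclusion_prob=incl,
            sigma2_e=float(s2e), sigma2_b=float(s2b), pi=float(pi),
            ess_sigma2_e=effective_sample_size(se_chain), sigma2_e_chain=se_chain,
        )
        return WGRResults(posterior, float(mu), col_means, self,
                          scenario={"model": self.prior, "pct_genotyped": 100})


# ---------------------------------------------------------------------------
# functional facade


def solve_pblup(y: pd.Series, a_inv: SparsePrecision, vc: VarianceComponents,
                pedigree: Pedigree | None = None, method: str = "auto") -> BLUPResults:
    """Pedigree BLUP from a precomputed A⁻¹ (functional form)."""
    mu, u = solve_animal_mme(y, a_inv, vc.lambda_g, method=method)
    return BLUPResults(mu, u, vc, scenario={"model": "PBLUP", "pct_genotyped": "n/a"})


def solve_ssgblup(y: pd.Series, h_inv, vc: VarianceComponents,
                  scenario_pct=None, method: str = "auto") -> BLUPResults:
    """ssGBLUP from a prebuilt H⁻¹ (functional form)."""
    mu, u = solve_animal_mme(y, h_inv, vc.lambda_g, method=method)
    label = f"ssGBLUP_{scenario_pct}" if scenario_pct is not None else "ssGBLUP"
    return BLUPResults(mu, u, vc, scenario={"model": label, "pct_genotyped": scenario_pct})


def gibbs_wgr(y: pd.Series, genotypes: GenotypeMatrix, prior: str,
              config: GibbsConfig, pi_fixed: float | None = None):
    """Fit a Bayesian WGR; returns (PosteriorSummary, WGRResults)."""
    res = BayesianWGR(y, genotypes, prior, config, pi_fixed=pi_fixed).fit()
    return res.posterior, res


def predict_out_of_sample(results: _ResultsBase, y_test: pd.Series,
                          which_set: str = "testing") -> pd.DataFrame:
    """Out-of-sample ModelFit rows: predictions from the training fit only."""
    return results.fit_frame(y_test, which_set=which_set)


def model_fit_frame(results: _ResultsBase, y_train: pd.Series,
                    y_test: pd.Series | None = None, panel: str = "") -> pd.DataFrame:
    """ModelFit table (training + optional testing) for one fitted scenario."""
    frames = [results.fit_frame(y_train, "training")]
    if y_test is not None and len(y_test):
        frames.append(results.fit_frame(y_test, "testing"))
    out = pd.concat(frames, ignore_index=True)
    if panel:
        out["panel"] = panel
    return out
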