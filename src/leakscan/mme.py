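"""Mixed-model equations: phenotype pre-correction and animal-model solvers.

The animal-model MME solved here has an intercept as the only fixed effect
(the genetic-evaluation stages run on pre-corrected phenotypes); the
pre-correction stage fits contemporary group and an optional covariate as
fixed effects together with common-litter and pedigree-animal random
effects, and strips the non-genetic terms from the raw phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kinship import HInverse, NumericalError, SparsePrecision
from .pedigree import ConfigError, Pedigree
from .simdata import DataError

# systems at or below this size are solved densely; above, by Jacobi-PCG
DENSE_LIMIT = 4000


@dataclass
class VarianceComponents:
    """Variance components (trait units²) driving the BLUP shrinkage."""

    sigma2_g: float
    sigma2_e: float
    sigma2_litter: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_g <= 0 or self.sigma2_e <= 0:
            raise ConfigError("genetic and residual variances must be positive")
        if self.sigma2_litter < 0:
            raise ConfigError("litter variance must be non-negative")

    @property
    def lambda_g(self) -> float:
        return self.sigma2_e / self.sigma2_g

    @property
    def lambda_litter(self) -> float:
        if self.sigma2_litter == 0:
            raise ConfigError("litter variance is zero; no litter effect in the model")
        return self.sigma2_e / self.sigma2_litter


def precorrect_phenotypes(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    vc: VarianceComponents,
    covariate_flag: bool = False,
) -> pd.DataFrame:
    """Adjust phenotypes for contemporary group, covariate and litter.

    Fits y = CG + (covariate) + litter + animal + e by the mixed-model
    equations (animal effects with A⁻¹·λ_g over the full pedigree, litter
    i.i.d. with λ_litter) and returns a copy of the table with
    ``precorrected_y = raw_y − ĈG − covariate·β̂ − litter̂``; the genetic
    effect and residual stay in the pre-corrected value.
    """
    from .kinship import a_inverse

    df = phenotypes.reset_index(drop=True)
    if df["cg"].nunique() < 1 or (df.groupby("cg").size() < 1).any():
        raise DataError("every contemporary group needs at least one record")
    n = len(df)
    y = df["raw_y"].to_numpy(dtype=np.float64)

    cg_codes, _ = pd.factorize(df["cg"])
    n_cg = cg_codes.max() + 1
    X_parts = [sp.csr_matrix((np.ones(n), (np.arange(n), cg_codes)), shape=(n, n_cg))]
    if covariate_flag:
        if "covariate" not in df or df["covariate"].isna().any():
            raise DataError("covariate requested but missing from the phenotype table")
        X_parts.append(sp.csr_matrix(df["covariate"].to_numpy()[:, None]))
    X = sp.hstack(X_parts, format="csr")
    n_fix = X.shape[1]

    lit_codes, _ = pd.factorize(df["litter"])
    n_lit = lit_codes.max() + 1
    Zl = sp.csr_matrix((np.ones(n), (np.arange(n), lit_codes)), shape=(n, n_lit))

    rows = pedigree.rows(df["animal_id"].to_numpy())
    Za = sp.csr_matrix((np.ones(n), (np.arange(n), rows)), shape=(n, pedigree.n))

    W = sp.hstack([X, Zl, Za], format="csr")
    C = (W.T @ W).tolil()
    lam_l = vc.lambda_litter if vc.sigma2_litter > 0 else None
    if lam_l is None and n_lit > 0:
        # no litter variance: drop litter from the model by an infinite penalty
        lam_l = 1e12
    a_inv = a_inverse(pedigree)
    C = C.tocsr()
    reg = sp.block_diag(
        [sp.csr_matrix((n_fix, n_fix)), lam_l * sp.identity(n_lit),
         vc.lambda_g * a_inv.matrix], format="csr")
    C = C + reg
    rhs = W.T @ y
    try:
        sol = spla.spsolve(C.tocsc(), rhs)
    except RuntimeError as exc:  # pragma: no cover
        raise DataError("singular pre-correction equations") from exc
    if np.any(~np.isfinite(sol)):
        raise DataError("singular fixed-effect block in pre-correction")

    fixed = X @ sol[:n_fix]
    litter_hat = Zl @ sol[n_fix : n_fix + n_lit]
    out = df.copy()
    out["precorrected_y"] = y - fixed - litter_hat
    out.attrs["fixed_solutions"] = sol[:n_fix]
    out.attrs["cg_solutions"] = sol[:n_cg]
    out.attrs["covariate_slope"] = float(sol[n_cg]) if covariate_flag else None
    out.attrs["litter_solutions"] = sol[n_fix : n_fix + n_lit]
    return out


def solve_animal_mme(
    y: pd.Series,
    k_inv,
    lambda_g: float,
    method: str = "auto",
    tol: float = 1e-10,
    maxiter: int = 10_000,
) -> tuple[float, pd.Series]:
    """Solve the intercept + animal-effect MME for all pedigree animals.

    ``y`` is indexed by the observed (phenotyped) animal ids; ``k_inv`` is a
    :class:`SparsePrecision` (A⁻¹) or :class:`HInverse` over the full
    pedigree ordering. Returns the intercept and the additive-value solution
    for every animal in the pedigree (animals without records are predicted
    through their relationships). Method "dense" uses a symmetric direct
    solve, "pcg" preconditioned conjugate gradients with a Jacobi
    preconditioner (relative residual tolerance ``tol``).
    """
    if lambda_g <= 0:
        raise ConfigError("lambda must be positive")
    ids = k_inv.animal_ids if isinstance(k_inv, SparsePrecision) else k_inv.animal_ids
    n_all = len(ids)
    lookup = {a: i for i, a in enumerate(ids)}
    try:
        obs = np.array([lookup[a] for a in y.index.to_numpy()])
    except KeyError as exc:
        raise DataError(f"phenotyped animal {exc.args[0]} not in pedigree") from None
    n_obs = len(obs)
    if n_obs == 0:
        raise DataError("no observations")
    yv = y.to_numpy(dtype=np.float64)

    zt_y = np.zeros(n_all)
    np.add.at(zt_y, obs, yv)
    ztz = np.zeros(n_all)
    np.add.at(ztz, obs, 1.0)
    rhs = np.concatenate([[yv.sum()], zt_y])

    n_eq = n_all + 1
    if method == "auto":
        method = "dense" if n_eq <= DENSE_LIMIT else "pcg"

    if method == "dense":
        K = k_inv.to_dense() if isinstance(k_inv, HInverse) else k_inv.to_dense()
        C = np.zeros((n_eq, n_eq))
        C[0, 0] = n_obs
        C[0, 1:] = ztz
        C[1:, 0] = ztz
        C[1:, 1:] = lambda_g * K
        C[np.arange(1, n_eq), np.arange(1, n_eq)] += ztz
        try:
            cf = scipy.linalg.cho_factor(C, lower=True, check_finite=False)
            sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
        except scipy.linalg.LinAlgError:
            sol = scipy.linalg.solve(C, rhs, assume_a="sym")
    else:
        if isinstance(k_inv, HInverse):
            k_diag = k_inv.a_inv.matrix.diagonal().copy()
            k_diag[k_inv.genotyped_rows] += np.diag(k_inv.correction)
            k_mv = k_inv.matvec
        else:
            k_diag = k_inv.matrix.diagonal()
            k_mv = lambda x: k_inv.matrix @ x

        def matvec(v):
            mu, u = v[0], v[1:]
            out = np.empty_like(v)
            out[0] = n_obs * mu + ztz @ u
            out[1:] = ztz * mu + ztz * u + lambda_g * k_mv(u)
            return out

        diag = np.concatenate([[n_obs], ztz + lambda_g * k_diag])
        M = spla.LinearOperator((n_eq, n_eq), matvec=lambda v: v / diag)
        A = spla.LinearOperator((n_eq, n_eq), matvec=matvec)
        sol, info = spla.cg(A, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
        if info != 0:
            raise NumericalError(
                f"PCG did not converge in {maxiter} iterations (info={info}); "
                "check variance components and H/A conditioning")

    return float(sol[0]), pd.Series(sol[1:], index=ids)
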