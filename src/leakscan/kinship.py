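"""Relationship matrices: pedigree A and A⁻¹, genomic G, and single-step H⁻¹.

The numerator relationship matrix A is built by the tabular method with
inbreeding; its sparse inverse by Henderson's rules using Mendelian-sampling
variances. The genomic matrix G follows VanRaden's first method on centered
dosages, optionally blended with and tuned to the pedigree relationships of
the genotyped animals (A22). H⁻¹ combines A⁻¹ with the genomic information
on the genotyped block, as used by single-step GBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .pedigree import Pedigree, PedigreeError
from .simdata import DataError, GenotypeMatrix


class NumericalError(RuntimeError):
    """Numerical failure (singular matrix, non-convergence)."""


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix with animal labels."""

    values: np.ndarray
    animal_ids: np.ndarray
    kind: str  # one of {"A", "A22", "G", "G_blended"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise DataError("matrix shape does not match animal labels")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise DataError("relationship matrix is not symmetric")

    def subset(self, ids, kind: str | None = None) -> "RelationshipMatrix":
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        rows = np.array([lookup[a] for a in np.asarray(ids, dtype=np.int64)])
        return RelationshipMatrix(self.values[np.ix_(rows, rows)],
                                  np.asarray(ids, dtype=np.int64), kind or self.kind)


@dataclass
class SparsePrecision:
    """Symmetric sparse precision matrix in an animal ordering."""

    matrix: sp.csr_matrix
    animal_ids: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        if self.matrix.shape != (len(self.animal_ids),) * 2:
            raise DataError("precision shape does not match animal labels")

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def to_triplets(self):
        coo = sp.triu(self.matrix.tocoo())
        return coo.row, coo.col, coo.data


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficient F = ½·a(sire, dam); founders 0."""
    A = a_matrix(pedigree)
    return np.diag(A.values) - 1.0


def a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a(x, y) = ½[a(x, sire_y) + a(x, dam_y)] for y after x (unknown parents
    contribute 0) and a(y, y) = 1 + ½·a(sire_y, dam_y).
    """
    sire, dam = pedigree.parent_rows()
    A = _tabular_a(sire, dam)
    return RelationshipMatrix(A, pedigree.animal_id, "A")


@njit(cache=True)
def _tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[s, j]
            if d >= 0:
                v += 0.5 * A[d, j]
            A[i, j] = v
            A[j, i] = v
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def a_inverse(pedigree: Pedigree) -> SparsePrecision:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    The Mendelian-sampling variance is d = ½ − ¼(F_sire + F_dam) with both
    parents known, ¾ − ¼F_parent with one known, and 1 with none.
    """
    n = pedigree.n
    sire, dam = pedigree.parent_rows()
    F = inbreeding_coefficients(pedigree)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mend = 0.75 - 0.25 * F[p]
        else:
            mend = 1.0
        alpha = 1.0 / mend
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(p, i, -0.5 * alpha)
                add(i, p, -0.5 * alpha)
                for q in (s, d):
                    if q >= 0:
                        add(p, q, 0.25 * alpha)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return SparsePrecision(M, pedigree.animal_id)


def g_matrix(genotypes: GenotypeMatrix, snp_subset=None) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    G = ZZ′ / (2Σ pⱼ(1−pⱼ)) with Z the dosages centered at 2pⱼ; allele
    frequencies are computed from the genotyped animals themselves,
    monomorphic SNPs are excluded from both Z and the denominator, and
    missing dosages are mean-imputed per SNP beforehand.
    """
    gm = genotypes if snp_subset is None else genotypes.subset_snps(np.asarray(snp_subset))
    X = gm.dosages_float(impute_mean=True)
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise DataError("all SNPs are monomorphic; G is undefined")
    X = X[:, keep]
    p = p[keep]
    Z = X - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, gm.animal_ids, "G")


def blend_tune_g(
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    blend_weight: float = 0.95,
    tune: bool = True,
) -> RelationshipMatrix:
    """Blend G with pedigree relationships: G* = w·G + (1−w)·A22.

    If ``tune``, G is first rescaled with two coefficients (G ← a + b·G) so
    its mean diagonal and mean off-diagonal match those of A22, putting the
    two matrices on a compatible base population scale before blending.
    """
    if not 0 < blend_weight <= 1:
        raise DataError("blend_weight must be in (0, 1]")
    if not np.array_equal(G.animal_ids, A22.animal_ids):
        raise DataError("G and A22 must share the same animal ordering")
    Gv = G.values
    n = Gv.shape[0]
    if tune and n > 1:
        off = ~np.eye(n, dtype=bool)
        md_g, mo_g = np.mean(np.diag(Gv)), np.mean(Gv[off])
        md_a, mo_a = np.mean(np.diag(A22.values)), np.mean(A22.values[off])
        if abs(md_g - mo_g) < 1e-12:
            raise NumericalError("cannot tune: G diagonal and off-diagonal means coincide")
        b = (md_a - mo_a) / (md_g - mo_g)
        a = md_a - b * md_g
        Gv = a + b * Gv
    out = blend_weight * Gv + (1.0 - blend_weight) * A22.values
    return RelationshipMatrix(out, G.animal_ids, "G_blended")


@dataclass
class HInverse:
    """H⁻¹ = A⁻¹ plus a genomic correction on the genotyped block.

    Stored as the sparse pedigree part plus the dense correction
    (G*)⁻¹ − (A22)⁻¹ with the positions of the genotyped animals, so it can
    be applied as an operator or densified for direct solves.
    """

    a_inv: SparsePrecision
    correction: np.ndarray
    genotyped_rows: np.ndarray

    @property
    def animal_ids(self) -> np.ndarray:
        return self.a_inv.animal_ids

    @property
    def shape(self):
        return self.a_inv.matrix.shape

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.a_inv.matrix @ x
        y[self.genotyped_rows] += self.correction @ x[self.genotyped_rows]
        return y

    def to_dense(self) -> np.ndarray:
        H = self.a_inv.to_dense()
        ix = np.ix_(self.genotyped_rows, self.genotyped_rows)
        H[ix] += self.correction
        return H


def h_inverse(
    a_inv: SparsePrecision,
    A22: RelationshipMatrix,
    G_star: RelationshipMatrix,
    genotyped_ids,
) -> HInverse:
    """Single-step H⁻¹: A⁻¹ with (G*)⁻¹ − (A22)⁻¹ added on the genotyped block."""
    genotyped_ids = np.asarray(genotyped_ids, dtype=np.int64)
    if not (np.array_equal(G_star.animal_ids, genotyped_ids)
            and np.array_equal(A22.animal_ids, genotyped_ids)):
        raise DataError("G*, A22 and genotyped_ids must agree in order")
    lookup = {a: i for i, a in enumerate(a_inv.animal_ids)}
    try:
        rows = np.array([lookup[a] for a in genotyped_ids])
    except KeyError as exc:
        raise PedigreeError(f"genotyped animal {exc.args[0]} not in pedigree") from None
    try:
        g_inv = np.linalg.inv(G_star.values)
        a22_inv = np.linalg.inv(A22.values)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular G* or A22; use blend_weight < 1 to regularize G"
        ) from exc
    corr = 0.5 * (g_inv + g_inv.T) - 0.5 * (a22_inv + a22_inv.T)
    return HInverse(a_inv, corr, rows)
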