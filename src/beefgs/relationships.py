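"""Relationship structures for multi-breed genetic evaluation.

Builds, for a topologically ordered pedigree whose base animals trace to
one founder population per breed:

* the inverse numerator relationship matrix augmented with unknown-parent
  groups (UPGs), assembled by Henderson's rules with exact inbreeding
  (Meuwissen-Luo recursion) and groups substituted for unknown parents
  (Quaas-Pollak transformed system, so animal solutions are total EBVs);
* the metafounder relationship structure: Γ = 8·Cov(P) from per-breed
  allele frequencies, the pedigree matrix A^Γ whose founder block is Γ, its
  sparse inverse, and the genotyped-subset block A22^Γ;
* the genomic matrix G^Γ = WW'/s with W = dosage - 1 and s = n_markers/2
  (no allele-frequency centering: the metafounder parameterisation absorbs
  it);
* the combined single-step inverse H^Γ⁻¹ = A^Γ⁻¹ + [0 0; 0 G^Γ⁻¹ - A22^Γ⁻¹].

For purebred pedigrees A^Γ decomposes exactly as
``Γ[b_i, b_j] + δ(b_i = b_j) · (1 - γ_b/2) · A_std`` which this module uses
for the genotyped block; the sparse inverse is assembled directly from the
generalized Henderson rules with mendelian variances
``d^Γ_i = (1 - γ_b/2) · d_i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from . import kernels

# ---------------------------------------------------------------------------
# Inbreeding / plain A utilities
# ---------------------------------------------------------------------------


def inbreeding(sire: np.ndarray, dam: np.ndarray,
               f_prev: np.ndarray | None = None) -> np.ndarray:
    """Pedigree inbreeding coefficients; extends ``f_prev`` if given."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    if f_prev is None:
        f_prev = np.empty(0, dtype=np.float64)
    return kernels.inbreeding(sire, dam, np.asarray(f_prev, dtype=np.float64))


def a_dense(sire, dam) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (small n)."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return A


def a_submatrix(sire, dam, idx, f: np.ndarray | None = None) -> np.ndarray:
    """A[idx, idx] by Colleau's indirect method (works for large pedigrees)."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    if f is None:
        f = inbreeding(sire, dam)
    dvec = kernels.mendelian_variance(sire, dam, f)
    return kernels.a_submatrix(sire, dam, dvec, np.asarray(idx, dtype=np.int64))


# ---------------------------------------------------------------------------
# Henderson assembly (shared by UPG and metafounder inverses)
# ---------------------------------------------------------------------------


def _henderson_coo(sire_e, dam_e, dvec, dim):
    """COO triplets for sum_i (1/d_i)(e_i - e_s/2 - e_d/2)(...)' with extended
    parent codes (>= 0 real or pseudo column; < 0 truly unknown)."""
    n = len(dvec)
    i = np.arange(n)
    rows = [i]
    cols = [i]
    vals = [1.0 / dvec]
    for p in (sire_e, dam_e):
        m = p >= 0
        rows += [i[m], p[m]]
        cols += [p[m], i[m]]
        vals += [-0.5 / dvec[m], -0.5 / dvec[m]]
    for p in (sire_e, dam_e):
        for q in (sire_e, dam_e):
            m = (p >= 0) & (q >= 0)
            rows.append(p[m])
            cols.append(q[m])
            vals.append(0.25 / dvec[m])
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(dim, dim),
    )
    return mat.tocsr()


def _check_pedigree(sire, dam):
    n = len(sire)
    for name, p in (("sire", sire), ("dam", dam)):
        bad = np.flatnonzero(p >= np.arange(n))
        if bad.size:
            raise ValueError(
                f"pedigree not topologically ordered: {name} of animal "
                f"{bad[0]} is {p[bad[0]]} (parents must precede offspring)"
            )


def a_inverse(sire, dam, f: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A⁻¹ without groups (unknown parents = unrelated founders)."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _check_pedigree(sire, dam)
    if f is None:
        f = inbreeding(sire, dam)
    dvec = kernels.mendelian_variance(sire, dam, f)
    return _henderson_coo(sire, dam, dvec, sire.size)


@dataclass
class PedigreeMatrixSet:
    """UPG-augmented inverse relationship structure.

    ``a_inv`` has dimension (n_animals + n_groups); animal rows first.
    ``q`` holds each animal's fractional group composition (rows sum to 1
    for animals with any unknown ancestry; here every base animal maps to
    its breed's group, so Q is a breed indicator for all animals).
    """

    a_inv: sp.csr_matrix
    q: np.ndarray
    n_animals: int
    n_groups: int
    f: np.ndarray


def build_a_inverse_upg(sire, dam, group_of_animal, n_groups,
                        f: np.ndarray | None = None) -> PedigreeMatrixSet:
    """A⁻¹ augmented with unknown-parent groups (Quaas-Pollak form).

    Unknown parents of animal ``i`` are replaced by group
    ``group_of_animal[i]`` (its breed).  Group columns follow the animal
    columns.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _check_pedigree(sire, dam)
    n = sire.size
    if f is None:
        f = inbreeding(sire, dam)
    dvec = kernels.mendelian_variance(sire, dam, f)  # group diagonal -> 0
    grp = np.asarray(group_of_animal, dtype=np.int64)
    sire_e = np.where(sire >= 0, sire, n + grp)
    dam_e = np.where(dam >= 0, dam, n + grp)
    a_inv = _henderson_coo(sire_e, dam_e, dvec, n + n_groups)
    # Q by recursive averaging of parental group fractions
    q = np.zeros((n, n_groups))
    for i in range(n):
        if sire[i] >= 0:
            q[i] += 0.5 * q[sire[i]]
        else:
            q[i, grp[i]] += 0.5
        if dam[i] >= 0:
            q[i] += 0.5 * q[dam[i]]
        else:
            q[i, grp[i]] += 0.5
    return PedigreeMatrixSet(a_inv=a_inv, q=q, n_animals=n, n_groups=n_groups, f=f)


# ---------------------------------------------------------------------------
# Metafounders
# ---------------------------------------------------------------------------


def gamma_from_freqs(p_by_breed: np.ndarray) -> np.ndarray:
    """Γ = 8 · Cov(P) across markers of per-breed allele-frequency columns.

    ``p_by_breed`` is (n_markers, m).  The covariance is taken over markers
    (rows as observations) and is invariant to relabelling alleles
    (p -> 1-p flips the sign of every centred column entry jointly).
    """
    P = np.asarray(p_by_breed, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need at least two markers to estimate Gamma")
    return 8.0 * np.atleast_2d(np.cov(P, rowvar=False, bias=False))


def make_psd(gamma: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues at zero (warn if repair was needed)."""
    w, v = np.linalg.eigh(gamma)
    if w.min() < -tol * max(1.0, w.max()):
        warnings.warn(
            f"Gamma not PSD (min eigenvalue {w.min():.3g}); clipping at 0"
        )
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def a_gamma_dense(sire, dam, breed, gamma: np.ndarray) -> np.ndarray:
    """Dense A^Γ by the tabular method with the metafounder block = Γ.

    Returns the (m + n) x (m + n) matrix with metafounders first.  Unknown
    parents (code < 0) are replaced by the animal's breed metafounder.
    For small pedigrees / oracle checks.
    """
    m = gamma.shape[0]
    n = len(sire)
    dim = m + n
    A = np.zeros((dim, dim))
    A[:m, :m] = gamma
    for i in range(n):
        s = sire[i] + m if sire[i] >= 0 else breed[i]
        d = dam[i] + m if dam[i] >= 0 else breed[i]
        r = i + m
        A[r, :r] = A[:r, r] = 0.5 * (A[s, :r] + A[d, :r])
        A[r, r] = 1.0 + 0.5 * A[s, d]
    return A


@dataclass
class GammaPedigree:
    """Sparse A^Γ⁻¹ with companion pieces for single-step assembly."""

    a_gamma_inv: sp.csr_matrix   # (n + m) with metafounder columns last
    gamma: np.ndarray
    n_animals: int
    n_meta: int
    f: np.ndarray                # standard inbreeding (Γ = 0 scale)
    dvec_std: np.ndarray


def build_a_gamma_inverse(sire, dam, breed, gamma,
                          f: np.ndarray | None = None) -> GammaPedigree:
    """Sparse A^Γ⁻¹ for a purebred pedigree with one metafounder per breed.

    Metafounder columns are appended after the animals.  Mendelian-sampling
    variances are ``(1 - γ_b/2) d_i`` and the metafounder block receives
    Γ⁻¹ (generalized Henderson rules).
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    breed = np.asarray(breed, dtype=np.int64)
    _check_pedigree(sire, dam)
    gamma = np.asarray(gamma, dtype=np.float64)
    m = gamma.shape[0]
    n = sire.size
    if f is None:
        f = inbreeding(sire, dam)
    dvec_std = kernels.mendelian_variance(sire, dam, f)
    c = 1.0 - 0.5 * np.diag(gamma)
    if np.any(c <= 0):
        raise ValueError("gamma diagonal must be < 2 for a valid A^Gamma")
    dvec = c[breed] * dvec_std
    sire_e = np.where(sire >= 0, sire, n + breed)
    dam_e = np.where(dam >= 0, dam, n + breed)
    a_inv = _henderson_coo(sire_e, dam_e, dvec, n + m)
    gamma_psd = make_psd(gamma)
    try:
        g_inv = np.linalg.inv(gamma_psd)
    except np.linalg.LinAlgError:
        g_inv = np.linalg.inv(gamma_psd + 1e-8 * np.eye(m))
    a_inv = (a_inv + sp.coo_matrix(
        (g_inv.ravel(),
         (np.repeat(np.arange(n, n + m), m), np.tile(np.arange(n, n + m), m))),
        shape=(n + m, n + m),
    )).tocsr()
    return GammaPedigree(a_gamma_inv=a_inv, gamma=gamma, n_animals=n,
                         n_meta=m, f=f, dvec_std=dvec_std)


def a_gamma_submatrix(sire, dam, breed, gamma, idx,
                      f: np.ndarray | None = None) -> np.ndarray:
    """Dense A^Γ[idx, idx] for a purebred pedigree.

    Uses A^Γ_ij = Γ[b_i, b_j] + δ(b_i = b_j)(1 - γ_b/2) A_std_ij.
    """
    idx = np.asarray(idx, dtype=np.int64)
    a22 = a_submatrix(sire, dam, idx, f=f)
    b = np.asarray(breed)[idx]
    gamma = np.asarray(gamma, dtype=np.float64)
    c = 1.0 - 0.5 * np.diag(gamma)
    same = b[:, None] == b[None, :]
    return gamma[np.ix_(b, b)] + np.where(same, c[b][None, :], 0.0) * a22


# ---------------------------------------------------------------------------
# Genomic and single-step matrices
# ---------------------------------------------------------------------------


def build_g_gamma(dosages: np.ndarray) -> np.ndarray:
    """G^Γ = WW'/s with W = dosage - 1 and s = n_markers / 2."""
    dosages = np.asarray(dosages)
    if np.any((dosages < 0) | (dosages > 2)):
        raise ValueError("dosages must be 0, 1 or 2 (missing not supported)")
    W = dosages.astype(np.float64) - 1.0
    s = dosages.shape[1] / 2.0
    return (W @ W.T) / s


@dataclass
class HGammaInverse:
    """H^Γ⁻¹ = A^Γ⁻¹ + scatter(G^Γ⁻¹ - A22^Γ⁻¹) over the genotyped block.

    Stored as the sparse pedigree part plus a dense correction confined to
    the genotyped rows/columns, which is how the solver consumes it.
    """

    sparse: sp.csr_matrix
    correction: np.ndarray | None
    geno_idx: np.ndarray | None
    dim: int

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.sparse @ x
        if self.correction is not None:
            y[self.geno_idx] += self.correction @ x[self.geno_idx]
        return y

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.sparse.diagonal()).copy()
        if self.correction is not None:
            d[self.geno_idx] += np.diag(self.correction)
        return d

    def to_sparse(self) -> sp.csr_matrix:
        if self.correction is None:
            return self.sparse
        m = self.geno_idx.size
        corr = sp.coo_matrix(
            (self.correction.ravel(),
             (np.repeat(self.geno_idx, m), np.tile(self.geno_idx, m))),
            shape=(self.dim, self.dim),
        )
        return (self.sparse + corr).tocsr()

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()


def build_h_gamma_inverse(a_gamma_inv: sp.csr_matrix, a22_gamma: np.ndarray,
                          g_gamma: np.ndarray, geno_idx: np.ndarray,
                          blend: float = 0.05) -> HGammaInverse:
    """Assemble H^Γ⁻¹ exactly; G^Γ is used raw unless numerically singular,
    in which case it is blended ``(1-blend)·G^Γ + blend·A22^Γ`` (logged)."""
    geno_idx = np.asarray(geno_idx, dtype=np.int64)
    dim = a_gamma_inv.shape[0]
    if geno_idx.size == 0:
        return HGammaInverse(sparse=a_gamma_inv, correction=None,
                             geno_idx=None, dim=dim)
    g_use = np.asarray(g_gamma, dtype=np.float64)
    try:
        cf = sla.cho_factor(g_use)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"G^Gamma numerically singular; blending {blend} toward A22^Gamma"
        )
        g_use = (1.0 - blend) * g_use + blend * a22_gamma
        cf = sla.cho_factor(g_use)  # raises if still singular
    g_inv = sla.cho_solve(cf, np.eye(geno_idx.size))
    a22_inv = sla.cho_solve(sla.cho_factor(a22_gamma), np.eye(geno_idx.size))
    corr = g_inv - a22_inv
    corr = 0.5 * (corr + corr.T)
    return HGammaInverse(sparse=a_gamma_inv, correction=corr,
                         geno_idx=geno_idx, dim=dim)
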