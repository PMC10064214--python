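"""Mixed-model equations for the two evaluators, and prediction accuracy.

The single-trait animal model is ``y = Xb + Zu + e`` with
``u ~ N(0, K σ²_a)`` and ``e ~ N(0, I σ²_e)``, solved at the true variance
components (λ = σ²_e/σ²_a).  Two relationship structures are supported:

* **UPG pedigree BLUP** — K⁻¹ is the unknown-parent-group augmented A⁻¹ in
  Quaas-Pollak form, so the animal equations solve directly for total EBVs
  u = Qs + a, and the group equations for the group effects s.  One group
  is constrained to zero (the group levels and the intercept are
  confounded).
* **Metafounder single-step GBLUP** — K⁻¹ is H^Γ⁻¹; metafounders are
  pseudo-animals with a proper prior (Γ), so no constraint is needed, and
  every animal, genotyped or not, receives a GEBV.

Fixed effects are the intercept and sex; if the recorded animals are all
of one sex the sex column is dropped (confounded with the intercept).
The solver is preconditioned conjugate gradients (Jacobi preconditioner,
relative-residual tolerance 1e-8 by default) with a sparse-LU fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .population import MALE, Population
from .presets import TraitConfig
from .relationships import (
    HGammaInverse,
    build_a_inverse_upg,
)


@dataclass
class MMESolution:
    beta: np.ndarray          # fixed-effect solutions
    u: np.ndarray             # all random solutions (animals then pseudo)
    n_animals: int
    n_iter: int
    converged: bool

    @property
    def ebv(self) -> np.ndarray:
        """Total (G)EBVs of the real animals."""
        return self.u[: self.n_animals]

    @property
    def group_solutions(self) -> np.ndarray:
        return self.u[self.n_animals:]


class _Operator(spla.LinearOperator):
    """MME coefficient matrix: sparse part + optional dense genotyped block."""

    def __init__(self, K_sparse, corr, corr_idx, lam):
        self.K = K_sparse
        self.corr = corr
        self.corr_idx = corr_idx
        self.lam = lam
        super().__init__(dtype=np.float64, shape=K_sparse.shape)

    def _matvec(self, x):
        x = np.asarray(x).ravel()
        y = self.K @ x
        if self.corr is not None:
            y[self.corr_idx] += self.lam * (self.corr @ x[self.corr_idx])
        return y


def solve_mme(rel_inv, n_u: int, n_animals: int, X: np.ndarray,
              obs_idx: np.ndarray, y_obs: np.ndarray, var_a: float,
              var_e: float, constrain: int | None = None,
              rtol: float = 1e-8, maxiter: int = 20000,
              x0: np.ndarray | None = None) -> MMESolution:
    """Assemble and solve the MME.

    ``rel_inv`` is either a sparse K⁻¹ of dimension ``n_u`` or an
    :class:`~beefgs.relationships.HGammaInverse`.  ``X`` is the fixed-effect
    design for the observed records (rows align with ``obs_idx``).
    ``constrain`` removes one random-effect equation (index into the u
    block) to handle UPG/intercept confounding.
    """
    lam = var_e / var_a
    n_f = X.shape[1]
    n_obs = obs_idx.size
    if n_obs != X.shape[0] or n_obs != y_obs.size:
        raise ValueError("design, observation index and y sizes disagree")

    Z = sp.coo_matrix(
        (np.ones(n_obs), (np.arange(n_obs), obs_idx)), shape=(n_obs, n_u)
    ).tocsr()
    Xs = sp.csr_matrix(X)
    if isinstance(rel_inv, HGammaInverse):
        K_uu_sparse = rel_inv.sparse * lam
        corr, corr_idx = rel_inv.correction, rel_inv.geno_idx
    else:
        K_uu_sparse = rel_inv * lam
        corr, corr_idx = None, None
    K = sp.bmat(
        [[Xs.T @ Xs, Xs.T @ Z], [Z.T @ Xs, Z.T @ Z + K_uu_sparse]],
        format="csr",
    )
    rhs = np.concatenate([X.T @ y_obs, Z.T @ y_obs])
    if corr_idx is not None:
        corr_idx_full = corr_idx + n_f
    else:
        corr_idx_full = None

    keep = np.ones(K.shape[0], dtype=bool)
    if constrain is not None:
        keep[n_f + constrain] = False
        K = K[keep][:, keep]
        rhs = rhs[keep]
        if corr_idx_full is not None:
            # constrained index is never genotyped; shift indices above it
            corr_idx_full = corr_idx_full - (corr_idx_full > (n_f + constrain))
    if x0 is not None and x0.size == n_f + n_u:
        x0 = x0[keep]

    op = _Operator(K, corr, corr_idx_full, lam)
    diag = np.asarray(K.diagonal()).copy()
    if corr is not None:
        diag[corr_idx_full] += lam * np.diag(corr)
    diag[diag <= 0] = 1.0
    M = spla.LinearOperator(K.shape, matvec=lambda x: x / diag)

    if x0 is not None and x0.size != rhs.size:
        x0 = None
    sol, info = spla.cg(op, rhs, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    n_iter = maxiter if info > 0 else -1
    converged = info == 0
    if info != 0:
        # fall back to a direct sparse solve
        K_full = op.K
        if corr is not None:
            m = corr_idx_full.size
            K_full = (K_full + sp.coo_matrix(
                (lam * corr.ravel(),
                 (np.repeat(corr_idx_full, m), np.tile(corr_idx_full, m))),
                shape=K.shape)).tocsr()
        try:
            sol = spla.spsolve(K_full.tocsc(), rhs)
            converged = True
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"MME solve failed to converge: {exc}") from exc

    full = np.empty(n_f + n_u)
    if constrain is not None:
        full[keep] = sol
        full[n_f + constrain] = 0.0
    else:
        full[:] = sol
    return MMESolution(beta=full[:n_f], u=full[n_f:], n_animals=n_animals,
                       n_iter=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# High-level entry points
# ---------------------------------------------------------------------------


def _design(pop: Population, obs_mask: np.ndarray):
    obs_idx = np.flatnonzero(obs_mask)
    male = (pop.sex[obs_idx] == MALE).astype(np.float64)
    if 0.0 < male.mean() < 1.0:
        X = np.column_stack([np.ones(obs_idx.size), male])
    else:  # single-sex records: sex confounded with the intercept
        X = np.ones((obs_idx.size, 1))
    return X, obs_idx


def solve_blup_upg(pop: Population, obs_mask: np.ndarray, variances: TraitConfig,
                   f: np.ndarray | None = None, rtol: float = 1e-8,
                   x0: np.ndarray | None = None) -> MMESolution:
    """Multi-breed UPG pedigree BLUP; returns total EBVs u = Qs + a."""
    n_groups = int(pop.breed.max()) + 1
    pms = build_a_inverse_upg(np.where(pop.sire >= 0, pop.sire, -1),
                              np.where(pop.dam >= 0, pop.dam, -1),
                              pop.breed, n_groups, f=f)
    X, obs_idx = _design(pop, obs_mask)
    return solve_mme(pms.a_inv, pop.n + n_groups, pop.n, X, obs_idx,
                     pop.y[obs_idx], variances.var_a, variances.var_e,
                     constrain=pop.n + n_groups - 1, rtol=rtol, x0=x0)


def solve_ssgblup_mf(pop: Population, obs_mask: np.ndarray,
                     h_inv: HGammaInverse, variances: TraitConfig,
                     rtol: float = 1e-8,
                     x0: np.ndarray | None = None) -> MMESolution:
    """Metafounder single-step GBLUP; GEBVs for every animal."""
    X, obs_idx = _design(pop, obs_mask)
    return solve_mme(h_inv, h_inv.dim, pop.n, X, obs_idx, pop.y[obs_idx],
                     variances.var_a, variances.var_e, constrain=None,
                     rtol=rtol, x0=x0)


def selection_ebv_solver(trait_cfg: TraitConfig, rtol: float = 1e-6):
    """EBV provider for the in-simulation selection loop (UPG BLUP on all
    records to date at the true variances)."""

    def _solve(pop: Population, obs_mask: np.ndarray, f: np.ndarray) -> np.ndarray:
        return solve_blup_upg(pop, obs_mask, trait_cfg, f=f, rtol=rtol).ebv

    return _solve


def accuracy(tbv: np.ndarray, ebv: np.ndarray,
             subset: np.ndarray | None = None) -> float:
    """Pearson correlation between TBV and (G)EBV over a subset.

    Returns NaN for empty subsets or degenerate variance.
    """
    t = np.asarray(tbv, dtype=np.float64)
    e = np.asarray(ebv, dtype=np.float64)
    if subset is not None:
        t = t[subset]
        e = e[subset]
    if t.size < 2 or t.std() == 0 or e.std() == 0:
        return float("nan")
    return float(np.corrcoef(t, e)[0, 1])
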