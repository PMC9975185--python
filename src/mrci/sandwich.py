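"""Robust (sandwich) variance estimation for the composite-likelihood fit.

The composite likelihood treats LD-correlated SNPs as independent, so the
usual inverse-Hessian variance is invalid.  The sandwich
``I^{-1} J I^{-1}`` repairs it: ``I`` is the sensitivity matrix (negative
Hessian of the CL) and ``J`` the variability matrix, whose cross terms sum
each SNP's score against the summed scores of all SNPs it tags,

    J = sum_k U_k (sum_{k' in tag(k)} U_{k'})^T.

All derivatives are symmetric (central) differences taken in the
unconstrained coordinates; the covariance is mapped back to the natural
scale through the analytic Jacobian of the transforms, which avoids
boundary pathologies for variance parameters near zero.  Directions with
vanishing curvature (parameters pinned against a boundary by the data) are
dropped via a pseudo-inverse and their standard errors reported as
not-available (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.stats import chi2 as chi2_dist

from .data import SummaryDataset
from .em import FitResult
from .enumeration import EnumerationPlan
from .likelihood import LikelihoodWorkspace
from .params import ModelParams, ParamTransform, SubModelSpec

__all__ = ["SandwichResult", "score_matrix", "sandwich_covariance", "wald_test"]

_RELATIVE_STEP = 1e-4
_CURVATURE_RCOND = 1e-9
_RIDGE_RCOND = 1e-5


@dataclass
class SandwichResult:
    """Sandwich covariance and per-parameter Wald tests for one fit."""

    free_names: tuple
    I_hat: np.ndarray
    J_hat: np.ndarray
    cov_z: np.ndarray
    cov: np.ndarray  # natural scale
    se: dict
    chi2: dict
    p: dict
    dropped: tuple = ()
    pseudo_inverse: bool = False

    def se_of(self, name: str) -> float:
        return self.se.get(name, float("nan"))

    def p_of(self, name: str) -> float:
        return self.p.get(name, float("nan"))


def _steps(z: np.ndarray, h: float) -> np.ndarray:
    return h * np.maximum(np.abs(z), 1.0)


def score_matrix(
    ws: LikelihoodWorkspace,
    params: ModelParams,
    transform: ParamTransform,
    h: float = _RELATIVE_STEP,
) -> np.ndarray:
    """(K, p) per-SNP score vectors by central differences in z-space."""
    z0 = transform.to_z(params)
    steps = _steps(z0, h)
    K = ws.data.K
    U = np.empty((K, transform.n))
    for j in range(transform.n):
        zp = z0.copy()
        zp[j] += steps[j]
        zm = z0.copy()
        zm[j] -= steps[j]
        lp = ws.loglik_per_snp(transform.to_params(zp, params))
        lm = ws.loglik_per_snp(transform.to_params(zm, params))
        U[:, j] = (lp - lm) / (2.0 * steps[j])
    if not np.all(np.isfinite(U)):
        j = int(np.argwhere(~np.isfinite(U))[0][1])
        raise FloatingPointError(
            f"non-finite score for parameter {transform.names[j]}"
        )
    return U


def score_vector(ws, params, transform, h: float = _RELATIVE_STEP) -> np.ndarray:
    """Total score (sum of per-SNP scores) in z-space."""
    return score_matrix(ws, params, transform, h).sum(axis=0)


def _cl_hessian(ws, params, transform, h):
    """Central-difference Hessian of the CL in z-space."""
    z0 = transform.to_z(params)
    steps = _steps(z0, h)
    p = transform.n

    def cl_at(z):
        return ws.cl(transform.to_params(z, params))

    f0 = cl_at(z0)
    H = np.empty((p, p))
    fp = np.empty(p)
    fm = np.empty(p)
    for j in range(p):
        zp = z0.copy()
        zp[j] += steps[j]
        zm = z0.copy()
        zm[j] -= steps[j]
        fp[j] = cl_at(zp)
        fm[j] = cl_at(zm)
        H[j, j] = (fp[j] - 2.0 * f0 + fm[j]) / steps[j] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            zpp = z0.copy(); zpp[i] += steps[i]; zpp[j] += steps[j]
            zpm = z0.copy(); zpm[i] += steps[i]; zpm[j] -= steps[j]
            zmp = z0.copy(); zmp[i] -= steps[i]; zmp[j] += steps[j]
            zmm = z0.copy(); zmm[i] -= steps[i]; zmm[j] -= steps[j]
            H[i, j] = H[j, i] = (
                cl_at(zpp) - cl_at(zpm) - cl_at(zmp) + cl_at(zmm)
            ) / (4.0 * steps[i] * steps[j])
    return H


def sandwich_covariance(
    data: SummaryDataset,
    fit: FitResult,
    plan: EnumerationPlan | None = None,
    h: float = _RELATIVE_STEP,
) -> SandwichResult:
    """Sandwich covariance ``I^{-1} J I^{-1}`` with LD-aware score sums."""
    submodel = fit.submodel
    params = fit.params_hat
    if plan is None:
        cfg = fit.config
        plan = EnumerationPlan.for_dataset(
            data,
            c_max=cfg.c_max if cfg else 4,
            c_total=cfg.c_total if cfg else 4,
            active=submodel.active,
        )
    ws = LikelihoodWorkspace(data, plan)
    transform = ParamTransform(
        submodel.free_names, rho0_scale=np.sqrt(data.n1 * data.n2)
    )

    U = score_matrix(ws, params, transform, h)
    Ubar = sp.csr_matrix(data.adjacency, dtype=float) @ U
    J = U.T @ Ubar
    J = 0.5 * (J + J.T)
    I = -_cl_hessian(ws, params, transform, h)
    I = 0.5 * (I + I.T)

    # Parameters live on wildly different scales (rho0 ~ 1e-5, deltas ~ 0.1),
    # so invert in correlation form: pre-scale by the root curvature, drop
    # only directions whose own curvature truly vanishes (boundary-pinned
    # parameters), and map back.
    p = transform.n
    diag = np.abs(np.diag(I))
    scale = diag.max() if diag.size else 1.0
    keep = diag > _CURVATURE_RCOND**2 * scale
    dropped = tuple(n for n, k in zip(transform.names, keep) if not k)

    cov_z = np.full((p, p), np.nan)
    idx = np.flatnonzero(keep)
    pseudo = False
    if idx.size:
        Ik = I[np.ix_(idx, idx)]
        Jk = J[np.ix_(idx, idx)]
        d = np.sqrt(np.abs(np.diag(Ik)))
        W = 1.0 / d
        I_s = W[:, None] * Ik * W[None, :]
        w, V = eigh(I_s)
        good = np.abs(w) > _CURVATURE_RCOND * np.abs(w).max()
        pseudo = not good.all()
        w_inv = np.where(good, 1.0 / np.where(good, w, 1.0), 0.0)
        I_inv = (W[:, None] * ((V * w_inv) @ V.T)) * W[None, :]
        cov_k = I_inv @ Jk @ I_inv
        cov_z[np.ix_(idx, idx)] = 0.5 * (cov_k + cov_k.T)
        # a parameter with substantial loading on a near-flat eigen-direction
        # of the (scaled) sensitivity matrix is not identified by the data;
        # the sandwich marginal variance along a likelihood ridge is
        # arbitrary, so its tests are reported as not available
        ridge = np.abs(w) < _RIDGE_RCOND * np.abs(w).max()
        if ridge.any():
            loading = np.abs(V[:, ridge]).max(axis=1)
            for local_j, glob_j in enumerate(idx):
                if loading[local_j] > 0.3:
                    dropped = dropped + (transform.names[glob_j],)

    z0 = transform.to_z(params)
    G = transform.jacobian(z0, params)
    cov_nat = np.full((p, p), np.nan)
    if idx.size:
        Gk = G[np.ix_(idx, idx)]
        cov_nat_k = Gk @ cov_z[np.ix_(idx, idx)] @ Gk.T
        cov_nat[np.ix_(idx, idx)] = cov_nat_k

    se, chi2, pvals = {}, {}, {}
    for j, name in enumerate(transform.names):
        var = cov_nat[j, j]
        if name in dropped or not np.isfinite(var) or var < 0:
            se[name] = float("nan")
            chi2[name] = float("nan")
            pvals[name] = float("nan")
            continue
        s = float(np.sqrt(var))
        se[name] = s
        est = getattr(params, name)
        if s > 0:
            c, pv = wald_test(est, s)
        else:
            c, pv = float("inf") if est != 0 else 0.0, 0.0 if est != 0 else 1.0
        chi2[name] = c
        pvals[name] = pv

    return SandwichResult(
        free_names=transform.names,
        I_hat=I,
        J_hat=J,
        cov_z=cov_z,
        cov=cov_nat,
        se=se,
        chi2=chi2,
        p=pvals,
        dropped=dropped,
        pseudo_inverse=pseudo,
    )


def wald_test(estimate: float, se: float):
    """Chi-square (1 df) Wald test of ``estimate = 0``."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    c = (estimate / se) ** 2
    return float(c), float(chi2_dist.sf(c, df=1))
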