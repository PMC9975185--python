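"""Bivariate mixture density of marginal effect estimates and the composite
log-likelihood.

Model summary
-------------
Conditional on the composition ``N_k`` of SNP ``k``'s tagging set, the pair
of standardized marginal-effect estimates ``(tau1_k, tau2_k)`` is bivariate
normal with mean zero and covariance built from three pieces, each scaled by
``(count / N_k*) * l_k`` and by ``1 / (1 - delta12*delta21)^2``:

* trait-1 variance: ``sigma1_sq`` (G1 tags), ``delta12^2 * sigma2_sq`` (G2
  tags) and ``sigmaC1_sq + delta12^2*sigmaC2_sq + 2*delta12*rhoC1C2`` (GC
  tags), plus ``a1 + 1/n1``;
* trait-2 variance: the mirror image with ``delta21`` and ``a2 + 1/n2``;
* cross-covariance: ``delta21*sigma1_sq`` (G1), ``delta12*sigma2_sq`` (G2),
  ``delta21*sigmaC1_sq + delta12*sigmaC2_sq + (1+delta12*delta21)*rhoC1C2``
  (GC), plus ``rho0``.

The per-SNP likelihood marginalizes the composition over its (truncated,
renormalized) multinomial prior; the composite log-likelihood sums the
per-SNP log densities over all K SNPs as if they were independent.  SNPs are
not independent under LD, which is why inference downstream uses a sandwich
variance rather than the inverse Hessian.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import logsumexp

from . import _kernels
from .data import SnpRecord, SummaryDataset
from .enumeration import ComponentCounts, EnumerationPlan
from .params import ModelParams

__all__ = [
    "marginal_covariance",
    "snp_log_likelihood",
    "composite_log_likelihood",
    "LikelihoodWorkspace",
    "genetic_correlation",
    "rg_variance",
]

_JITTER = 1e-12
_LOG_FLOOR = -745.0


def component_slopes(params: ModelParams):
    """Per-component LD-scaled contributions to (var1, var2, cov).

    Returns three length-3 arrays (order G1, G2, GC); multiplying by the
    tagged fraction ``count/N*`` and the LD score and adding the intercepts
    ``(a1 + 1/n1, a2 + 1/n2, rho0)`` yields the conditional covariance.
    """
    d12, d21 = params.delta12, params.delta21
    denom = (1.0 - d12 * d21) ** 2
    s1, s2 = params.sigma1_sq, params.sigma2_sq
    c1, c2, r = params.sigmaC1_sq, params.sigmaC2_sq, params.rhoC1C2
    A1 = np.array([s1, d12 * d12 * s2, c1 + d12 * d12 * c2 + 2.0 * d12 * r]) / denom
    A2 = np.array([d21 * d21 * s1, s2, c2 + d21 * d21 * c1 + 2.0 * d21 * r]) / denom
    Ac = np.array([d21 * s1, d12 * s2, d21 * c1 + d12 * c2 + (1.0 + d12 * d21) * r]) / denom
    return A1, A2, Ac


def marginal_covariance(
    counts: ComponentCounts,
    ld_score: float,
    n_tagged: int,
    n1: float,
    n2: float,
    params: ModelParams,
):
    """Conditional covariance of ``(tau1_hat, tau2_hat)`` given a composition.

    Returns ``(var1, var2, cov, clamped)``; ``clamped`` flags a repair of a
    covariance that left the positive-definite region.
    """
    if abs(params.delta12 * params.delta21) >= 1.0:
        raise ValueError("|delta12*delta21| >= 1")
    if n_tagged < 1:
        raise ValueError("n_tagged must be >= 1")
    A1, A2, Ac = component_slopes(params)
    f = np.array([counts.n_g1, counts.n_g2, counts.n_gc], dtype=float) / n_tagged
    w = f * ld_score
    var1 = float(A1 @ w) + params.a1 + 1.0 / n1
    var2 = float(A2 @ w) + params.a2 + 1.0 / n2
    cov = float(Ac @ w) + params.rho0
    clamped = False
    bound = math.sqrt(max(var1, 0.0) * max(var2, 0.0))
    if abs(cov) >= bound:
        cov = math.copysign(0.999 * bound, cov)
        clamped = True
    return var1, var2, cov, clamped


def snp_log_likelihood(
    record: SnpRecord,
    params: ModelParams,
    plan: EnumerationPlan,
    n1: float,
    n2: float,
) -> float:
    """Log mixture density for one SNP (scalar reference implementation).

    Computed with a log-sum-exp so densities down to ``exp(-700)`` do not
    underflow.  The vectorized :class:`LikelihoodWorkspace` path must agree
    with this function to numerical precision.
    """
    counts = plan.counts(record.n_tagged)
    logprior = plan.log_priors(record.n_tagged, params)
    terms = np.empty(len(counts))
    for i, (n1c, n2c, ncc, n0c) in enumerate(counts):
        v1, v2, cv, _ = marginal_covariance(
            ComponentCounts(int(n1c), int(n2c), int(ncc), int(n0c)),
            record.ld_score,
            record.n_tagged,
            n1,
            n2,
            params,
        )
        terms[i] = _bvn_logpdf(record.tau1_hat, record.tau2_hat, v1, v2, cv)
    return float(logsumexp(logprior + terms))


def _bvn_logpdf(x1, x2, v1, v2, cv):
    v1 = v1 + _JITTER
    v2 = v2 + _JITTER
    det = v1 * v2 - cv * cv
    quad = (v2 * x1 * x1 - 2.0 * cv * x1 * x2 + v1 * x2 * x2) / det
    return -0.5 * (quad + math.log(det)) - math.log(2.0 * math.pi)


class LikelihoodWorkspace:
    """Grouped, contiguous views of a dataset for fast likelihood sweeps.

    SNPs are grouped by tagging-set size so each group shares one truncated
    composition set; the numba kernels then evaluate the mixture density for
    the whole group at once.
    """

    def __init__(self, data: SummaryDataset, plan: EnumerationPlan):
        self.data = data
        self.plan = plan
        self.groups = []
        order = []
        for nstar in np.unique(data.n_tagged):
            idx = np.flatnonzero(data.n_tagged == nstar)
            order.append(idx)
            self.groups.append(
                {
                    "nstar": int(nstar),
                    "idx": idx,
                    "tau1": np.ascontiguousarray(data.tau1[idx]),
                    "tau2": np.ascontiguousarray(data.tau2[idx]),
                    "ell": np.ascontiguousarray(data.ld_score[idx]),
                    "counts": plan.counts(int(nstar)),
                }
            )
        self.n_evaluations = sum(
            len(g["idx"]) * len(g["counts"]) for g in self.groups
        )
        self.clamp_count = 0

    def _group_inputs(self, g, params: ModelParams):
        A1, A2, Ac = component_slopes(params)
        f = g["counts"][:, :3].astype(float) / g["nstar"]
        s1 = np.ascontiguousarray(f @ A1)
        s2 = np.ascontiguousarray(f @ A2)
        sc = np.ascontiguousarray(f @ Ac)
        b1 = params.a1 + 1.0 / self.data.n1
        b2 = params.a2 + 1.0 / self.data.n2
        logprior = np.ascontiguousarray(self.plan.log_priors(g["nstar"], params))
        return s1, s2, sc, b1, b2, params.rho0, logprior

    def loglik_per_snp(self, params: ModelParams) -> np.ndarray:
        """(K,) per-SNP log likelihood, in dataset order."""
        out = np.empty(self.data.K)
        clamped = 0
        for g in self.groups:
            s1, s2, sc, b1, b2, b0, logprior = self._group_inputs(g, params)
            buf = np.empty(len(g["idx"]))
            clamped += _kernels.group_loglik(
                g["tau1"], g["tau2"], g["ell"], s1, s2, sc, b1, b2, b0,
                logprior, buf,
            )
            out[g["idx"]] = buf
        self.clamp_count += clamped
        self._last_clamped = clamped
        return out

    def cl(self, params: ModelParams) -> float:
        """Composite log-likelihood."""
        return float(self.loglik_per_snp(params).sum())

    def log_terms(self, params: ModelParams):
        """Per-group (m, C) matrices of log(prior * density) for the E-step."""
        result = []
        for g in self.groups:
            s1, s2, sc, b1, b2, b0, logprior = self._group_inputs(g, params)
            buf = np.empty((len(g["idx"]), len(s1)))
            self.clamp_count += _kernels.group_logterms(
                g["tau1"], g["tau2"], g["ell"], s1, s2, sc, b1, b2, b0,
                logprior, buf,
            )
            result.append((g, buf))
        return result


def composite_log_likelihood(
    data: SummaryDataset, params: ModelParams, plan: EnumerationPlan
) -> float:
    """Sum of per-SNP log mixture densities over all K SNPs.

    Raises if any per-SNP term is non-finite, naming the SNP.
    """
    ws = LikelihoodWorkspace(data, plan)
    ll = ws.loglik_per_snp(params)
    bad = np.flatnonzero(~np.isfinite(ll))
    if bad.size:
        raise FloatingPointError(
            f"non-finite log-likelihood at SNP {data.snp_ids[bad[0]]}"
        )
    return float(ll.sum())


def genetic_correlation(params: ModelParams) -> float:
    """Genetic correlation implied by the fitted mixture parameters.

    The numerator is the covariance of the two traits' total additive
    genetic values under the reciprocal model; the denominator the geometric
    mean of the two genetic variances (the common ``1/(1-d12*d21)^2`` factor
    cancels).  Clamped to [-1, 1].
    """
    p = params
    d12, d21, r = p.delta12, p.delta21, p.rhoC1C2
    num = (
        p.pi1 * d21 * p.sigma1_sq
        + p.pi2 * d12 * p.sigma2_sq
        + p.piC * (d21 * p.sigmaC1_sq + d12 * p.sigmaC2_sq + (1.0 + d12 * d21) * r)
    )
    var1 = (
        p.pi1 * p.sigma1_sq
        + p.pi2 * d12 * d12 * p.sigma2_sq
        + p.piC * (p.sigmaC1_sq + d12 * d12 * p.sigmaC2_sq + 2.0 * d12 * r)
    )
    var2 = (
        p.pi1 * d21 * d21 * p.sigma1_sq
        + p.pi2 * p.sigma2_sq
        + p.piC * (p.sigmaC2_sq + d21 * d21 * p.sigmaC1_sq + 2.0 * d21 * r)
    )
    if var1 <= 0.0 or var2 <= 0.0:
        raise ValueError("genetic variance is zero for at least one trait")
    rg = num / math.sqrt(var1 * var2)
    return float(np.clip(rg, -1.0, 1.0))


def rg_variance(params: ModelParams, param_cov: np.ndarray, free_names,
                h: float = 1e-5) -> float:
    """Delta-method variance of the genetic correlation.

    ``param_cov`` is the (natural-scale) covariance of the free parameters
    listed in ``free_names``; the gradient is a central difference with a
    relative step ``h``.
    """
    free_names = tuple(free_names)
    g = np.zeros(len(free_names))
    for j, name in enumerate(free_names):
        v = getattr(params, name)
        step = h * max(abs(v), 1e-3)
        up = genetic_correlation(params.replace(**{name: v + step}))
        dn = genetic_correlation(params.replace(**{name: v - step}))
        g[j] = (up - dn) / (2.0 * step)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient in rg_variance")
    return float(g @ param_cov @ g)
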